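import itertools

import numpy as np
import pytest

import pbclus as pb

from conftest import planted_blocks


def stress_bruteforce(M, mode):
    M = np.asarray(M, dtype=float)
    n, m = M.shape
    if mode == "moore":
        offs = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    else:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    total = 0.0
    for i in range(n):
        for j in range(m):
            for di, dj in offs:
                k, l = i + di, j + dj
                if 0 <= k < n and 0 <= l < m:
                    total += (M[i, j] - M[k, l]) ** 2
    return total


def rate_bruteforce(counts):
    """Oracle: exhaustive injective assignment of the smaller side."""
    counts = np.asarray(counts)
    r, c = counts.shape
    best = 0
    if r <= c:
        for perm in itertools.permutations(range(c), r):
            best = max(best, sum(counts[i, perm[i]] for i in range(r)))
    else:
        for perm in itertools.permutations(range(r), c):
            best = max(best, sum(counts[perm[j], j] for j in range(c)))
    return best / counts.sum()


class TestStress:
    def test_constant_matrix_is_zero(self):
        m = np.full((5, 5), 3.0)
        assert pb.stress(m, "moore") == 0.0
        assert pb.stress(m, "neumann") == 0.0

    def test_two_by_two_neumann(self):
        assert pb.stress(np.array([[0.0, 1.0], [1.0, 0.0]]), "neumann") == pytest.approx(8.0)

    @pytest.mark.parametrize("mode", ["moore", "neumann"])
    def test_matches_bruteforce(self, mode, rng):
        for _ in range(5):
            m = rng.random((6, 6))
            assert pb.stress(m, mode) == pytest.approx(stress_bruteforce(m, mode))

    @pytest.mark.parametrize("mode", ["moore", "neumann"])
    def test_seriated_blocks_below_shuffled(self, mode, rng):
        m = planted_blocks([5, 5]).astype(float)
        p = rng.permutation(10)
        shuffled = m[np.ix_(p, p)]
        assert pb.stress(m, mode) < pb.stress(shuffled, mode)


class TestFisherIndex:
    @staticmethod
    def _partition(labels):
        ids = [str(i + 1) for i in range(len(labels))]
        return pb.Partition(labels=dict(zip(ids, labels)), K=len(set(labels)))

    def test_singleton_clusters_give_zero(self):
        X = pb.FeatureTable(values=[[0.0, 0.0], [1.0, 1.0]])
        part = self._partition([1, 2])
        assert pb.fisher_index(X, part) == pytest.approx(0.0)

    def test_single_cluster_is_error(self):
        X = pb.FeatureTable(values=[[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError):
            pb.fisher_index(X, self._partition([1, 1, 1]))

    def test_six_point_configuration_matches_hand_expansion(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [5, 5], [6, 5], [5, 6]], dtype=float)
        X = pb.FeatureTable(values=pts)
        part = self._partition([1, 1, 1, 2, 2, 2])
        # independent scatter computation
        g1, g2 = pts[:3], pts[3:]
        m1, m2 = g1.mean(0), g2.mean(0)
        grand = pts.mean(0)
        sw = sum(np.outer(x - m1, x - m1) for x in g1) + \
             sum(np.outer(x - m2, x - m2) for x in g2)
        sb = 3 * np.outer(m1 - grand, m1 - grand) + 3 * np.outer(m2 - grand, m2 - grand)
        expected = np.trace(sw) / np.trace(sb)
        assert pb.fisher_index(X, part) == pytest.approx(expected)

    def test_translation_and_scale_invariance(self, rng):
        pts = rng.normal(size=(12, 3))
        labels = [1] * 6 + [2] * 6
        base = pb.fisher_index(pb.FeatureTable(values=pts), self._partition(labels))
        shifted = pb.fisher_index(pb.FeatureTable(values=pts + 7.5), self._partition(labels))
        scaled = pb.fisher_index(pb.FeatureTable(values=3.0 * pts), self._partition(labels))
        assert shifted == pytest.approx(base)
        assert scaled == pytest.approx(base)

    def test_ousted_points_excluded(self):
        pts = np.array([[0, 0], [0.1, 0], [5, 5], [5.1, 5], [100, 100]], dtype=float)
        X = pb.FeatureTable(values=pts)
        labels = dict(zip(X.row_ids, [1, 1, 2, 2, pb.OUSTED]))
        part = pb.Partition(labels=labels, K=2)
        clean = pb.fisher_index(pb.FeatureTable(values=pts[:4]),
                                self._partition([1, 1, 2, 2]))
        assert pb.fisher_index(X, part) == pytest.approx(clean)


class TestClassificationRate:
    def test_printed_benchmark_tables(self):
        township = pb.ContingencyTable(counts=[[8, 0, 0, 0],
                                               [0, 4, 0, 0],
                                               [0, 0, 2, 0],
                                               [0, 1, 0, 1]])
        assert round(pb.classification_rate(township), 2) == 0.94

        ruspini = pb.ContingencyTable(counts=np.diag([50, 35, 15, 20]))
        assert pb.classification_rate(ruspini) == pytest.approx(1.0)

        geysers = pb.ContingencyTable(counts=[[88, 2, 7], [0, 105, 0], [0, 0, 97]])
        assert round(pb.classification_rate(geysers), 2) == 0.97

        channel2 = pb.ContingencyTable(counts=[[214, 0], [0, 79]])
        assert pb.classification_rate(channel2) == pytest.approx(1.0)

        channel2_mda = pb.ContingencyTable(counts=[[515, 2], [5, 277]])
        assert round(100 * pb.classification_rate(channel2_mda), 2) == 99.12

    def test_invariant_under_row_and_column_permutation(self, rng):
        counts = rng.integers(0, 50, size=(4, 5))
        base = pb.classification_rate(pb.ContingencyTable(counts=counts))
        p, q = rng.permutation(4), rng.permutation(5)
        permuted = pb.ContingencyTable(counts=counts[np.ix_(p, q)])
        assert pb.classification_rate(permuted) == pytest.approx(base)

    def test_matches_exhaustive_assignment_oracle(self, rng):
        for _ in range(20):
            r = int(rng.integers(1, 5))
            c = int(rng.integers(1, 6))
            counts = rng.integers(0, 30, size=(r, c))
            if counts.sum() == 0:
                counts[0, 0] = 1
            table = pb.ContingencyTable(counts=counts)
            assert pb.classification_rate(table) == pytest.approx(rate_bruteforce(counts))

    def test_contingency_builder_drops_ousted(self):
        ref = [1, 1, 2, 2, 2]
        pred = [1, pb.OUSTED, 2, 2, 2]
        table = pb.contingency_table(ref, pred)
        assert table.counts.sum() == 4
        assert pb.classification_rate(table) == pytest.approx(1.0)
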