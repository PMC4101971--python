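import math

import numpy as np
import pytest

import pbclus as pb

from conftest import planted_blocks, random_symmetric_binary


def rle_transitions(row):
    """Oracle: number of runs minus one, via run-length encoding."""
    runs = 1
    for a, b in zip(row, row[1:]):
        if a != b:
            runs += 1
    return runs - 1


class TestAlternationCount:
    @pytest.mark.parametrize(
        "row, expected",
        [("100100", 3), ("0101", 3), ("000000", 0), ("111111", 0)],
    )
    def test_single_rows(self, row, expected):
        m = np.array([[int(c) for c in row]])
        assert pb.alternation_count(m) == expected

    def test_worked_example_totals(self, table2):
        assert pb.alternation_count(table2.binary[1]) == 17
        assert pb.alternation_count(table2.binary[2]) == 15
        assert pb.alternation_count(table2.sorted[1]) == 9
        assert pb.alternation_count(table2.sorted[2]) == 8
        assert pb.alternation_count(table2.sorted[3]) == 3

    def test_row_permutation_invariant_column_permutation_not(self, rng):
        m = random_symmetric_binary(rng, 9, density=0.4)
        base = pb.alternation_count(m)
        p = rng.permutation(9)
        assert pb.alternation_count(m[p, :]) == base
        changed = False
        for _ in range(20):
            q = rng.permutation(9)
            if pb.alternation_count(m[:, q]) != base:
                changed = True
                break
        assert changed


class TestCompactnessRatio:
    def test_worked_example_printed_values(self, table2):
        res = pb.reorder(table2.binary[2])
        assert pb.compactness_ratio(table2.binary[2], res) == pytest.approx(15 / 8)
        # level-1 printed pair evaluates via the pair scorer
        _, ratios = pb.select_from_pairs(
            {lam: (table2.binary[lam], table2.sorted[lam]) for lam in (1, 2)}
        )
        assert round(ratios[1], 2) == 1.89
        assert round(ratios[2], 2) == 1.88

    def test_identity_ordering_gives_ratio_one(self, rng):
        m = random_symmetric_binary(rng, 6, density=0.5)
        identity = pb.OrderingResult(
            permutation=pb.Permutation(order=list(range(6)), ousted=[]),
            ordered=m, objective=0.0, consecutive=np.ones(5),
        )
        assert pb.compactness_ratio(m, identity) == pytest.approx(1.0)

    def test_greedy_ratio_dominates_identity_when_it_compacts(self, rng):
        # monotone in the ordered alternation count
        for _ in range(10):
            m = random_symmetric_binary(rng, 8, density=0.4)
            res = pb.reorder(m)
            identity = pb.OrderingResult(
                permutation=pb.Permutation(order=list(range(8)), ousted=[]),
                ordered=m, objective=0.0, consecutive=np.ones(7),
            )
            if pb.alternation_count(res.ordered) < pb.alternation_count(m):
                assert pb.compactness_ratio(m, res) > pb.compactness_ratio(m, identity)

    def test_as_printed_is_reciprocal(self, table2):
        res = pb.reorder(table2.binary[2])
        c = pb.compactness_ratio(table2.binary[2], res)
        cp = pb.compactness_ratio(table2.binary[2], res, as_printed=True)
        assert c * cp == pytest.approx(1.0)

    def test_degenerate_perfect_ordering_sentinel(self):
        m = planted_blocks([3])  # all-ones: zero alternations anywhere
        res = pb.reorder(m)
        with pytest.raises(ValueError):
            pb.compactness_ratio(m, res)


class TestRunCriterion:
    def test_single_row_contributions(self):
        rows = {"111000": 1 / 3, "0101": 3 / 2}
        for row, expected in rows.items():
            vec = [int(c) for c in row]
            n = len(vec)
            m = np.array([vec] * n)  # every row identical
            res = pb.OrderingResult(
                permutation=pb.Permutation(order=list(range(n)), ousted=[]),
                ordered=m, objective=0.0, consecutive=np.ones(n - 1),
            )
            assert pb.run_criterion(res) == pytest.approx(n * expected)

    def test_matches_rle_oracle_on_random_rows(self, rng):
        m = random_symmetric_binary(rng, 8, density=0.5)
        res = pb.reorder(m)
        block = res.retained_block()
        expected = sum(
            rle_transitions(row.tolist())
            / max(min(int((row == 0).sum()), int((row == 1).sum())), 1)
            for row in block
        )
        assert pb.run_criterion(res) == pytest.approx(expected)

    def test_block_structure_beats_shuffled(self, rng):
        m = planted_blocks([4, 4])
        res = pb.reorder(m)
        p = np.array([0, 4, 1, 5, 2, 6, 3, 7])
        shuffled = m[np.ix_(p, p)]
        res_bad = pb.OrderingResult(
            permutation=pb.Permutation(order=list(range(8)), ousted=[]),
            ordered=shuffled, objective=0.0, consecutive=np.ones(7),
        )
        assert pb.run_criterion(res) < pb.run_criterion(res_bad)


class TestSelectLevel:
    def test_worked_example_printed_pairs_select_level_two(self, table2):
        lam, ratios = pb.select_from_pairs(
            {lam: (table2.binary[lam], table2.sorted[lam]) for lam in (1, 2, 3)}
        )
        assert lam == 2
        assert ratios[1] > ratios[2]

    def test_single_level_family(self, table2):
        fam = pb.ParsimonyFamily(levels=[2], matrices={2: table2.binary[2]})
        lam, res = pb.select_level(fam)
        assert lam == 2
        assert res.permutation.ousted == [1]

    def test_three_separated_clusters_give_three_blocks(self):
        cov = 0.01 * np.eye(2)
        spec = pb.MixtureSpec(
            components=[((-0.4, -0.3), cov, 30), ((0.4, -0.3), cov, 30),
                        ((0.0, 0.3), cov, 30)],
            seed=7,
        )
        X, _ = pb.gen_mixture(spec)
        D = pb.compute_dissimilarity(X)
        B = pb.common_neighbor_counts(pb.build_adjacency(D))
        fam = pb.build_family(B)
        lam, res = pb.select_level(fam, criterion="compression")
        part = pb.extract_partition(res, pb.find_breakpoints(res.consecutive),
                                    ids=X.row_ids)
        assert part.K == 3

    def test_all_levels_degenerate_raises(self):
        fam = pb.ParsimonyFamily(levels=[1], matrices={1: np.ones((3, 3), dtype=int)})
        with pytest.raises(ValueError, match="degenerate"):
            pb.select_level(fam, criterion="compactness")


def test_scan_reports_both_criteria(table2):
    fam = pb.build_family(table2.B, levels=[1, 2])
    scores, orderings = pb.scan_levels(fam)
    assert [s.level for s in scores] == [1, 2]
    for s in scores:
        assert s.c == pytest.approx(1.0 / s.compression)
        assert s.run_value >= 0
        assert s.level in orderings
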