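"""Synthetic data generators emulating the method's study conditions.

Three families of inputs are covered:

- 2-d/4-d Gaussian mixtures with controllable overlap and imbalance, with
  optional contamination by uniform noise in a hypercube (either replacing a
  fraction of the sample or adding extra points on top of it);
- an overlap series of three Gaussian components whose means slide from a
  fully separated configuration toward complete superposition;
- template-based extracellular spike waveforms: 32-sample biphasic shapes
  (negative trough then positive peak), amplitude-jittered, noise-corrupted
  and per-waveform normalized.

A small worked-example fixture of common-neighbor matrices (stored exactly
as printed in the source worked example, including its known typographical
quirks — in particular it is not exactly symmetric) is also provided for
tests and demos.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neighborhood import CommonNeighborMatrix, FeatureTable

__all__ = [
    "NOISE",
    "MixtureSpec",
    "SpikeSimSpec",
    "gen_mixture",
    "add_uniform_noise",
    "gen_overlap_series",
    "gen_spikes",
    "spike_templates",
    "table2_fixture",
    "Table2Fixture",
]

#: ground-truth label for uniform-noise contamination points
NOISE = "NOISE"


@dataclass
class MixtureSpec:
    """A Gaussian mixture with optional uniform-noise replacement.

    ``components`` is a list of (mean, covariance, count) triples.
    ``noise_fraction`` in [0, 1) is the fraction of the total sample whose
    coordinates are replaced by uniform draws in ``noise_box`` (labelled
    NOISE); use :func:`add_uniform_noise` to append noise on top of the
    sample instead.
    """

    components: list[tuple]
    noise_fraction: float = 0.0
    noise_box: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        if not 0 <= self.noise_fraction < 1:
            raise ValueError("noise_fraction must be in [0, 1)")
        dims = set()
        for mean, cov, count in self.components:
            mean = np.asarray(mean, dtype=float)
            cov = np.asarray(cov, dtype=float)
            if count < 1:
                raise ValueError("component counts must be >= 1")
            if cov.shape != (mean.size, mean.size):
                raise ValueError("covariance shape does not match mean dimension")
            if (np.linalg.eigvalsh((cov + cov.T) / 2) < -1e-10).any():
                raise ValueError("covariance must be positive semidefinite")
            dims.add(mean.size)
        if len(dims) != 1:
            raise ValueError("all components must share one dimension")
        self.dimension = dims.pop()


def gen_mixture(spec: MixtureSpec) -> tuple[FeatureTable, list]:
    """Draw a labelled sample from a Gaussian mixture spec.

    Component sizes are exact as specified. When ``noise_fraction`` > 0,
    round(fraction * n) points chosen at random are replaced by uniform
    draws in the noise hypercube and labelled NOISE. Rows are emitted in a
    random arrival order by default (``shuffle=True``), as real recordings
    are; labels stay aligned with rows. Reproducible given the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    chunks, labels = [], []
    for k, (mean, cov, count) in enumerate(spec.components, start=1):
        chunks.append(rng.multivariate_normal(np.asarray(mean, float),
                                              np.asarray(cov, float), size=count))
        labels.extend([k] * count)
    x = np.vstack(chunks)
    labels = list(labels)
    n = x.shape[0]
    n_noise = int(round(spec.noise_fraction * n))
    if n_noise:
        lo, hi = spec.noise_box
        idx = rng.choice(n, size=n_noise, replace=False)
        x[idx] = rng.uniform(lo, hi, size=(n_noise, spec.dimension))
        for i in idx:
            labels[i] = NOISE
    if spec.shuffle:
        perm = rng.permutation(n)
        x = x[perm]
        labels = [labels[i] for i in perm]
    return FeatureTable(values=x), labels


def add_uniform_noise(
    table: FeatureTable,
    labels: list,
    ratio: float,
    box: tuple[float, float] = (-1.0, 1.0),
    seed: int = 0,
    shuffle: bool = True,
) -> tuple[FeatureTable, list]:
    """Append round(ratio * n) uniform-noise points to an existing sample.

    ``ratio`` is relative to the current sample size and may exceed 1
    (e.g. 2.0 adds twice as many noise points as there are data points).
    By default the contaminated sample is returned in a random arrival
    order (labels stay aligned).
    """
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    rng = np.random.default_rng(seed)
    n, p = table.values.shape
    n_noise = int(round(ratio * n))
    lo, hi = box
    noise = rng.uniform(lo, hi, size=(n_noise, p))
    values = np.vstack([table.values, noise])
    out_labels = list(labels) + [NOISE] * n_noise
    if shuffle:
        perm = rng.permutation(values.shape[0])
        values = values[perm]
        out_labels = [out_labels[i] for i in perm]
    return FeatureTable(values=values), out_labels


def gen_overlap_series(
    x: float,
    y: float,
    n_per_cluster: int = 50,
    sigma: float = 0.03,
    seed: int = 0,
) -> tuple[FeatureTable, list]:
    """Three isotropic Gaussians whose overlap is steered by (x, y).

    Means are m1 = (x, y), m2 = (x, −y), m3 = (0, −y), each with covariance
    sigma² I. (x, y) = (0.30, 0.225) is the fully separated end of the
    series and (0, 0) complete superposition. The default spread
    sigma = 0.03 makes the separated end genuinely separated (the closest
    pair of means, 0.3 apart, sits 10 sigma apart).
    """
    if x < 0 or y < 0:
        raise ValueError("x and y must be non-negative")
    means = [(x, y), (x, -y), (0.0, -y)]
    cov = (sigma ** 2) * np.eye(2)
    spec = MixtureSpec(
        components=[(m, cov, n_per_cluster) for m in means], seed=seed
    )
    return gen_mixture(spec)


@dataclass
class SpikeSimSpec:
    """Template-based extracellular spike waveform simulation.

    Each waveform is template × (1 + jitter·z) + noise_sd·ε with z, ε
    standard normal, then normalized to unit L2 norm — emulating normalized
    spike snippets of ``waveform_length`` samples (default 32) from 1–4
    putative neurons with distinct biphasic shapes.
    """

    n_templates: int = 2
    counts: tuple = (214, 79)
    waveform_length: int = 32
    amplitude_jitter: float = 0.1
    noise_sd: float = 0.02
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.n_templates <= 4:
            raise ValueError("n_templates must be in 1..4")
        if len(self.counts) != self.n_templates:
            raise ValueError("counts must list one size per template")
        if any(c < 1 for c in self.counts):
            raise ValueError("counts must be >= 1")
        if self.waveform_length < 4:
            raise ValueError("waveform too short")


def spike_templates(n_templates: int = 4, length: int = 32) -> np.ndarray:
    """Distinct canonical biphasic spike shapes (trough then peak).

    Each template is a sum of a negative and a positive Gaussian bump with
    per-template trough depth, peak latency and widths, unit-normalized.
    """
    t = np.arange(length, dtype=float)
    # (trough depth, trough pos frac, trough width, peak height, peak pos frac, peak width)
    params = [
        (-1.0, 0.28, 0.055, 0.55, 0.55, 0.12),
        (-1.0, 0.35, 0.10, 0.35, 0.70, 0.18),
        (-0.6, 0.25, 0.04, 0.90, 0.45, 0.08),
        (-1.0, 0.45, 0.07, 0.25, 0.80, 0.25),
    ][:n_templates]
    out = []
    for depth, tp, tw, height, pp, pw in params:
        shape = depth * np.exp(-((t - tp * length) ** 2) / (2 * (tw * length) ** 2))
        shape += height * np.exp(-((t - pp * length) ** 2) / (2 * (pw * length) ** 2))
        out.append(shape / np.linalg.norm(shape))
    return np.array(out)


def gen_spikes(spec: SpikeSimSpec) -> tuple[FeatureTable, list]:
    """Simulate labelled, per-waveform-normalized spike snippets."""
    rng = np.random.default_rng(spec.seed)
    templates = spike_templates(spec.n_templates, spec.waveform_length)
    rows, labels = [], []
    for k, count in enumerate(spec.counts, start=1):
        base = templates[k - 1]
        gains = 1.0 + spec.amplitude_jitter * rng.standard_normal(count)
        noise = spec.noise_sd * rng.standard_normal((count, spec.waveform_length))
        wf = gains[:, None] * base[None, :] + noise
        wf /= np.linalg.norm(wf, axis=1, keepdims=True)
        rows.append(wf)
        labels.extend([k] * count)
    values = np.vstack(rows)
    if spec.shuffle:
        perm = rng.permutation(values.shape[0])
        values = values[perm]
        labels = [labels[i] for i in perm]
    return FeatureTable(values=values), labels


@dataclass
class Table2Fixture:
    """The printed worked-example matrices: raw counts, per-level binaries
    and per-level sorted (seriated) forms, stored exactly as printed."""

    B: CommonNeighborMatrix
    binary: dict[int, np.ndarray]
    sorted: dict[int, np.ndarray]


def _rows(*strings: str) -> np.ndarray:
    return np.array([[int(ch) for ch in s] for s in strings], dtype=np.int64)


def table2_fixture() -> Table2Fixture:
    """6-observation worked example with three parsimony levels.

    The raw count matrix is asymmetric as printed (entry (1,4)=3 vs
    (4,1)=2), which a true Gram matrix cannot produce; it is kept verbatim
    so the printed per-level binaries and sorted matrices can be reproduced.
    """
    b = _rows("200300", "010000", "003033", "200300", "003033", "003033")
    binary = {
        1: _rows("100100", "010000", "001011", "100100", "001011", "001011"),
        2: _rows("100100", "000000", "001011", "100100", "001011", "001011"),
        3: _rows("100100", "000000", "001011", "100000", "001011", "001011"),
    }
    sorted_ = {
        1: _rows("110000", "110000", "001110", "001110", "001110", "000001"),
        2: _rows("110000", "110000", "001110", "001110", "001110", "000000"),
        3: _rows("111000", "111000", "111000", "000000", "000000", "000000"),
    }
    return Table2Fixture(B=CommonNeighborMatrix(b=b), binary=binary, sorted=sorted_)
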