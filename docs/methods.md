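# Methods

## Model and assumptions

`pbclus` assumes that cluster structure in a dataset expresses itself as
*shared neighborhoods*: two observations belong together when many other
observations are close to both. The pipeline converts a dissimilarity
matrix into a one-parameter family of binary "at least λ common
ε-neighbors" matrices, seriates each into block-diagonal form, and selects
the sparsity level whose seriated matrix is most compact. Because
membership is driven by neighborhood overlap rather than centroid distance,
the method handles elongated (non-spherical) and imbalanced clusters, and
contamination is removed structurally: a noise point shares few neighbors
with anything, so its column empties ("ousted") as λ grows instead of
distorting a cluster.

The approach is deterministic: every tie in the seriation (seed choice,
chain attachment, component order) is broken on the smallest original
index, so a given input always yields the same output.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `metric` | `euclidean` | dissimilarity between observations; `pnorm(p)`, `correlation`, `spearman`, `maximum` also supported. Euclidean is the working choice for normalized spike waveforms; rank/extremum metrics did not change the structure in our runs. |
| `quantile` | 0.25 | distance quantile defining ε when not set explicitly; the first quartile makes roughly a quarter of all pairs neighbors, enough for within-cluster pairs to dominate at moderate cluster counts. Linear interpolation on the sorted off-diagonal multiset (i < j, no self-distances). |
| `epsilon` | unset | explicit neighborhood radius, overrides the quantile. Boundary distances d = ε count as neighbors. |
| `levels` | `auto` | parsimony scan 1 … max off-diagonal common-neighbor count; beyond the top everything is ousted. |
| `criterion` | `compression` (pipeline) | level selector; see below. |
| `strong_threshold` | 0.5 | Tanimoto level that counts as "strongly correlated" when choosing each component's seed column (the chain is grown from the member with the most strong neighbors). The similarity is ≥ ½ when two columns share at least half their union. |
| `tau` | 0.0 | rupture threshold on consecutive Tanimoto similarities. 0 cuts only at exact disconnection — correct for separated clusters. For contaminated or overlapping data, retained noise can leave weak bridges between blocks; there we cut at `tau = 0.5`, the same level as `strong_threshold` (adjacent columns sharing less than half their neighborhoods do not belong to one block). Raising `tau` can only split segments, never merge them. |

## Binarization details

Each entry of the common-neighbor matrix, diagonal included, is thresholded
at b_ij ≥ λ; the diagonal is then forced to 1 in any row that keeps at
least one off-diagonal 1 (a retained observation is always its own
neighbor, even when its raw self-count sits below the level). A row left
all-zero is ousted at that level. This rule reproduces the package's
six-observation worked example at every self-consistent printed cell; the
worked example's raw count matrix is stored verbatim even though it is not
exactly symmetric (a Gram matrix cannot produce it — two cells are
evidently misprinted), and the symmetry invariant is waived for that
fixture alone.

## Level selection

Three scores are computed for every non-empty level and logged in the scan
report:

- **compactness** — unordered/ordered row-alternation totals. This is the
  worked-example convention: its values on the printed example are
  17/9 ≈ 1.89, 15/8 ≈ 1.88, and its argmin retains level 2 there. As a
  *selector* on real scans it is degenerate: the top of the scan always
  retains a few identical columns, and on input in arbitrary row order the
  unordered total collapses with the retained mass, so the ratio decreases
  monotonically toward maximal sparsity (measured profiles fall from ≈ 42
  to ≈ 7.6 across a clean three-cluster scan, always electing the level
  that ousts almost everything).
- **compression** — the reciprocal, ordered/unordered: the fraction of raw
  alternation mass that survives seriation. Its argmin sits where
  reordering achieves the most relative compaction, i.e. where real block
  structure exists; it shows the interior minimum along the scan that one
  expects from a compactness criterion, and it is the pipeline default.
- **run** — per retained row of the seriated matrix, the number of 0↔1
  transitions divided by min(#zeros, #ones) (floored at 1), summed over
  rows. The pair-count variant of the denominator (min of adjacent 0,0 and
  1,1 pair counts) is available as a switch. Useful as a cross-check; its
  tail can also dip on near-degenerate levels, so it is not the default.

Entirely-zero levels are skipped; a level whose seriated matrix has no
alternations at all cannot be scored by the ratios and is skipped too;
ties go to the smallest λ.

## Seriation

Within the retained columns, connected components of the support-overlap
graph (Tanimoto > 0) are found; any column outside a component is exactly
orthogonal to it, so components can be ordered freely — we emit them by
smallest member index for determinism. Inside a component the chain grows
greedily from the seed, always appending the unplaced column most similar
to the *last placed* one. The greedy objective (sum of consecutive
Tanimoto similarities) is bounded by the exhaustive optimum and attains it
on block-diagonal inputs with identical within-block columns; on general
inputs it is a heuristic, and because Tanimoto values of binary vectors tie
frequently, relabeling the input can change the chain (and its alternation
total) through the index tie-break — the objective is only guaranteed
invariant on tie-free or exact-block structures. Ousted columns are
appended after all components, matching the all-zero border rows of a
printed seriated matrix, and are never interleaved.

## Synthetic data

The generators emulate the study conditions end to end:

- **Gaussian mixtures** (`gen_mixture`): exact per-component counts,
  arbitrary dimension, optional replacement of a fraction of points by
  uniform noise in a hypercube ([−1,1]^d by default); `add_uniform_noise`
  instead appends noise on top of a sample, with ratios above 1 allowed
  (e.g. 100–200 % contamination sweeps). The three-cluster reference
  configuration uses means (−0.4,−0.3), (0.4,−0.3), (0,0.3) with isotropic
  σ = 0.1 per axis, 50 points each — the "voluntarily separated" regime
  (pairwise mean separations of 6–8 σ). We read the stated diagonal
  dispersion values as per-axis standard deviations: taken as variances
  they would put the components 1–1.3 σ apart, i.e. heavily overlapped,
  contradicting the separated-groups description these runs require.
- **Overlap series** (`gen_overlap_series`): three isotropic components at
  m1 = (x, y), m2 = (x, −y), m3 = (0, −y); (0.30, 0.225) is the fully
  separated end, (0, 0) complete superposition. The component spread is a
  free parameter; the default σ = 0.03 is chosen so the designated
  separated end is in fact separated (closest means 10 σ apart) — at
  σ ≥ 0.05 the nearest pair of grid means is ≤ 6 σ apart and the
  endpoint contradicts its own description. Only the qualitative trend
  (recovery degrades as the means collapse) is asserted, not specific
  rates, since the true spread behind the printed rate table is unstated.
- **Spike waveforms** (`gen_spikes`): 1–4 distinct biphasic templates
  (negative trough, positive peak, per-template widths and latencies) of 32
  samples, each waveform amplitude-jittered (×(1 + 0.1 z)), noise-corrupted
  (σ = 0.02 per sample) and then normalized to unit L2 norm, emulating
  normalized spike snippets. The reference two-unit condition uses counts
  (214, 79).

All generators shuffle the row order by default (labels stay aligned):
real observations arrive in arbitrary order, and the alternation-normalized
selection criteria are meaningless on input pre-sorted by component (the
unordered matrix is then already block-diagonal). Same seed ⇒ bit-identical
output.

What the generators do **not** emulate: raw voltage traces, spike
detection/alignment jitter, electrode drift, overlapping (superimposed)
spikes, or non-Gaussian cluster shapes. A passing recovery test therefore
shows the pipeline works when the waveform-similarity structure is clean;
it does not certify performance on recordings where detection artifacts
dominate.

## Numerical choices and degenerate inputs

- Tanimoto of two all-zero vectors is undefined and raises; all-zero
  columns are removed (ousted) before any similarity is computed.
- The quantile uses linear interpolation; ε at quantile 1.0 yields the
  complete graph and a constant common-neighbor matrix.
- The compactness ratio returns +inf (sentinel) when the seriated matrix
  has zero alternations but the raw one does not.
- Fisher index: the within/between scatter ratio is reduced to a scalar by
  the trace ratio (the standard criterion); the determinant ratio is an
  option. It requires K ≥ 2 and distinct cluster means; ousted points are
  excluded.
- Classification rate: the cluster-to-class matching is solved exactly by
  the Hungarian algorithm for any table size; the total includes every
  table entry (for live partitions, ousted observations are excluded
  before tabulation). Report rounding is half-up at the printed precision.
- Dissimilarity input is validated symmetric to 1e−9 and averaged with its
  transpose to squash float asymmetry.

## Problem sizes

The shipped tests and acceptance runs use 90–300 observations (150-point
three-cluster runs, 210-point 30 %-contamination runs, 300-point
equal-noise runs, 293 spike waveforms) and exhaustive permutation oracles
at n ≤ 6 — the regime the method targets (a few hundred spikes per
channel); the scan is quadratic in n per level and linear in the number of
levels.

## Known limitations

- The greedy chain can split one true cluster across two blocks when a
  bridge point sits between clusters at low λ; small samples (≤ 30 per
  cluster) occasionally merge two clusters at the selected level.
- With heavy uniform contamination the selected level retains some noise
  points inside cluster blocks; they are labelled with the cluster they
  attach to (the rate on true points is unaffected, but cluster sizes are
  inflated).
- The compactness/compression criteria compare alternation totals, so they
  are only meaningful when the input row order carries no block structure
  of its own — hence the generators' shuffling, and caution when data
  arrive pre-sorted.
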