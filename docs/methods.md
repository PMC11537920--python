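# Methods

This note records the model, the numerical conventions, and the design
choices behind `eegtopo`, in the order the pipeline runs.

## Signal model and preprocessing

A recording is a channels × samples matrix in microvolts with a sampling
rate `fs` (EDF input via MNE, or plain CSV with a channel-name header
row).  Band decomposition uses a 4th-order Butterworth band-pass applied
forward and backward (`sosfiltfilt`), so the filter is zero phase, output
length equals input length, and the effective attenuation slope is twice
the one-way design — comfortably more than 20 dB one octave beyond each
band edge (verified against the designed frequency response in the test
suite).  The clinical band table is delta 1–3, theta 4–7, alpha 8–12,
beta 13–30, gamma 31–49 Hz; it is configuration, not code.

Time is 0-based and windows are half-open `[start, end)` seconds, so
adjacent segments never share a sample.  The default analysis window is
(126, 150) s, a configuration default chosen to match common practice of
picking a single informative resting-state stretch; note that a 24-second
window is inconsistent with a 40-second segmentation grid, so the window
is deliberately a free parameter rather than hard-wired.  Segmentation
into fixed-length windows (`segment_windows`) yields
`⌊(duration − length)/stride⌋ + 1` segments, non-overlapping when
`stride = length`.

## Connectivity

The dissimilarity is `D_ij = 1 − |r_ij|` with `r` the sample Pearson
correlation over the window; the absolute value makes strong
anticorrelation as "close" as strong correlation.  The matrix is clamped
into [0, 1] after rounding and symmetrized at machine precision.  `D` is a
bounded dissimilarity, not necessarily a metric; the Vietoris–Rips
construction does not require the triangle inequality.  A channel that is
constant over the window has undefined correlation and is reported as an
error rather than silently imputed.

## Persistent homology

The filtration runs on `[0, max_ij D_ij]`: past the largest off-diagonal
entry every edge (and hence every triangle of the flag complex) is
present, so the complex provably stops changing there — this
operationalizes the "stop when the complex stops changing" rule without a
tunable cutoff.

The production reduction (`vr_persistence`) computes:

* **H0** by Kruskal union-find over edges sorted by (weight, i, j).  Every
  tree edge kills a component, so finite dim-0 deaths are exactly the MST
  edge weights; all dim-0 births are 0 and exactly one essential class
  remains.
* **H1** by column reduction of the triangle boundary matrix over GF(2),
  edges indexed in filtration order, triangles filtered by the maximum of
  their edge values.  A reduced triangle column with pivot edge `e` kills
  the cycle born at `e`'s filtration value.

Simplices with equal filtration value are ordered by (value, dimension,
lexicographic vertex tuple), making the reduction deterministic.
Zero-lifetime H1 pairs (a cycle filled the instant it closes, as in any
triangle) are dropped; dim-0 pairs are all kept, including zero-lifetime
ones, so the number of dim-0 pairs always equals the number of channels.
Essential classes are excluded from every downstream vectorization and
from the cycle analysis, uniformly.

`brute_force_persistence` is an intentionally naive, independent oracle:
enumerate every simplex up to dimension 2, build the full boundary matrix,
run the textbook left-to-right reduction, guard at n ≤ 12.  The two routes
share output conventions only; agreement is exact multiset equality and is
exercised on hundreds of random matrices.

## Vectorization

All curve/raster features share one grid per diagram: `n_bins` (default
100) evenly spaced points from the minimum birth to the maximum finite
death, both homology dimensions pooled, so the 22 features of one diagram
are sampled consistently.  Degenerate diagrams (no finite pairs) produce
zero features.

* **Landscape** λ_k(t): k-th largest tent `max(min(t − b, d − t), 0)`,
  evaluated directly at each grid point (O(pairs × bins) with a sort);
  layers are pointwise non-increasing by construction.
* **Betti curve**: count of pairs with `b ≤ t < d`.
* **Heat kernel**: sum over pairs of an isotropic Gaussian at (b, d) minus
  its mirror at (d, b), sampled on grid × grid; antisymmetric across the
  diagonal.  The bandwidths σ ∈ {1.6, 3.2} are in *grid-pixel* units,
  converted to filtration units as σ·Δt.  Correlation-distance filtrations
  span at most 1.0, so a σ of 1.6–3.2 filtration units would smooth the
  whole diagram into nothing; pixel units are the only non-degenerate
  reading of bandwidths of that magnitude, and they track the diagram's
  own scale.
* **Persistence entropy**: natural-log Shannon entropy of lifetimes
  normalized by total persistence; a single pair gives 0, equal lifetimes
  give ln n, and the value is invariant to rescaling the filtration.  The
  log base is a global constant factor; natural log is used throughout.

Amplitudes are Riemann approximations of function-space L_p norms: the
summed |v|^p is weighted by Δt for curves and layer stacks and by Δt² for
rasters before the 1/p power.  The canonical 22-vector (per band, with
the band index appended as a 23rd column) is frozen as: 8 landscape
amplitudes (p ∈ {1,2} × layers ∈ {1,2} × H0/H1), 4 Betti amplitudes
(p × dim), 8 heat amplitudes (p × σ × dim), 2 entropies (dim).

## Synthetic cohorts

The generator plants a *correlation ring*: each ring position carries a
unit-variance Gaussian source, zero-phase band-limited to the carrier band
(default 1–49 Hz, the full delta-through-gamma range, so the planted
structure is visible in every band-filtered view, as resting-EEG effects
typically are).  Each ring channel mixes its neighborhood's sources with a
circular Gaussian kernel whose width is solved by bisection so that the
*adjacent*-channel correlation equals `coupling` (default 0.8) after
accounting for independent sensor noise (`noise_sd`, default 0.3 relative
to unit signal variance).  A strict ring covariance — coupling on adjacent
pairs, zero elsewhere — is not positive semi-definite once coupling
exceeds 0.5, so correlation necessarily decays smoothly with ring lag;
that smooth decay is precisely the ring geometry that yields one dominant
H1 class in the filtration.  Channels on no ring are independent
band-limited noise.  Everything is deterministic given the generator seed (one
substream per subject).

Default study conditions: 20 subjects per group, 16 channels, 500 Hz,
120 s; patients carry one 6-ring on channels 0–5, controls none.

What the generator does *not* emulate: volume conduction and field spread,
1/f spectra, artifacts, nonstationarity, per-subject anatomy.  Passing
tests therefore demonstrate that the pipeline recovers planted correlation
topology at realistic noise levels — not that any clinical population is
separable.

## Classification protocol

One row per (subject, band): 22 amplitudes + band index.  Classifiers are
logistic regression and an RBF SVM (both behind a per-fold standard
scaler), a random forest, and LightGBM.  Cross-validation is stratified
and *subject-grouped* by default, so a subject's five band rows never
straddle a train/test split; plain row-level folds are available behind a
flag for protocol parity, but they leak subjects and inflate accuracy.
Univariate feature selection scores each feature by held-out accuracy of
the best model (LightGBM) on a stratified seeded split and keeps features
at or above the threshold (0.55 or 0.60, inclusive); an empty selection
falls back to all features with a warning.  Tuning is nested: grid search
on training folds only, metrics from outer folds, chosen parameters
logged per fold.  Metrics (accuracy, precision, recall, F1) are averaged
over folds from stored confusion matrices.

## Cycle-ratio node importance

For each band and non-overlapping segment (default 40 s), the top-5
longest-lived 1-cycles of the segment's diagram select subgraphs: all
edges with `D_ij ≤ birth`, the threshold at which the class provably
exists and is not yet filled (the death threshold is available as an
alternative).  The analysis uses dim-1 classes because dim-0 classes are
all born at 0, where the 1-skeleton has no edges — a dim-0 birth-threshold
graph is empty by construction.

The cycle ratio of node i sums, over every node j lying on a cycle, the
fraction of j's minimum-length cycles that contain i (including j = i, so
every cyclic node scores ≥ 1).  Shortest cycles through j are enumerated
by iterative-deepening DFS from j with a BFS-distance pruning bound and a
canonical-direction rule so each cycle is found once; enumeration is
capped (default 10⁴ cycles per node) with a warning.  Nodes outside every
biconnected component of ≥ 3 vertices are skipped outright.  Per graph,
nodes are ranked by score (ties by node index) and the top 10 are tallied
across graphs; the tally localizes the channels carrying the persistent
topology.

## Problem sizes and numerical conventions

The shipped verification studies use desk-scale sizes chosen to keep the
whole suite fast while leaving the statistics unambiguous: 200 random
matrices (n ∈ [3, 10]) for oracle equivalence, 50 for the MST identity,
the full connected small-graph atlas (≤ 7 nodes, 996 isomorphism classes)
for the cycle-ratio oracle, and 20 + 20-subject cohorts over ten seeds
(five in the acceptance script) for the recovery study.  Filtration
values are compared exactly (both reduction routes consume identical
floats); matrix symmetry is checked at 1e−12, correlation clamping at
[0, 1]; the label-permuted control is judged against the binomial
chance band [0.35, 0.65].
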