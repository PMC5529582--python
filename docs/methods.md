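# Methods

This note documents the models and procedures implemented in
`contextconn`, the parameters that matter, the synthetic data the package
tests itself against, and the numerical and design choices made where the
procedure was genuinely open.

## Preprocessing and windowing

Parcel timeseries (T samples × N nodes per subject, sampling interval TR
in seconds) are demeaned, linearly detrended, despiked, band-pass filtered
and variance-normalized. Despiking replaces samples with |robust z| > 4
(median/MAD, MAD scaled by 1.4826) by linear interpolation from the
nearest clean samples. The band-pass is a 4th-order Butterworth applied
forward and backward (zero phase), default band 0.01–0.15 Hz. Constant
node series are returned as zeros, with a warning, so node indexing never
shifts.

Sliding windows of `length_s` seconds (default 44.64 s = 62 samples at
TR 0.72 s) advance by `step_s` (default one sample). Each window is
weighted by a taper: a unit rectangle of the window length convolved with
a Gaussian kernel (σ default 3 samples), truncated to the window support
and normalized to sum 1. Windows whose mean framewise displacement exceeds
0.18 mm are censored; censored windows stay in place (so window indexing
and provenance remain aligned) but are excluded from every downstream
statistic.

## Windowed connectivity

A window holds fewer observations than the connectome has edges, so the
per-window graph is estimated as an L1-penalized precision matrix
(graphical lasso, penalty λ default 0.1) on the taper-weighted correlation
matrix, reported as partial correlations ρ_ij = −P_ij / √(P_ii P_jj) so
all edge weights lie in (−1, 1). λ = 0 falls back to the dense
pseudo-inverse. A window that fails to converge is retried with the
penalty doubled and otherwise censored with a warning. Edges are
vectorized in a single lexicographic (i < j) pair order shared by every
module. Numerical choice: the lasso's duality-gap tolerance is 5e-3;
against a 1e-4 solve the partial correlations move by at most ~0.02,
far below between-state differences, at roughly a tenth of the cost.

## Canonical networks

The static connectome is the per-subject Pearson matrix, Fisher-z averaged
across subjects. Community detection (Louvain, best modularity over seeded
restarts) runs on the cortical submatrix with negative weights removed.
The resolution γ is trained by scanning a grid and scoring each partition
against an a-priori reference with the pairwise cost: 0 if neither
partition co-assigns a pair, n/(m−n) if only the reference does, +1 if
only the candidate does, −1 if both do, where m is the reference's
intramodular pair count and n the node count; summed over unique pairs, a
perfect match scores −m. Ties in the grid break toward smaller γ.

## NC-states

Within-network window vectors are clustered by k-means under the L1
metric. The exact L1 minimizer of a cluster is the coordinate-wise median,
so centroid updates are medians (k-medians); the best of `restarts`
seeded random initializations by within-cluster L1 sum wins, and an empty
cluster is re-seeded from the farthest window. The clustering is exposed
as a scikit-learn-compatible estimator (`KMediansL1`) so it composes with
sklearn model selection; `fit_ncstates` is a thin wrapper.

The state count k is the smallest k whose fractional WCSS improvement to
k+1 falls below 0.05 (the curve is cum-min smoothed if restart noise makes
it non-monotone). Cluster validity is a permutation test: each edge column
is shuffled independently (marginals preserved, inter-edge structure
destroyed) and p = (1 + #{null WCSS ≤ observed}) / (n_perm + 1).
Replication splits subjects in half, refits per half, matches each half-1
centroid greedily to its most-correlated half-2 centroid, and requires
both r > 0.8 and r above the 95th percentile of the same statistic on
phase-randomized edge timeseries.

## Context and concordance

Each subject's non-censored windows form the ordered layers of a
multilayer network (negative edges zeroed); Leiden optimization of
multilayer modularity with uniform ordinal inter-layer coupling ω (default
1.0, resolution γ from the static training) labels every node in every
window. Allegiance over a window set is the exact co-assignment frequency.
A state's WBCC is its allegiance matrix plus the inverse-Fisher of the
mean Fisher-z whole-cortex edge vector over its windows. Displacement from
baseline divides block-mean allegiance (per network pair, self-pairs
excluded on the diagonal blocks) in the state's windows by the same
quantity over all windows; zero baseline blocks are reported missing.

Concordance C(A_i, B_j) = ln(P(A_i|B_j)/P(A_i)) is estimated from
empirical frequencies over aligned windows, pooled across subjects. Cells
with zero joint count are NaN (excluded from summaries), not −∞.
Significance is two-sided with the +1-corrected empirical p against each
of three nulls — whole sequences permuted across subjects, sequences
re-simulated from the pooled first-order Markov chain and observed initial
states, and per-subject circular rotation (the categorical analogue of a
phase shift, since Fourier phase is undefined for labels) — and a cell is
significant only under all three. With very few subjects the cross-subject
permutation null is conservative, because permutations that fix subjects
in place reproduce part of the observed coupling; from about six subjects
on this is immaterial.

## Independence

Fisher-z whole-cortex windows are scored against a subsystem's contextual
centroids by the within-cluster sum of squared correlation distances to
the *nearest* centroid. Anchors:

* **upper (−1, maximal interdependence)**: k-means on all cortical
  features under the scored objective itself — assignment by correlation
  distance, mean centroids. (Fitting in another metric, e.g. L1 medians in
  z-space, does not bound the correlation-distance WCSS: median centroids
  score systematically worse than mean centroids on the same assignments,
  so the bound is fit in the metric it is scored in.)
* **zero**: mean WCSS of `n_pseudo` random node sets matched in size and
  state count to the subsystem (default 1000; the test suite and the
  acceptance script use 100 with correspondingly wider expectations).
* **lower (+1, maximal independence)**: degenerate hybrid centroids equal
  to the time-averaged cortical vector everywhere except the subsystem's
  own edge columns, which carry its NC-state centroids.

The score maps WCSS piecewise-linearly through (upper → −1, pseudo mean →
0, lower → +1), clamping outside the anchors with a warning. The
independence test is p = (1 + #{pseudo ≥ observed})/(n_pseudo + 1) for the
"more independent" direction. A concordance-based assay computes the mean
strictly-positive and strictly-negative finite concordance between
subsystem states and a k=8 whole-cortex state model fit once globally
(k configurable).

The INT (maximally interdependent) search draws `n_pseudo` pseudo-networks
(default 8 nodes, 8 states), tallies node membership in the lowest-WCSS
quintile, restricts the pool to nodes strictly above the median tally
(relaxing to ≥ median with a warning if the strict cut leaves fewer nodes
than the requested size — a small-`n_pseudo` degeneracy), redraws, and
returns the minimum-WCSS set.

## Synthetic data: what it emulates, and what it does not

The generator produces per-subject multivariate Gaussian samples from a
block factor model with hidden-Markov regime switching:

* **Networks and states.** Each network's state determines how it
  fractionates (1, 2 or 3 contiguous sub-blocks at default k = 3) and the
  within-sub-block correlation (defaults 0.25 / 0.45 / 0.65). States
  differing in *topology*, not just level, are what make them separable in
  the partial-correlation domain: equicorrelated blocks differing only in
  level produce nearly identical precision matrices
  (ρ ≈ r/(1+(n−2)r) saturates).
* **Switching.** States are constant over blocks of 124 samples (two
  window lengths) drawn from a sticky row-stochastic transition matrix
  (self-probability 0.4 at default k = 3), so windows rarely straddle a
  regime change; ground-truth window labels use the state at the window
  centre.
* **Coupling.** A planted coupling pulls network B into state b with
  probability 0.8 whenever network A enters state a, and adds a shared
  factor (+0.15 correlation) while the pair is co-active. The temporal
  sync is what produces above-chance concordance; a correlation boost
  alone would not change state co-occurrence.
* **Global mode.** A two-state hidden-Markov "integration" mode activates
  one of two planted cross-network matchings (one node per network per
  group) with per-node loading adapted to the remaining variance budget
  (cap 0.45). Pairwise/small-group factors are used deliberately: they
  survive precision estimation, whereas a single global factor shared by
  all nodes is explained away. This mode is what random pseudo-networks —
  which straddle networks and therefore see integration edges — can track
  but single modular networks cannot, making canonical networks genuinely
  more independent than pseudo-networks in the generated data.
* **Hubs.** With hubs enabled, the global mode is routed through an
  8-node hub block instead: the active partition of the hub block into
  groups depends jointly on the global configuration and on a gate
  network's state, so hub-hub edges switch fully on/off and jointly encode
  the configuration and network states. Hub-rich node sets explain
  strictly more cortical variance (WCSS decreases monotonically in the
  number of hubs drawn), which is what makes the planted hub set
  recoverable by the INT search.
* **Motion.** FD traces are folded-normal baselines (σ 0.04 mm) with
  Poisson motion bursts (rate 0.005 per sample, geometric duration,
  log-normal amplitude around 0.3 mm).

The spec is validated at construction: any state combination whose factor
loadings would demand negative residual variance is rejected with the
offending node named.

What the generator does **not** emulate: hemodynamic convolution,
physiological or scanner noise spectra, spatial maps, inter-subject
variability in network topography, and non-Gaussian heavy tails. Passing
tests therefore demonstrate that the pipeline recovers the statistical
structure it claims to detect — block communities, switching precision
topologies, state co-occurrence, differential global coupling — not that
it would behave identically on real fMRI.

## Problem sizes and defaults used in the package's own checks

The default synthetic study conditions are 3 networks × 12 cortical nodes
plus 4 subcortical nodes, 6 subjects × 2000 samples at TR 0.72 s, with the
62-sample window stepped by 6 samples (≈1944 windows in total); the hub
variant uses 4 subjects × 1200 samples with 8 additional hub nodes.
Pseudo-network nulls in the tests and the acceptance script use
n_pseudo = 100 and 5–10 clustering restarts. Multilayer community
detection cost grows steeply with the number of layers, so context-level
unit tests run on single-subject reduced problems.

## Known limitations

* The elbow rule's 0.05 threshold is a convention; on low-dimensional or
  heavy-noise data the WCSS curve may lack a clean knee.
* Greedy (not optimal) matching of split-half centroids can understate
  similarity when two centroids are near-collinear.
* The multilayer backend labels only non-censored windows; heavy motion
  censoring shortens and fragments the layer sequence, and cross-subject
  concordance permutation requires equal per-subject lengths (align to the
  intersection mask upstream, or the CLI falls back to pooled concordance
  without significance).
* WCSS-based independence compares subsystems at matched k; comparing
  subsystems with different state counts is not meaningful on this scale.
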