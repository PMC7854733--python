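# Methods

This note documents the models, estimators, and design choices behind
`restconn`, in the spirit of a package methods appendix. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Spectral connectivity (wPLI)

Recordings are cut into fixed-length epochs (default 2 s, 50%
overlap), Hann-tapered, and Fourier transformed; the cross-spectrum
`X_ij(f) = F_i(f) conj(F_j(f))` is Hermitian per epoch and bin. The
weighted phase lag index is

    wPLI_ij(f) = |E{|Im X_ij| sgn(Im X_ij)}| / E{|Im X_ij|}

with `E{}` across epochs. Because `|x| sgn(x) = x`, the numerator is
equivalently `|E{Im X}|`; the code keeps the weighted form explicit
and the tests pin it to a direct evaluation of the formula at 1e−12.
Conventions:

* **0/0 rule.** Bins where `E{|Im X|} = 0` (perfect zero-lag coupling)
  contribute wPLI 0: a purely real cross-spectrum carries no lag
  information.
* **Band value.** Unweighted mean of per-bin wPLI over bins in the
  half-open interval `[lo, hi)`, so the five bands partition 1–80 Hz
  without double-counting shared edges. Whether band averaging should
  precede or follow any across-block pooling is genuinely open; the
  per-bin-then-average choice is a documented default.
* **No debiasing.** The plain estimator is used; the debiased-squared
  variant is out of scope.
* **Estimator properties.** wPLI is invariant to positive rescaling of
  any channel (the magnitudes cancel) and insensitive to instantaneous
  mixing: mixed white-noise channels correlate strongly in time yet
  keep wPLI at the finite-sample floor. Both are asserted in tests.

The floor itself scales like `1/sqrt(n_epochs)` per bin; with 180 s
recordings it sits near 0.08–0.15 per band. Assertions about "no
coupling" therefore use 0.2 as the practical ceiling, averaged over
seeds.

**Spectral resolution caveat.** At the 2 s default the Hann mainlobe
spans ±1 Hz, a full band-edge bin at 0.5 Hz resolution, so coupling
near a band edge bleeds one bin into the neighbouring band.
Band-specificity checks (planted theta coupling must not appear in
alpha) run at 4 s epochs with 75% overlap (0.25 Hz bins); epoch length
and overlap are ordinary arguments everywhere.

## Graph metrics over the network-cost sweep

A nonnegative symmetric connectivity matrix is thresholded at network
cost `c` by retaining the `round(c · n(n−1)/2)` strongest edges
(round half away from zero — at 10% cost on 70 nodes this is exactly
242 edges) and binarizing. Ties break by descending weight then
lexicographic node-pair order, making edge sets nest across costs and
runs deterministic. Metrics are computed on the binary graph; the
printed binary forms of the equations are taken at face value, and a
weighted variant is deliberately not a default.

* **Modularity.** `Q = Σ_u [e_uu − (Σ_v e_uv)²]` with `e_uv` the
  proportion of link endpoints joining modules `u` and `v` (stub
  counting, within-module stubs counted twice over `2m`). This
  reproduces the analytic anchors used in tests: two disjoint
  4-cliques at their planted partition give exactly 0.5, a single
  module gives exactly 0, and a 3+3 split of K6 gives −0.1; it equals
  Newman–Girvan modularity, which networkx recomputes independently
  in the tests.
* **Partition search.** Seeded Louvain (networkx) with best-of-100
  restarts by default; the single-module partition (Q = 0) is the
  fallback, so returned Q is never negative. On graphs of ≤ 10 nodes
  the tests compare against exhaustive enumeration of all set
  partitions. No particular optimizer is canonical for this metric;
  Louvain restarts are the package's choice.
* **Efficiency.** Global efficiency is the mean of `1/d_ij` over
  ordered pairs with unreachable pairs contributing 0; local
  efficiency applies the same quantity to each node's neighbour
  subgraph, normalized by `k_i(k_i−1)`, with `E_loc,i = 0` for degree
  < 2 and for isolated nodes. Shortest paths come from
  scipy.sparse.csgraph; tests pin both metrics to a hand-rolled BFS
  oracle and to networkx. Disconnected graphs are allowed throughout.

The default cost grid is {0.10, 0.15, 0.20, 0.25, 0.30}: sparse enough
to avoid saturating every metric, dense enough that conclusions do
not hinge on one threshold.

## Seed-based fMRI connectivity

Seeds are spheres in MNI millimetre space. The centre is snapped to
the nearest voxel centre (counts become invariant under whole-voxel
translation), and a voxel belongs to the ROI when its centre lies
within the radius, boundary inclusive — on a 3 mm isotropic grid a
5 mm sphere covers 19 voxels (offsets with i²+j²+k² ≤ 2), on a 2 mm
grid 81. The seed time course is the per-volume ROI mean.
Connectivity is Pearson correlation mapped through Fisher's
`z = log((1+a)/(1−a))/2` (pinned to `atanh` at 1e−12); `|r| = 1` is an
error by default to avoid silent infinities, with an explicit
clip-to-(1−1e−7) mode.

* **Runs.** Multi-run sessions default to correlate-per-run,
  transform, and average z across runs; concatenation after per-run
  standardization is the alternative, and on synthetic data the two
  agree to < 0.05 (tested).
* **Whole-brain score.** The per-subject scalar summarizing a
  seed-to-whole-brain map is not canonically defined; the default
  reducer is the mean of |z| over in-mask voxels excluding the seed's
  own ROI (it yields positive scores of magnitude ~1 on data with
  realistic correlation spread), with mean-z and mean-positive-z
  selectable. This is a modeling choice, flagged as such.
* **Constant voxels** (outside-brain padding) get r = 0 rather than
  NaN; a constant *seed* time course is an error.

## Group statistics

Student pooled-variance t throughout (the reproducible published
contrasts at n = 23/23 imply pooled df = 44), two-sided p; Cohen's
d = mean difference over the pooled SD. One-way ANOVA and the
balanced mixed (split-plot) ANOVA are explicit sums-of-squares
decompositions: the between-group effect is tested against subjects
within groups, the within-subject effect and interaction against the
within × subjects residual; partial eta squared uses each effect's own
error term (`η²_p = SS_effect/(SS_effect+SS_error)`, recoverable from
F as `F·df1/(F·df1+df2)`). Balance (equal group sizes, every subject
at every level exactly once) is required and checked; sphericity
corrections are not applied, matching the uncorrected convention the
reported analyses follow. No multiple-comparison correction is applied
by default; Bonferroni/FDR is an explicit helper. pingouin recomputes
the mixed ANOVA independently in the tests.

Sample size uses the normal approximation
`n = ceil(2((z_{1−α/2}+z_power)/d)²)`: d = 0.92 at α = 0.05 and power
0.90 gives 25 per group. An exact noncentral-t search is available and
can differ by about one subject (d = 0.5, power 0.80: 63 vs 64).

## Synthetic data: what it emulates and what it does not

All generators are pure functions of (spec, seed) via numpy
`SeedSequence`; identical calls are bit-identical.

* **Lag-coupled oscillators.** Each coupled pair shares a band-limited
  Gaussian oscillation built in the frequency domain: a random-phase
  spectrum confined to `center ± bandwidth/2` (default 2.8 Hz) with a
  cosine-squared roll-off over the outer 0.6 Hz. The partner channel
  is the real part of the analytic signal rotated by the phase lag, so
  the lag is exact at every supported frequency and the instantaneous
  phase is well defined. Compact spectral support is essential: a
  literal sinusoid with random-walk phase has Lorentzian tails that
  carry a *consistent* lag into neighbouring bands, defeating any
  band-specificity check. `coupling_snr` is the ratio of coupled
  variance to the white-noise variance per channel (noise is Gaussian
  and white; 1/f structure, artifacts, and head geometry are not
  modeled). Zero-lag volume conduction is emulated by an instantaneous
  mixing matrix applied after generation.
* **Planted-partition graphs.** Independent edges with probability
  `p_in` within and `p_out` between modules; the deterministic limits
  (cliques, complete graph) are exact.
* **Two-group fMRI studies.** Per run, every network ROI's latent time
  course loads on one shared network signal with correlation `ρ`;
  each ROI voxel adds N(0, noise_sd²) noise, and out-of-network voxels
  are independent noise of matching marginal variance. Because the
  m-voxel ROI mean attenuates the latent correlation by
  `1/(1 + noise_sd²/m)`, the latent `ρ` is inflated by that factor
  (using the mean ROI size) so the *observed* seed-mean correlation
  lands on the requested `within_network_r`; targets that would
  require `|ρ| ≥ 1` raise. Negative targets are supported for two
  ROIs. Defaults mirror a standard acquisition: 155 volumes per run,
  TR 2 s, 3 runs, 3 mm voxels. Hemodynamics, motion, physiological
  noise, and spatial autocorrelation are not modeled — passing tests
  show the estimators and statistics behave correctly under the
  assumed correlation structure, not that they are robust to real
  scanner artifacts.

## Problem sizes in the validation runs

The Monte-Carlo checks use sizes chosen to make sampling error small
relative to the asserted margins: planted-lag recovery over 20 seeded
180 s recordings (4 channels, 200 Hz); two-group fMRI detection over
100 replicate studies of 23 subjects per group on an 8×8×8-voxel 3 mm
grid with two 19-voxel ROIs, 150 volumes, one run (the within-network
contrast r = 0.45 vs 0.12 gives per-study t near 12, so the ≥ 90%
detection bound is far from the sampling noise); and the null mixed
ANOVA over 500 replicate 3-group × 8-subject × 5-cost tables (type-I
rate binomial SD ≈ 0.01 against a ±0.03 band). Graph oracles run
exhaustively: all-pairs BFS on 8-node graphs and full set-partition
enumeration (Bell(10) = 115 975) on up to 10 nodes.

## Known limitations

* EDF recordings are read (via MNE) but not written; the native
  on-disk recording format is TSV plus a JSON sidecar.
* The mixed ANOVA requires a fully balanced design; unbalanced data
  should go to a mixed-effects model outside this package.
* wPLI band values at 2 s epochs blur one bin across band edges (see
  the spectral-resolution caveat); use longer epochs when band
  specificity near edges matters.
* The whole-brain reducer is an explicit assumption, not a canonical
  definition; report which reducer was used.
* No EEG artifact rejection or fMRI preprocessing is included — inputs
  are assumed clean and already normalized to MNI space.
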