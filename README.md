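# restconn

Resting-state functional connectivity analysis for EEG and fMRI, built
around the measures used to probe network integrity after mild
traumatic brain injury: weighted phase lag index (wPLI) connectivity
with graph-theoretic metrics over a network-cost sweep, seed-based
fMRI connectivity with Fisher r-to-z normalization, and the
group-level statistics that compare patient and control cohorts.
A seeded synthetic-data module generates EEG-like recordings with
planted phase-lag coupling, graphs with planted modules, and two-group
fMRI studies with a configurable connectivity contrast, so every stage
of the pipeline can be validated end to end without subject data.

## The measures

**wPLI.** For channels *i, j* with complex cross-spectrum *X*,

    wPLI = |E{|Im X| sgn(Im X)}| / E{|Im X|}

with the expectation across epochs per frequency bin, then averaged
over the bins of each band (delta 1–5, theta 5–8, alpha 8–12, beta
12–30, low gamma 30–80 Hz; half-open intervals). Zero-lag (volume
conducted) mixing yields a purely real cross-spectrum and hence wPLI
near 0; a constant nonzero phase lag yields 1.

**Graph metrics at fixed network cost.** A wPLI matrix is thresholded
to retain the strongest `cost · n(n−1)/2` edges (cost 10–30%, step 5%)
and binarized. On each graph: modularity `Q = Σ_u [e_uu − (Σ_v e_uv)²]`
of the best seeded-Louvain partition, global efficiency
`E_glob = mean of 1/d_ij over node pairs`, and local efficiency (the
same quantity on each node's neighbour subgraph). The cost sweep feeds
a mixed-design ANOVA with group as the between-subject factor and cost
as the within-subject factor.

**Seed-based fMRI connectivity.** Spherical seeds at MNI coordinates
(5 mm radius, 19 voxels on a 3 mm grid) yield mean time courses;
connectivity is the Pearson correlation of a seed's time course with
every in-brain voxel or with a second seed, mapped through Fisher's
`z = log((1+a)/(1−a))/2`. Eight canonical working-memory-network seeds
(DMN, CEN, DAN, SN; one primary and one within-network partner each)
are bundled.

**Group statistics.** Pooled-variance two-sample t (from raw samples
or printed summary statistics) with Cohen's d, one-way and balanced
mixed-design ANOVA with partial eta squared, Pearson brain–behavior
correlation, and a priori per-group sample size
`n = ceil(2((z_{1−α/2}+z_power)/d)²)`.

## Worked example

```python
import numpy as np
from restconn import *

# an 8-channel recording whose first two channels share a 6.5 Hz
# oscillation lagged by pi/4 (SNR 10), everything else white noise
rec = gen_lagged_oscillators(
    n_channels=8, fs=250.0, duration=180.0,
    oscillators=[OscillatorSpec(channel_pair=(0, 1), center_freq=6.5,
                                phase_lag=np.pi / 4, coupling_snr=10.0)],
    seed=1,
)
theta = band_wpli(rec, bands=(DEFAULT_BANDS[1],), epoch_len=4.0, overlap=0.75)[0]
print(f"theta wPLI, coupled pair: {theta.values[0, 1]:.3f}")
print(f"theta wPLI, strongest uncoupled pair: {theta.values[2:, 2:].max():.3f}")

for r in cost_sweep(theta.values, seed=1, subject_id="demo", band="theta"):
    print(f"cost {r.cost:.2f}:  Q = {r.q:.3f}   Eglob = {r.eglob:.3f}")

res = t_from_summary(GroupSummary(23, 0.16, 0.16), GroupSummary(23, 0.43, 0.26))
print(f"t({res.df[0]:.0f}) = {res.statistic:.1f}, p = {res.p:.5f}")
print("n per group:", n_per_group(0.92, alpha=0.05, power=0.90))
```

prints

```
theta wPLI, coupled pair: 0.987
theta wPLI, strongest uncoupled pair: 0.160
cost 0.10:  Q = 0.444   Eglob = 0.125
cost 0.15:  Q = 0.406   Eglob = 0.190
cost 0.20:  Q = 0.278   Eglob = 0.298
cost 0.25:  Q = 0.245   Eglob = 0.321
cost 0.30:  Q = 0.219   Eglob = 0.339
t(44) = -4.2, p = 0.00011
n per group: 25
```

The planted lag is recovered only in the coupled pair's theta wPLI
(uncoupled pairs stay at the finite-sample noise floor); modularity
falls and global efficiency rises as denser graphs are retained; the
summary-statistic t-test reproduces a two-group connectivity contrast
at 23 subjects per group; and detecting a d = 0.92 group effect at 90%
power requires 25 subjects per group.

## Command line

`restconn` exposes `simulate-eeg`, `simulate-fmri`, `wpli`,
`graph-metrics`, `seed-map`, `group-stats`, `power`, `seed-table`, and
the end-to-end `run-eeg` / `run-fmri` drivers configured by a YAML
file (flags override keys). Pipelines write TSV/NIfTI artifacts, a run
log, and a `manifest.json`; reruns with the same config and seed are
byte-identical.

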