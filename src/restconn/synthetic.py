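"""Seeded synthetic data with the structure the analysis assumes.

Three generators make every downstream stage testable without subject
data:

* ``gen_lagged_oscillators`` — multichannel EEG-like noise in which
  chosen channel pairs share a narrowband oscillation with a fixed
  phase lag, optionally passed through an instantaneous (zero-lag)
  mixing matrix emulating volume conduction.  A wPLI estimator must
  recover the lagged pairs and ignore the mixing.
* ``gen_modular_graph`` — planted-partition random graphs for checking
  modularity and community recovery.
* ``gen_fmri_study`` — two-group 4-D volumes in which voxels inside
  network ROIs share latent time courses whose inter-ROI correlation
  differs between groups by a configurable amount, emulating a
  weakened-connectivity contrast.

Each generator is a pure function of (spec, seed): identical calls
return bit-identical output.  Channel noise is Gaussian and white.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seed import SeedSpec, Volume4D, sphere_roi
from .spectral import Recording

__all__ = [
    "OscillatorSpec",
    "MixingSpec",
    "PlantedGraphSpec",
    "FmriStudySpec",
    "SubjectScans",
    "FmriStudy",
    "default_affine",
    "gen_lagged_oscillators",
    "gen_modular_graph",
    "gen_fmri_study",
]


@dataclass(frozen=True)
class OscillatorSpec:
    """A lag-coupled channel pair.

    The oscillation is a band-limited Gaussian process (random-phase
    spectrum confined to center_freq +/- bandwidth/2), so instantaneous
    phase is well defined and spectral support stays inside one
    analysis band.  The second channel's analytic signal is the first
    rotated by ``phase_lag`` radians (second channel lags).
    ``coupling_snr`` is the ratio of coupled-component variance to the
    additive channel-noise variance.
    """

    channel_pair: tuple[int, int]
    center_freq: float
    phase_lag: float
    coupling_snr: float
    bandwidth: float = 2.8
    edge_width: float = 0.6

    def __post_init__(self) -> None:
        if not self.center_freq > 0:
            raise ValueError("center_freq must be positive")
        if not (-math.pi < self.phase_lag <= math.pi):
            raise ValueError("phase_lag must lie in (-pi, pi]")
        if not self.coupling_snr > 0:
            raise ValueError("coupling_snr must be positive")
        if not 0 < self.bandwidth < 2 * self.center_freq:
            raise ValueError("bandwidth must be positive and below 2*center_freq")
        if not 0 <= self.edge_width <= self.bandwidth / 2:
            raise ValueError("edge_width must lie in [0, bandwidth/2]")


@dataclass(frozen=True)
class MixingSpec:
    """Instantaneous channels x channels mixing applied after signal
    generation; the identity means no volume conduction."""

    matrix: tuple  # nested tuples for hashability; any 2-D array-like accepted

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("mixing matrix must be square")
        if not np.all(np.isfinite(m)):
            raise ValueError("mixing matrix must be finite")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    @classmethod
    def identity(cls, n: int) -> "MixingSpec":
        return cls(matrix=tuple(map(tuple, np.eye(n))))


@dataclass(frozen=True)
class PlantedGraphSpec:
    """Planted-partition graph: p_in within modules, p_out between."""

    n_nodes: int
    module_sizes: tuple[int, ...]
    p_in: float
    p_out: float
    seed: int

    def __post_init__(self) -> None:
        if sum(self.module_sizes) != self.n_nodes:
            raise ValueError("module_sizes must sum to n_nodes")
        if not 0 <= self.p_out <= self.p_in <= 1:
            raise ValueError("require 0 <= p_out <= p_in <= 1")

    def labels(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.module_sizes)), self.module_sizes)


@dataclass(frozen=True)
class FmriStudySpec:
    """Two-or-more-group synthetic resting-state fMRI study.

    ``within_network_r`` gives each group's target inter-ROI
    correlation of seed-mean time courses; the latent correlation is
    inflated by the voxel-noise attenuation factor so the *observed*
    ROI-mean correlation lands on target.
    """

    n_subjects_per_group: int
    grid_dims: tuple[int, int, int]
    voxel_size: float
    n_volumes: int
    n_runs: int
    tr: float
    network_rois: tuple[SeedSpec, ...]
    within_network_r: tuple[float, ...]
    noise_sd: float
    seed: int
    group_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_volumes < 10:
            raise ValueError("need n_volumes >= 10")
        if any(not -1 < r < 1 for r in self.within_network_r):
            raise ValueError("within_network_r must lie in (-1, 1)")
        if len(self.network_rois) < 2:
            raise ValueError("need >= 2 network ROIs")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.group_names is not None and len(self.group_names) != len(
            self.within_network_r
        ):
            raise ValueError("group_names must match within_network_r length")

    @property
    def n_groups(self) -> int:
        return len(self.within_network_r)


@dataclass
class SubjectScans:
    subject_id: str
    group: str
    runs: list[Volume4D]


@dataclass
class FmriStudy:
    """Generated study: subjects with group labels plus the planted
    truth (ROI voxel sets, latent correlations)."""

    subjects: list[SubjectScans]
    spec: FmriStudySpec
    rois: dict[str, np.ndarray]
    latent_r: dict[str, float] = field(default_factory=dict)


def gen_lagged_oscillators(
    n_channels: int,
    fs: float,
    duration: float,
    oscillators: list[OscillatorSpec],
    mixing: MixingSpec | None = None,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> Recording:
    """Channels x samples recording with lag-coupled oscillator pairs.

    Each oscillator adds, to its two channels, the real part of one
    band-limited analytic signal and of the same signal rotated by the
    phase lag; white Gaussian noise is added per channel and the mixing
    matrix (if any) is applied last, so coupled pairs carry the
    specified lag at center_freq *before* mixing.
    """
    n = int(round(duration * fs))
    if n < 1000:
        raise ValueError("need duration * fs >= 1000 samples")
    nyquist = fs / 2.0
    for osc in oscillators:
        if osc.center_freq >= nyquist:
            raise ValueError(
                f"center_freq {osc.center_freq} Hz at or above Nyquist ({nyquist} Hz)"
            )
        if osc.center_freq + osc.bandwidth / 2 >= nyquist:
            raise ValueError("oscillator band extends to Nyquist; lower bandwidth")
        i, j = osc.channel_pair
        if not (0 <= i < n_channels and 0 <= j < n_channels) or i == j:
            raise ValueError(f"invalid channel pair {osc.channel_pair}")
    mix = None
    if mixing is not None:
        mix = mixing.as_array()
        if mix.shape != (n_channels, n_channels):
            raise ValueError("mixing matrix must be n_channels x n_channels")

    rng = np.random.default_rng(seed)
    data = noise_sd * rng.standard_normal((n_channels, n))
    freqs = np.fft.fftfreq(n, 1.0 / fs)
    for osc in oscillators:
        lo = osc.center_freq - osc.bandwidth / 2
        hi = osc.center_freq + osc.bandwidth / 2
        sel = (freqs >= lo) & (freqs <= hi)  # positive frequencies only
        f_in = freqs[sel]
        env = np.ones(f_in.size)
        if osc.edge_width > 0:
            # cosine-squared roll-off keeps spectral support compact
            left = f_in < lo + osc.edge_width
            right = f_in > hi - osc.edge_width
            env[left] = np.sin(0.5 * np.pi * (f_in[left] - lo) / osc.edge_width) ** 2
            env[right] = np.sin(0.5 * np.pi * (hi - f_in[right]) / osc.edge_width) ** 2
        coeffs = np.zeros(n, dtype=complex)
        coeffs[sel] = env * np.exp(1j * rng.uniform(0, 2 * np.pi, f_in.size))
        analytic = np.fft.ifft(coeffs) * n  # analytic: positive-frequency support
        a_sig = analytic.real
        b_sig = (analytic * np.exp(-1j * osc.phase_lag)).real  # b lags a
        scale = math.sqrt(osc.coupling_snr) * noise_sd / a_sig.std()
        i, j = osc.channel_pair
        data[i] += scale * a_sig
        data[j] += scale * b_sig
    if mix is not None:
        data = mix @ data
    return Recording(data=data, fs=fs)


def gen_modular_graph(spec: PlantedGraphSpec) -> np.ndarray:
    """Binary symmetric hollow adjacency with planted modules."""
    rng = np.random.default_rng(spec.seed)
    labels = spec.labels()
    n = spec.n_nodes
    same = labels[:, None] == labels[None, :]
    p = np.where(same, spec.p_in, spec.p_out)
    draw = rng.random((n, n))
    upper = np.triu(draw < p, k=1)
    adj = (upper | upper.T).astype(np.int8)
    return adj


def default_affine(
    grid_dims: tuple[int, int, int], voxel_size: float
) -> np.ndarray:
    """Isotropic RAS affine with the grid centered on mm origin."""
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    aff[:3, 3] = -voxel_size * (np.asarray(grid_dims) - 1) / 2.0
    return aff


def _latent_correlation(spec: FmriStudySpec, mean_roi_size: float) -> list[float]:
    """Inflate target ROI-mean correlations for voxel-noise attenuation.

    A voxel is u_k + noise_sd * eps, so the m-voxel ROI mean has
    variance 1 + noise_sd^2/m and corr(mean_a, mean_b) =
    rho_latent / (1 + noise_sd^2/m); solve for rho_latent.
    """
    factor = 1.0 + spec.noise_sd**2 / mean_roi_size
    out = []
    for r in spec.within_network_r:
        rho = r * factor
        if abs(rho) >= 1:
            raise ValueError(
                f"within_network_r {r} unreachable at noise_sd {spec.noise_sd}"
            )
        out.append(rho)
    return out


def gen_fmri_study(spec: FmriStudySpec) -> FmriStudy:
    """Generate per-subject 4-D volumes with planted network structure.

    Per run, all ROIs share one network latent g(t); ROI k's latent is
    sqrt(rho) g + sqrt(1-rho) h_k, every ROI voxel adds N(0, noise_sd^2)
    voxel noise, and out-of-network voxels are independent noise with
    the same marginal variance.  Negative targets are supported for two
    ROIs (opposite loading on g).
    """
    affine = default_affine(spec.grid_dims, spec.voxel_size)
    rois = {
        roi.name: sphere_roi(roi, affine, spec.grid_dims) for roi in spec.network_rois
    }
    mean_m = float(np.mean([len(v) for v in rois.values()]))
    latents = _latent_correlation(spec, mean_m)
    if any(rho < 0 for rho in latents) and len(rois) > 2:
        raise ValueError("negative within_network_r supported only for 2 ROIs")
    names = list(rois)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            sa = {tuple(v) for v in rois[names[a]]}
            if sa & {tuple(v) for v in rois[names[b]]}:
                raise ValueError(f"ROIs {names[a]!r} and {names[b]!r} overlap")

    group_names = spec.group_names or tuple(
        f"group{i + 1}" for i in range(spec.n_groups)
    )
    ss = np.random.SeedSequence(spec.seed)
    subj_seqs = ss.spawn(spec.n_groups * spec.n_subjects_per_group)
    bg_sd = math.sqrt(1.0 + spec.noise_sd**2)
    subjects = []
    latent_r = {}
    for gi, gname in enumerate(group_names):
        rho = latents[gi]
        latent_r[gname] = rho
        s_rho = math.sqrt(abs(rho))
        s_res = math.sqrt(1 - abs(rho))
        for si in range(spec.n_subjects_per_group):
            seq = subj_seqs[gi * spec.n_subjects_per_group + si]
            rng = np.random.default_rng(seq)
            runs = []
            for _ in range(spec.n_runs):
                t = spec.n_volumes
                data = bg_sd * rng.standard_normal((t, *spec.grid_dims))
                g = rng.standard_normal(t)
                for k, name in enumerate(names):
                    sign = -1.0 if (rho < 0 and k == 1) else 1.0
                    u = sign * s_rho * g + s_res * rng.standard_normal(t)
                    vox = rois[name]
                    noise = spec.noise_sd * rng.standard_normal((t, len(vox)))
                    data[:, vox[:, 0], vox[:, 1], vox[:, 2]] = u[:, None] + noise
                runs.append(Volume4D(data=data, affine=affine))
            subjects.append(
                SubjectScans(
                    subject_id=f"{gname}_s{si + 1:02d}", group=gname, runs=runs
                )
            )
    return FmriStudy(subjects=subjects, spec=spec, rois=rois, latent_r=latent_r)
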