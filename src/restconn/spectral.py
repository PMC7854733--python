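"""Band-limited cross-spectra and the weighted phase lag index (wPLI).

The wPLI quantifies phase synchronization between two signals as the
asymmetry of their phase-difference distribution, weighting each
observation by the magnitude of the imaginary cross-spectrum:

    wPLI = |E{|Im X| sgn(Im X)}| / E{|Im X|}

with X the complex cross-spectrum and the expectation taken across
epochs at each frequency bin.  Because instantaneous (zero-lag) mixing
of sources — volume conduction through the scalp — produces a purely
real cross-spectrum, wPLI is insensitive to it, unlike coherence or
correlation.  Values range from 0 (no consistent phase lag) to 1
(constant nonzero phase lag).

The band-level value is the unweighted mean of per-bin wPLI over the
bins falling in the half-open interval [lo, hi), so the five default
EEG bands partition 1-80 Hz without double counting shared edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal import get_window

__all__ = [
    "Recording",
    "BandSpec",
    "CrossSpectrumStack",
    "BandWpliMatrix",
    "DEFAULT_BANDS",
    "segment_epochs",
    "cross_spectra",
    "wpli",
    "band_wpli",
]


@dataclass
class Recording:
    """Multichannel time series: ``data`` is channels x samples."""

    data: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")
        if not self.labels:
            self.labels = [f"ch{i + 1:02d}" for i in range(self.data.shape[0])]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count must equal channel count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass(frozen=True)
class BandSpec:
    """Frequency band, half-open: bins with lo <= f < hi belong to it."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band edges ({self.lo}, {self.hi})")


#: Canonical resting-state EEG analysis bands.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 5.0),
    BandSpec("theta", 5.0, 8.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta", 12.0, 30.0),
    BandSpec("gamma", 30.0, 80.0),
)


@dataclass
class CrossSpectrumStack:
    """Per-epoch complex cross-spectra: values is (epochs, bins, C, C)."""

    values: np.ndarray
    freqs: np.ndarray
    band: BandSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.values.ndim != 4 or self.values.shape[2] != self.values.shape[3]:
            raise ValueError("values must be (epochs, bins, channels, channels)")
        if self.values.shape[1] != self.freqs.size:
            raise ValueError("freqs length must match the bin axis")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]


@dataclass
class BandWpliMatrix:
    """Symmetric channel x channel wPLI matrix for one band."""

    values: np.ndarray
    band: BandSpec
    n_observations: int
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("wPLI matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("wPLI matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("wPLI diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("wPLI values must lie in [0, 1]")


def segment_epochs(
    rec: Recording, epoch_len: float, overlap: float = 0.0
) -> list[np.ndarray]:
    """Cut a recording into fixed-length epochs.

    Epochs advance by ``epoch_len * (1 - overlap)`` seconds; a trailing
    partial epoch is discarded.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    n_per = int(round(epoch_len * rec.fs))
    if n_per < 2:
        raise ValueError("epoch must span at least 2 samples")
    if n_per > rec.n_samples:
        raise ValueError(
            f"epoch ({epoch_len} s) longer than recording ({rec.duration} s)"
        )
    step = max(1, int(round(n_per * (1 - overlap))))
    starts = range(0, rec.n_samples - n_per + 1, step)
    return [rec.data[:, s : s + n_per] for s in starts]


def _band_bins(n_samples: int, fs: float, band: BandSpec) -> tuple[np.ndarray, np.ndarray]:
    nyquist = fs / 2.0
    if band.hi > nyquist:
        raise ValueError(
            f"band {band.name} ({band.lo}-{band.hi} Hz) exceeds Nyquist ({nyquist} Hz)"
        )
    freqs = rfftfreq(n_samples, 1.0 / fs)
    sel = (freqs >= band.lo) & (freqs < band.hi)
    if not sel.any():
        raise ValueError(
            f"no frequency bins fall inside band {band.name}; use longer epochs"
        )
    return freqs[sel], sel


def cross_spectra(
    epochs: list[np.ndarray],
    band: BandSpec,
    fs: float,
    taper: str = "hann",
) -> CrossSpectrumStack:
    """Tapered-FFT cross-spectral estimates for one band.

    Returns one complex C x C matrix per (epoch, in-band frequency bin);
    each matrix is Hermitian by construction (X_ij = conj(X_ji)), so the
    imaginary part is antisymmetric with a zero diagonal.
    """
    if len(epochs) < 2:
        raise ValueError("need >= 2 epochs (expectation over epochs undefined)")
    if any(e.shape != epochs[0].shape for e in epochs):
        raise ValueError("epochs must share one shape")
    n = epochs[0].shape[1]
    freqs, sel = _band_bins(n, fs, band)
    win = get_window(taper, n, fftbins=True)
    mats = []
    for ep in epochs:
        spec = rfft(ep * win, axis=1)[:, sel]  # (C, B)
        # X[b, i, j] = F_i(b) * conj(F_j(b))
        x = np.einsum("ib,jb->bij", spec, np.conj(spec))
        mats.append(x)
    return CrossSpectrumStack(values=np.stack(mats), freqs=freqs, band=band)


def wpli(stack: CrossSpectrumStack) -> BandWpliMatrix:
    """wPLI from a cross-spectrum stack.

    Per bin: |E{|Im X| sgn(Im X)}| / E{|Im X|} with E across epochs;
    bins where the denominator vanishes contribute 0 (a purely zero-lag
    coupling carries no lag information).  The band value is the mean of
    per-bin wPLI across in-band bins.
    """
    im = stack.values.imag  # (E, B, C, C)
    num = np.abs(np.mean(np.abs(im) * np.sign(im), axis=0))
    den = np.mean(np.abs(im), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_bin = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    vals = per_bin.mean(axis=0)
    vals = 0.5 * (vals + vals.T)
    np.fill_diagonal(vals, 0.0)
    vals = np.clip(vals, 0.0, 1.0)
    return BandWpliMatrix(values=vals, band=stack.band, n_observations=stack.n_epochs)


def band_wpli(
    rec: Recording,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    epoch_len: float = 2.0,
    overlap: float = 0.5,
    taper: str = "hann",
) -> list[BandWpliMatrix]:
    """Per-band wPLI matrices for a recording.

    Composition of :func:`segment_epochs` -> :func:`cross_spectra` ->
    :func:`wpli`, with the FFT shared across bands and the per-epoch
    cross-spectra accumulated rather than stored (identical numerics,
    bounded memory for long recordings).
    """
    epochs = segment_epochs(rec, epoch_len, overlap)
    if len(epochs) < 2:
        raise ValueError("need >= 2 epochs")
    n = epochs[0].shape[1]
    selections = [_band_bins(n, rec.fs, b) for b in bands]
    win = get_window(taper, n, fftbins=True)
    c = rec.n_channels
    sums = [np.zeros((f.size, c, c)) for f, _ in selections]
    abs_sums = [np.zeros((f.size, c, c)) for f, _ in selections]
    for ep in epochs:
        spec = rfft(ep * win, axis=1)  # (C, bins)
        for k, (_, sel) in enumerate(selections):
            s = spec[:, sel]
            im = np.einsum("ib,jb->bij", s, np.conj(s)).imag
            sums[k] += im  # |Im| * sgn(Im) == Im
            abs_sums[k] += np.abs(im)
    out = []
    n_ep = len(epochs)
    for k, band in enumerate(bands):
        num = np.abs(sums[k] / n_ep)
        den = abs_sums[k] / n_ep
        per_bin = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        vals = per_bin.mean(axis=0)
        vals = 0.5 * (vals + vals.T)
        np.fill_diagonal(vals, 0.0)
        vals = np.clip(vals, 0.0, 1.0)
        out.append(
            BandWpliMatrix(
                values=vals, band=band, n_observations=n_ep, labels=list(rec.labels)
            )
        )
    return out
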