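"""Seed-based resting-state fMRI connectivity with Fisher r-to-z.

Spherical regions of interest are placed at MNI millimetre coordinates
(a 5 mm sphere on a 3 mm isotropic grid covers 19 voxels), the mean
time course inside each seed is extracted, and connectivity is the
Pearson correlation of that time course with every in-mask voxel
(seed-to-whole-brain) or with a second seed's time course
(seed-to-seed), normalized by Fisher's transformation

    z = log((1 + a) / (1 - a)) / 2.

Multi-run sessions are handled per run (correlate, transform, average
z across runs) by default; concatenation after per-run standardization
is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "Volume4D",
    "SeedSpec",
    "ConnectivityMap",
    "SubjectConnectivityScore",
    "sphere_roi",
    "seed_timecourse",
    "fisher_z",
    "correlation_map",
    "seed_whole_brain_score",
    "seed_seed_z",
    "multi_run_seed_seed_z",
    "multi_run_whole_brain_score",
    "concatenate_runs",
]


@dataclass
class Volume4D:
    """4-D scan: ``data`` is time x X x Y x Z; ``affine`` maps voxel
    indices to MNI mm; ``mask`` flags in-brain voxels (default: all)."""

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (time, x, y, z)")
        if self.data.shape[0] < 10:
            raise ValueError("need >= 10 time points")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[1:], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[1:]:
                raise ValueError("mask dims must match spatial dims")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass(frozen=True)
class SeedSpec:
    """Spherical seed: MNI mm center and radius."""

    name: str
    center: tuple[float, float, float]
    radius: float = 5.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if len(self.center) != 3:
            raise ValueError("center must be (x, y, z) in mm")


@dataclass
class ConnectivityMap:
    """Voxelwise Fisher-z map for one seed; NaN outside the mask."""

    values: np.ndarray
    seed: SeedSpec
    subject_id: str = ""


@dataclass
class SubjectConnectivityScore:
    """One scalar z per subject and seed (or seed pair)."""

    subject_id: str
    seed_name: str
    score: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("connectivity score must be finite")


def sphere_roi(
    seed: SeedSpec, affine: np.ndarray, grid_dims: tuple[int, int, int]
) -> np.ndarray:
    """Voxel indices (N x 3) whose centers lie within the seed radius.

    The seed center is snapped to the nearest voxel center first, so
    voxel counts are invariant under whole-voxel translation; the
    boundary is inclusive (a 5 mm sphere on a 3 mm grid -> 19 voxels).
    """
    affine = np.asarray(affine, dtype=float)
    inv = np.linalg.inv(affine)
    vox = inv @ np.array([*seed.center, 1.0])
    center_vox = np.rint(vox[:3]).astype(int)
    if np.any(center_vox < 0) or np.any(center_vox >= np.array(grid_dims)):
        raise ValueError(
            f"seed {seed.name!r} center maps outside the grid: voxel {center_vox}"
        )
    center_mm = (affine @ np.array([*center_vox, 1.0]))[:3]
    # bounding box in voxel steps along each axis
    step = np.linalg.norm(affine[:3, :3], axis=0)
    half = np.ceil(seed.radius / step).astype(int)
    lo = np.maximum(center_vox - half, 0)
    hi = np.minimum(center_vox + half, np.array(grid_dims) - 1)
    rng = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    grid = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    homo = np.hstack([grid, np.ones((grid.shape[0], 1))])
    mm = homo @ affine.T
    dist = np.linalg.norm(mm[:, :3] - center_mm, axis=1)
    voxels = grid[dist <= seed.radius + 1e-9]
    if voxels.size == 0:  # pragma: no cover - center voxel always qualifies
        raise ValueError(f"seed {seed.name!r} produced an empty ROI")
    return voxels.astype(int)


def seed_timecourse(vol: Volume4D, roi: np.ndarray) -> np.ndarray:
    """Mean over ROI voxels at each time point."""
    roi = np.asarray(roi, dtype=int)
    if roi.ndim != 2 or roi.shape[1] != 3:
        raise ValueError("roi must be an N x 3 voxel index array")
    if not vol.mask[roi[:, 0], roi[:, 1], roi[:, 2]].all():
        raise ValueError("ROI extends outside the brain mask")
    return vol.data[:, roi[:, 0], roi[:, 1], roi[:, 2]].mean(axis=1)


def fisher_z(a, clip: bool = False):
    """Fisher r-to-z: z = log((1 + a) / (1 - a)) / 2.

    Odd and strictly increasing; |a| >= 1 raises unless ``clip`` is set,
    which clips to +/-(1 - 1e-7).
    """
    arr = np.asarray(a, dtype=float)
    if np.any(np.abs(arr) >= 1):
        if not clip:
            raise ValueError("|r| >= 1 has infinite z; pass clip=True to bound it")
        arr = np.clip(arr, -1 + 1e-7, 1 - 1e-7)
    z = 0.5 * (np.log1p(arr) - np.log1p(-arr))
    return float(z) if np.isscalar(a) else z


def _pearson_to_tc(series: np.ndarray, tc: np.ndarray) -> np.ndarray:
    """Columnwise Pearson r of series (T x V) against tc (T,); constant
    columns get r = 0."""
    tc_c = tc - tc.mean()
    tc_norm = np.linalg.norm(tc_c)
    if tc_norm == 0:
        raise ValueError("seed time course is constant")
    s_c = series - series.mean(axis=0)
    s_norm = np.linalg.norm(s_c, axis=0)
    safe = s_norm > 0
    r = np.zeros(series.shape[1])
    r[safe] = (s_c[:, safe].T @ tc_c) / (s_norm[safe] * tc_norm)
    return np.clip(r, -1.0, 1.0)


def correlation_map(
    vol: Volume4D, tc: np.ndarray, clip: bool = False, subject_id: str = "",
    seed: SeedSpec | None = None,
) -> ConnectivityMap:
    """Fisher-z map of each in-mask voxel's correlation with ``tc``."""
    tc = np.asarray(tc, dtype=float)
    if tc.shape != (vol.n_volumes,):
        raise ValueError("time course length must equal the number of volumes")
    flat = vol.data.reshape(vol.n_volumes, -1)
    in_mask = vol.mask.ravel()
    r = _pearson_to_tc(flat[:, in_mask], tc)
    z = fisher_z(r, clip=clip)
    out = np.full(in_mask.shape, np.nan)
    out[in_mask] = z
    return ConnectivityMap(
        values=out.reshape(vol.grid_dims),
        seed=seed or SeedSpec("seed", (0.0, 0.0, 0.0), 1.0),
        subject_id=subject_id,
    )


_REDUCERS = {
    "mean_abs": lambda z: float(np.mean(np.abs(z))),
    "mean": lambda z: float(np.mean(z)),
    "mean_pos": lambda z: float(np.mean(z[z > 0])) if np.any(z > 0) else 0.0,
}


def seed_whole_brain_score(
    cmap: ConnectivityMap,
    mask: np.ndarray,
    roi: np.ndarray | None = None,
    reducer: str = "mean_abs",
) -> SubjectConnectivityScore:
    """Reduce a z map to one scalar over in-mask voxels, excluding the
    seed's own voxels.  Default reducer: mean |z|."""
    if reducer not in _REDUCERS:
        raise ValueError(f"unknown reducer {reducer!r}; options {sorted(_REDUCERS)}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    include = mask.copy()
    if roi is not None:
        roi = np.asarray(roi, dtype=int)
        include[roi[:, 0], roi[:, 1], roi[:, 2]] = False
    z = cmap.values[include]
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValueError("no voxels left after excluding the seed ROI")
    return SubjectConnectivityScore(
        subject_id=cmap.subject_id,
        seed_name=f"{cmap.seed.name}-WholeBrain",
        score=_REDUCERS[reducer](z),
    )


def seed_seed_z(
    vol: Volume4D, a: SeedSpec, b: SeedSpec, clip: bool = False, subject_id: str = ""
) -> SubjectConnectivityScore:
    """Fisher z of the Pearson correlation between two seeds' mean time
    courses.  Overlapping ROIs are rejected."""
    roi_a = sphere_roi(a, vol.affine, vol.grid_dims)
    roi_b = sphere_roi(b, vol.affine, vol.grid_dims)
    set_a = {tuple(v) for v in roi_a}
    set_b = {tuple(v) for v in roi_b}
    if set_a & set_b:
        raise ValueError(f"seeds {a.name!r} and {b.name!r} overlap")
    tc_a = seed_timecourse(vol, roi_a)
    tc_b = seed_timecourse(vol, roi_b)
    r, _ = sps.pearsonr(tc_a, tc_b)
    return SubjectConnectivityScore(
        subject_id=subject_id,
        seed_name=f"{a.name}-{b.name}",
        score=fisher_z(float(r), clip=clip),
    )


def concatenate_runs(runs: list[Volume4D]) -> Volume4D:
    """Concatenate runs in time after per-run voxelwise standardization
    (zero mean, unit variance; constant voxels left at zero)."""
    if not runs:
        raise ValueError("no runs")
    pieces = []
    for run in runs:
        d = run.data - run.data.mean(axis=0)
        sd = run.data.std(axis=0)
        sd[sd == 0] = 1.0
        pieces.append(d / sd)
    return Volume4D(
        data=np.concatenate(pieces, axis=0), affine=runs[0].affine, mask=runs[0].mask
    )


def multi_run_seed_seed_z(
    runs: list[Volume4D],
    a: SeedSpec,
    b: SeedSpec,
    how: str = "average",
    clip: bool = False,
    subject_id: str = "",
) -> SubjectConnectivityScore:
    """Seed-seed z across runs: per-run z averaged (default) or computed
    on standardized concatenated runs."""
    if how == "average":
        zs = [seed_seed_z(r, a, b, clip=clip, subject_id=subject_id).score for r in runs]
        score = float(np.mean(zs))
    elif how == "concat":
        score = seed_seed_z(
            concatenate_runs(runs), a, b, clip=clip, subject_id=subject_id
        ).score
    else:
        raise ValueError("how must be 'average' or 'concat'")
    return SubjectConnectivityScore(
        subject_id=subject_id, seed_name=f"{a.name}-{b.name}", score=score
    )


def multi_run_whole_brain_score(
    runs: list[Volume4D],
    seed: SeedSpec,
    how: str = "average",
    reducer: str = "mean_abs",
    clip: bool = False,
    subject_id: str = "",
) -> SubjectConnectivityScore:
    """Seed-to-whole-brain score across runs (reduce per run, average by
    default; or reduce the standardized concatenation)."""
    vols = runs if how == "average" else [concatenate_runs(runs)]
    if how not in ("average", "concat"):
        raise ValueError("how must be 'average' or 'concat'")
    scores = []
    for vol in vols:
        roi = sphere_roi(seed, vol.affine, vol.grid_dims)
        tc = seed_timecourse(vol, roi)
        cmap = correlation_map(vol, tc, clip=clip, subject_id=subject_id, seed=seed)
        scores.append(
            seed_whole_brain_score(cmap, vol.mask, roi=roi, reducer=reducer).score
        )
    return SubjectConnectivityScore(
        subject_id=subject_id,
        seed_name=f"{seed.name}-WholeBrain",
        score=float(np.mean(scores)),
    )
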