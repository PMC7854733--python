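"""On-disk formats.

Recordings travel as TSV sample matrices (rows = channels, first
column = label) with a JSON sidecar holding the sampling rate; EDF
files are read through MNE when available.  Connectivity matrices and
metric/score tables are TSV; 4-D volumes and z maps are NIfTI via
nibabel (spatial axes first on disk, time first in memory).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .graph import GraphMetricRecord
from .seed import SeedSpec, Volume4D
from .spectral import BandSpec, BandWpliMatrix, Recording

__all__ = [
    "TABLE3_SEEDS",
    "PRIMARY_SEEDS",
    "SEED_PAIRS",
    "write_recording",
    "read_recording",
    "write_wpli_matrix",
    "read_wpli_matrix",
    "metric_records_to_frame",
    "write_metric_table",
    "read_metric_table",
    "write_volume",
    "read_volume",
    "read_mask",
    "write_zmap",
    "write_seed_table",
    "read_seed_table",
]

#: The eight working-memory-network seeds (MNI mm, 5 mm radius):
#: one primary and one secondary region per network (DMN, CEN, DAN, SN).
TABLE3_SEEDS: tuple[SeedSpec, ...] = (
    SeedSpec("rPCC", (5.0, -49.0, 40.0)),
    SeedSpec("vmPFC", (-4.0, 54.0, 0.0)),
    SeedSpec("rDLPFC", (44.0, 36.0, 20.0)),
    SeedSpec("rPPC", (42.0, -56.0, 50.0)),
    SeedSpec("rIPS", (39.0, -42.0, 51.0)),
    SeedSpec("FEF", (-26.0, 10.0, 51.0)),
    SeedSpec("rAI", (42.0, 0.0, 2.0)),
    SeedSpec("BA47", (38.0, 24.0, -12.0)),
)

#: Primary seed per network, used against the whole brain.
PRIMARY_SEEDS: tuple[str, ...] = ("rPCC", "rDLPFC", "rIPS", "rAI")

#: Within-network seed pairs (primary, secondary).
SEED_PAIRS: tuple[tuple[str, str], ...] = (
    ("rPCC", "vmPFC"),
    ("rDLPFC", "rPPC"),
    ("rIPS", "FEF"),
    ("rAI", "BA47"),
)


def write_recording(rec: Recording, path: str | Path) -> tuple[Path, Path]:
    """TSV matrix (label + samples per row) plus JSON sidecar (fs)."""
    path = Path(path)
    frame = pd.DataFrame(rec.data, index=rec.labels)
    frame.to_csv(path, sep="\t", header=False, float_format="%.10g")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"fs": rec.fs, "labels": rec.labels}))
    return path, sidecar


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return Recording(
            data=raw.get_data(), fs=float(raw.info["sfreq"]), labels=raw.ch_names
        )
    sidecar = json.loads(path.with_suffix(".json").read_text())
    frame = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return Recording(
        data=frame.to_numpy(dtype=float),
        fs=float(sidecar["fs"]),
        labels=[str(x) for x in sidecar["labels"]],
    )


def write_wpli_matrix(mat: BandWpliMatrix, path: str | Path) -> Path:
    """Labelled TSV matrix plus a JSON provenance sidecar."""
    path = Path(path)
    labels = mat.labels or [f"ch{i + 1:02d}" for i in range(mat.values.shape[0])]
    pd.DataFrame(mat.values, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.10g"
    )
    meta = {
        "band": {"name": mat.band.name, "lo": mat.band.lo, "hi": mat.band.hi},
        "n_observations": mat.n_observations,
    }
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def read_wpli_matrix(path: str | Path) -> BandWpliMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    meta = json.loads(path.with_suffix(".json").read_text())
    return BandWpliMatrix(
        values=frame.to_numpy(dtype=float),
        band=BandSpec(**meta["band"]),
        n_observations=int(meta["n_observations"]),
        labels=[str(c) for c in frame.columns],
    )


def metric_records_to_frame(records: list[GraphMetricRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject": r.subject_id,
                "band": r.band,
                "cost": r.cost,
                "Q": r.q,
                "Eglob": r.eglob,
                "Eloc": r.eloc,
            }
            for r in records
        ]
    )


def write_metric_table(records: list[GraphMetricRecord], path: str | Path) -> Path:
    path = Path(path)
    metric_records_to_frame(records).to_csv(path, sep="\t", index=False)
    return path


def read_metric_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_volume(vol: Volume4D, path: str | Path) -> Path:
    """NIfTI with spatial axes first (x, y, z, t) as on disk."""
    path = Path(path)
    img = nib.Nifti1Image(np.moveaxis(vol.data, 0, -1), vol.affine)
    nib.save(img, path)
    return path


def read_volume(path: str | Path, mask: np.ndarray | None = None) -> Volume4D:
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.get_fdata()), -1, 0)
    return Volume4D(data=data, affine=np.asarray(img.affine), mask=mask)


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0


def write_zmap(cmap_values: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(cmap_values, dtype=float), affine), path)
    return path


def write_seed_table(seeds: tuple[SeedSpec, ...], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {"name": s.name, "x": s.center[0], "y": s.center[1], "z": s.center[2],
             "radius": s.radius}
            for s in seeds
        ]
    ).to_csv(path, sep="\t", index=False)
    return path


def read_seed_table(path: str | Path) -> tuple[SeedSpec, ...]:
    frame = pd.read_csv(path, sep="\t")
    return tuple(
        SeedSpec(
            name=str(row["name"]),
            center=(float(row["x"]), float(row["y"]), float(row["z"])),
            radius=float(row["radius"]),
        )
        for _, row in frame.iterrows()
    )
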