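"""Readers and writers for the on-disk interchange formats.

Stacks travel as multi-page TIFF with a JSON sidecar holding the voxel
sizes and modality tag; everything else is plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from repliconscope.datatypes import DnaHistogram, FibreSegment, FibreTrack, VoxelStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_fibre_tracks",
    "read_fibre_tracks",
    "write_histogram",
    "read_histogram",
    "write_timelapse_labels",
    "read_timelapse_labels",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: VoxelStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.data, dtype=np.float32))
    meta = {
        "voxel_xy_nm": stack.voxel_xy,
        "voxel_z_nm": stack.voxel_z,
        "modality": stack.modality,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path) -> VoxelStack:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        meta = {"voxel_xy_nm": 1.0, "voxel_z_nm": 1.0, "modality": "unknown"}
    return VoxelStack(
        data, meta["voxel_xy_nm"], meta["voxel_z_nm"], meta.get("modality", "unknown")
    )


def write_fibre_tracks(tracks: list[FibreTrack], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "fibre_id": t.fibre_id,
            "segment_index": i,
            "label": seg.label,
            "start_um": seg.start_um,
            "end_um": seg.end_um,
            "censored": int(seg.censored),
        }
        for t in tracks
        for i, seg in enumerate(t.segments)
    ]
    pd.DataFrame(
        rows,
        columns=["fibre_id", "segment_index", "label", "start_um", "end_um", "censored"],
    ).to_csv(path, index=False, float_format="%.6f")
    return path


def read_fibre_tracks(path: str | Path) -> list[FibreTrack]:
    df = pd.read_csv(path)
    tracks = []
    for fid, grp in df.groupby("fibre_id", sort=True):
        grp = grp.sort_values("segment_index")
        segs = [
            FibreSegment(
                row.label, float(row.start_um), float(row.end_um),
                bool(getattr(row, "censored", 0)),
            )
            for row in grp.itertuples()
        ]
        tracks.append(FibreTrack(int(fid), segs))
    return tracks


def write_histogram(hist: DnaHistogram, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"channel": hist.channels, "count": hist.counts}).to_csv(
        path, index=False
    )
    meta = {}
    if hist.reference_window is not None:
        meta["reference_window"] = list(hist.reference_window)
    if hist.sample_window is not None:
        meta["sample_window"] = list(hist.sample_window)
    if meta:
        _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_histogram(
    path: str | Path,
    reference_window: tuple[float, float] | None = None,
    sample_window: tuple[float, float] | None = None,
) -> DnaHistogram:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        reference_window = reference_window or tuple(meta.get("reference_window", ()))
        sample_window = sample_window or tuple(meta.get("sample_window", ()))
    return DnaHistogram(
        df["channel"].to_numpy(float),
        df["count"].to_numpy(float),
        reference_window or None,
        sample_window or None,
    )


def write_timelapse_labels(labels: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    labels.to_csv(path, index=False)
    return path


def read_timelapse_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
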