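"""Synthetic time-lapse stage-label sequences.

Cells cycle through M -> G1 -> Se -> Sm -> Sl -> G2 -> M. The emitted
per-frame labels report G1 and G2 frames as ``"homogeneous"`` (a uniform
replisome-marker distribution does not distinguish the two gap stages);
downstream analysis disambiguates them from their neighbours.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["STAGE_ORDER", "generate_timelapse_labels", "frames_per_stage"]

STAGE_ORDER = ("M", "G1", "Se", "Sm", "Sl", "G2")

_HOMOGENEOUS = {"G1", "G2"}


def frames_per_stage(duration_hours: float, frame_interval_min: float) -> int:
    """Convert a stage duration to a frame count (round half up)."""
    return int(np.floor(duration_hours * 60.0 / frame_interval_min + 0.5))


def generate_timelapse_labels(
    stage_durations: dict[str, float],
    *,
    frame_interval_min: float = 15.0,
    n_cells: int = 1,
    n_frames: int | None = None,
    random_start: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate per-cell frame label sequences.

    Parameters
    ----------
    stage_durations
        Hours per stage, keyed by ``M, G1, Se, Sm, Sl, G2``. A single
        ``"S"`` key may be given instead of the three sub-stages and is
        split evenly.
    n_frames
        Frames per cell; defaults to two full cycles so every cell
        contains at least one complete run of each stage.
    random_start
        Start each cell at a random phase of the cycle.

    Returns a tidy frame with columns ``cell_id, frame, label`` where G1
    and G2 frames are emitted as ``"homogeneous"``.
    """
    if frame_interval_min <= 0:
        raise ValueError("frame interval must be positive")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    durations = dict(stage_durations)
    if any(v < 0 for v in durations.values()):
        raise ValueError("stage durations must be >= 0")
    s_frames: dict[str, int] = {}
    if "S" in durations:
        # allocate the rounded total S frame count across the three
        # sub-stages so the pooled S duration keeps sub-frame accuracy
        total = frames_per_stage(durations.pop("S"), frame_interval_min)
        base, rem = divmod(total, 3)
        for i, sub in enumerate(("Se", "Sm", "Sl")):
            s_frames[sub] = base + (1 if i < rem else 0)
            durations.setdefault(sub, 0.0)
    unknown = set(durations) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if sum(durations.get(s, 0.0) for s in STAGE_ORDER) <= 0 and not any(
        s_frames.values()
    ):
        raise ValueError("at least one stage duration must be positive")

    cycle: list[str] = []
    for stage in STAGE_ORDER:
        if stage in s_frames:
            n = s_frames[stage] + frames_per_stage(
                durations.get(stage, 0.0), frame_interval_min
            )
        else:
            n = frames_per_stage(durations.get(stage, 0.0), frame_interval_min)
        cycle.extend([stage] * n)
    if not cycle:
        raise ValueError("cycle contains no frames at this frame interval")
    cycle_arr = np.array(cycle)
    n_cycle = len(cycle_arr)
    total = n_frames if n_frames is not None else 2 * n_cycle

    rng = np.random.default_rng(seed)
    rows = []
    for cell in range(n_cells):
        offset = int(rng.integers(0, n_cycle)) if random_start else 0
        idx = (offset + np.arange(total)) % n_cycle
        labels = cycle_arr[idx]
        labels = np.where(np.isin(labels, list(_HOMOGENEOUS)), "homogeneous", labels)
        rows.append(
            pd.DataFrame(
                {"cell_id": cell, "frame": np.arange(total), "label": labels}
            )
        )
    return pd.concat(rows, ignore_index=True)
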