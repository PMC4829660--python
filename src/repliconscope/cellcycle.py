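"""Cell-cycle stage durations from per-frame time-lapse labels.

Homogeneous (uniform replisome marker) frames are first resolved to G1
or G2 from their neighbouring stages, then per-cell durations are frame
counts multiplied by the frame interval, and finally per-stage
population statistics and the doubling time are assembled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from repliconscope.fibres import SummaryStats, summarize

__all__ = [
    "S_STAGES",
    "StageDurationTable",
    "disambiguate_homogeneous",
    "stage_durations",
    "population_summary",
]

S_STAGES = ("Se", "Sm", "Sl")
UNRESOLVED = "unresolved"


def disambiguate_homogeneous(labels: list[str]) -> tuple[list[str], int]:
    """Resolve ``"homogeneous"`` runs to G1 or G2 using their neighbours.

    A run following M (or preceding S) becomes G1; a run following S (or
    preceding M) becomes G2. Runs without an informative neighbour stay
    ``"unresolved"``. Returns the resolved sequence and the number of
    unresolved frames.
    """
    if not labels:
        raise ValueError("label sequence must be non-empty")
    out = list(labels)
    n_unresolved = 0
    i = 0
    while i < len(out):
        if out[i] != "homogeneous":
            i += 1
            continue
        j = i
        while j < len(out) and out[j] == "homogeneous":
            j += 1
        prev = out[i - 1] if i > 0 else None
        nxt = out[j] if j < len(out) else None
        if prev == "M" or (nxt in S_STAGES or nxt == "S"):
            stage = "G1"
        elif prev in S_STAGES or prev == "S" or nxt == "M":
            stage = "G2"
        else:
            stage = UNRESOLVED
            n_unresolved += j - i
        out[i:j] = [stage] * (j - i)
        i = j
    return out, n_unresolved


def _complete_runs(labels: list[str]) -> list[tuple[str, int]]:
    """Maximal constant runs not touching either sequence boundary."""
    runs: list[tuple[str, int, bool]] = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        runs.append((labels[i], j - i, i > 0 and j < len(labels)))
        i = j
    return [(lab, n) for lab, n, complete in runs if complete]


def stage_durations(
    labels: list[str],
    frame_interval_min: float = 15.0,
    *,
    complete_runs_only: bool = False,
    pool_s: bool = False,
    allow_unresolved: bool = False,
) -> dict[str, float]:
    """Per-stage durations (hours) for one cell.

    By default every frame of a stage contributes
    ``frame_interval / 60`` hours. With ``complete_runs_only`` each stage
    is measured from its interior runs only (runs cut by the start or
    end of the recording are dropped), averaging if a stage was fully
    observed more than once; stages with no complete run are omitted.
    With ``pool_s`` the contiguous Se/Sm/Sl block is measured as one
    ``"S"`` stage.
    """
    if frame_interval_min <= 0:
        raise ValueError("frame interval must be positive")
    if not labels:
        raise ValueError("label sequence must be non-empty")
    if UNRESOLVED in labels and not allow_unresolved:
        raise ValueError(
            "sequence contains unresolved frames; resolve them first or pass "
            "allow_unresolved=True to skip them"
        )
    work = list(labels)
    if pool_s:
        work = ["S" if lab in S_STAGES else lab for lab in work]
    hours_per_frame = frame_interval_min / 60.0
    if not complete_runs_only:
        out: dict[str, float] = {}
        for lab in work:
            if lab == UNRESOLVED:
                continue
            out[lab] = out.get(lab, 0.0) + hours_per_frame
        return out
    per_stage: dict[str, list[float]] = {}
    for lab, n in _complete_runs(work):
        if lab == UNRESOLVED:
            continue
        per_stage.setdefault(lab, []).append(n * hours_per_frame)
    return {lab: float(np.mean(v)) for lab, v in per_stage.items()}


@dataclass
class StageDurationTable:
    """Population statistics of stage durations, in hours."""

    stages: dict[str, SummaryStats]
    doubling_time_from_means: float
    doubling_time_per_cell: SummaryStats | None


def _stats(values: list[float]) -> SummaryStats:
    if len(values) >= 2:
        return summarize(values)
    return SummaryStats(float(values[0]), float("nan"), float("nan"), float("nan"), 1)


def population_summary(per_cell: list[dict[str, float]]) -> StageDurationTable:
    """Combine per-cell stage durations into a population table.

    Cells contribute only the stages they completed, so the n can differ
    per stage. The doubling time is reported both as the sum of the
    per-stage means and, for cells with every major stage observed, as
    the mean per-cell full-cycle length.
    """
    if not per_cell:
        raise ValueError("need at least one cell")
    pooled: dict[str, list[float]] = {}
    for cell in per_cell:
        cell = dict(cell)
        if "S" not in cell and all(s in cell for s in S_STAGES):
            cell["S"] = sum(cell[s] for s in S_STAGES)
        for stage, hours in cell.items():
            pooled.setdefault(stage, []).append(hours)
    stages = {stage: _stats(vals) for stage, vals in pooled.items()}

    major = ("G1", "S", "G2", "M")
    doubling_from_means = sum(stages[s].mean for s in major if s in stages)
    cycle_lengths = [
        sum(cell.get("S", sum(cell.get(s, 0.0) for s in S_STAGES)) if stage == "S"
            else cell[stage] for stage in major)
        for cell in per_cell
        if all(stage in cell or (stage == "S" and all(s in cell for s in S_STAGES))
               for stage in major)
    ]
    per_cell_doubling = _stats(cycle_lengths) if cycle_lengths else None
    return StageDurationTable(stages, float(doubling_from_means), per_cell_doubling)
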