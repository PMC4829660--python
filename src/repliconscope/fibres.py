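"""Fork-speed and inter-origin-distance estimation from combed-fibre
track tables, plus the descriptive statistics used throughout the
reports.

Conventions: combing stretch factor 2 kbp per micrometre; fork speed is
the second-pulse track length divided by the pulse duration; an origin
is called at the midpoint of a first-pulse region flanked on both sides
by second-pulse signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from repliconscope.datatypes import FibreTrack

__all__ = [
    "SummaryStats",
    "SlidingAverage",
    "track_length_kbp",
    "fork_speed",
    "fork_speeds_from_track",
    "inter_origin_distances",
    "summarize",
    "sliding_average",
]

#: two-sided 95% normal quantile (consistent with the printed CIs)
Z_95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class SummaryStats:
    """Mean, sample s.d., s.e.m. and 95% CI half-width of one variable."""

    mean: float
    sd: float
    sem: float
    ci95: float
    n: int


def track_length_kbp(length_um: float, stretch: float = 2.0) -> float:
    """Convert a measured track length from micrometres to kbp."""
    if length_um < 0:
        raise ValueError("track length must be >= 0")
    if stretch <= 0:
        raise ValueError("stretch factor must be positive")
    return length_um * stretch


def fork_speed(track_kbp: float, pulse_minutes: float = 30.0) -> float:
    """Fork speed in kbp/min from a single-pulse track length."""
    if pulse_minutes <= 0:
        raise ValueError("pulse duration must be positive")
    if track_kbp < 0:
        raise ValueError("track length must be >= 0")
    return track_kbp / pulse_minutes


def fork_speeds_from_track(
    track: FibreTrack, *, pulse_minutes: float = 30.0, stretch: float = 2.0
) -> list[float]:
    """Fork speeds from the second-pulse segments of one fibre.

    Only segments representing a single unobstructed fork are used: the
    segment must border first-pulse signal on exactly one side (a
    second-pulse stretch bounded by first-pulse signal on both sides is a
    termination region of two converging forks) and must not be censored
    by a fibre end. Censored segments are skipped with a warning.
    """
    speeds: list[float] = []
    segs = track.segments
    for i, seg in enumerate(segs):
        if seg.label != "pulse2":
            continue
        prev_label = segs[i - 1].label if i > 0 else None
        next_label = segs[i + 1].label if i + 1 < len(segs) else None
        p1_sides = (prev_label == "pulse1") + (next_label == "pulse1")
        if p1_sides != 1:
            continue
        if seg.censored:
            warnings.warn(
                f"fibre {track.fibre_id}: skipping censored second-pulse segment",
                stacklevel=2,
            )
            continue
        # a segment ending at the fibre boundary is cut even if unflagged
        if seg.start_um <= 1e-9 or seg.end_um >= track.length_um - 1e-9:
            continue
        speeds.append(fork_speed(track_length_kbp(seg.length_um, stretch), pulse_minutes))
    return speeds


def inter_origin_distances(
    track: FibreTrack, *, stretch: float = 2.0, include_gap_origins: bool = False
) -> list[float]:
    """Centre-to-centre distances (kbp) between adjacent called origins.

    An origin is called at the midpoint of a maximal non-second-pulse
    region that contains first-pulse signal (or, with
    ``include_gap_origins``, any such region) and is flanked by
    second-pulse signal on both sides. Fewer than two origins yield an
    empty list.
    """
    segs = track.segments
    centres: list[float] = []
    i = 0
    while i < len(segs):
        if segs[i].label == "pulse2":
            i += 1
            continue
        j = i
        has_p1 = False
        censored = False
        while j < len(segs) and segs[j].label != "pulse2":
            has_p1 = has_p1 or segs[j].label == "pulse1"
            censored = censored or segs[j].censored
            j += 1
        flanked = i > 0 and j < len(segs)  # pulse2 on both sides
        if flanked and not censored and (has_p1 or include_gap_origins):
            centres.append(0.5 * (segs[i].start_um + segs[j - 1].end_um))
        i = j
    if len(centres) < 2:
        return []
    return [track_length_kbp(b - a, stretch) for a, b in zip(centres, centres[1:])]


def summarize(values: np.ndarray | list[float]) -> SummaryStats:
    """Mean, sample s.d. (n-1), s.e.m. = sd/sqrt(n) and 95% CI half-width."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two observations to summarize")
    sd = float(arr.std(ddof=1))
    sem = sd / np.sqrt(arr.size)
    return SummaryStats(float(arr.mean()), sd, sem, Z_95 * sem, int(arr.size))


@dataclass(frozen=True)
class SlidingAverage:
    """Running means plus a convergence flag for the sample-size check."""

    running_means: np.ndarray
    converged: bool


def sliding_average(
    values: np.ndarray | list[float],
    *,
    window: int | None = None,
    tolerance: float = 0.05,
) -> SlidingAverage:
    """Running mean after each observation (or over a moving window).

    The series is flagged converged when every running mean in its final
    quarter lies within ``tolerance`` (as a fraction) of the final mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two observations")
    if window is not None:
        if window < 1 or window > arr.size:
            raise ValueError("window must lie in [1, n]")
        kernel = np.ones(window) / window
        running = np.convolve(arr, kernel, mode="valid")
    else:
        running = np.cumsum(arr) / np.arange(1, arr.size + 1)
    final = running[-1]
    tail = running[-max(1, len(running) // 4):]
    scale = abs(final) if final != 0 else 1.0
    converged = bool(np.all(np.abs(tail - final) <= tolerance * scale))
    return SlidingAverage(running, converged)
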