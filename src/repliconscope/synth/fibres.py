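"""Synthetic DNA-combing fibres.

Each fibre carries bidirectional replication tracks produced by a
30 min + 30 min dual nucleotide pulse. Origins fire during the first
pulse; each origin launches a leftward and a rightward fork with
independently drawn speeds. Converging forks of adjacent origins
terminate where they meet; origins overrun by a neighbouring fork before
their own firing time stay passive. Segments falling outside the fibre
are truncated and flagged censored (fibre breakage).

Ground truth records per-fork speeds for forks that synthesised through
the entire second pulse unobstructed, and per-pair inter-origin
distances for adjacent fired origins whose bidirectional patterns remain
individually resolvable (both forks alive into the second pulse).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from repliconscope.datatypes import FibreSegment, FibreTrack

__all__ = ["FibreSetTruth", "generate_fibre_set"]


@dataclass
class _Fork:
    origin_kbp: float
    direction: int  # +1 right, -1 left
    speed: float  # kbp/min
    t_fire: float
    t_stop: float  # min; <= 2 * pulse
    terminated: bool = False  # met a converging fork
    censored: bool = False  # truncated by a fibre end

    def position(self, t: float) -> float:
        t = min(t, self.t_stop)
        if t <= self.t_fire:
            return self.origin_kbp
        return self.origin_kbp + self.direction * self.speed * (t - self.t_fire)


@dataclass
class FibreSetTruth:
    """Generator-side ground truth for one synthetic fibre set."""

    fork_speeds_kbp_min: list[float] = field(default_factory=list)
    iods_kbp: list[float] = field(default_factory=list)
    n_origins_fired: int = 0
    n_origins_passive: int = 0
    n_forks_censored: int = 0
    n_forks_terminated: int = 0


def _draw_positive(rng: np.random.Generator, mean: float, sd: float, floor: float) -> float:
    if sd <= 0:
        return float(mean)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > floor:
            return float(v)
    raise RuntimeError("could not draw a positive value; check distribution parameters")


def generate_fibre_set(
    n_fibres: int,
    true_rfs: tuple[float, float],
    true_iod: tuple[float, float],
    *,
    pulse_minutes: float = 30.0,
    stretch: float = 2.0,
    fibre_length_kbp: tuple[float, float] = (250.0, 500.0),
    seed: int = 0,
) -> tuple[list[FibreTrack], FibreSetTruth]:
    """Generate combed fibres with dual-pulse replication tracks.

    Parameters
    ----------
    true_rfs
        ``(mean, sd)`` of the per-fork speed distribution, kbp/min.
    true_iod
        ``(mean, sd)`` of the inter-origin spacing distribution, kbp.
    pulse_minutes
        Duration of each of the two nucleotide pulses.
    stretch
        Combing stretch factor in kbp per micrometre; segment
        coordinates are emitted in micrometres (kbp / stretch).
    fibre_length_kbp
        ``(lo, hi)`` of the uniform fibre-length distribution.
    """
    if pulse_minutes <= 0 or stretch <= 0:
        raise ValueError("pulse duration and stretch factor must be positive")
    if true_rfs[0] <= 0 or true_iod[0] <= 0:
        raise ValueError("distribution means must be positive")
    lo, hi = fibre_length_kbp
    if lo <= 0 or hi < lo:
        raise ValueError("fibre length range must be positive")
    if n_fibres < 0:
        raise ValueError("n_fibres must be >= 0")

    rng = np.random.default_rng(seed)
    t_end = 2.0 * pulse_minutes
    tracks: list[FibreTrack] = []
    truth = FibreSetTruth()

    for fid in range(n_fibres):
        length = float(rng.uniform(lo, hi))
        # origin candidate positions: random phase, then IOD-distributed gaps
        positions: list[float] = []
        x = float(rng.uniform(0.0, _draw_positive(rng, *true_iod, floor=1.0)))
        while x < length:
            positions.append(x)
            x += _draw_positive(rng, *true_iod, floor=1.0)

        candidates = [
            {
                "x": p,
                "t0": float(rng.uniform(0.0, pulse_minutes)),
                "vl": _draw_positive(rng, *true_rfs, floor=0.05),
                "vr": _draw_positive(rng, *true_rfs, floor=0.05),
            }
            for p in positions
        ]

        forks: list[_Fork] = []
        origins: list[dict] = []  # fired origins with their fork objects
        frontier: _Fork | None = None  # rightmost active rightward fork
        for cand in candidates:
            if frontier is not None and frontier.position(cand["t0"]) >= cand["x"]:
                truth.n_origins_passive += 1
                continue
            left = _Fork(cand["x"], -1, cand["vl"], cand["t0"], t_end)
            right = _Fork(cand["x"], +1, cand["vr"], cand["t0"], t_end)
            if frontier is not None:
                # converging forks meet where positions coincide
                t_meet = (
                    cand["x"]
                    - frontier.origin_kbp
                    + frontier.speed * frontier.t_fire
                    + left.speed * left.t_fire
                ) / (frontier.speed + left.speed)
                if t_meet < min(frontier.t_stop, t_end):
                    frontier.t_stop = t_meet
                    frontier.terminated = True
                    left.t_stop = t_meet
                    left.terminated = True
            forks.extend([left, right])
            origins.append({"x": cand["x"], "left": left, "right": right})
            frontier = right
        truth.n_origins_fired += len(origins)

        # clip forks at fibre ends
        for fork in forks:
            end_pos = fork.position(fork.t_stop)
            if end_pos < 0.0 or end_pos > length:
                boundary = 0.0 if fork.direction < 0 else length
                t_hit = fork.t_fire + abs(boundary - fork.origin_kbp) / fork.speed
                if t_hit < fork.t_stop:
                    fork.t_stop = t_hit
                    fork.censored = True
                    fork.terminated = False

        truth.n_forks_censored += sum(f.censored for f in forks)
        truth.n_forks_terminated += sum(f.terminated for f in forks)

        # label intervals in kbp: pulse1 = [t_fire, pulse), pulse2 = [pulse, 2*pulse)
        intervals: list[tuple[str, float, float, bool]] = []
        for fork in forks:
            for label, a, b in (
                ("pulse1", fork.t_fire, pulse_minutes),
                ("pulse2", pulse_minutes, t_end),
            ):
                cut = fork.t_stop < b
                b = min(b, fork.t_stop)
                if b <= a:
                    continue
                p0, p1 = fork.position(a), fork.position(b)
                start = float(np.clip(min(p0, p1), 0.0, length))
                end = float(np.clip(max(p0, p1), 0.0, length))
                # only the interval actually cut by the fibre end is censored
                if end > start:
                    intervals.append((label, start, end, fork.censored and cut))

        # merge touching same-label intervals into ordered segments
        intervals.sort(key=lambda iv: (iv[1], iv[2]))
        merged: list[list] = []
        for label, start, end, cens in intervals:
            if merged and merged[-1][0] == label and start <= merged[-1][2] + 1e-9:
                merged[-1][2] = max(merged[-1][2], end)
                merged[-1][3] = merged[-1][3] or cens
            else:
                merged.append([label, start, end, cens])

        segments: list[FibreSegment] = []
        cursor = 0.0
        for label, start, end, cens in merged:
            if start > cursor + 1e-9:
                segments.append(FibreSegment("gap", cursor / stretch, start / stretch))
            segments.append(FibreSegment(label, start / stretch, end / stretch, cens))
            cursor = max(cursor, end)
        if cursor < length - 1e-9:
            segments.append(FibreSegment("gap", cursor / stretch, length / stretch))
        tracks.append(FibreTrack(fid, segments))

        # ground truth: fork speeds from unobstructed full-second-pulse forks
        for fork in forks:
            if not fork.censored and not fork.terminated and fork.t_stop >= t_end:
                truth.fork_speeds_kbp_min.append(fork.speed)
        # ground truth: IODs between adjacent resolvable fired origins
        def _resolvable(o: dict) -> bool:
            return o["left"].t_stop > pulse_minutes and o["right"].t_stop > pulse_minutes

        for a, b in zip(origins, origins[1:]):
            if _resolvable(a) and _resolvable(b):
                truth.iods_kbp.append(b["x"] - a["x"])

    return tracks, truth
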