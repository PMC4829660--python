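"""Origin-firing schedules and the time-averaged number of
simultaneously active replicons.

Whether origins fire in sequential synchronous waves or uniformly
asynchronously, every replicon stays active for one lifetime inside
S-phase, so the time-averaged parallel count equals
``N_tot * lifetime / T_S`` up to sampling error. The simulation verifies
that equivalence rather than assuming it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FiringSchedule", "simulate_firing_schedule"]


@dataclass(frozen=True)
class FiringSchedule:
    """Replicon count, lifetime and S-phase duration (minutes)."""

    n_replicons: int
    lifetime_min: float
    s_phase_min: float

    def __post_init__(self) -> None:
        if self.n_replicons < 1:
            raise ValueError("n_replicons must be >= 1")
        if self.lifetime_min <= 0 or self.s_phase_min <= 0:
            raise ValueError("lifetime and S-phase duration must be positive")
        if self.lifetime_min > self.s_phase_min:
            raise ValueError("replicon lifetime cannot exceed S-phase duration")

    @property
    def expected_parallel(self) -> float:
        """Closed-form time-averaged number of active replicons."""
        return self.n_replicons * self.lifetime_min / self.s_phase_min


def draw_activation_times(
    schedule: FiringSchedule, mode: str, rng: np.random.Generator
) -> np.ndarray:
    """Activation times (minutes) under a firing mode.

    ``synchronous_waves`` fires equal-sized waves spaced one lifetime
    apart; ``uniform_asynchronous`` draws each activation uniformly over
    the window that keeps the replicon inside S-phase.
    """
    n, tau, t_s = schedule.n_replicons, schedule.lifetime_min, schedule.s_phase_min
    window = t_s - tau
    if mode == "uniform_asynchronous":
        return rng.uniform(0.0, window, size=n) if window > 0 else np.zeros(n)
    if mode == "synchronous_waves":
        n_waves = max(1, int(round(t_s / tau)))
        wave_times = (
            np.linspace(0.0, window, n_waves) if n_waves > 1 else np.zeros(1)
        )
        sizes = np.full(n_waves, n // n_waves)
        sizes[: n % n_waves] += 1
        return np.repeat(wave_times, sizes)
    raise ValueError(
        f"unknown mode {mode!r}; use 'synchronous_waves' or 'uniform_asynchronous'"
    )


def simulate_firing_schedule(
    schedule: FiringSchedule,
    mode: str,
    *,
    n_time_samples: int = 4000,
    seed: int = 0,
) -> float:
    """Time-averaged count of simultaneously active replicons.

    A replicon activated at ``a`` is active for ``a <= t < a + lifetime``;
    the average is taken over a midpoint time grid spanning S-phase.
    """
    rng = np.random.default_rng(seed)
    activations = np.sort(draw_activation_times(schedule, mode, rng))
    t = (np.arange(n_time_samples) + 0.5) * schedule.s_phase_min / n_time_samples
    active = np.searchsorted(activations, t, side="right") - np.searchsorted(
        activations, t - schedule.lifetime_min, side="right"
    )
    return float(active.mean())
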