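"""Derived genome-duplication parameters with error propagation.

Combines genome size (GS), replication fork speed (RFS), inter-origin
distance (IOD), S-phase duration and the counted number of replication
foci into: total replicons, replicon lifetime, limiting-factor reuse
cycles, forks and replicons active in parallel, and the replicons-per-
focus quotient with its first-order propagated uncertainty.

Genome size is handled internally in kbp; reports follow the customary
units (10^3 Mbp, kbp, minutes, hours).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "Measurement",
    "ReplicationParameters",
    "RepliconSummary",
    "total_replicons",
    "replicon_lifetime",
    "reuse_cycles",
    "forks_in_parallel",
    "single_fork_duplication_hours",
    "replicons_per_rfi",
    "propagate_mse",
    "build_summary",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


class Measurement(NamedTuple):
    """A central value with its standard error."""

    value: float
    sem: float = 0.0

    @property
    def relative(self) -> float:
        return self.sem / self.value if self.value else float("nan")


@dataclass(frozen=True)
class ReplicationParameters:
    """The five measured inputs of the replicon calculation.

    gs_kbp: genome size in kbp; rfs: kbp/min; iod: kbp;
    t_s_min: S-phase duration in minutes; n_rfi: counted foci.
    """

    gs_kbp: Measurement
    rfs: Measurement
    iod: Measurement
    t_s_min: Measurement
    n_rfi: Measurement

    def __post_init__(self) -> None:
        for name in ("gs_kbp", "rfs", "iod", "t_s_min", "n_rfi"):
            m: Measurement = getattr(self, name)
            if m.value <= 0:
                raise ValueError(f"{name} central value must be positive")
            if m.sem < 0:
                raise ValueError(f"{name} uncertainty must be >= 0")

    @classmethod
    def from_table_units(
        cls,
        gs_tmbp: tuple[float, float],
        rfs: tuple[float, float],
        iod: tuple[float, float],
        t_s_min: tuple[float, float],
        n_rfi: tuple[float, float],
    ) -> "ReplicationParameters":
        """Build from report units: GS in 10^3 Mbp, the rest as printed."""
        gs_val, gs_sem = gs_tmbp
        return cls(
            gs_kbp=Measurement(gs_val * 1e6, gs_sem * 1e6),
            rfs=Measurement(*rfs),
            iod=Measurement(*iod),
            t_s_min=Measurement(*t_s_min),
            n_rfi=Measurement(*n_rfi),
        )


def total_replicons(gs_kbp: float, iod_kbp: float) -> int:
    """Total replicons fired across S-phase: genome size / mean IOD."""
    if iod_kbp <= 0:
        raise ValueError("IOD must be positive")
    if gs_kbp <= 0:
        raise ValueError("genome size must be positive")
    return _round_half_up(gs_kbp / iod_kbp)


def replicon_lifetime(iod_kbp: float, rfs_kbp_min: float) -> float:
    """Minutes to synthesize an average bidirectional replicon: IOD / (2 RFS)."""
    if rfs_kbp_min <= 0:
        raise ValueError("fork speed must be positive")
    if iod_kbp < 0:
        raise ValueError("IOD must be >= 0")
    return iod_kbp / (2.0 * rfs_kbp_min)


def reuse_cycles(t_s_min: float, lifetime_min: float) -> int:
    """How often each limiting-factor molecule is reused in one S-phase."""
    if lifetime_min <= 0:
        raise ValueError("replicon lifetime must be positive")
    if t_s_min <= 0:
        raise ValueError("S-phase duration must be positive")
    return _round_half_up(t_s_min / lifetime_min)


def single_fork_duplication_hours(gs_kbp: float, rfs_kbp_min: float) -> float:
    """Hours a single fork would need to duplicate the whole genome."""
    if gs_kbp <= 0 or rfs_kbp_min <= 0:
        raise ValueError("inputs must be positive")
    return gs_kbp / rfs_kbp_min / 60.0


def forks_in_parallel(gs_kbp: float, rfs_kbp_min: float, t_s_min: float) -> float:
    """Replication forks that must operate in parallel: GS / RFS / T_S."""
    if min(gs_kbp, rfs_kbp_min, t_s_min) <= 0:
        raise ValueError("inputs must be positive")
    return gs_kbp / rfs_kbp_min / t_s_min


def replicons_per_rfi(replicons_parallel: float, n_rfi: float) -> float:
    """Calculated parallel replicons per counted replication focus."""
    if n_rfi <= 0:
        raise ValueError("counted RFi must be positive")
    return replicons_parallel / n_rfi


def propagate_mse(quotient: float, relative_uncertainties: Iterable[float]) -> float:
    """First-order (variance-formula) uncertainty of a product/quotient.

    MSE = |quotient| * sqrt(sum of squared relative uncertainties).
    """
    rel = np.asarray(list(relative_uncertainties), dtype=float)
    if not np.all(np.isfinite(rel)) or not np.isfinite(quotient):
        raise ValueError("inputs must be finite")
    if np.any(rel < 0):
        raise ValueError("relative uncertainties must be >= 0")
    return float(abs(quotient) * np.sqrt(np.sum(rel**2)))


@dataclass(frozen=True)
class RepliconSummary:
    """All derived quantities of the genome-duplication calculation."""

    params: ReplicationParameters
    total_replicons: int
    replicon_lifetime_min: float
    reuse_cycles: int
    single_fork_hours: float
    forks_in_parallel: float
    replicons_in_parallel: float
    replicons_per_rfi: float
    mse: float

    def to_dict(self) -> dict:
        p = self.params
        return {
            "experimental": {
                "rfs_kbp_min": p.rfs.value,
                "rfs_sem": p.rfs.sem,
                "iod_kbp": p.iod.value,
                "iod_sem": p.iod.sem,
                "gs_tmbp": p.gs_kbp.value / 1e6,
                "gs_sem_tmbp": p.gs_kbp.sem / 1e6,
                "n_rfi": p.n_rfi.value,
                "n_rfi_sem": p.n_rfi.sem,
                "t_s_min": p.t_s_min.value,
                "t_s_sem": p.t_s_min.sem,
            },
            "calculations": {
                "total_replicons": self.total_replicons,
                "replicon_lifetime_min": self.replicon_lifetime_min,
                "reuse_cycles": self.reuse_cycles,
                "single_fork_hours": self.single_fork_hours,
                "forks_in_parallel": self.forks_in_parallel,
                "forks_in_parallel_rounded": _round_half_up(self.forks_in_parallel),
                "replicons_in_parallel": self.replicons_in_parallel,
                "replicons_per_rfi": self.replicons_per_rfi,
                "replicons_per_rfi_2dp": round(self.replicons_per_rfi, 2),
                "mse": self.mse,
            },
        }


def build_summary(
    params: ReplicationParameters, *, mse_inputs: tuple[str, ...] = ("gs_kbp", "rfs", "t_s_min", "n_rfi")
) -> RepliconSummary:
    """Compose every derived quantity from the measured parameters.

    ``mse_inputs`` selects which measured quantities contribute their
    relative standard errors to the propagated uncertainty of the
    replicons-per-focus quotient.
    """
    gs, rfs = params.gs_kbp.value, params.rfs.value
    iod, t_s, n_rfi = params.iod.value, params.t_s_min.value, params.n_rfi.value
    lifetime = replicon_lifetime(iod, rfs)
    forks = forks_in_parallel(gs, rfs, t_s)
    replicons_parallel = forks / 2.0
    quotient = replicons_per_rfi(replicons_parallel, n_rfi)
    rel = [getattr(params, name).relative for name in mse_inputs]
    return RepliconSummary(
        params=params,
        total_replicons=total_replicons(gs, iod),
        replicon_lifetime_min=lifetime,
        reuse_cycles=reuse_cycles(t_s, lifetime),
        single_fork_hours=single_fork_duplication_hours(gs, rfs),
        forks_in_parallel=forks,
        replicons_in_parallel=replicons_parallel,
        replicons_per_rfi=quotient,
        mse=propagate_mse(quotient, rel),
    )
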