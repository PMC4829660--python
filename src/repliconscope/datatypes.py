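"""Shared data containers used across the simulation and analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelStack",
    "FociGroundTruth",
    "FibreSegment",
    "FibreTrack",
    "DnaHistogram",
]


@dataclass
class VoxelStack:
    """A 3D intensity grid with physical voxel dimensions.

    Parameters
    ----------
    data
        Intensities as a ``(z, y, x)`` array of non-negative values.
    voxel_xy
        Lateral voxel size in nanometres.
    voxel_z
        Axial voxel size in nanometres.
    modality
        Free-form tag identifying the imaging modality the grid emulates
        (``"confocal"``, ``"widefield_decon"``, ``"sim"`` ...).
    """

    data: np.ndarray
    voxel_xy: float
    voxel_z: float
    modality: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x), got ndim={self.data.ndim}")
        if self.data.shape[0] < 1:
            raise ValueError("stack must contain at least one plane")
        if self.voxel_xy <= 0 or self.voxel_z <= 0:
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy_with(self, data: np.ndarray) -> "VoxelStack":
        """Return a new stack with the same metadata but different voxels."""
        return VoxelStack(data, self.voxel_xy, self.voxel_z, self.modality)


@dataclass
class FociGroundTruth:
    """Exact focus geometry produced by the simulator.

    ``centroids_nm`` is an ``(n, 3)`` array of ``(x, y, z)`` positions in
    nanometres, in the physical coordinate frame of the rendered stack.
    """

    centroids_nm: np.ndarray
    intensities: np.ndarray
    nuclear_mask: np.ndarray
    cluster_ids: np.ndarray

    def __post_init__(self) -> None:
        self.centroids_nm = np.atleast_2d(np.asarray(self.centroids_nm, dtype=float))
        if self.centroids_nm.size == 0:
            self.centroids_nm = np.empty((0, 3))
        if self.centroids_nm.shape[1] != 3:
            raise ValueError("centroids must be (n, 3) arrays of (x, y, z)")
        n = self.centroids_nm.shape[0]
        if len(self.intensities) != n or len(self.cluster_ids) != n:
            raise ValueError("per-focus arrays must match the number of centroids")

    @property
    def count(self) -> int:
        return int(self.centroids_nm.shape[0])


@dataclass
class FibreSegment:
    """One labeled stretch on a combed DNA fibre, in micrometres."""

    label: str  # "pulse1" | "pulse2" | "gap"
    start_um: float
    end_um: float
    censored: bool = False

    def __post_init__(self) -> None:
        if self.label not in ("pulse1", "pulse2", "gap"):
            raise ValueError(f"unknown segment label {self.label!r}")
        if self.start_um < 0 or self.end_um < self.start_um:
            raise ValueError("segment positions must satisfy 0 <= start <= end")

    @property
    def length_um(self) -> float:
        return self.end_um - self.start_um


@dataclass
class FibreTrack:
    """Ordered, non-overlapping labeled segments on one stretched fibre."""

    fibre_id: int
    segments: list[FibreSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start_um < a.end_um - 1e-9:
                raise ValueError("segments must be ordered and non-overlapping")

    @property
    def length_um(self) -> float:
        if not self.segments:
            return 0.0
        return self.segments[-1].end_um


@dataclass
class DnaHistogram:
    """Channel-indexed DNA flow-cytometry histogram.

    ``reference_window`` and ``sample_window`` annotate the channel ranges
    (inclusive) containing the reference (splenocyte) G0/G1 peak and the
    sample G1 peak respectively.
    """

    channels: np.ndarray
    counts: np.ndarray
    reference_window: tuple[float, float] | None = None
    sample_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.channels.shape != self.counts.shape:
            raise ValueError("channels and counts must have identical shape")
        if np.any(np.diff(self.channels) <= 0):
            raise ValueError("channels must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def window_slice(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        return (self.channels >= lo) & (self.channels <= hi)
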