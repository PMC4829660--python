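"""Counting of replication foci in 3D stacks.

Two protocols are implemented. The conventional (confocal / wide-field)
protocol smooths each slice with a mean filter, normalizes the stack,
marks slice-wise local maxima, regenerates small Gaussian objects around
them and counts 3D connected components. The super-resolution protocol
removes background with the triangle threshold, labels connected
components and splits touching objects with a marker-controlled 3D
watershed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from repliconscope.datatypes import VoxelStack

__all__ = [
    "FociCount",
    "RatioResult",
    "ConfocalParams",
    "SimParams",
    "mean_filter_slices",
    "normalize_stack",
    "find_stack_maxima",
    "reconstruct_focal_objects",
    "count_objects_3d",
    "count_confocal_rfi",
    "triangle_threshold",
    "separate_touching_objects",
    "count_sim_rfi",
    "resolution_ratio",
]

logger = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class FociCount:
    """Result of a counting protocol on one nucleus."""

    count: int
    labels: np.ndarray
    volumes: list[int]
    protocol: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_labels = len(np.unique(self.labels[self.labels > 0]))
        if self.count != n_labels:
            raise ValueError("count must equal the number of distinct nonzero labels")


@dataclass
class RatioResult:
    """Super-resolution to conventional count ratios for a population."""

    per_cell: list[float]
    pooled: float
    combined: float
    dispersion: float


@dataclass(frozen=True)
class ConfocalParams:
    """Parameters of the conventional counting pipeline."""

    mean_radius: float = 1.5
    noise_tolerance: float = 0.1
    gaussian_radius: float = 1.0
    intensity_threshold: float = 0.05
    min_voxels: int = 4


@dataclass(frozen=True)
class SimParams:
    """Parameters of the super-resolution counting pipeline."""

    n_bins: int = 256
    smooth_sigma: float = 1.0
    h_split: float = 0.2
    min_voxels: int = 10
    separate: bool = True


def _disk_footprint(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    return (y * y + x * x) <= radius * radius


def mean_filter_slices(stack: VoxelStack, radius: float = 1.5) -> VoxelStack:
    """Replace each z-slice by its mean over a disk of the given radius.

    A radius of 1.5 px yields the 9-pixel disk (3x3 including diagonals).
    Edges are handled by replication.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if stack.data.size == 0:
        raise ValueError("cannot filter an empty stack")
    foot = _disk_footprint(radius)
    kernel = (foot / foot.sum())[None, :, :]
    out = ndimage.correlate(stack.data.astype(float), kernel, mode="nearest")
    return stack.copy_with(out)


def normalize_stack(stack: VoxelStack) -> VoxelStack:
    """Affinely map the whole-stack intensity range onto [0, 1]."""
    data = stack.data.astype(float)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        raise ValueError("stack has zero dynamic range; cannot normalize")
    return stack.copy_with((data - lo) / (hi - lo))


def find_stack_maxima(stack: VoxelStack, noise_tolerance: float = 0.1) -> np.ndarray:
    """Mark 2D local maxima in every slice, one voxel per maximum.

    A maximum must exceed the level at which it would merge with a
    higher neighbourhood by more than ``noise_tolerance`` (h-maxima
    criterion) and must also clear the slice background (its median) by
    the same tolerance — otherwise the unconditional global maximum of
    every pure-background slice would be marked. Plateau maxima are
    collapsed to their brightest voxel, ties broken by lowest flat
    index, so the output is deterministic.
    """
    if noise_tolerance < 0:
        raise ValueError("noise tolerance must be >= 0")
    data = stack.data.astype(float)
    out = np.zeros(data.shape, dtype=bool)
    h = max(noise_tolerance, 1e-9)
    for z in range(data.shape[0]):
        plane = data[z]
        if plane.max() == plane.min():
            continue
        peaks = h_maxima(plane, h).astype(bool)
        peaks &= plane > np.median(plane) + noise_tolerance
        if not peaks.any():
            continue
        lab, n = ndimage.label(peaks, structure=np.ones((3, 3), dtype=bool))
        for sl in ndimage.find_objects(lab):
            region = lab[sl] > 0
            vals = np.where(region, plane[sl], -np.inf)
            iy, ix = np.unravel_index(np.argmax(vals), vals.shape)
            out[z, sl[0].start + iy, sl[1].start + ix] = True
    return out


def reconstruct_focal_objects(
    maxima_map: np.ndarray, gaussian_radius: float = 1.0
) -> np.ndarray:
    """Convolve a binary maxima map with a small in-plane Gaussian.

    The kernel integrates to one, so the total intensity of the output
    equals the number of marked voxels (up to edge truncation).
    """
    maxima_map = np.asarray(maxima_map)
    if maxima_map.dtype != bool and not np.isin(maxima_map, (0, 1)).all():
        raise ValueError("maxima map must be binary")
    return ndimage.gaussian_filter(
        maxima_map.astype(float), sigma=(0.0, gaussian_radius, gaussian_radius)
    )


def count_objects_3d(
    data: np.ndarray | VoxelStack,
    intensity_threshold: float,
    min_voxels: int = 4,
    *,
    protocol: str = "confocal",
    params: dict | None = None,
) -> FociCount:
    """Count 26-connected components above a threshold, dropping objects
    smaller than ``min_voxels``."""
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    arr = data.data if isinstance(data, VoxelStack) else np.asarray(data)
    mask = arr > intensity_threshold
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    if n:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_voxels)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
        kept = np.unique(labels[labels > 0])
        remap = np.zeros(labels.max() + 1, dtype=labels.dtype)
        remap[kept] = np.arange(1, kept.size + 1)
        labels = remap[labels]
        n = kept.size
        volumes = list(np.bincount(labels.ravel())[1:])
    else:
        volumes = []
    return FociCount(int(n), labels, [int(v) for v in volumes], protocol, params or {})


def count_confocal_rfi(
    stack: VoxelStack, params: ConfocalParams | None = None
) -> FociCount:
    """Conventional-resolution counting pipeline.

    mean filter -> normalize -> slice-wise maxima -> Gaussian object
    reconstruction -> 3D connected-component count.
    """
    params = params or ConfocalParams()
    smoothed = mean_filter_slices(stack, params.mean_radius)
    normed = normalize_stack(smoothed)
    maxima = find_stack_maxima(normed, params.noise_tolerance)
    objects = reconstruct_focal_objects(maxima, params.gaussian_radius)
    return count_objects_3d(
        objects,
        params.intensity_threshold,
        params.min_voxels,
        protocol="confocal",
        params=asdict(params),
    )


def triangle_threshold(
    counts: np.ndarray, bin_centers: np.ndarray | None = None
) -> float:
    """Triangle (geometric) threshold of an intensity histogram.

    Draws the line from the histogram peak to the far end of its longer
    tail and returns the bin maximizing the perpendicular distance from
    the histogram to that line. Deterministic: ties resolve to the bin
    closest to the peak.
    """
    counts = np.asarray(counts, dtype=float)
    nonzero = np.flatnonzero(counts)
    if nonzero.size < 2:
        raise ValueError("histogram must have at least two non-empty bins")
    peak = int(np.argmax(counts))
    lo, hi = int(nonzero[0]), int(nonzero[-1])
    # far tail = the nonzero extreme farther from the peak
    tail = hi if (hi - peak) >= (peak - lo) else lo
    if tail == peak:
        raise ValueError("degenerate histogram: peak coincides with its tail")
    x0, y0 = float(peak), counts[peak]
    x1, y1 = float(tail), counts[tail]
    span = np.arange(min(peak, tail), max(peak, tail) + 1)
    # perpendicular distance from (x, counts[x]) to the peak-tail line
    num = np.abs((y1 - y0) * span - (x1 - x0) * counts[span] + x1 * y0 - y1 * x0)
    best = span[int(np.argmax(num))] if tail > peak else span[::-1][int(np.argmax(num[::-1]))]
    if bin_centers is not None:
        return float(np.asarray(bin_centers, dtype=float)[best])
    return float(best)


def separate_touching_objects(
    labels: np.ndarray,
    stack: VoxelStack,
    *,
    smooth_sigma: float = 1.0,
    h_split: float = 0.1,
) -> np.ndarray:
    """Split labeled components by marker-controlled 3D watershed.

    Markers are h-maxima of the smoothed, range-normalized intensity
    inside the labeled mask; components without any marker keep a marker
    at their brightest voxel. Disconnected components can never merge,
    so the output label count is >= the input count.
    """
    labels = np.asarray(labels)
    mask = labels > 0
    if not mask.any():
        return labels.copy()
    data = stack.data.astype(float)
    if smooth_sigma > 0:
        data = ndimage.gaussian_filter(data, smooth_sigma)
    h = max(h_split, 1e-9)
    out = np.zeros_like(labels)
    next_label = 0
    # process each component in its (padded) bounding box; components are
    # disjoint, so per-component watershed cannot merge anything. The
    # split depth h is taken relative to each component's own intensity
    # range so dim objects are treated like bright ones.
    for comp, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        sl = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim))
            for s, dim in zip(sl, labels.shape)
        )
        comp_mask = labels[sl] == comp
        sub = data[sl]
        lo, hi = sub[comp_mask].min(), sub[comp_mask].max()
        sub = (sub - lo) / (hi - lo) if hi > lo else np.zeros_like(sub)
        peaks = h_maxima(sub, h).astype(bool) & comp_mask
        markers, n_markers = ndimage.label(peaks, structure=_STRUCT_26)
        if n_markers == 0:
            vals = np.where(comp_mask, sub, -np.inf)
            markers[np.unravel_index(np.argmax(vals), vals.shape)] = 1
            n_markers = 1
        if n_markers == 1:
            out[sl][comp_mask] = next_label + 1
        else:
            ws = watershed(-sub, markers=markers, mask=comp_mask)
            out[sl][comp_mask] = ws[comp_mask] + next_label
        next_label += n_markers
    return out


def count_sim_rfi(stack: VoxelStack, params: SimParams | None = None) -> FociCount:
    """Super-resolution counting pipeline.

    triangle background threshold -> 26-connected labeling -> removal of
    sub-minimum objects -> watershed separation of touching objects.
    """
    params = params or SimParams()
    data = stack.data.astype(float)
    counts, edges = np.histogram(data, bins=params.n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    thr = triangle_threshold(counts, centers)
    base = count_objects_3d(data, thr, params.min_voxels, protocol="sim")
    labels = base.labels
    if params.separate:
        labels = separate_touching_objects(
            labels, stack, smooth_sigma=params.smooth_sigma, h_split=params.h_split
        )
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < params.min_voxels)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
    kept = np.unique(labels[labels > 0])
    remap = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    remap[kept] = np.arange(1, kept.size + 1)
    labels = remap[labels]
    volumes = list(np.bincount(labels.ravel())[1:]) if kept.size else []
    result_params = asdict(params)
    result_params["threshold"] = thr
    return FociCount(
        int(kept.size), labels, [int(v) for v in volumes], "sim", result_params
    )


def resolution_ratio(
    sr_counts: list[int] | np.ndarray, conventional_counts: list[int] | np.ndarray
) -> RatioResult:
    """Per-cell and pooled super-resolution / conventional count ratios.

    Cells with a zero conventional count are excluded with a warning.
    The pooled ratio is sum(SR) / sum(conventional); the combined ratio
    averages the per-cell mean with the pooled ratio.
    """
    sr = np.asarray(sr_counts, dtype=float)
    conv = np.asarray(conventional_counts, dtype=float)
    if sr.shape != conv.shape:
        raise ValueError("paired count vectors must have equal length")
    bad = conv <= 0
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} cell(s) with zero conventional count",
            stacklevel=2,
        )
        sr, conv = sr[~bad], conv[~bad]
    if sr.size == 0:
        raise ValueError("no cells with positive conventional counts")
    per_cell = sr / conv
    pooled = float(sr.sum() / conv.sum())
    combined = float((per_cell.mean() + pooled) / 2.0)
    dispersion = float(per_cell.std(ddof=1)) if per_cell.size > 1 else 0.0
    return RatioResult(list(per_cell), pooled, combined, dispersion)
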