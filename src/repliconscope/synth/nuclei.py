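"""Synthetic 3D nuclei: PSF-blurred point foci inside an ellipsoidal
nucleus, rendered on a modality-specific voxel grid with shot and read
noise.

Geometry generation and rendering are separated so that the very same
ground-truth focus set can be rendered under different optical profiles
(the comparison the counting protocols are validated against).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from repliconscope.datatypes import FociGroundTruth, VoxelStack
from repliconscope.synth.profiles import ModalityProfile

__all__ = [
    "ClusterConfig",
    "FociGeometry",
    "generate_foci_geometry",
    "render_geometry",
    "generate_nucleus_stack",
]


@dataclass(frozen=True)
class ClusterConfig:
    """Thomas-process-style parent/offspring clustering of foci.

    ``fixed_size`` makes every cluster exactly ``mean_size`` foci instead
    of Poisson-distributed; ``offspring_min_separation_nm`` keeps
    siblings apart within a cluster (best effort, falls back to
    unconstrained placement if the ball is too crowded).
    """

    enabled: bool = False
    mean_size: float = 5.0
    radius_nm: float = 250.0
    axial_radius_nm: float | None = None  # defaults to radius_nm (spherical)
    parent_min_separation_nm: float = 0.0
    offspring_min_separation_nm: float = 0.0
    fixed_size: bool = False

    def __post_init__(self) -> None:
        if self.enabled and (self.mean_size < 1 or self.radius_nm <= 0):
            raise ValueError("cluster mean size must be >= 1 and radius > 0")


@dataclass
class FociGeometry:
    """Focus positions in a nucleus-centred frame, before rendering."""

    centroids_nm: np.ndarray  # (n, 3) of (x, y, z), origin at nucleus centre
    intensities: np.ndarray  # integrated photons per focus
    cluster_ids: np.ndarray
    semiaxes_nm: tuple[float, float, float]  # (x, y, z)

    @property
    def count(self) -> int:
        return int(np.atleast_2d(self.centroids_nm).shape[0]) if self.centroids_nm.size else 0


def _sample_in_ellipsoid(rng: np.random.Generator, n: int, semiaxes: np.ndarray) -> np.ndarray:
    """Uniform points in an origin-centred ellipsoid, as (n, 3) of (x, y, z)."""
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-1.0, 1.0, size=(2 * (n - got) + 8, 3))
        keep = np.sum(cand**2, axis=1) <= 1.0
        cand = cand[keep][: n - got]
        pts[got : got + len(cand)] = cand
        got += len(cand)
    return pts * semiaxes


def _dart_throw(
    rng: np.random.Generator,
    n: int,
    semiaxes: np.ndarray,
    min_separation: float,
    axial_scale: float = 1.0,
    max_attempts_per_point: int = 500,
) -> np.ndarray:
    """Uniform ellipsoid points with a hard minimum pairwise distance.

    ``axial_scale`` < 1 deflates the z component of the distance metric,
    i.e. the axial exclusion range becomes ``min_separation / axial_scale``
    (optical resolution is worse along z).
    """
    scale = np.array([1.0, 1.0, axial_scale])
    placed: list[np.ndarray] = []
    attempts = 0
    budget = max_attempts_per_point * max(n, 1)
    while len(placed) < n:
        if attempts > budget:
            raise RuntimeError(
                f"could not place {n} foci at min separation {min_separation} nm; "
                "nucleus too small or separation too large"
            )
        cand = _sample_in_ellipsoid(rng, 1, semiaxes)[0]
        attempts += 1
        if placed:
            d2 = np.sum(((np.asarray(placed) - cand) * scale) ** 2, axis=1)
            if d2.min() < min_separation**2:
                continue
        placed.append(cand)
    return np.asarray(placed) if placed else np.empty((0, 3))


def generate_foci_geometry(
    n_foci: int,
    *,
    nucleus_semiaxes_nm: tuple[float, float, float] = (8000.0, 6000.0, 3000.0),
    clustering: ClusterConfig | None = None,
    min_separation_nm: float = 0.0,
    axial_scale: float = 1.0,
    intensity_mean: float = 2000.0,
    intensity_sd: float = 0.0,
    seed: int = 0,
) -> FociGeometry:
    """Draw ground-truth focus centroids inside an ellipsoidal nucleus.

    ``min_separation_nm`` enforces a hard minimum pairwise distance;
    ``axial_scale`` < 1 widens the exclusion range along z by 1/scale
    (use lateral/axial FWHM of the coarsest rendering modality to make
    the separation resolution-equivalent in every direction). With
    clustering enabled, cluster parents are placed first (optionally
    dart-thrown to a minimum separation) and offspring are scattered
    uniformly in a ball of ``radius_nm`` around each parent, rejected
    back inside the nucleus.
    """
    if n_foci < 0:
        raise ValueError("n_foci must be >= 0")
    semi = np.asarray(nucleus_semiaxes_nm, dtype=float)
    if np.any(semi <= 0):
        raise ValueError("nucleus semi-axes must be positive")
    rng = np.random.default_rng(seed)
    clustering = clustering or ClusterConfig()

    if n_foci == 0:
        return FociGeometry(
            np.empty((0, 3)), np.empty(0), np.empty(0, dtype=int), tuple(semi)
        )

    if clustering.enabled:
        # draw parents until their Poisson offspring budget covers n_foci
        sizes: list[int] = []
        while sum(sizes) < n_foci:
            if clustering.fixed_size:
                sizes.append(int(round(clustering.mean_size)))
            else:
                sizes.append(max(1, int(rng.poisson(clustering.mean_size))))
        n_parents = len(sizes)
        if clustering.parent_min_separation_nm > 0:
            parents = _dart_throw(
                rng, n_parents, semi, clustering.parent_min_separation_nm, axial_scale
            )
        else:
            parents = _sample_in_ellipsoid(rng, n_parents, semi)
        centroids = np.empty((n_foci, 3))
        cluster_ids = np.empty(n_foci, dtype=int)
        idx = 0
        min_sib = clustering.offspring_min_separation_nm
        radii = np.array([
            clustering.radius_nm,
            clustering.radius_nm,
            clustering.axial_radius_nm
            if clustering.axial_radius_nm is not None
            else clustering.radius_nm,
        ])
        for cid, (parent, size) in enumerate(zip(parents, sizes)):
            siblings: list[np.ndarray] = []
            for _ in range(size):
                if idx >= n_foci:
                    break
                cand = parent
                for _try in range(300):
                    offset = rng.normal(size=3)
                    r = np.linalg.norm(offset)
                    if r == 0:
                        continue
                    offset = offset / r * rng.uniform() ** (1 / 3) * radii
                    cand = parent + offset
                    if np.sum((cand / semi) ** 2) > 1.0:
                        continue
                    if min_sib > 0 and siblings and (
                        np.min(np.sum((np.asarray(siblings) - cand) ** 2, axis=1))
                        < min_sib**2
                    ):
                        continue
                    break
                siblings.append(cand)
                centroids[idx] = cand
                cluster_ids[idx] = cid
                idx += 1
    else:
        if min_separation_nm > 0:
            centroids = _dart_throw(rng, n_foci, semi, min_separation_nm, axial_scale)
        else:
            centroids = _sample_in_ellipsoid(rng, n_foci, semi)
        cluster_ids = np.arange(n_foci)

    intensities = np.full(n_foci, float(intensity_mean))
    if intensity_sd > 0:
        intensities = rng.normal(intensity_mean, intensity_sd, size=n_foci)
        intensities = np.clip(intensities, intensity_mean * 0.05, None)
    return FociGeometry(centroids, intensities, cluster_ids, tuple(semi))


def _add_gaussian_spot(
    data: np.ndarray,
    centre_vox: np.ndarray,  # (z, y, x) in voxel units, fractional
    sigma_vox: np.ndarray,  # (z, y, x)
    photons: float,
    truncate: float = 4.0,
) -> None:
    """Accumulate one anisotropic Gaussian spot in place (integrated photons)."""
    lo = np.maximum(np.floor(centre_vox - truncate * sigma_vox).astype(int), 0)
    hi = np.minimum(np.ceil(centre_vox + truncate * sigma_vox).astype(int) + 1,
                    np.asarray(data.shape))
    if np.any(hi <= lo):
        return
    axes = [np.arange(lo[d], hi[d], dtype=float) for d in range(3)]
    gs = [
        np.exp(-0.5 * ((ax - centre_vox[d]) / sigma_vox[d]) ** 2)
        / (np.sqrt(2.0 * np.pi) * sigma_vox[d])
        for d, ax in enumerate(axes)
    ]
    spot = photons * gs[0][:, None, None] * gs[1][None, :, None] * gs[2][None, None, :]
    data[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]] += spot


def render_geometry(
    geometry: FociGeometry,
    profile: ModalityProfile,
    *,
    seed: int = 0,
    shape: tuple[int, int, int] | None = None,
    margin_sigmas: float = 4.0,
) -> tuple[VoxelStack, FociGroundTruth]:
    """Render a focus geometry under an optical profile.

    Returns the noisy stack and the ground truth with centroids shifted
    to the stack's physical coordinate frame (nm from the stack corner).
    """
    semi = np.asarray(geometry.semiaxes_nm)
    margin_nm = np.array(
        [
            margin_sigmas * profile.axial_psf_sigma + 2 * profile.voxel_z,
            margin_sigmas * profile.lateral_psf_sigma + 2 * profile.voxel_xy,
            margin_sigmas * profile.lateral_psf_sigma + 2 * profile.voxel_xy,
        ]
    )
    extent_nm = 2 * semi[::-1] + 2 * margin_nm  # (z, y, x)
    voxel = np.array([profile.voxel_z, profile.voxel_xy, profile.voxel_xy])
    auto_shape = np.ceil(extent_nm / voxel).astype(int)
    if shape is None:
        shape_arr = auto_shape
    else:
        shape_arr = np.asarray(shape, dtype=int)
        if np.any(shape_arr * voxel < 2 * semi[::-1]):
            raise ValueError("requested stack shape cannot contain the nucleus ellipsoid")
    centre_nm = shape_arr * voxel / 2.0  # nucleus centre, (z, y, x)

    rng = np.random.default_rng(seed)
    noise = profile.noise_model
    signal = np.zeros(tuple(shape_arr), dtype=float)
    sigma_vox = np.array(
        [
            profile.axial_psf_sigma / profile.voxel_z,
            profile.lateral_psf_sigma / profile.voxel_xy,
            profile.lateral_psf_sigma / profile.voxel_xy,
        ]
    )
    centroids = np.atleast_2d(geometry.centroids_nm) if geometry.count else np.empty((0, 3))
    # centroids are (x, y, z) relative to the nucleus centre
    for (x, y, z), photons in zip(centroids, geometry.intensities):
        pos_nm = centre_nm + np.array([z, y, x])
        # subtract half a voxel so that integer voxel indices refer to
        # voxel centres
        centre_vox = pos_nm / voxel - 0.5
        _add_gaussian_spot(signal, centre_vox, sigma_vox, float(photons))

    counts = rng.poisson(signal + noise.background).astype(float) * noise.gain
    if noise.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, noise.read_noise_sd, size=counts.shape)
    counts = np.clip(counts, 0.0, None).astype(np.float32)

    zz, yy, xx = np.meshgrid(
        (np.arange(shape_arr[0]) + 0.5) * voxel[0] - centre_nm[0],
        (np.arange(shape_arr[1]) + 0.5) * voxel[1] - centre_nm[1],
        (np.arange(shape_arr[2]) + 0.5) * voxel[2] - centre_nm[2],
        indexing="ij",
    )
    mask = (xx / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (zz / semi[2]) ** 2 <= 1.0

    stack = VoxelStack(counts, profile.voxel_xy, profile.voxel_z, profile.name)
    shifted = centroids + centre_nm[::-1] if geometry.count else centroids
    truth = FociGroundTruth(
        centroids_nm=shifted,
        intensities=np.asarray(geometry.intensities, dtype=float),
        nuclear_mask=mask,
        cluster_ids=np.asarray(geometry.cluster_ids, dtype=int),
    )
    return stack, truth


def generate_nucleus_stack(
    n_foci: int,
    profile: ModalityProfile,
    *,
    clustering: ClusterConfig | None = None,
    nucleus_semiaxes_nm: tuple[float, float, float] = (8000.0, 6000.0, 3000.0),
    min_separation_nm: float = 0.0,
    axial_scale: float = 1.0,
    intensity_mean: float = 2000.0,
    intensity_sd: float = 0.0,
    shape: tuple[int, int, int] | None = None,
    seed: int = 0,
) -> tuple[VoxelStack, FociGroundTruth]:
    """Generate a noisy 3D nucleus stack together with its ground truth.

    Deterministic in all arguments including ``seed``: geometry and
    rendering use independent streams derived from the same seed.
    """
    geometry = generate_foci_geometry(
        n_foci,
        nucleus_semiaxes_nm=nucleus_semiaxes_nm,
        clustering=clustering,
        min_separation_nm=min_separation_nm,
        axial_scale=axial_scale,
        intensity_mean=intensity_mean,
        intensity_sd=intensity_sd,
        seed=seed,
    )
    return render_geometry(geometry, profile, seed=seed + 1, shape=shape)
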