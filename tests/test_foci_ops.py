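import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repliconscope import foci
from repliconscope.datatypes import VoxelStack


def stack_of(data):
    return VoxelStack(np.asarray(data, dtype=float), 100.0, 300.0)


class TestMeanFilter:
    def test_constant_unchanged(self):
        st_ = stack_of(np.full((3, 8, 8), 7.0))
        out = foci.mean_filter_slices(st_, 1.5)
        np.testing.assert_allclose(out.data, 7.0)

    def test_single_pixel_disk_average(self):
        """Brute-force oracle: r=1.5 disk covers 9 pixels, so an isolated
        bright pixel V averages to V/9 at its own position."""
        data = np.zeros((1, 15, 15))
        data[0, 7, 7] = 90.0
        out = foci.mean_filter_slices(stack_of(data), 1.5)
        # oracle: enumerate offsets with dx^2 + dy^2 <= r^2
        offsets = [
            (dy, dx)
            for dy in range(-2, 3)
            for dx in range(-2, 3)
            if dy * dy + dx * dx <= 1.5**2
        ]
        assert len(offsets) == 9
        oracle = sum(data[0, 7 + dy, 7 + dx] for dy, dx in offsets) / len(offsets)
        assert out.data[0, 7, 7] == pytest.approx(oracle)
        assert out.data[0, 7, 7] == pytest.approx(10.0)

    def test_range_bounded(self, rng):
        data = rng.uniform(0, 100, size=(4, 16, 16))
        out = foci.mean_filter_slices(stack_of(data), 1.5)
        assert out.data.max() <= data.max() + 1e-9
        assert out.data.min() >= data.min() - 1e-9

    def test_validation(self):
        with pytest.raises(ValueError):
            foci.mean_filter_slices(stack_of(np.zeros((1, 4, 4))), 0.0)


class TestNormalize:
    def test_affine_map(self):
        st_ = stack_of(np.array([[[2.0, 4.0, 6.0]]]))
        out = foci.normalize_stack(st_)
        np.testing.assert_allclose(out.data, [[[0.0, 0.5, 1.0]]])

    def test_idempotent(self, rng):
        st_ = stack_of(rng.uniform(5, 50, size=(3, 8, 8)))
        once = foci.normalize_stack(st_)
        twice = foci.normalize_stack(once)
        np.testing.assert_allclose(once.data, twice.data)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            foci.normalize_stack(stack_of(np.full((2, 4, 4), 3.0)))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 1000), min_size=4, max_size=40))
    def test_order_preserved(self, values):
        arr = np.array(values).reshape(1, 1, -1)
        if arr.max() == arr.min():
            return
        out = foci.normalize_stack(stack_of(arr)).data.ravel()
        src = arr.ravel()
        order = np.argsort(src, kind="stable")
        assert np.all(np.diff(out[order]) >= -1e-12)


def brute_force_slice_maxima(plane, tol):
    """Oracle: exhaustive check that a pixel strictly dominates every
    other pixel reachable without climbing above (value - tol)."""
    marked = []
    for y in range(plane.shape[0]):
        for x in range(plane.shape[1]):
            v = plane[y, x]
            # a pixel is an h-maximum if no higher pixel is reachable via
            # a path staying above v - tol
            from collections import deque

            seen = {(y, x)}
            queue = deque([(y, x)])
            dominated = False
            while queue:
                cy, cx = queue.popleft()
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = cy + dy, cx + dx
                        if not (0 <= ny < plane.shape[0] and 0 <= nx < plane.shape[1]):
                            continue
                        if (ny, nx) in seen:
                            continue
                        if plane[ny, nx] > v:
                            dominated = True
                            queue.clear()
                            break
                        if plane[ny, nx] > v - tol:
                            seen.add((ny, nx))
                            queue.append((ny, nx))
                    if dominated:
                        break
            if not dominated:
                marked.append((y, x))
    return marked


class TestFindStackMaxima:
    def test_single_blob_one_maximum(self, blob_stack_factory):
        st_ = blob_stack_factory([(4, 16, 16)])
        norm = foci.normalize_stack(st_)
        maxima = foci.find_stack_maxima(norm, 0.1)
        assert maxima[4].sum() == 1

    def test_two_blobs_oracle(self, blob_stack_factory):
        """Two blobs > 2 sigma apart: brute-force path-based oracle agrees
        on the central slice."""
        st_ = blob_stack_factory([(4, 16, 8), (4, 16, 24)])
        norm = foci.normalize_stack(st_)
        maxima = foci.find_stack_maxima(norm, 0.1)
        plane = norm.data[4]
        oracle = brute_force_slice_maxima(plane, 0.1)
        # the oracle returns the same *number* of distinct maxima regions
        assert maxima[4].sum() == 2
        marked = set(map(tuple, np.argwhere(maxima[4])))
        assert marked <= set(oracle)

    def test_flat_slice_no_maxima(self):
        st_ = stack_of(np.zeros((3, 16, 16)))
        st_.data[1, 8, 8] = 1.0  # give the stack dynamic range elsewhere
        maxima = foci.find_stack_maxima(st_, 0.1)
        assert maxima[0].sum() == 0
        assert maxima[2].sum() == 0

    def test_plateau_single_mark(self):
        data = np.zeros((1, 16, 16))
        data[0, 6:9, 6:9] = 1.0
        maxima = foci.find_stack_maxima(stack_of(data), 0.1)
        assert maxima.sum() == 1

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            foci.find_stack_maxima(stack_of(np.zeros((1, 4, 4))), -0.1)


class TestReconstruct:
    def test_empty_map(self):
        out = foci.reconstruct_focal_objects(np.zeros((2, 8, 8), dtype=bool))
        assert out.sum() == 0

    def test_single_voxel_kernel_sum(self):
        m = np.zeros((1, 21, 21), dtype=bool)
        m[0, 10, 10] = True
        out = foci.reconstruct_focal_objects(m, 1.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_superposition(self):
        m = np.zeros((3, 32, 32), dtype=bool)
        m[0, 5, 5] = m[1, 16, 16] = m[2, 26, 26] = True
        out = foci.reconstruct_focal_objects(m, 1.0)
        assert out.sum() == pytest.approx(3.0, abs=1e-5)


class TestCountObjects3D:
    def test_diagonal_touch_is_one_object(self):
        data = np.zeros((4, 8, 8))
        data[1, 2:4, 2:4] = 1.0
        data[2, 4:6, 4:6] = 1.0  # touches only at the (z, y, x) diagonal
        res = foci.count_objects_3d(data, 0.5, min_voxels=1)
        assert res.count == 1

    def test_threshold_above_max(self):
        data = np.ones((2, 4, 4))
        res = foci.count_objects_3d(data, 5.0, min_voxels=1)
        assert res.count == 0
        assert res.volumes == []

    def test_min_voxels_filter(self):
        data = np.zeros((3, 10, 10))
        data[1, 1, 1] = 1.0  # 1-voxel speck
        data[1, 5:7, 5:7] = 1.0  # 4-voxel object
        res = foci.count_objects_3d(data, 0.5, min_voxels=4)
        assert res.count == 1
        assert res.volumes == [4]

    def test_min_voxels_validation(self):
        with pytest.raises(ValueError):
            foci.count_objects_3d(np.zeros((1, 4, 4)), 0.5, min_voxels=0)


class TestTriangleThreshold:
    def brute_force(self, counts):
        counts = np.asarray(counts, dtype=float)
        peak = int(np.argmax(counts))
        nz = np.flatnonzero(counts)
        lo, hi = int(nz[0]), int(nz[-1])
        tail = hi if (hi - peak) >= (peak - lo) else lo
        x0, y0, x1, y1 = peak, counts[peak], tail, counts[tail]
        norm = np.hypot(x1 - x0, y1 - y0)
        best, best_d = None, -1.0
        span = range(min(peak, tail), max(peak, tail) + 1)
        for b in span:
            d = abs((y1 - y0) * b - (x1 - x0) * counts[b] + x1 * y0 - y1 * x0) / norm
            if d > best_d + 1e-12:
                best_d, best = d, b
            elif abs(d - best_d) <= 1e-12 and abs(b - peak) < abs(best - peak):
                best = b
        return float(best)

    def test_brute_force_oracle_random(self, rng):
        """Implementation equals exhaustive point-line-distance search."""
        for _ in range(100):
            counts = rng.integers(0, 1000, size=rng.integers(8, 64))
            counts[rng.integers(0, len(counts))] += 1500  # clear peak
            assert foci.triangle_threshold(counts) == self.brute_force(counts)

    def test_crafted_16_bin(self):
        counts = np.array([0, 2, 80, 400, 180, 90, 45, 30, 20, 14, 9, 6, 4, 2, 1, 1])
        assert foci.triangle_threshold(counts) == self.brute_force(counts)

    def test_threshold_on_longer_tail_side(self):
        counts = np.array([1, 5, 60, 200, 60, 25, 12, 8, 5, 3, 2, 1, 1, 1])
        thr = foci.triangle_threshold(counts)
        assert thr > 3  # peak at 3, long tail to the right

    def test_translation_equivariance(self):
        counts = np.array([0, 3, 50, 300, 120, 40, 15, 6, 2, 1])
        centers = np.arange(10, dtype=float)
        t0 = foci.triangle_threshold(counts, centers)
        t1 = foci.triangle_threshold(counts, centers + 42.0)
        assert t1 == pytest.approx(t0 + 42.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            foci.triangle_threshold(np.array([0, 5, 0, 0]))


class TestSeparateTouching:
    def test_single_sphere_unchanged(self, blob_stack_factory):
        st_ = blob_stack_factory([(4, 16, 16)])
        labels = (st_.data > 0.1).astype(np.int32)
        out = foci.separate_touching_objects(labels, st_)
        assert len(np.unique(out[out > 0])) == 1

    def test_dumbbell_splits(self, blob_stack_factory):
        """Two equal blobs fused at ~1.5 sigma separation are split."""
        st_ = blob_stack_factory([(4, 16, 12), (4, 16, 20)], sigmas=(1.5, 2.5, 2.5))
        labels = (st_.data > 0.25).astype(np.int32)
        assert len(np.unique(labels)) == 2  # background + one fused object
        out = foci.separate_touching_objects(labels, st_, h_split=0.2)
        assert len(np.unique(out[out > 0])) == 2

    def test_never_merges(self, rng, blob_stack_factory):
        centres = [(z, y, x) for z, y, x in rng.integers(3, 28, size=(6, 3))]
        st_ = blob_stack_factory(centres, shape=(32, 32, 32))
        from scipy import ndimage

        labels, n_before = ndimage.label(st_.data > 0.2, np.ones((3, 3, 3)))
        out = foci.separate_touching_objects(labels, st_)
        assert len(np.unique(out[out > 0])) >= n_before


class TestResolutionRatio:
    def test_identity(self):
        res = foci.resolution_ratio([10, 20, 30], [10, 20, 30])
        assert res.per_cell == [1.0, 1.0, 1.0]
        assert res.pooled == 1.0
        assert res.dispersion == 0.0

    def test_arithmetic(self):
        res = foci.resolution_ratio([10, 20], [2, 4])
        assert res.per_cell == [5.0, 5.0]
        assert res.pooled == pytest.approx(30 / 6)
        assert res.combined == pytest.approx(5.0)

    def test_zero_conventional_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            res = foci.resolution_ratio([10, 20], [0, 4])
        assert res.per_cell == [5.0]

    def test_pooled_is_sum_over_sum(self, rng):
        sr = rng.integers(100, 6000, size=12)
        conv = rng.integers(50, 1500, size=12)
        res = foci.resolution_ratio(sr, conv)
        assert res.pooled == pytest.approx(sr.sum() / conv.sum())
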