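import collections

import numpy as np
import pytest
from scipy import ndimage

from conefinder.localize import (
    DetectionParams,
    SweepGrid,
    extended_maxima,
    filter_regions,
    gaussian_smooth,
    localize_cones,
    region_centroids,
    sweep_detection_params,
)

FOOT8 = np.ones((3, 3))


def brute_force_extended_maxima(arr, h):
    """Independent oracle: geodesic dilation to fixpoint, then plateau
    flood-fill regional maxima."""
    marker = arr - h
    while True:
        new = np.minimum(ndimage.grey_dilation(marker, footprint=FOOT8), arr)
        if np.array_equal(new, marker):
            break
        marker = new
    rec = marker
    H, W = rec.shape
    dominated = ndimage.grey_dilation(rec, footprint=FOOT8) > rec
    visited = np.zeros((H, W), bool)
    labels = np.zeros((H, W), int)
    n = 0
    for i in range(H):
        for j in range(W):
            if visited[i, j]:
                continue
            v = rec[i, j]
            comp = []
            queue = collections.deque([(i, j)])
            visited[i, j] = True
            while queue:
                a, b = queue.popleft()
                comp.append((a, b))
                for da in (-1, 0, 1):
                    for db in (-1, 0, 1):
                        na, nb = a + da, b + db
                        if 0 <= na < H and 0 <= nb < W and not visited[na, nb] \
                                and rec[na, nb] == v:
                            visited[na, nb] = True
                            queue.append((na, nb))
            if not any(dominated[a, b] for a, b in comp):
                n += 1
                for a, b in comp:
                    labels[a, b] = n
    return labels, n


def labelings_equal_up_to_renumbering(l1, l2):
    if (l1 > 0).sum() != (l2 > 0).sum() or ((l1 > 0) != (l2 > 0)).any():
        return False
    pairs = set(zip(l1.ravel().tolist(), l2.ravel().tolist()))
    return (
        len(pairs)
        == len({a for a, _ in pairs})
        == len({b for _, b in pairs})
    )


class TestGaussianSmooth:
    def test_sigma_zero_is_identity(self, rng):
        m = rng.random((10, 10))
        assert (gaussian_smooth(m, 0.0) is not None) and (gaussian_smooth(m, 0.0) == m).all()

    def test_constant_map_unchanged(self):
        m = np.full((9, 9), 0.3)
        np.testing.assert_allclose(gaussian_smooth(m, 1.7), m)

    def test_impulse_matches_direct_kernel(self):
        # oracle: outer product of the normalized discrete 1-D Gaussian
        sigma = 1.0
        radius = int(np.ceil(4 * sigma))
        xs = np.arange(-radius, radius + 1)
        k1 = np.exp(-(xs**2) / (2 * sigma**2))
        k1 /= k1.sum()
        impulse = np.zeros((21, 21))
        impulse[10, 10] = 1.0
        out = gaussian_smooth(impulse, sigma)
        np.testing.assert_allclose(out[10, 10], k1[radius] ** 2, rtol=1e-10)
        np.testing.assert_allclose(out.sum(), 1.0, atol=1e-6)

    def test_negative_sigma(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros((4, 4)), -1.0)


class TestExtendedMaxima:
    def test_two_peaks_merge_at_large_h(self):
        m = np.zeros((7, 7))
        m[2, 2] = 1.0
        m[5, 5] = 0.3
        labels, n = extended_maxima(m, 0.5)
        assert n == 1 and labels[2, 2] == 1

    def test_two_peaks_split_at_small_h(self):
        m = np.zeros((7, 7))
        m[2, 2] = 1.0
        m[5, 5] = 0.3
        _, n = extended_maxima(m, 0.2)
        assert n == 2

    def test_constant_map_single_whole_frame_region(self):
        labels, n = extended_maxima(np.full((6, 8), 0.4), 0.1)
        assert n == 1 and (labels == 1).all()

    @pytest.mark.parametrize("h", [0.1, 0.3, 0.5])
    def test_agrees_with_brute_force_oracle(self, h):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            arr = np.round(rng.random((12, 12)), 2)
            l1, n1 = extended_maxima(arr, h)
            l2, n2 = brute_force_extended_maxima(arr, h)
            assert n1 == n2
            assert labelings_equal_up_to_renumbering(l1, l2)

    def test_raising_h_never_adds_regions(self, rng):
        for _ in range(20):
            arr = rng.random((15, 15))
            ns = [extended_maxima(arr, h)[1] for h in (0.05, 0.15, 0.3, 0.6)]
            assert ns == sorted(ns, reverse=True)


class TestFilterRegions:
    def _one_region(self):
        labels = np.zeros((5, 5), int)
        labels[1:3, 1:3] = 1
        return labels

    def test_kept_above_threshold(self):
        labels = self._one_region()
        orig = np.zeros((5, 5))
        orig[1, 1] = 0.8
        out, n = filter_regions(labels, 1, orig, 0.5)
        assert n == 1 and (out == labels).all()

    def test_removed_below_threshold(self):
        labels = self._one_region()
        orig = np.zeros((5, 5))
        orig[1, 1] = 0.8
        _, n = filter_regions(labels, 1, orig, 0.9)
        assert n == 0

    def test_t_zero_keeps_everything(self, rng):
        arr = rng.random((10, 10))
        labels, n = extended_maxima(arr, 0.2)
        out, m = filter_regions(labels, n, arr, 0.0)
        assert m == n and (out == labels).all()

    def test_mean_statistic_option(self):
        labels = self._one_region()
        orig = np.zeros((5, 5))
        orig[1, 1] = 0.8  # region mean = 0.2, max = 0.8
        assert filter_regions(labels, 1, orig, 0.5, statistic="max")[1] == 1
        assert filter_regions(labels, 1, orig, 0.5, statistic="mean")[1] == 0


class TestRegionCentroids:
    def test_singleton_pixel(self):
        labels = np.zeros((8, 8), int)
        labels[4, 3] = 1  # row 4, col 3
        out = region_centroids(labels, 1)
        assert tuple(out[0]) == (3.0, 4.0)

    def test_square_block_symmetry(self):
        labels = np.zeros((8, 8), int)
        labels[2:4, 5:7] = 1
        np.testing.assert_allclose(region_centroids(labels, 1)[0], [5.5, 2.5])

    def test_diamond_centered(self):
        from conefinder.preprocess import make_label_map

        labels = make_label_map(np.array([[7.0, 7.0]]), (15, 15), 1).astype(int)
        np.testing.assert_allclose(region_centroids(labels, 1)[0], [7.0, 7.0])

    def test_empty(self):
        assert region_centroids(np.zeros((4, 4), int), 0).shape == (0, 2)


def _two_bump_map(centers, size=40, amp=0.9, s=2.0):
    yy, xx = np.mgrid[0:size, 0:size]
    m = np.zeros((size, size))
    for x, y in centers:
        m += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * s**2))
    return m


class TestLocalizeCones:
    def test_empty_map_detects_nothing(self):
        out = localize_cones(np.zeros((20, 20)), DetectionParams(1.0, 0.3, 0.25))
        assert len(out) == 0

    def test_two_bumps_recovered_within_1px(self):
        centers = [(10.0, 12.0), (30.0, 27.0)]
        m = _two_bump_map(centers)
        out = localize_cones(m, DetectionParams(1.0, 0.3, 0.25))
        assert len(out) == 2
        d = np.linalg.norm(out[:, None] - np.array(centers)[None], axis=2).min(axis=1)
        assert (d < 1.0).all()

    def test_deterministic(self, rng):
        m = rng.random((25, 25))
        p = DetectionParams(0.8, 0.2, 0.1)
        np.testing.assert_array_equal(localize_cones(m, p), localize_cones(m, p))

    def test_raising_t_never_adds_cones(self, rng):
        for _ in range(10):
            m = rng.random((20, 20))
            counts = [
                len(localize_cones(m, DetectionParams(0.5, 0.2, t)))
                for t in (0.0, 0.2, 0.5, 0.8)
            ]
            assert counts == sorted(counts, reverse=True)


class TestSweep:
    def test_default_grid_cardinalities(self):
        g = SweepGrid()
        assert len(g.sigmas) == 21 and len(g.hs) == 11 and len(g.ts) == 9
        assert len(g) == 2079

    def test_singleton_grid_returned(self):
        m = _two_bump_map([(10.0, 10.0)])
        g = SweepGrid(sigmas=(0.7,), hs=(0.3,), ts=(0.2,))
        best = sweep_detection_params([m], [np.array([[10.0, 10.0]])], g)
        assert best == DetectionParams(0.7, 0.3, 0.2)

    def test_perfect_triple_wins(self):
        centers = np.array([[10.0, 12.0], [30.0, 27.0]])
        m = _two_bump_map(centers)
        # t = 0.95 kills every region; t = 0.25 recovers both bumps exactly
        g = SweepGrid(sigmas=(1.0,), hs=(0.3,), ts=(0.25, 0.95))
        best = sweep_detection_params([m], [centers], g)
        assert best == DetectionParams(1.0, 0.3, 0.25)

    def test_tie_breaks_lexicographically_smallest(self):
        centers = np.array([[10.0, 12.0], [30.0, 27.0]])
        m = _two_bump_map(centers)
        # both sigmas give Dice 1 on this easy map -> smallest sigma wins
        g = SweepGrid(sigmas=(0.5, 1.0), hs=(0.3,), ts=(0.25,))
        best = sweep_detection_params([m], [centers], g)
        assert best.sigma == 0.5

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            sweep_detection_params([], [], SweepGrid())
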