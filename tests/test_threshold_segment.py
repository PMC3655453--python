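"""Symmetric-histogram statistics and implant-seeded segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gdmap import (
    BinaryMask,
    T1Map,
    SymmetricHistogramStats,
    segment_contrast,
    symmetric_histogram,
    tissue_threshold,
)


def mirror_oracle(values, bin_width):
    """Independent brute-force mirror-and-SD computation."""
    values = np.asarray(values, float)
    lo = float(values.min())
    edges = [lo]
    while edges[-1] < values.max():
        edges.append(edges[-1] + bin_width)
    if len(edges) < 2:
        edges.append(lo + bin_width)
    counts = [0] * (len(edges) - 1)
    for v in values:
        for b in range(len(edges) - 1):
            last = b == len(edges) - 2
            if edges[b] <= v < edges[b + 1] or (last and v == edges[-1]):
                counts[b] += 1
                break
    peak_bin = counts.index(max(counts))
    peak = (edges[peak_bin] + edges[peak_bin + 1]) / 2
    upper = [v for v in values if v >= peak]
    mirrored = upper + [2 * peak - v for v in upper]
    mean = sum(mirrored) / len(mirrored)
    sd = (sum((v - mean) ** 2 for v in mirrored) / (len(mirrored) - 1)) ** 0.5
    return peak, sd, peak - sd


class TestSymmetricHistogram:
    def test_matches_hand_enumerated_oracle_on_toy_multisets(self):
        cases = [
            ([2000, 2500, 3000, 3000, 3000, 3500, 4000, 9000], 500.0),
            ([100, 150, 150, 200, 900], 50.0),
            (list(range(0, 1000, 7)), 100.0),
        ]
        for values, bw in cases:
            stats = symmetric_histogram(values, bin_width=bw)
            peak, sd, thr = mirror_oracle(values, bw)
            assert stats.peak_t1 == pytest.approx(peak)
            assert stats.sigma == pytest.approx(sd)
            assert stats.threshold == pytest.approx(thr)

    def test_symmetric_sample_reproduces_its_own_stats(self, rng):
        """Mirroring an already-symmetric sample is (nearly) the identity."""
        mu, sd = 2800.0, 400.0
        z = rng.normal(0, 1, 20000)
        vals = np.concatenate([mu + sd * z, mu - sd * z])  # exactly symmetric
        stats = symmetric_histogram(vals, bin_width=50.0)
        assert abs(stats.peak_t1 - mu) <= 25.0  # within half a bin
        assert stats.sigma == pytest.approx(sd, rel=0.05)
        assert stats.threshold == pytest.approx(mu - sd, rel=0.05)

    def test_threshold_identity_exact(self, rng):
        vals = rng.normal(2800, 300, 5000)
        stats = symmetric_histogram(vals, bin_width=50.0)
        assert stats.threshold == stats.peak_t1 - stats.sigma  # bit-exact

    def test_contaminated_left_tail_does_not_move_sigma(self, rng):
        """Contrast-shortened voxels (left tail) must not inflate the SD."""
        clean = rng.normal(2800, 300, 20000)
        contaminated = np.concatenate([clean, rng.uniform(100, 1200, 2000)])
        s_clean = symmetric_histogram(clean, 50.0)
        s_cont = symmetric_histogram(contaminated, 50.0)
        assert s_cont.sigma == pytest.approx(s_clean.sigma, rel=0.05)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(shift=st.floats(min_value=-2000, max_value=5000))
    def test_sigma_shift_invariant(self, shift):
        # values chosen interior to their bins so float rounding of the
        # shifted edges cannot flip bin membership
        base = np.array([2000.0, 2510, 3020, 3020, 3020, 3490, 4010, 9030])
        s0 = symmetric_histogram(base, 500.0)
        s1 = symmetric_histogram(base + shift, 500.0)
        assert s1.sigma == pytest.approx(s0.sigma, rel=1e-9)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            symmetric_histogram([2800.0] * 500, 50.0)

    def test_from_peak_sigma_derives_threshold(self):
        stats = SymmetricHistogramStats.from_peak_sigma(2817.0, 852.0)
        assert stats.threshold == 1965.0


def make_map(t1, na=None):
    t1 = np.asarray(t1, float)
    na = np.zeros(t1.shape, bool) if na is None else na
    return T1Map(np.where(na, np.nan, t1), na, np.ones(t1.shape), (0.3, 0.3, 2.0))


def bmask(arr):
    return BinaryMask(np.asarray(arr, bool), (0.3, 0.3, 2.0))


class TestTissueThreshold:
    def test_na_voxels_excluded_from_count(self, rng):
        t1 = rng.normal(2800, 300, (10, 10, 4))
        na = np.zeros(t1.shape, bool)
        na[:3, :3, 0] = True
        m = make_map(t1, na)
        stats = tissue_threshold(m, bmask(np.ones(t1.shape)), 50.0)
        assert stats.n_voxels == t1.size - na.sum()

    def test_broader_tissue_has_larger_sigma(self, rng):
        narrow = make_map(rng.normal(2800, 200, (12, 12, 4)))
        broad = make_map(rng.normal(2800, 700, (12, 12, 4)))
        ones = bmask(np.ones((12, 12, 4)))
        assert (
            tissue_threshold(broad, ones, 50.0).sigma
            > tissue_threshold(narrow, ones, 50.0).sigma
        )

    def test_empty_mask_is_hard_error(self, rng):
        m = make_map(rng.normal(2800, 300, (6, 6, 2)))
        with pytest.raises(ValueError):
            tissue_threshold(m, bmask(np.zeros((6, 6, 2))), 50.0)


def flood_fill_oracle(candidates, seeds, connectivity):
    """Brute-force BFS flood fill from the seed voxels."""
    from collections import deque

    shape = candidates.shape
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [
            (i, j, k)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
    out = np.zeros(shape, bool)
    q = deque(map(tuple, np.argwhere(seeds & candidates)))
    out[seeds & candidates] = True
    while q:
        i, j, k = q.popleft()
        for di, dj, dk in offsets:
            a, b, c = i + di, j + dj, k + dk
            if 0 <= a < shape[0] and 0 <= b < shape[1] and 0 <= c < shape[2]:
                if candidates[a, b, c] and not out[a, b, c]:
                    out[a, b, c] = True
                    q.append((a, b, c))
    return out


class TestSegmentContrast:
    def _stats(self, threshold):
        return SymmetricHistogramStats.from_peak_sigma(threshold + 500.0, 500.0)

    def test_only_blob_touching_implant_included(self):
        t1 = np.full((12, 12, 3), 3000.0)
        t1[4:6, 4:6, 1] = 1000.0  # touching blob
        t1[9:11, 9:11, 1] = 1000.0  # detached blob
        implant = np.zeros(t1.shape, bool)
        implant[3, 4, 1] = True
        region = segment_contrast(
            make_map(t1), self._stats(1965.0), bmask(np.ones(t1.shape)), bmask(implant)
        )
        assert region.mask.mask[4, 4, 1] and region.mask.mask[5, 5, 1]
        assert not region.mask.mask[9, 9, 1]
        assert region.mask.n_voxels == 1 + 4  # implant + touching blob

    def test_no_subthreshold_voxels_leaves_implant_only(self):
        t1 = np.full((8, 8, 2), 3000.0)
        implant = np.zeros(t1.shape, bool)
        implant[4, 4, 0] = True
        region = segment_contrast(
            make_map(t1), self._stats(1000.0), bmask(np.ones(t1.shape)), bmask(implant)
        )
        np.testing.assert_array_equal(region.mask.mask, implant)

    def test_na_adjacent_to_implant_included(self):
        t1 = np.full((8, 8, 2), 3000.0)
        na = np.zeros(t1.shape, bool)
        na[4, 5, 0] = True  # cement/high-concentration voxel next to implant
        implant = np.zeros(t1.shape, bool)
        implant[4, 4, 0] = True
        region = segment_contrast(
            make_map(t1, na), self._stats(1000.0), bmask(np.ones(t1.shape)), bmask(implant)
        )
        assert region.mask.mask[4, 5, 0]

    def test_empty_implant_is_hard_error(self):
        t1 = np.full((6, 6, 2), 3000.0)
        with pytest.raises(ValueError):
            segment_contrast(
                make_map(t1),
                self._stats(1965.0),
                bmask(np.ones(t1.shape)),
                bmask(np.zeros(t1.shape)),
            )

    def test_monotone_in_threshold(self, rng):
        t1 = rng.uniform(500, 4000, (16, 16, 6))
        implant = np.zeros(t1.shape, bool)
        implant[8, 8, 3] = True
        tissue = bmask(np.ones(t1.shape))
        prev = None
        for thr in (1000.0, 2000.0, 3000.0):
            region = segment_contrast(make_map(t1), self._stats(thr), tissue, bmask(implant))
            if prev is not None:
                assert (prev <= region.mask.mask).all()  # raising never shrinks
            prev = region.mask.mask

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_agrees_with_flood_fill_oracle(self, connectivity, rng):
        for _ in range(25):
            shape = tuple(rng.integers(10, 21, 3))
            t1 = rng.uniform(500, 4000, shape)
            na = rng.random(shape) < 0.05
            implant = np.zeros(shape, bool)
            implant[tuple(rng.integers(0, s) for s in shape)] = True
            tissue = rng.random(shape) < 0.8
            thr = 2000.0
            region = segment_contrast(
                make_map(t1, na), self._stats(thr), bmask(tissue), bmask(implant),
                connectivity=connectivity,
            )
            candidates = implant | (tissue & (na | (np.where(na, np.inf, t1) <= thr)))
            expected = flood_fill_oracle(candidates, implant, connectivity)
            np.testing.assert_array_equal(region.mask.mask, expected)

    def test_zero_noise_phantom_region_is_plume_plus_rod(self, small_spec):
        """On a noise-free fitted phantom, a threshold placed in the gap
        between contrast-shortened and native T1 recovers plume + rod
        exactly."""
        import dataclasses

        from gdmap import fit_t1_volume, generate_scene, simulate_acquisition

        spec = dataclasses.replace(
            small_spec, noise_sigma=0.0, muscle_t1_sd=10.0, canal_t1_sd=10.0
        )
        scene = generate_scene(spec, seed=31)
        series = simulate_acquisition(scene, seed=32)
        t1_map = fit_t1_volume(series)
        # native draws sit within ~5 SD of 2817; the faintest plume voxel is
        # well below 2700 ms, so 2700 separates the two populations
        stats = SymmetricHistogramStats.from_peak_sigma(2817.0, 117.0)
        region = segment_contrast(
            t1_map, stats, scene.masks["muscle"], scene.masks["implant"]
        )
        expected = scene.masks["plume"].mask | scene.masks["implant"].mask
        np.testing.assert_array_equal(region.mask.mask, expected)
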