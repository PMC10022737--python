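"""Segmentation contracts: histogram-minimum threshold (with independent
oracle), fiber extraction, watershed separation, partition invariant."""

import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, strategies as st

import debriscope as dsc
from debriscope.segment import (
    UnimodalHistogramError,
    extract_fibers,
    minimum_threshold,
    minimum_threshold_hist,
    separate_aggregates,
)

from conftest import make_disk, study_scene_spec


# ---------------------------------------------------------------------------
# independent brute-force oracle for the iterative-smoothing threshold

def oracle_minimum_threshold(counts, max_iter=10_000):
    """Naive loop-based reimplementation: smooth with a replicate-edge
    3-point mean until exactly two (plateau-aware) maxima remain, then take
    the lowest minimum bin between them."""
    h = [float(v) for v in counts]
    n = len(h)

    def maxima(hh):
        out, i = [], 0
        while i < n:
            j = i
            while j + 1 < n and hh[j + 1] == hh[i]:
                j += 1
            if (
                (i == 0 or hh[i - 1] < hh[i])
                and (j == n - 1 or hh[j + 1] < hh[j])
                and hh[i] > 0
            ):
                out.append((i + j) // 2)
            i = j + 1
        return out

    for _ in range(max_iter + 1):
        m = maxima(h)
        if len(m) == 2:
            lo, hi = m
            best, best_v = lo, h[lo]
            for k in range(lo, hi + 1):
                if h[k] < best_v:
                    best, best_v = k, h[k]
            return best
        if len(m) < 2:
            raise UnimodalHistogramError("unimodal")
        h = [
            (h[max(k - 1, 0)] + h[k] + h[min(k + 1, n - 1)]) / 3.0
            for k in range(n)
        ]
    raise UnimodalHistogramError("not bimodal")


def random_bimodal_histogram(rng, n_bins=256):
    mu1 = rng.uniform(0.1, 0.4) * n_bins
    mu2 = rng.uniform(0.6, 0.9) * n_bins
    s1, s2 = rng.uniform(3, 15, size=2)
    n1, n2 = rng.integers(500, 50_000, size=2)
    samples = np.concatenate(
        [rng.normal(mu1, s1, n1), rng.normal(mu2, s2, n2)]
    )
    idx = np.clip(samples.astype(int), 0, n_bins - 1)
    return np.bincount(idx, minlength=n_bins)


class TestMinimumThreshold:
    def test_two_delta_histogram(self):
        counts = np.zeros(256)
        counts[10], counts[200] = 500, 700
        # already exactly two maxima; every between-mode bin is a minimum,
        # ties break to the lowest bin index
        assert minimum_threshold_hist(counts) == 11

    def test_two_level_image_mask_is_bright_mode(self):
        img = np.full((20, 20), 0.1)
        img[5:10, 5:10] = 0.9
        bm, thr = minimum_threshold(img)
        assert np.array_equal(bm.mask, img == 0.9)
        assert 0.1 < thr < 0.9

    def test_constant_image_is_unimodal_error(self):
        with pytest.raises(UnimodalHistogramError):
            minimum_threshold(np.full((10, 10), 0.5))

    def test_oracle_equivalence_sampled(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            counts = random_bimodal_histogram(rng)
            assert minimum_threshold_hist(counts) == oracle_minimum_threshold(counts)

    def test_gaussian_mixture_image_matches_oracle(self):
        rng = np.random.default_rng(0)
        samples = np.concatenate(
            [rng.normal(50, 10, 50_000), rng.normal(180, 10, 50_000)]
        )
        img = np.clip(samples, 0, 255).reshape(250, 400)
        bm, _ = minimum_threshold(img, n_bins=256)
        vmin, vmax = img.min(), img.max()
        idx = np.clip(((img - vmin) / (vmax - vmin) * 256).astype(int), 0, 255)
        t = oracle_minimum_threshold(np.bincount(idx.ravel(), minlength=256))
        assert bm.threshold_bin == t
        assert np.array_equal(bm.mask, idx > t)

    def test_mask_matches_recorded_threshold_value(self):
        rng = np.random.default_rng(3)
        img = rng.random((50, 50)) ** 3 + (rng.random((50, 50)) > 0.8)
        bm, thr = minimum_threshold(img)
        assert bm.mask.sum() > 0
        # pixels strictly above the threshold bin are foreground
        assert bm.mask[img > thr].all()


class TestExtractFibers:
    def test_interior_circle_is_particulate(self, dic_acq):
        mask = make_disk((101, 101), 50, 50, 20)
        fibers, part = extract_fibers(mask, dic_acq)
        assert fibers == []
        assert ndi.label(part)[1] == 1

    def test_sinusoidal_spanning_band_is_one_fiber(self, dic_acq):
        t = np.linspace(0, 1, 800)
        x, y = t * 199, 100 + 30 * np.sin(2 * np.pi * 1.5 * t)
        pm = np.zeros((200, 200), bool)
        pm[np.round(y).astype(int), np.round(x).astype(int)] = True
        mask = ndi.distance_transform_edt(~pm) <= 2.5
        fibers, part = extract_fibers(mask, dic_acq)
        assert len(fibers) == 1
        assert part.sum() == 0
        assert {"left", "right"} <= set(fibers[0].borders_touched)

    def test_band_diameter_and_size_bin(self, dic_acq):
        band = np.zeros((200, 200), dtype=bool)
        band[87:113, :] = True  # 26 px wide at 2.5625 px/um -> 10.15 um
        fibers, _ = extract_fibers(band, dic_acq)
        assert len(fibers) == 1
        assert fibers[0].diameter_um == pytest.approx(26 / 2.5625, rel=0.02)
        assert fibers[0].size_bin == "large"

    def test_narrow_band_is_small_bin(self, dic_acq):
        band = np.zeros((120, 120), dtype=bool)
        band[58:68, :] = True  # 10 px -> 3.9 um <= 8 um
        fibers, _ = extract_fibers(band, dic_acq)
        assert len(fibers) == 1
        assert fibers[0].size_bin == "small"

    def test_empty_mask(self, dic_acq):
        fibers, part = extract_fibers(np.zeros((30, 30), bool), dic_acq)
        assert fibers == [] and part.sum() == 0

    def test_partition_of_debris_pixels(self, dic_acq):
        """Fiber pixels and particulate pixels exactly partition the
        above-speckle debris pixels."""
        scene = dsc.generate_scene(study_scene_spec(seed=2))
        bm, _ = minimum_threshold(scene.synthetic_debris_probability())
        fibers, part = extract_fibers(bm, dic_acq)
        fiber_px = np.zeros_like(part)
        for fb in fibers:
            assert not (fb.mask & part).any()
            fiber_px |= fb.mask
        # partition covers every component at/above the speckle cutoff
        lab, n = ndi.label(bm.mask, structure=np.ones((3, 3), int))
        sizes = np.bincount(lab.ravel())
        above = bm.mask & (sizes[lab] >= 2)
        assert np.array_equal(fiber_px | part, above)


class TestSeparateAggregates:
    def test_single_circle_one_label(self):
        labels = separate_aggregates(make_disk((101, 101), 50, 50, 20))
        assert len(np.unique(labels)) - 1 == 1

    def test_two_overlapping_circles_split(self):
        mask = make_disk((60, 60), 30, 22, 10) | make_disk((60, 60), 30, 38, 10)
        labels = separate_aggregates(mask)
        assert len(np.unique(labels)) - 1 == 2

    def test_25_disjoint_blobs_keep_25_labels(self):
        mask = np.zeros((300, 300), bool)
        for i in range(25):
            mask |= make_disk((300, 300), 15 + 28 * (i // 5), 15 + 28 * (i % 5), 6)
        assert ndi.label(mask)[1] == 25
        labels = separate_aggregates(mask)
        assert len(np.unique(labels)) - 1 == 25

    def test_never_merges_components(self):
        rng = np.random.default_rng(4)
        mask = np.zeros((120, 120), bool)
        for _ in range(12):
            mask |= make_disk((120, 120), rng.integers(10, 110), rng.integers(10, 110), 7)
        n_cc = ndi.label(mask, structure=np.ones((3, 3), int))[1]
        labels = separate_aggregates(mask)
        assert len(np.unique(labels)) - 1 >= n_cc
        assert np.array_equal(labels > 0, mask)

    def test_empty_mask(self):
        assert separate_aggregates(np.zeros((10, 10), bool)).max() == 0

    def test_deterministic(self):
        mask = make_disk((80, 80), 40, 30, 12) | make_disk((80, 80), 40, 50, 12)
        assert np.array_equal(separate_aggregates(mask), separate_aggregates(mask))


@given(
    lo=st.integers(min_value=5, max_value=100),
    hi=st.integers(min_value=150, max_value=250),
    m1=st.integers(min_value=100, max_value=10_000),
    m2=st.integers(min_value=100, max_value=10_000),
)
def test_two_delta_threshold_always_between_modes(lo, hi, m1, m2):
    counts = np.zeros(256)
    counts[lo], counts[hi] = m1, m2
    t = minimum_threshold_hist(counts)
    assert lo <= t < hi
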