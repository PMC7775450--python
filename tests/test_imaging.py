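"""Image quantifiers: thresholds, motility, vacuole area, cluster detection."""

import numpy as np
import pytest

from glycobind.imaging import (ImageStack, auto_threshold, detect_clusters,
                               motility_index, to_uint8,
                               vacuole_area_fraction)
from glycobind.kinetics import fit_vacuole_kinetics
from glycobind.synthetic import (GeneratorConfig, gen_cluster_image,
                                 gen_motility_stack, gen_vacuole_stack)


def triangle_threshold_oracle(img8: np.ndarray) -> int:
    """Exhaustive Zack triangle threshold on a 256-bin histogram.

    Draw a line from the histogram peak to the far end of the longer tail;
    the threshold is the bin whose histogram point lies farthest below that
    line, searched over every candidate bin.  The search IS the definition.
    """
    hist = np.bincount(img8.ravel(), minlength=256).astype(float)
    peak = int(np.argmax(hist))
    nz = np.nonzero(hist)[0]
    lo, hi = int(nz[0]), int(nz[-1])
    # longer tail side
    end = hi if (hi - peak) >= (peak - lo) else lo
    if end == peak:
        return peak
    x1, y1, x2, y2 = peak, hist[peak], end, hist[end]
    best, best_d = peak, -1.0
    rng = range(peak + 1, end + 1) if end > peak else range(end, peak)
    norm = np.hypot(x2 - x1, y2 - y1)
    for b in rng:
        d = abs((y2 - y1) * b - (x2 - x1) * hist[b] + x2 * y1 - y2 * x1) / norm
        if d > best_d:
            best, best_d = b, d
    return best


class TestAutoThreshold:
    @pytest.mark.parametrize("method", ["mean_dark", "triangle_dark"])
    @pytest.mark.parametrize("frac_bright", [0.3, 0.7])
    def test_two_level_image_separated_exactly(self, method, frac_bright):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((64, 64)) < frac_bright, 200, 10
                       ).astype(np.uint8)
        mask = auto_threshold(img, method)
        np.testing.assert_array_equal(mask, img == 200)

    def test_triangle_matches_exhaustive_oracle(self):
        """Peak-plus-skewed-tail histogram: threshold between mode and tail."""
        rng = np.random.default_rng(1)
        base = np.full(10000, 20, dtype=np.uint8)
        tail = (20 + 230 * rng.power(3.0, 1500)).astype(np.uint8)
        img = np.concatenate([base, tail]).reshape(100, 115)
        oracle = triangle_threshold_oracle(img)
        assert 20 < oracle < 250
        mask = auto_threshold(img, "triangle_dark")
        # package mask must match the oracle's to within one histogram bin
        candidates = [img > (oracle + d) for d in (-1, 0, 1)]
        assert any(np.array_equal(mask, c) for c in candidates)

    def test_mean_threshold_of_uniform_image(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, size=(128, 128), dtype=np.uint8)
        mask = auto_threshold(img, "mean_dark")
        np.testing.assert_array_equal(mask, img > img.mean())

    def test_affine_intensity_invariance(self):
        """8-bit rescaling leaves the triangle mask unchanged."""
        rng = np.random.default_rng(3)
        img = (rng.gamma(2.0, 20.0, (80, 80))).astype(float)
        m1 = auto_threshold(img, "triangle_dark")
        m2 = auto_threshold(0.25 * img + 40.0, "triangle_dark")
        np.testing.assert_array_equal(m1, m2)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            auto_threshold(np.full((8, 8), 7, dtype=np.uint8))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            auto_threshold(np.eye(8), "otsu")


class TestMotilityIndex:
    def _stack(self, frames):
        return ImageStack(frames=np.asarray(frames), pixel_size_um=0.5,
                          frame_interval_min=5.0)

    def test_identical_frames_score_zero(self):
        rng = np.random.default_rng(4)
        frame = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        res = motility_index(self._stack([frame] * 5))
        assert res.n_transitions == 4
        np.testing.assert_array_equal(res.index_series, np.zeros(4))

    def test_alternating_binary_frames_brute_force(self):
        """4x4 all-dark/all-bright alternation: population SD of {0,1} = 0.5."""
        lo = np.zeros((4, 4), dtype=np.uint8)
        hi = np.full((4, 4), 255, dtype=np.uint8)
        lo[0, 0], hi[0, 0] = 255, 0  # keep each frame non-constant
        res = motility_index(self._stack([lo, hi, lo, hi]))
        # brute force: every pixel flips between mask values 0 and 1
        assert res.index_series == pytest.approx([0.5, 0.5, 0.5])

    def test_jitter_magnitude_ordering(self):
        """Doubling the frame jitter strictly raises the mean index."""
        means = []
        for sigma in (1.0, 2.0):
            vals = []
            for seed in range(5):
                stack = gen_motility_stack(GeneratorConfig(
                    seed=seed, options={"sigma_profile": np.full(9, sigma),
                                        "n_frames": 10}))
                vals.append(motility_index(stack).index_series.mean())
            means.append(np.mean(vals))
        assert means[1] > means[0]

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            motility_index(self._stack([np.eye(4)]))


class TestVacuoleAreaFraction:
    def test_blank_stack_all_zero(self):
        stack = ImageStack(np.zeros((5, 32, 32), dtype=np.uint8), 0.5, 5.0,
                           channel="fluorescence")
        tc = vacuole_area_fraction(stack, n_cells=3)
        np.testing.assert_array_equal(tc.values, np.zeros(5))

    def test_single_disk_area(self):
        """One bright disk of radius r: area within pixelation error of pi r^2."""
        size, r_px, px_um = 128, 20, 0.5
        yy, xx = np.mgrid[0:size, 0:size]
        disk = ((yy - 64) ** 2 + (xx - 64) ** 2 <= r_px**2)
        frame = np.where(disk, 220, 15).astype(np.uint8)
        stack = ImageStack(frame[None], px_um, 5.0, channel="fluorescence")
        tc = vacuole_area_fraction(stack, n_cells=1)
        expected = np.pi * (r_px * px_um) ** 2
        assert tc.values[0] == pytest.approx(expected, rel=0.05)

    def test_end_to_end_hill_recovery(self):
        """Disk stacks grown on a Hill schedule fit back k_half within 15%."""
        errs = []
        for seed in range(5):
            stack, truth = gen_vacuole_stack(GeneratorConfig(
                scenario="cap250", seed=seed))
            tc = vacuole_area_fraction(stack, n_cells=10)
            fit = fit_vacuole_kinetics(tc)
            assert fit.converged
            errs.append(abs(fit.params.k_half - truth.k_half)
                        / truth.k_half)
        assert np.median(errs) <= 0.15

    def test_zero_cells_rejected(self):
        stack = ImageStack(np.zeros((2, 8, 8), dtype=np.uint8), 0.5, 5.0)
        with pytest.raises(ValueError):
            vacuole_area_fraction(stack, n_cells=0)


class TestDetectClusters:
    def test_isolated_spots_counted_exactly(self):
        """25 well-separated PSF spots in 1 um^2: all found, none invented."""
        px_nm, size = 20.0, 50  # 1 um x 1 um
        yy, xx = np.mgrid[0:size, 0:size]
        img = np.zeros((size, size))
        centers = [(5 + 10 * i, 5 + 10 * j) for i in range(5)
                   for j in range(5)]
        sigma = 60 / 2.355 / px_nm
        for cy, cx in centers:
            img += 150 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                                / (2 * sigma**2))
        res = detect_clusters(img, px_nm)
        assert res.n_clusters == 25
        assert res.density_per_um2 == pytest.approx(25.0)
        # grid spacing 10 px = 200 nm
        assert res.mean_spacing_nm == pytest.approx(200.0, rel=0.05)

    def test_empty_field(self):
        rng = np.random.default_rng(5)
        img = rng.poisson(5.0, (100, 100)).astype(float)
        res = detect_clusters(img, 20.0)
        assert res.n_clusters <= 1
        assert res.mean_spacing_nm is None or res.n_clusters > 1

    def test_density_unbiased_across_range(self):
        """CSR-corrected density within 15% for 5-40 clusters/um^2."""
        for target in (5.0, 22.0, 40.0):
            rec = []
            for seed in range(8):
                img, _ = gen_cluster_image(GeneratorConfig(
                    seed=seed, options={"density_per_um2": target}))
                rec.append(detect_clusters(img, 20.0)
                           .density_csr_corrected_per_um2)
            assert np.median(rec) == pytest.approx(target, rel=0.15)

    def test_too_coarse_pixels_rejected(self):
        with pytest.raises(ValueError):
            detect_clusters(np.zeros((10, 10)), pixel_size_nm=200.0)


def test_to_uint8_full_range():
    img = np.array([[0.0, 0.5], [1.0, 0.25]])
    out = to_uint8(img)
    assert out.dtype == np.uint8
    assert out.min() == 0 and out.max() == 255
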