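"""Otsu binarization, slice-difference metric, normalization, regression."""

import numpy as np
import pytest

import widefieldct as w
from widefieldct.quality import sampled_indices


def exhaustive_otsu(image: np.ndarray, nbins: int = 256) -> float:
    """Independent Otsu oracle: scan every candidate bin, maximize the
    between-class variance  w0*w1*(mu0-mu1)^2  computed from first
    principles on the histogram."""
    data = np.asarray(image).ravel()
    counts, edges = np.histogram(data, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    best_t, best_v = None, -1.0
    total = counts.sum()
    for k in range(1, nbins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, centers[k - 1]
    return best_t


class TestOtsu:
    def test_two_level_image_perfectly_separated(self):
        img = np.array([[10.0] * 8, [200.0] * 8] * 4)
        t = w.otsu_threshold(img)
        assert 10 < t < 200
        assert set(np.unique(img > t)) == {False, True}

    def test_matches_exhaustive_scan_oracle(self):
        # empty bins between the modes make the between-class variance
        # exactly flat there, so compare the induced classifications (any
        # cut inside the plateau separates the classes identically)
        rng = np.random.default_rng(0)
        img = np.concatenate(
            [rng.normal(40, 8, 3000), rng.normal(160, 12, 2000)]
        ).reshape(50, 100)
        t = w.otsu_threshold(img)
        oracle = exhaustive_otsu(img)
        bin_width = np.ptp(img) / 256
        assert abs(t - oracle) <= 2 * bin_width + 1e-9
        assert np.mean((img > t) != (img > oracle)) <= 1e-3

    def test_bimodal_mixture_misclassification_below_one_percent(self):
        rng = np.random.default_rng(1)
        n = 100_000
        a = rng.normal(50, 10, n // 2)
        b = rng.normal(150, 10, n // 2)
        img = np.concatenate([a, b])
        t = w.otsu_threshold(img)
        wrong = (a > t).sum() + (b <= t).sum()
        assert wrong / n < 0.01

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            w.otsu_threshold(np.full((8, 8), 3.0))


class TestSliceDifference:
    def test_identical_slices_zero(self):
        s = (np.arange(64).reshape(8, 8) % 2).astype(np.uint8)
        assert w.slice_difference(s, s) == 0

    def test_complementary_slices_count_all_pixels(self):
        s = (np.arange(64).reshape(8, 8) % 2).astype(np.uint8)
        assert w.slice_difference(s, 1 - s) == 64

    def test_constructed_five_pixel_difference(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        b = a.copy()
        for r, c in [(0, 0), (1, 5), (3, 3), (6, 2), (7, 7)]:
            b[r, c] = 1
        assert w.slice_difference(a, b) == 5

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            w.slice_difference(np.zeros((4, 4)), np.zeros((4, 5)))

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError):
            w.slice_difference(np.full((4, 4), 0.5), np.zeros((4, 4)))

    def test_is_a_metric_on_binary_slices(self):
        rng = np.random.default_rng(2)
        a, b, c = (rng.integers(0, 2, (16, 16)).astype(np.uint8) for _ in range(3))
        dab = w.slice_difference(a, b)
        assert dab == w.slice_difference(b, a)
        assert w.slice_difference(a, a) == 0
        assert dab <= w.slice_difference(a, c) + w.slice_difference(c, b)


class TestProtocolError:
    def test_stride_five_on_1024_slices_samples_205(self):
        assert sampled_indices(1024, 5).size == 205

    @pytest.mark.parametrize(
        "n, stride", [(1024, 5), (100, 7), (13, 13), (5, 1)]
    )
    def test_stride_sampling_count_and_first_slice(self, n, stride):
        idx = sampled_indices(n, stride)
        assert idx[0] == 0
        assert idx.size == int(np.ceil(n / stride))

    def test_volume_vs_itself_zero(self):
        rng = np.random.default_rng(3)
        vol = rng.normal(size=(20, 16, 16))
        rep = w.protocol_error(vol, vol, slice_stride=5)
        assert rep.mean_E == 0.0
        assert rep.std_E == 0.0
        assert rep.per_slice_E.size == 4

    def test_summary_matches_direct_recomputation(self):
        rng = np.random.default_rng(4)
        va = rng.normal(size=(12, 24, 24)) + np.linspace(0, 2, 24)
        vb = va + rng.normal(0, 0.5, va.shape)
        rep = w.protocol_error(va, vb, slice_stride=3)
        direct = [
            w.slice_difference(w.binarize(va[k]), w.binarize(vb[k]))
            for k in range(0, 12, 3)
        ]
        assert np.array_equal(rep.per_slice_E, np.array(direct, dtype=float))
        assert rep.mean_E == pytest.approx(np.mean(direct))
        assert rep.std_E == pytest.approx(np.std(direct))

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            w.protocol_error(np.zeros((0, 4, 4)), np.zeros((0, 4, 4)), 5)


class TestNormalizeQuality:
    def test_endpoint_mapping(self):
        out = w.normalize_quality([0.0, 100.0], (16.0, 116.0))
        assert np.allclose(out, [116.0, 16.0])

    def test_equally_spaced_errors_give_equally_spaced_qualities(self):
        out = w.normalize_quality([10.0, 20.0, 30.0], (20.0, 100.0))
        assert np.allclose(np.diff(out), -40.0)

    def test_output_range_equals_requested_range(self):
        rng = np.random.default_rng(5)
        e = rng.uniform(5, 50, 12)
        out = w.normalize_quality(e, (16.0, 116.0))
        assert out.min() == pytest.approx(16.0)
        assert out.max() == pytest.approx(116.0)

    def test_order_reversal(self):
        e = np.array([3.0, 1.0, 2.0])
        out = w.normalize_quality(e, (0.0, 100.0))
        assert np.argsort(out).tolist() == np.argsort(-e).tolist()

    def test_degenerate_all_equal_rejected(self):
        with pytest.raises(ValueError):
            w.normalize_quality([5.0, 5.0, 5.0], (16.0, 116.0))


class TestFitLine:
    def test_two_points_exact(self):
        fit = w.fit_line([0.0, 1.0], [1.0, 3.0])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(6)
        x = np.linspace(0, 9, 10)
        y = 0.7 * x + 2.0 + rng.normal(0, 0.3, 10)
        fit = w.fit_line(x, y)
        # closed-form normal equations
        A = np.vstack([x, np.ones_like(x)]).T
        slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
        ss_res = np.sum((y - (slope * x + intercept)) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.r_squared == pytest.approx(1 - ss_res / ss_tot)

    def test_constant_response(self):
        fit = w.fit_line([0.0, 1.0, 2.0], [4.0, 4.0, 4.0])
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            w.fit_line([2.0, 2.0], [1.0, 5.0])


@pytest.fixture(scope="module")
def tiny_setup():
    g = w.plan_widefield(128, 48, 8, pixel_size_um=1.0)
    ladder = w.make_protocol_ladder(g, 50, [(4, 4, 4), (2, 2, 2), (1, 0.5, 1)])
    return g, ladder


class TestSimulatedCurve:

    def test_gold_standard_has_best_quality(self, tiny_setup):
        g, ladder = tiny_setup
        curve = w.simulate_quality_curve(g, ladder, noise_sd=0.0, seed=0)
        qualities = [q for _, q in curve]
        assert qualities[0] == max(qualities)

    def test_identical_seed_identical_curve(self, tiny_setup):
        g, ladder = tiny_setup
        a = w.simulate_quality_curve(g, ladder, noise_sd=0.05, seed=9)
        b = w.simulate_quality_curve(g, ladder, noise_sd=0.05, seed=9)
        assert a == b

    def test_quality_decreases_with_fewer_projections(self, tiny_setup):
        g, ladder = tiny_setup
        curve = w.simulate_quality_curve(g, ladder, noise_sd=0.02, seed=1)
        qualities = [q for _, q in curve]
        assert qualities == sorted(qualities, reverse=True)
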