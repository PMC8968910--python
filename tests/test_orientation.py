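import numpy as np
import pytest
from skimage.transform import rotate

from magnegel.orientation import (
    BIN_WIDTH_DEG,
    N_BINS,
    DegenerateImageError,
    DirectionalityHistogram,
    GrayImage,
    average_histograms,
    binarize_actin,
    classify_anisotropy,
    fit_gaussian,
    fourier_directionality,
)
from magnegel.synthetic import SceneSpec, generate_fiber_image


def grating(angle_deg: float, n: int = 256, period: float = 16.0) -> GrayImage:
    """Sinusoidal grating whose stripes run along ``angle_deg``."""
    rad = np.radians(angle_deg)
    rows, cols = np.mgrid[0:n, 0:n]
    # phase varies perpendicular to the stripe direction (row axis down)
    phase = (np.sin(rad) * cols + np.cos(rad) * rows) * 2 * np.pi / period
    return GrayImage(data=0.5 + 0.4 * np.sin(phase))


def make_hist(amounts: np.ndarray) -> DirectionalityHistogram:
    amounts = np.asarray(amounts, float)
    return DirectionalityHistogram(
        amounts=amounts / amounts.sum(),
        bin_edges_deg=np.linspace(0.0, 180.0, N_BINS + 1),
    )


class TestGrayImage:
    def test_too_small(self):
        with pytest.raises(ValueError):
            GrayImage(data=np.zeros((32, 32)))

    def test_bad_pixel_size(self):
        with pytest.raises(ValueError):
            GrayImage(data=np.zeros((64, 64)), pixel_size_um=0.0)


class TestFourierDirectionality:
    def test_histogram_contract(self):
        h = fourier_directionality(grating(90.0))
        assert h.amounts.shape == (N_BINS,)
        assert h.amounts.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(h.amounts >= 0)

    @pytest.mark.parametrize("angle", [0.0, 30.0, 60.0, 90.0, 120.0, 150.0])
    def test_grating_peak_location(self, angle):
        h = fourier_directionality(grating(angle))
        peak = h.peak_bin_center_deg
        diff = abs((peak - angle + 90.0) % 180.0 - 90.0)
        assert diff <= 2.0 * BIN_WIDTH_DEG

    def test_white_noise_stays_near_uniform(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            h = fourier_directionality(GrayImage(rng.random((256, 256))))
            assert h.amounts.max() < 3.0 / N_BINS

    def test_constant_image_raises_or_uniform(self):
        img = GrayImage(np.full((64, 64), 7.0))
        with pytest.raises(DegenerateImageError):
            fourier_directionality(img)
        h = fourier_directionality(img, on_degenerate="uniform")
        assert h.degenerate
        np.testing.assert_allclose(h.amounts, 1.0 / N_BINS)

    def test_rotation_equivariance(self):
        img, _ = generate_fiber_image(
            SceneSpec(orientation_mean_deg=90.0, orientation_spread_deg=2.0, seed=3)
        )
        base = fit_gaussian(fourier_directionality(img)).center_deg
        rotated = rotate(np.asarray(img.data, float), 30.0)
        shifted = fit_gaussian(
            fourier_directionality(GrayImage(rotated + 1e-9))
        ).center_deg
        diff = (shifted - base) % 180.0
        assert diff == pytest.approx(30.0, abs=2.0)

    def test_non_square_image(self):
        rad = np.radians(90.0)
        rows, cols = np.mgrid[0:128, 0:200]
        phase = (np.sin(rad) * cols + np.cos(rad) * rows) * 2 * np.pi / 16
        h = fourier_directionality(GrayImage(0.5 + 0.4 * np.sin(phase)))
        assert abs(h.peak_bin_center_deg - 90.0) <= 2 * BIN_WIDTH_DEG


class TestFitGaussian:
    def test_exact_gaussian_recovery(self):
        centers = np.arange(1.0, 180.0, 2.0)
        y = 0.002 + 0.05 * np.exp(-((centers - 88.0) ** 2) / (2 * 5.0**2))
        fit = fit_gaussian(make_hist(y))
        assert fit.converged
        assert fit.center_deg == pytest.approx(88.0, abs=0.5)
        assert fit.sd_deg == pytest.approx(5.0, abs=0.5)

    def test_wraparound_peak_near_zero(self):
        centers = np.arange(1.0, 180.0, 2.0)
        d = np.minimum(np.abs(centers - 3.0), 180.0 - np.abs(centers - 3.0))
        y = 0.001 + 0.05 * np.exp(-(d**2) / (2 * 6.0**2))
        fit = fit_gaussian(make_hist(y))
        assert fit.converged
        assert min(fit.center_deg, 180.0 - fit.center_deg) <= 4.0

    def test_uniform_histogram_degenerate(self):
        fit = fit_gaussian(make_hist(np.ones(N_BINS)))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-6)

    def test_noisy_recovery_unbiased(self):
        centers = np.arange(1.0, 180.0, 2.0)
        clean = 0.002 + 0.05 * np.exp(-((centers - 88.0) ** 2) / (2 * 5.0**2))
        rng = np.random.default_rng(0)
        recovered = []
        for _ in range(10):
            noisy = np.clip(clean + rng.normal(0, 0.002, N_BINS), 1e-9, None)
            recovered.append(fit_gaussian(make_hist(noisy)).center_deg)
        assert np.mean(recovered) == pytest.approx(88.0, abs=1.0)


class TestClassifyAnisotropy:
    def test_aligned_scene_anisotropic(self):
        img, truth = generate_fiber_image(
            SceneSpec(orientation_mean_deg=90.0, orientation_spread_deg=5.0, seed=1)
        )
        h = fourier_directionality(img)
        fit = fit_gaussian(h)
        call = classify_anisotropy(fit, h)
        assert call.is_anisotropic
        assert call.peak_center_deg == pytest.approx(90.0, abs=3.0)

    def test_isotropic_scene_not_anisotropic(self):
        img, _ = generate_fiber_image(SceneSpec(kind="isotropic_fibers", seed=2))
        h = fourier_directionality(img)
        call = classify_anisotropy(fit_gaussian(h), h)
        assert not call.is_anisotropic
        assert call.peak_center_deg is None

    def test_bimodal_not_anisotropic(self):
        centers = np.arange(1.0, 180.0, 2.0)
        y = (
            0.002
            + 0.05 * np.exp(-((centers - 45.0) ** 2) / (2 * 4.0**2))
            + 0.045 * np.exp(-((centers - 135.0) ** 2) / (2 * 4.0**2))
        )
        h = make_hist(y)
        call = classify_anisotropy(fit_gaussian(h), h)
        assert not call.is_anisotropic

    def test_call_invariant(self):
        from magnegel.orientation import AnisotropyCall

        with pytest.raises(ValueError):
            AnisotropyCall(is_anisotropic=True, peak_center_deg=None)
        with pytest.raises(ValueError):
            AnisotropyCall(is_anisotropic=False, peak_center_deg=42.0)


class TestBinarizeActin:
    def test_two_level_image_exact_split(self):
        rng = np.random.default_rng(1)
        data = np.where(rng.random((64, 64)) > 0.5, 200.0, 20.0)
        binary = binarize_actin(GrayImage(data))
        np.testing.assert_array_equal(np.asarray(binary.data), data > 100)

    def test_single_valued_raises(self):
        with pytest.raises(DegenerateImageError):
            binarize_actin(GrayImage(np.full((64, 64), 3.0)))

    def test_contrast_inversion_invariance(self):
        img, _ = generate_fiber_image(
            SceneSpec(orientation_mean_deg=60.0, orientation_spread_deg=3.0, seed=4)
        )
        data = np.asarray(img.data, float)
        h1 = fourier_directionality(GrayImage(data))
        h2 = fourier_directionality(GrayImage(data.max() - data))
        assert abs(h1.peak_bin_center_deg - h2.peak_bin_center_deg) <= BIN_WIDTH_DEG


class TestAverageHistograms:
    def test_idempotence(self):
        h = fourier_directionality(grating(40.0))
        avg = average_histograms([h, h, h])
        np.testing.assert_allclose(avg.amounts, h.amounts, rtol=1e-12)

    def test_two_disjoint_single_bins(self):
        a = np.zeros(N_BINS)
        a[10] = 1.0
        b = np.zeros(N_BINS)
        b[50] = 1.0
        avg = average_histograms([make_hist(a), make_hist(b)])
        assert avg.amounts[10] == pytest.approx(0.5)
        assert avg.amounts[50] == pytest.approx(0.5)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            average_histograms([])

    def test_mixed_binning_raises(self):
        h = make_hist(np.ones(N_BINS))
        other = DirectionalityHistogram(
            amounts=np.full(N_BINS, 1.0 / N_BINS),
            bin_edges_deg=np.linspace(0.0, 180.0, N_BINS + 1) + 0.5,
        )
        with pytest.raises(ValueError):
            average_histograms([h, other])

    def test_replicate_average_tightens_peak_variance(self):
        singles, averaged = [], []
        for seed in range(8):
            hists = [
                fourier_directionality(
                    generate_fiber_image(
                        SceneSpec(orientation_mean_deg=90.0, orientation_spread_deg=5.0,
                                  seed=seed * 10 + k)
                    )[0]
                )
                for k in range(3)
            ]
            singles.append(fit_gaussian(hists[0]).center_deg)
            averaged.append(fit_gaussian(average_histograms(hists)).center_deg)
        assert np.var(averaged) <= np.var(singles) + 0.5
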