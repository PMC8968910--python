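"""Fourier-spectrum directionality analysis of grayscale micrographs.

The distribution of oriented structure over [0, 180) degrees is estimated
from the angular distribution of 2-D power-spectral energy: a Hann window
suppresses edge artifacts, the DC neighbourhood is excluded, spectral
power is integrated in angular sectors, and the sector angle is mapped to
the orthogonal structure orientation.  Histograms use 90 bins of 2 degrees;
0 degrees is a transect across the image width (a horizontal structure).
A Gaussian with baseline is fitted to the histogram and a single-isolated-
peak criterion classifies the image as anisotropic or not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, signal
from skimage.filters import threshold_otsu

__all__ = [
    "GrayImage",
    "DirectionalityHistogram",
    "GaussianFitResult",
    "AnisotropyCall",
    "fourier_directionality",
    "fit_gaussian",
    "classify_anisotropy",
    "binarize_actin",
    "average_histograms",
]

N_BINS = 90
BIN_WIDTH_DEG = 2.0


class DegenerateImageError(ValueError):
    """Raised for constant or otherwise information-free images."""


@dataclass(frozen=True)
class GrayImage:
    """2-D grayscale image with physical pixel size (µm/pixel)."""

    data: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError("image must be 2-D")
        if min(arr.shape) < 64:
            raise ValueError("image must be at least 64x64 pixels")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        object.__setattr__(self, "data", arr)


@dataclass(frozen=True)
class DirectionalityHistogram:
    """Normalized amount of oriented structure in 2-degree bins."""

    amounts: np.ndarray  # (90,), sums to 1
    bin_edges_deg: np.ndarray  # (91,)
    degenerate: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.amounts, dtype=float)
        if a.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins")
        if np.any(a < -1e-12):
            raise ValueError("amounts must be non-negative")
        if abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("amounts must sum to 1")
        object.__setattr__(self, "amounts", a)

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:]) / 2.0

    @property
    def peak_bin_center_deg(self) -> float:
        return float(self.bin_centers_deg[int(np.argmax(self.amounts))])


@dataclass(frozen=True)
class GaussianFitResult:
    """baseline + amplitude * exp(-(theta-center)^2 / (2 sd^2)) fit."""

    center_deg: float
    sd_deg: float
    amplitude: float
    baseline: float
    r_squared: float
    converged: bool


@dataclass(frozen=True)
class AnisotropyCall:
    is_anisotropic: bool
    peak_center_deg: float | None

    def __post_init__(self) -> None:
        if self.is_anisotropic != (self.peak_center_deg is not None):
            raise ValueError("peak_center present iff anisotropic")


def _uniform_histogram() -> DirectionalityHistogram:
    edges = np.linspace(0.0, 180.0, N_BINS + 1)
    return DirectionalityHistogram(
        amounts=np.full(N_BINS, 1.0 / N_BINS), bin_edges_deg=edges, degenerate=True
    )


def fourier_directionality(
    img: GrayImage,
    low_freq_exclude: float = 3.0,
    on_degenerate: str = "raise",
) -> DirectionalityHistogram:
    """Directionality histogram from the 2-D power spectrum.

    Parameters
    ----------
    img : GrayImage
        Input micrograph (any bit depth; converted to float).
    low_freq_exclude : float
        Radius (in frequency pixels of the padded square spectrum) around
        DC to exclude.
    on_degenerate : {"raise", "uniform"}
        Behaviour for constant images: raise, or return the flagged
        uniform histogram.
    """
    data = np.asarray(img.data, dtype=float)
    if np.ptp(data) == 0:
        if on_degenerate == "uniform":
            return _uniform_histogram()
        raise DegenerateImageError("constant image has no orientation content")

    data = data - data.mean()
    wr = np.hanning(data.shape[0])
    wc = np.hanning(data.shape[1])
    windowed = data * wr[:, None] * wc[None, :]

    n = max(windowed.shape)
    padded = np.zeros((n, n))
    padded[: windowed.shape[0], : windowed.shape[1]] = windowed

    power = np.abs(np.fft.fftshift(np.fft.fft2(padded))) ** 2
    freq = np.fft.fftshift(np.fft.fftfreq(n)) * n  # frequency-pixel units
    u, v = np.meshgrid(freq, freq, indexing="xy")  # u: column freq, v: row freq
    radius = np.hypot(u, v)
    mask = (radius > low_freq_exclude) & (radius <= n / 2.0)

    # spectral energy of a structure at angle theta lies at theta +/- 90;
    # rows of the array are the image y axis, so -v gives a right-handed frame
    spectral_angle = np.degrees(np.arctan2(-v, u))
    structure_angle = np.mod(spectral_angle + 90.0, 180.0)

    edges = np.linspace(0.0, 180.0, N_BINS + 1)
    idx = np.clip((structure_angle[mask] / BIN_WIDTH_DEG).astype(int), 0, N_BINS - 1)
    amounts = np.bincount(idx, weights=power[mask], minlength=N_BINS)
    total = amounts.sum()
    if total <= 0:
        if on_degenerate == "uniform":
            return _uniform_histogram()
        raise DegenerateImageError("no spectral energy outside the excluded band")
    return DirectionalityHistogram(amounts=amounts / total, bin_edges_deg=edges)


def _gauss(theta: np.ndarray, baseline: float, amp: float, center: float, sd: float):
    return baseline + amp * np.exp(-((theta - center) ** 2) / (2.0 * sd**2))


def fit_gaussian(hist: DirectionalityHistogram) -> GaussianFitResult:
    """Least-squares Gaussian+baseline fit with circular mode centering.

    Bins are circularly shifted so the mode sits mid-range before fitting
    (orientation is 180-periodic); the center is reported in original
    coordinates, in [0, 180).
    """
    y = hist.amounts
    centers = hist.bin_centers_deg
    mode = int(np.argmax(y))
    shift = N_BINS // 2 - mode
    y_shifted = np.roll(y, shift)

    baseline0 = float(np.percentile(y_shifted, 25))
    amp0 = float(y_shifted.max() - baseline0)
    p0 = [baseline0, max(amp0, 1e-12), centers[N_BINS // 2], 10.0]
    try:
        popt, _ = optimize.curve_fit(
            _gauss,
            centers,
            y_shifted,
            p0=p0,
            bounds=([0.0, 0.0, 0.0, 0.1], [1.0, 1.0, 180.0, 1000.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return GaussianFitResult(
            center_deg=float(centers[mode]),
            sd_deg=float("nan"),
            amplitude=0.0,
            baseline=float(np.mean(y)),
            r_squared=0.0,
            converged=False,
        )
    baseline, amp, center_shifted, sd = popt
    resid = y_shifted - _gauss(centers, *popt)
    ss_tot = float(np.sum((y_shifted - y_shifted.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    center = (center_shifted - shift * BIN_WIDTH_DEG) % 180.0
    return GaussianFitResult(
        center_deg=float(center),
        sd_deg=float(sd),
        amplitude=float(amp),
        baseline=float(baseline),
        r_squared=r2,
        converged=True,
    )


def classify_anisotropy(
    fit: GaussianFitResult,
    hist: DirectionalityHistogram,
    amplitude_factor: float = 2.0,
    r2_threshold: float = 0.5,
    secondary_peak_frac: float = 0.5,
) -> AnisotropyCall:
    """Single-isolated-peak test.

    Anisotropic iff the fit converged, amplitude > amplitude_factor x
    baseline (with a floor of the uniform level), the fit explains the
    histogram (R^2 above threshold), and no second local maximum rises
    above ``secondary_peak_frac`` of the main peak height over baseline.
    """
    uniform = 1.0 / N_BINS
    if not fit.converged or hist.degenerate:
        return AnisotropyCall(False, None)
    if fit.amplitude <= amplitude_factor * max(fit.baseline, 0.25 * uniform):
        return AnisotropyCall(False, None)
    if fit.r_squared < r2_threshold:
        return AnisotropyCall(False, None)

    # secondary-peak scan on the mode-centered histogram; tile three
    # periods so wrapped peaks at the array edge are still detected
    y = np.roll(hist.amounts, N_BINS // 2 - int(np.argmax(hist.amounts)))
    tiled = np.concatenate([y, y, y])
    peaks, props = signal.find_peaks(tiled, height=fit.baseline)
    main = N_BINS + N_BINS // 2
    in_middle = (peaks >= N_BINS) & (peaks < 2 * N_BINS)
    main_height = y[N_BINS // 2] - fit.baseline
    half_sd_bins = max(int(round(fit.sd_deg / BIN_WIDTH_DEG)), 1)
    for p, h in zip(peaks[in_middle], props["peak_heights"][in_middle]):
        if abs(p - main) <= 2 * half_sd_bins:
            continue  # same lobe as the main peak
        if (h - fit.baseline) > secondary_peak_frac * main_height:
            return AnisotropyCall(False, None)
    return AnisotropyCall(True, fit.center_deg)


def binarize_actin(img: GrayImage, threshold: float | None = None) -> GrayImage:
    """Otsu (or fixed-threshold) binarization; output feeds directionality."""
    data = np.asarray(img.data, dtype=float)
    if np.ptp(data) == 0:
        raise DegenerateImageError("single-valued image cannot be thresholded")
    t = threshold_otsu(data) if threshold is None else threshold
    return GrayImage(data=(data > t).astype(np.uint8), pixel_size_um=img.pixel_size_um)


def average_histograms(
    hists: Sequence[DirectionalityHistogram],
) -> DirectionalityHistogram:
    """Per-bin arithmetic mean of replicate histograms, renormalized."""
    if len(hists) == 0:
        raise ValueError("need at least one histogram")
    edges0 = hists[0].bin_edges_deg
    for h in hists[1:]:
        if not np.array_equal(h.bin_edges_deg, edges0):
            raise ValueError("histograms must share identical binning")
    mean = np.mean([h.amounts for h in hists], axis=0)
    return DirectionalityHistogram(amounts=mean / mean.sum(), bin_edges_deg=edges0)
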