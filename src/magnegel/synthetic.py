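"""Seeded synthetic-micrograph generators with ground truth.

Each generator is a pure function of its ``SceneSpec`` (the seed
included): aligned/isotropic fibrous textures, dark MNP strings on a
bright background, gel images with dark inter-fiber gap bands, and
elongated-cell actin images.  Ground-truth orientation parameters and
gap layouts are returned alongside the rendered image so analysis-module
estimates can be checked for parameter recovery.

Angle convention matches the analysis: 0 degrees is a horizontal
structure (along image width), 90 degrees vertical, increasing
counter-clockwise when the image is displayed row 0 on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage import draw

from .orientation import GrayImage

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "generate_fiber_image",
    "generate_segmented_gel",
    "generate_mnp_string_image",
    "generate_actin_image",
    "generate_noise_image",
    "generate",
]

SceneKind = Literal[
    "aligned_fibers",
    "isotropic_fibers",
    "mnp_strings",
    "segmented_gel",
    "actin_cells",
    "noise",
]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene."""

    kind: SceneKind = "aligned_fibers"
    size: tuple[int, int] = (256, 256)  # rows, cols
    pixel_size_um: float = 1.61
    orientation_mean_deg: float = 90.0
    orientation_spread_deg: float = 5.0
    density: int = 120  # number of fibers / strings
    gap_positions_um: tuple[float, ...] = ()
    gap_widths_um: tuple[float, ...] = ()
    cell_count: int = 50
    cell_aspect_ratio: float = 4.0
    noise_level: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.orientation_spread_deg < 0:
            raise ValueError("orientation spread must be >= 0")
        if any(w <= 0 for w in self.gap_widths_um):
            raise ValueError("gap widths must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually drew."""

    orientation_mean_deg: float | None = None
    orientation_spread_deg: float | None = None
    orientations_deg: tuple[float, ...] = ()
    gap_count: int = 0
    gap_spans_um: tuple[tuple[float, float], ...] = ()
    is_isotropic: bool = False
    blank: bool = False


def _draw_orientations(spec: SceneSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Wrapped-Gaussian (mod 180) or uniform orientation draws, degrees."""
    if spec.kind in ("isotropic_fibers", "noise"):
        return rng.uniform(0.0, 180.0, n)
    return np.mod(
        rng.normal(spec.orientation_mean_deg, spec.orientation_spread_deg, n), 180.0
    )


def _render_lines(
    shape: tuple[int, int],
    centers: np.ndarray,
    angles_deg: np.ndarray,
    lengths: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Accumulate unit-intensity anti-aliased line segments onto a canvas."""
    canvas = np.zeros(shape, dtype=float)
    rows, cols = shape
    for (r0, c0), ang, L in zip(centers, angles_deg, lengths):
        rad = np.radians(ang)
        dc, dr = np.cos(rad), -np.sin(rad)  # row axis points down
        t = np.arange(-L / 2.0, L / 2.0, 0.5)
        rr = r0 + dr * t
        cc = c0 + dc * t
        keep = (rr >= 0) & (rr < rows - 1) & (cc >= 0) & (cc < cols - 1)
        rr, cc = rr[keep], cc[keep]
        if rr.size == 0:
            continue
        fr, fc = np.floor(rr).astype(int), np.floor(cc).astype(int)
        ar, ac = rr - fr, cc - fc
        # bilinear splat
        np.add.at(canvas, (fr, fc), (1 - ar) * (1 - ac))
        np.add.at(canvas, (fr, fc + 1), (1 - ar) * ac)
        np.add.at(canvas, (fr + 1, fc), ar * (1 - ac))
        np.add.at(canvas, (fr + 1, fc + 1), ar * ac)
    return ndimage.gaussian_filter(canvas, sigma=1.0)


def _finalize(canvas: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> GrayImage:
    noisy = canvas + rng.normal(scale=spec.noise_level, size=canvas.shape)
    clipped = np.clip(noisy, 0.0, 1.0)
    return GrayImage(
        data=np.round(clipped * 255).astype(np.uint8),
        pixel_size_um=spec.pixel_size_um,
    )


def generate_fiber_image(spec: SceneSpec) -> tuple[GrayImage, GroundTruth]:
    """Bright fibers on dark background; aligned or isotropic."""
    rng = np.random.default_rng(spec.seed)
    n = spec.density
    rows, cols = spec.size
    blank = n == 0 and spec.noise_level == 0
    orientations = _draw_orientations(spec, n, rng)
    centers = rng.uniform([0, 0], [rows, cols], size=(n, 2))
    lengths = rng.uniform(0.4, 0.9, n) * min(rows, cols)
    canvas = _render_lines((rows, cols), centers, orientations, lengths, rng)
    canvas = np.clip(canvas / 1.5, 0.0, 1.0) * 0.9
    img = _finalize(canvas, spec, rng)
    isotropic = spec.kind == "isotropic_fibers"
    return img, GroundTruth(
        orientation_mean_deg=None if isotropic else spec.orientation_mean_deg,
        orientation_spread_deg=None if isotropic else spec.orientation_spread_deg,
        orientations_deg=tuple(orientations),
        is_isotropic=isotropic,
        blank=blank,
    )


def _merged_gap_spans(
    spec: SceneSpec,
) -> tuple[tuple[tuple[float, float], ...], tuple[tuple[float, float], ...]]:
    """All band spans (µm, merged where overlapping) and the qualifying ones."""
    intervals = sorted(
        (p, p + w) for p, w in zip(spec.gap_positions_um, spec.gap_widths_um)
    )
    merged: list[list[float]] = []
    for lo, hi in intervals:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    all_spans = tuple((lo, hi) for lo, hi in merged)
    qualifying = tuple((lo, hi) for lo, hi in merged if hi - lo >= 15.0)
    return all_spans, qualifying


def generate_segmented_gel(spec: SceneSpec) -> tuple[GrayImage, GroundTruth]:
    """Bright fibrous background crossed by dark vertical gap bands.

    Bands are parallel to the field axis (vertical in the image) so they
    intersect the half-height transect; ground truth counts only merged
    bands of physical width >= 15 µm.
    """
    rows, cols = spec.size
    width_um = cols * spec.pixel_size_um
    if any(p + w > width_um or p < 0 for p, w in zip(spec.gap_positions_um, spec.gap_widths_um)):
        raise ValueError("gap layout does not fit in the image width")
    rng = np.random.default_rng(spec.seed)
    n = spec.density
    orientations = _draw_orientations(spec, n, rng)
    centers = rng.uniform([0, 0], [rows, cols], size=(n, 2))
    lengths = rng.uniform(0.5, 1.0, n) * rows
    texture = _render_lines((rows, cols), centers, orientations, lengths, rng)
    canvas = 0.55 + 0.4 * np.clip(texture / 2.0, 0.0, 1.0)

    all_spans, qualifying = _merged_gap_spans(spec)
    for lo, hi in all_spans:
        c0 = int(round(lo / spec.pixel_size_um))
        c1 = int(round(hi / spec.pixel_size_um))
        canvas[:, c0:c1] *= 0.02
    img = _finalize(canvas, spec, rng)
    return img, GroundTruth(
        orientation_mean_deg=spec.orientation_mean_deg,
        orientation_spread_deg=spec.orientation_spread_deg,
        gap_count=len(qualifying),
        gap_spans_um=qualifying,
    )


def generate_mnp_string_image(spec: SceneSpec) -> tuple[GrayImage, GroundTruth]:
    """Dark elongated MNP strings on a bright light-microscopy background."""
    rng = np.random.default_rng(spec.seed)
    n = spec.density
    rows, cols = spec.size
    orientations = _draw_orientations(spec, n, rng)
    centers = rng.uniform([0, 0], [rows, cols], size=(n, 2))
    lengths = rng.uniform(0.15, 0.5, n) * min(rows, cols)
    strings = _render_lines((rows, cols), centers, orientations, lengths, rng)
    canvas = 0.9 - 0.8 * np.clip(strings / 1.2, 0.0, 1.0)
    img = _finalize(canvas, spec, rng)
    return img, GroundTruth(
        orientation_mean_deg=spec.orientation_mean_deg,
        orientation_spread_deg=spec.orientation_spread_deg,
        orientations_deg=tuple(orientations),
    )


def generate_actin_image(spec: SceneSpec) -> tuple[GrayImage, GroundTruth]:
    """Elongated ellipse cells at orientations from the spec distribution.

    Aspect ratio 1 carries no orientation information; the ground truth
    flags such scenes as isotropic-like (``blank`` orientation content).
    """
    if spec.cell_count < 1:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.size
    n = spec.cell_count
    orientations = _draw_orientations(spec, n, rng)
    canvas = np.zeros((rows, cols), dtype=float)
    minor = max(2.0, min(rows, cols) / 40.0)
    major = minor * spec.cell_aspect_ratio
    for i in range(n):
        r0 = rng.uniform(0, rows)
        c0 = rng.uniform(0, cols)
        # positive skimage rotation matches the row-up angle convention here
        rr, cc = draw.ellipse(
            r0, c0, minor, major, shape=(rows, cols),
            rotation=np.radians(orientations[i]),
        )
        canvas[rr, cc] = np.maximum(canvas[rr, cc], rng.uniform(0.6, 0.95))
    canvas = ndimage.gaussian_filter(canvas, sigma=0.8)
    img = _finalize(canvas, spec, rng)
    no_orientation_info = spec.cell_aspect_ratio <= 1.0
    uniform = spec.kind in ("isotropic_fibers", "noise")
    return img, GroundTruth(
        orientation_mean_deg=None if (uniform or no_orientation_info) else spec.orientation_mean_deg,
        orientation_spread_deg=None if (uniform or no_orientation_info) else spec.orientation_spread_deg,
        orientations_deg=tuple(orientations),
        is_isotropic=uniform or no_orientation_info,
    )


def generate_noise_image(spec: SceneSpec) -> tuple[GrayImage, GroundTruth]:
    """Pure white-noise scene (isotropic by construction)."""
    rng = np.random.default_rng(spec.seed)
    data = rng.random(spec.size)
    img = GrayImage(
        data=np.round(data * 255).astype(np.uint8),
        pixel_size_um=spec.pixel_size_um,
    )
    return img, GroundTruth(is_isotropic=True)


_DISPATCH = {
    "aligned_fibers": generate_fiber_image,
    "isotropic_fibers": generate_fiber_image,
    "mnp_strings": generate_mnp_string_image,
    "segmented_gel": generate_segmented_gel,
    "actin_cells": generate_actin_image,
    "noise": generate_noise_image,
}


def generate(spec: SceneSpec) -> tuple[GrayImage, GroundTruth]:
    """Dispatch on ``spec.kind``."""
    try:
        fn = _DISPATCH[spec.kind]
    except KeyError:
        raise ValueError(f"unknown scene kind: {spec.kind!r}") from None
    return fn(spec)
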