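"""Run-length gap statistic along a half-height intensity transect.

A qualifying gap is a maximal run of consecutive non-excluded transect
pixels whose gray value is strictly below 25% of the transect maximum and
whose physical length is at least 15 µm.  Excluded pixels participate in
neither the maximum nor any run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ProfileTransect",
    "SegmentationResult",
    "extract_transect",
    "count_segments",
    "apply_exclusion",
    "average_counts",
]


@dataclass(frozen=True)
class ProfileTransect:
    """Gray values along the image width at half height."""

    values: np.ndarray
    pixel_size_um: float
    excluded: np.ndarray | None = None  # bool mask, True = disregarded

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("transect needs at least 2 ordered values")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        ex = (
            np.zeros(v.size, dtype=bool)
            if self.excluded is None
            else np.asarray(self.excluded, dtype=bool)
        )
        if ex.shape != v.shape:
            raise ValueError("exclusion mask must match transect length")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "excluded", ex)


@dataclass(frozen=True)
class SegmentationResult:
    """Qualifying gaps found on one transect."""

    gap_count: int
    gap_spans_um: tuple[tuple[float, float], ...]
    threshold_value: float
    excluded_positions: int


def extract_transect(image: np.ndarray, pixel_size_um: float) -> ProfileTransect:
    """Single pixel row at floor(height/2), carrying the pixel size."""
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("image must be 2-D with height >= 2")
    row = arr.shape[0] // 2
    return ProfileTransect(values=arr[row].astype(float), pixel_size_um=pixel_size_um)


def apply_exclusion(
    transect: ProfileTransect, ranges: Sequence[tuple[int, int]]
) -> ProfileTransect:
    """Mark half-open pixel ranges [start, stop) as disregarded."""
    mask = transect.excluded.copy()
    n = transect.values.size
    for start, stop in ranges:
        if start < 0 or stop > n or start >= stop:
            raise ValueError(f"exclusion range ({start}, {stop}) out of bounds")
        mask[start:stop] = True
    return replace(transect, excluded=mask)


def count_segments(
    transect: ProfileTransect,
    threshold_frac: float = 0.25,
    min_len_um: float = 15.0,
    count_edge_runs: bool = True,
) -> SegmentationResult:
    """Count qualifying low-intensity gaps on the transect.

    Threshold = ``threshold_frac`` x max over non-excluded pixels; runs are
    maximal stretches of non-excluded pixels strictly below threshold;
    a run qualifies if run_pixels x pixel_size >= ``min_len_um``.
    """
    values = transect.values
    excluded = transect.excluded
    active = ~excluded
    if not np.any(active):
        raise ValueError("all transect positions are excluded")
    threshold = threshold_frac * float(values[active].max())
    below = (values < threshold) & active

    spans: list[tuple[float, float]] = []
    n = values.size
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            length_um = (j - i) * transect.pixel_size_um
            touches_edge = i == 0 or j == n
            if length_um >= min_len_um and (count_edge_runs or not touches_edge):
                spans.append(
                    (i * transect.pixel_size_um, j * transect.pixel_size_um)
                )
            i = j
        else:
            i += 1
    return SegmentationResult(
        gap_count=len(spans),
        gap_spans_um=tuple(spans),
        threshold_value=threshold,
        excluded_positions=int(excluded.sum()),
    )


def average_counts(results: Sequence[SegmentationResult]) -> tuple[float, float]:
    """Mean and standard deviation of gap counts over replicate images."""
    if len(results) == 0:
        raise ValueError("need at least one result")
    counts = np.array([r.gap_count for r in results], dtype=float)
    return float(counts.mean()), float(counts.std())
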