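"""Image and table I/O helpers.

TIFF files are read/written with ``tifffile`` (pixel size from/to
resolution tags); PNG via ``imageio``.  Histograms and trajectories go to
plain CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .orientation import DirectionalityHistogram, GrayImage


def read_image(path: str | Path, pixel_size_um: float | None = None) -> GrayImage:
    """Read a grayscale TIFF/PNG; TIFF resolution tags set the pixel size.

    An explicit ``pixel_size_um`` always wins; otherwise TIFFs fall back
    to their XResolution tag and other formats to 1 µm/px.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            data = page.asarray()
            if pixel_size_um is None:
                tag = page.tags.get("XResolution")
                unit = page.tags.get("ResolutionUnit")
                if tag is not None:
                    num, den = tag.value
                    if num > 0:
                        per_unit = num / den  # pixels per unit
                        scale = {2: 25400.0, 3: 10000.0}.get(
                            getattr(unit, "value", 3) if unit is None else unit.value, 10000.0
                        )
                        pixel_size_um = scale / per_unit
    else:
        data = iio.imread(path)
    if data.ndim == 3:
        data = data.mean(axis=-1)
    return GrayImage(data=np.asarray(data), pixel_size_um=pixel_size_um or 1.0)


def write_image(path: str | Path, img: GrayImage) -> None:
    """Write TIFF (with pixel-size tags, centimeter unit) or PNG."""
    path = Path(path)
    data = np.asarray(img.data)
    if path.suffix.lower() in (".tif", ".tiff"):
        px_per_cm = 10000.0 / img.pixel_size_um
        tifffile.imwrite(
            path,
            data,
            resolution=(px_per_cm, px_per_cm),
            resolutionunit="CENTIMETER",
        )
    else:
        iio.imwrite(path, data.astype(np.uint8))


def write_histogram_csv(path: str | Path, hist: DirectionalityHistogram) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bin_start_deg", "bin_end_deg", "amount"])
        for lo, hi, amount in zip(
            hist.bin_edges_deg[:-1], hist.bin_edges_deg[1:], hist.amounts
        ):
            writer.writerow([f"{lo:g}", f"{hi:g}", repr(float(amount))])


def read_histogram_csv(path: str | Path) -> DirectionalityHistogram:
    starts, ends, amounts = [], [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            starts.append(float(row["bin_start_deg"]))
            ends.append(float(row["bin_end_deg"]))
            amounts.append(float(row["amount"]))
    edges = np.array(starts + [ends[-1]])
    return DirectionalityHistogram(amounts=np.array(amounts), bin_edges_deg=edges)


def write_trajectories_csv(path: str | Path, positions: np.ndarray, dt: float) -> None:
    """positions: (n_steps+1, n_particles, 3)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["particle", "t", "x", "y", "z"])
        n_steps, n_particles, _ = positions.shape
        for p in range(n_particles):
            for s in range(n_steps):
                x, y, z = positions[s, p]
                writer.writerow([p, f"{s * dt:.4f}", repr(x), repr(y), repr(z)])


def write_fieldmap_csv(path: str | Path, grid: np.ndarray) -> None:
    """grid: (N, 7) of x, y, z, Bx, By, Bz, |B|."""
    header = ["x", "y", "z", "Bx", "By", "Bz", "B_mag"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for row in grid:
            writer.writerow([repr(float(v)) for v in row])
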