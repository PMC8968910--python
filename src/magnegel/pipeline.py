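"""Experiment orchestration: simulate, generate, analyze, report.

An :class:`ExperimentConfig` (usually loaded from YAML) describes the
magnet device, the particle-tracing run, and a list of synthetic image
groups (e.g. an MNP dose series mapped to gap frequencies).  The single
global seed propagates deterministically to every stage, so a rerun with
the same config produces a byte-identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import write_fieldmap_csv, write_histogram_csv, write_trajectories_csv
from .magnetics import (
    MagnetDevice,
    calibrate_device,
    default_device,
    device_field,
    fieldmap_grid,
    sample_region_gradient_stats,
)
from .magnetophoresis import (
    FluidSpec,
    ParticleSpec,
    SimConfig,
    motion_directionality,
    run_simulation,
)
from .orientation import (
    average_histograms,
    classify_anisotropy,
    fit_gaussian,
    fourier_directionality,
)
from .segmentation import average_counts, count_segments, extract_transect
from .synthetic import SceneSpec, generate

logger = logging.getLogger("magnegel")

__all__ = [
    "ExperimentConfig",
    "GroupConfig",
    "load_experiment_config",
    "run_experiment",
    "validate_report",
    "random_gap_layout",
    "build_device",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class DeviceConfig:
    face_length_mm: float = 40.0
    face_width_mm: float = 20.0
    depth_mm: float = 10.0
    gap_mm: float = 7.2
    remanence_T: float = 1.31
    calibration_target_mT: float | None = 52.3


@dataclass(frozen=True)
class GroupConfig:
    """One experimental group: replicate synthetic scenes + analyses."""

    name: str
    scene: SceneSpec
    n_images: int = 3
    n_gaps: int | None = None  # segmented_gel dose knob; random layout per image


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int = 0
    output_dir: str = "magnegel_out"
    device: DeviceConfig = field(default_factory=DeviceConfig)
    simulation: SimConfig | None = field(default_factory=SimConfig)
    groups: tuple[GroupConfig, ...] = ()


def build_device(cfg: DeviceConfig) -> MagnetDevice:
    """Construct and (optionally) calibrate the device from its config."""
    dev = default_device(
        face_length=cfg.face_length_mm * 1e-3,
        face_width=cfg.face_width_mm * 1e-3,
        depth=cfg.depth_mm * 1e-3,
        gap=cfg.gap_mm * 1e-3,
        remanence=cfg.remanence_T,
    )
    if cfg.calibration_target_mT is not None:
        dev = calibrate_device(dev, cfg.calibration_target_mT * 1e-3)
    return dev


def random_gap_layout(
    n_gaps: int,
    width_um: float,
    rng: np.random.Generator,
    min_width_um: float = 16.0,
    max_width_um: float = 40.0,
    margin_um: float = 5.0,
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Non-overlapping qualifying gap bands placed uniformly in the width."""
    positions: list[float] = []
    widths: list[float] = []
    attempts = 0
    while len(positions) < n_gaps and attempts < 1000 * max(n_gaps, 1):
        attempts += 1
        w = rng.uniform(min_width_um, max_width_um)
        p = rng.uniform(0.0, width_um - w)
        if all(
            p + w + margin_um < q or q + wq + margin_um < p
            for q, wq in zip(positions, widths)
        ):
            positions.append(p)
            widths.append(w)
    if len(positions) < n_gaps:
        raise StageError(f"generation: could not place {n_gaps} gaps in {width_um} µm")
    order = np.argsort(positions)
    return (
        tuple(positions[i] for i in order),
        tuple(widths[i] for i in order),
    )


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    """Parse the experiment YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    dev = DeviceConfig(**raw.get("device", {}))
    sim_raw = raw.get("simulation")
    sim = SimConfig(**sim_raw) if sim_raw is not None else None
    groups = []
    for g in raw.get("groups", []):
        scene = SceneSpec(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in g.get("scene", {}).items()
        })
        groups.append(
            GroupConfig(
                name=g["name"],
                scene=scene,
                n_images=g.get("n_images", 3),
                n_gaps=g.get("n_gaps"),
            )
        )
    return ExperimentConfig(
        seed=raw.get("seed", 0),
        output_dir=raw.get("output_dir", "magnegel_out"),
        device=dev,
        simulation=sim,
        groups=tuple(groups),
    )


def _analyze_group(
    group: GroupConfig, seed: int, out_dir: Path
) -> dict:
    """Generate replicates, run directionality + segmentation analyses."""
    hists = []
    seg_results = []
    rng = np.random.default_rng(seed)
    for i in range(group.n_images):
        scene = replace(group.scene, seed=seed + i)
        if group.scene.kind == "segmented_gel" and group.n_gaps is not None:
            width_um = scene.size[1] * scene.pixel_size_um
            pos, wid = random_gap_layout(group.n_gaps, width_um, rng)
            scene = replace(scene, gap_positions_um=pos, gap_widths_um=wid)
        img, truth = generate(scene)
        hist = fourier_directionality(img, on_degenerate="uniform")
        hists.append(hist)
        if scene.kind == "segmented_gel":
            transect = extract_transect(np.asarray(img.data), scene.pixel_size_um)
            seg_results.append(count_segments(transect))
    mean_hist = average_histograms(hists)
    fit = fit_gaussian(mean_hist)
    call = classify_anisotropy(fit, mean_hist)
    write_histogram_csv(out_dir / f"{group.name}_hist.csv", mean_hist)
    out = {
        "name": group.name,
        "n_images": group.n_images,
        "fitted_peak_deg": fit.center_deg,
        "fitted_sd_deg": fit.sd_deg,
        "fit_r_squared": fit.r_squared,
        "is_anisotropic": call.is_anisotropic,
    }
    if seg_results:
        mean_count, sd_count = average_counts(seg_results)
        out["mean_gap_count"] = mean_count
        out["sd_gap_count"] = sd_count
        out["gap_counts"] = [r.gap_count for r in seg_results]
    return out


def run_experiment(cfg: ExperimentConfig, write_trajectories: bool = False) -> dict:
    """Run every configured stage and write the JSON report.

    Returns the report dict; artifacts land in ``cfg.output_dir``.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "versions": {"magnegel": __version__}}

    try:
        device = build_device(cfg.device)
        mid_B = float(np.linalg.norm(device_field(device, device.midpoint).B))
        grad_stats = sample_region_gradient_stats(device, n=7)
        report["device"] = {
            "midpoint_B_mT": mid_B * 1e3,
            "calibration_target_mT": cfg.device.calibration_target_mT,
            "mean_grad_B_T_per_m": grad_stats["mean_grad_B_T_per_m"],
        }
        write_fieldmap_csv(out_dir / "fieldmap.csv", fieldmap_grid(device, n=9))
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"magnetics: {exc}") from exc

    if cfg.simulation is not None:
        try:
            sim = replace(cfg.simulation, rng_seed=cfg.seed)
            traj = run_simulation(device, sim, ParticleSpec(), FluidSpec())
            md = motion_directionality(traj)
            report["simulation"] = {
                "median_angle_deg": md.median_deg,
                "mode_bin_deg": list(md.mode_bin_deg),
                "n_particles": sim.n_particles,
                "n_excluded": md.n_excluded,
            }
            np.savetxt(
                out_dir / "angles.csv",
                md.angles_deg,
                header="angle_deg",
                comments="",
            )
            if write_trajectories:
                write_trajectories_csv(out_dir / "trajectories.csv", traj.positions, sim.dt)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"simulation: {exc}") from exc

    groups = []
    for k, group in enumerate(cfg.groups):
        try:
            groups.append(_analyze_group(group, seed=cfg.seed + 1000 * (k + 1), out_dir=out_dir))
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"group {group.name}: {exc}") from exc
    report["groups"] = groups

    validate_report(report)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("experiment complete: %s", out_dir / "report.json")
    return report


# -- minimal JSON-schema subset validation (type/properties/required/items) --

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "integer": int,
    "number": (int, float),
}


def _check(instance, schema, path: str) -> None:
    expected = schema.get("type")
    if expected is not None:
        pytype = _TYPES[expected]
        if expected == "integer" and isinstance(instance, bool):
            raise ValueError(f"{path}: bool is not integer")
        if instance is not None and not isinstance(instance, pytype):
            raise ValueError(f"{path}: expected {expected}, got {type(instance).__name__}")
    if expected == "object" and isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                _check(instance[key], sub, f"{path}.{key}")
    if expected == "array" and isinstance(instance, list):
        item_schema = schema.get("items")
        if item_schema:
            for i, item in enumerate(instance):
                _check(item, item_schema, f"{path}[{i}]")


def validate_report(report: dict) -> None:
    """Validate the report against the bundled JSON schema (subset)."""
    schema = json.loads(
        resources.files("magnegel").joinpath("schemas/report_schema.json").read_text()
    )
    _check(report, schema, "$")
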