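"""Overdamped magnetophoretic particle tracing between two magnets.

Particles feel a force proportional to the gradient of the squared field,

    F = 2 pi r_p^3 mu0 mu_f * (mu_p - mu_f) / (mu_p + 2 mu_f) * grad(|H|^2),

and drift at the Stokes terminal velocity F / (6 pi eta r_p).  Trajectories
are integrated with explicit Euler inside a reflective cubic well; the
net-motion angle of each particle is reported in degrees from the axis
orthogonal to the applied field (field axis maps to 90 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .constants import K_BOLTZMANN, MU0
from .magnetics import MagnetDevice, grad_H2

__all__ = [
    "ParticleSpec",
    "FluidSpec",
    "SimConfig",
    "TrajectorySet",
    "MotionDirectionality",
    "magnetophoretic_force",
    "drift_velocity",
    "initialize_ensemble",
    "run_simulation",
    "motion_directionality",
]


@dataclass(frozen=True)
class ParticleSpec:
    """Magnetic nanoparticle physical parameters (defaults: 250 nm MNP)."""

    radius: float = 125e-9
    susceptibility: float = 6.27
    density: float = 5240.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if 1.0 + self.susceptibility <= 0:
            raise ValueError("relative permeability must be positive")

    @property
    def rel_permeability(self) -> float:
        return 1.0 + self.susceptibility


@dataclass(frozen=True)
class FluidSpec:
    """Carrier fluid parameters (defaults: water)."""

    susceptibility: float = 0.0
    viscosity: float = 1.0e-3
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")

    @property
    def rel_permeability(self) -> float:
        return 1.0 + self.susceptibility


@dataclass(frozen=True)
class SimConfig:
    """Integration settings for one particle-tracing run."""

    dt: float = 0.01
    t_end: float = 0.1
    n_particles: int = 1000
    rng_seed: int = 0
    droplet_volume: float = 1e-7  # m^3 (100 µl)
    well_half: float = 3.5e-3  # cubic well half-side, m; cube fits the magnet gap
    well_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    brownian: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_end < self.dt:
            raise ValueError("t_end must be >= dt")
        if self.n_particles < 1:
            raise ValueError("need at least one particle")

    @property
    def droplet_radius(self) -> float:
        return (3.0 * self.droplet_volume / (4.0 * np.pi)) ** (1.0 / 3.0)

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


@dataclass(frozen=True)
class TrajectorySet:
    """Positions (n_steps+1, n_particles, 3) of every traced particle."""

    positions: np.ndarray
    dt: float

    @property
    def start(self) -> np.ndarray:
        return self.positions[0]

    @property
    def end(self) -> np.ndarray:
        return self.positions[-1]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]


@dataclass(frozen=True)
class MotionDirectionality:
    """Net-motion angle statistics over an ensemble."""

    angles_deg: np.ndarray
    bin_edges_deg: np.ndarray
    counts: np.ndarray
    median_deg: float
    mode_bin_deg: tuple[float, float]
    n_excluded: int


def magnetophoretic_force(
    particle: ParticleSpec, fluid: FluidSpec, gradH2: np.ndarray
) -> np.ndarray:
    """Magnetophoretic force (N) for a given grad(|H|^2) (A^2/m^3).

    Vectorized over trailing-axis-3 arrays of gradients.
    """
    g = np.asarray(gradH2, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("gradH2 must be finite")
    mu_p = particle.rel_permeability
    mu_f = fluid.rel_permeability
    denom = mu_p + 2.0 * mu_f
    if denom == 0:
        raise ValueError("nonphysical permeabilities: mu_p + 2 mu_f = 0")
    cm = (mu_p - mu_f) / denom
    return 2.0 * np.pi * particle.radius**3 * MU0 * mu_f * cm * g


def drift_velocity(
    force: np.ndarray, particle: ParticleSpec, fluid: FluidSpec
) -> np.ndarray:
    """Stokes terminal velocity v = F / (6 pi eta r_p), m/s."""
    return np.asarray(force, dtype=float) / (
        6.0 * np.pi * fluid.viscosity * particle.radius
    )


def initialize_ensemble(cfg: SimConfig) -> np.ndarray:
    """Uniform positions inside the central droplet sphere, (n, 3) in m.

    Deterministic for a fixed ``cfg.rng_seed``.
    """
    r_drop = cfg.droplet_radius
    if r_drop > cfg.well_half:
        raise ValueError("droplet does not fit inside the well")
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_particles
    # rejection-free: direction x radius with cube-root law
    directions = rng.normal(size=(n, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = r_drop * rng.random(n) ** (1.0 / 3.0)
    return np.asarray(cfg.well_center) + directions * radii[:, None]


def _reflect(pos: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Mirror positions back into the box [lo, hi] per axis.

    In-bounds coordinates are returned bitwise unchanged; per-step
    displacements are far smaller than the box, so a few passes suffice.
    """
    p = pos
    for _ in range(100):
        out_lo = p < lo
        out_hi = p > hi
        if not (np.any(out_lo) or np.any(out_hi)):
            break
        p = np.where(out_lo, 2 * lo - p, p)
        p = np.where(out_hi, 2 * hi - p, p)
    return np.clip(p, lo, hi)


def run_simulation(
    device: MagnetDevice,
    cfg: SimConfig,
    particle: ParticleSpec | None = None,
    fluid: FluidSpec | None = None,
    velocity_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    positions0: np.ndarray | None = None,
) -> TrajectorySet:
    """Trace the ensemble with explicit Euler and reflective walls.

    ``velocity_fn`` overrides the physical drift (test harness hook);
    otherwise v(x) = F(grad|H|^2(x)) / (6 pi eta r_p).
    """
    particle = particle or ParticleSpec()
    fluid = fluid or FluidSpec()
    pos = initialize_ensemble(cfg) if positions0 is None else np.array(positions0, float)
    lo = np.asarray(cfg.well_center) - cfg.well_half
    hi = np.asarray(cfg.well_center) + cfg.well_half
    if np.any(pos < lo) or np.any(pos > hi):
        raise ValueError("particle initialized outside the well")

    if velocity_fn is None:

        def velocity_fn(x: np.ndarray) -> np.ndarray:
            g = grad_H2(device, x)
            return drift_velocity(magnetophoretic_force(particle, fluid, g), particle, fluid)

    rng = np.random.default_rng(cfg.rng_seed + 1)
    diff_coef = K_BOLTZMANN * fluid.temperature / (
        6.0 * np.pi * fluid.viscosity * particle.radius
    )
    n_steps = cfg.n_steps
    out = np.empty((n_steps + 1, cfg.n_particles, 3))
    out[0] = pos
    for step in range(1, n_steps + 1):
        v = velocity_fn(pos)
        pos = pos + v * cfg.dt
        if cfg.brownian:
            pos = pos + rng.normal(
                scale=np.sqrt(2.0 * diff_coef * cfg.dt), size=pos.shape
            )
        pos = _reflect(pos, lo, hi)
        out[step] = pos
    return TrajectorySet(positions=out, dt=cfg.dt)


def motion_directionality(
    traj: TrajectorySet,
    bin_width_deg: float = 0.5,
    field_axis: int = 0,
    orthogonal_axis: int = 1,
) -> MotionDirectionality:
    """Net-motion angles from the orthogonal axis, folded to [0, 180).

    The field axis maps to 90 degrees; the in-plane orthogonal axis to 0.
    Particles with zero net displacement are excluded and counted.
    """
    disp = traj.end - traj.start
    d_field = disp[:, field_axis]
    d_orth = disp[:, orthogonal_axis]
    nonzero = (d_field != 0.0) | (d_orth != 0.0)
    n_excluded = int(np.sum(~nonzero))
    if not np.any(nonzero):
        raise ValueError("degenerate run: every particle has zero net displacement")
    theta = np.degrees(np.arctan2(d_field[nonzero], d_orth[nonzero])) % 180.0
    edges = np.arange(0.0, 180.0 + bin_width_deg, bin_width_deg)
    counts, _ = np.histogram(theta, bins=edges)
    mode_idx = int(np.argmax(counts))
    return MotionDirectionality(
        angles_deg=theta,
        bin_edges_deg=edges,
        counts=counts,
        median_deg=float(np.median(theta)),
        mode_bin_deg=(float(edges[mode_idx]), float(edges[mode_idx + 1])),
        n_excluded=n_excluded,
    )
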