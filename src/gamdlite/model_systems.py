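"""Analytic toy potentials and a Langevin integrator.

The potentials stand in for all-atom force fields: each surface is
decomposed into a "core" term and a periodic "dihedral-like" term so that
dual-boost accelerated sampling has two distinct energy channels to act
on, exactly as in production MD engines.  Full system energy is always
``core + dihedral``.

A BAOAB-splitting Langevin integrator generates canonical (and, through a
boost callback, accelerated) trajectories whose long-run histograms
converge to the Boltzmann distribution of the simulated potential.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import KB, FORCE_TO_ACC

__all__ = [
    "PotentialSurface",
    "LangevinSpec",
    "ToyTrajectory",
    "DomainError",
    "IntegrationFailure",
    "OracleUnavailable",
    "double_well",
    "harmonic_well",
    "dual_term_surface",
    "flat_surface",
    "surface_from_config",
    "evaluate_energy",
    "evaluate_force",
    "run_langevin",
    "analytic_pmf",
    "binned_reference_pmf",
]


class DomainError(ValueError):
    """Coordinate outside the declared domain of a potential surface."""


class IntegrationFailure(RuntimeError):
    """Numerical blow-up during Langevin integration."""


class OracleUnavailable(ValueError):
    """No closed-form / quadrature PMF is available for this surface."""


@dataclass(frozen=True)
class PotentialSurface:
    """Analytic energy function split into core + dihedral-like terms.

    ``energy_core`` / ``energy_dihedral`` map a coordinate sequence to
    kcal/mol; the companion ``force_*`` callables return the negative
    gradient per coordinate.  ``dihedral_period`` declares the period of
    the dihedral term along ``dihedral_axis`` (None if the term is
    identically zero).
    """

    dimension: int
    energy_core: Callable[[Sequence[float]], float]
    force_core: Callable[[Sequence[float]], Sequence[float]]
    energy_dihedral: Callable[[Sequence[float]], float] = lambda x: 0.0
    force_dihedral: Callable[[Sequence[float]], Sequence[float]] = None  # type: ignore
    parameters: dict = field(default_factory=dict)
    domain: tuple = ((-math.inf, math.inf),)
    dihedral_period: Optional[float] = None
    dihedral_axis: int = 0
    kind: str = "custom"

    def __post_init__(self):
        if self.force_dihedral is None:
            object.__setattr__(
                self, "force_dihedral", lambda x: [0.0] * self.dimension
            )
        if len(self.domain) != self.dimension:
            object.__setattr__(self, "domain", tuple(self.domain) * self.dimension)

    def in_domain(self, x: Sequence[float]) -> bool:
        return all(lo <= xi <= hi for xi, (lo, hi) in zip(x, self.domain))


@dataclass(frozen=True)
class LangevinSpec:
    """Parameters of a Langevin run (BAOAB splitting).

    friction is the collision rate in 1/ps, mass an effective mass in amu
    shared by every degree of freedom; x0 the starting coordinates.
    """

    temperature: float  # K
    friction: float  # 1/ps
    timestep: float  # ps
    n_steps: int
    seed: int
    mass: float = 12.0
    x0: tuple = (0.0,)
    stride: int = 1

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class ToyTrajectory:
    """Recorded frames of one simulation stage.

    ``boosts`` holds per-frame (dV_total, dV_dihedral) for boosted stages
    and is None for plain cMD.
    """

    frames: np.ndarray  # (n, d)
    energies_total: np.ndarray  # full potential energy per frame
    energies_dihedral: np.ndarray
    spec: LangevinSpec
    stage_label: str = "cMD"
    boosts: Optional[np.ndarray] = None  # (n, 2): dv_total, dv_dihedral

    def __post_init__(self):
        n = len(self.frames)
        if not (len(self.energies_total) == len(self.energies_dihedral) == n):
            raise ValueError("per-frame arrays must have equal length")
        if self.stage_label == "cMD" and self.boosts is not None:
            raise ValueError("cMD stage carries no boosts")
        if self.stage_label != "cMD" and self.boosts is None:
            raise ValueError(f"stage {self.stage_label!r} requires boosts")
        if self.boosts is not None and len(self.boosts) != n:
            raise ValueError("boosts must match frame count")

    def __len__(self):
        return len(self.frames)

    @property
    def dv_sum(self) -> np.ndarray:
        """Total boost per frame (sum over boosted terms); zeros for cMD."""
        if self.boosts is None:
            return np.zeros(len(self))
        return self.boosts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        d = self.frames.shape[1]
        data = {"frame": np.arange(len(self))}
        for j in range(d):
            data[f"x{j}"] = self.frames[:, j]
        data["V_total"] = self.energies_total
        data["V_dihedral"] = self.energies_dihedral
        if self.boosts is not None:
            data["dV_total"] = self.boosts[:, 0]
            data["dV_dihedral"] = self.boosts[:, 1]
        else:
            data["dV_total"] = 0.0
            data["dV_dihedral"] = 0.0
        return pd.DataFrame(data)

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    def to_xyz(self, path, element: str = "C"):
        """Multi-frame XYZ for visualization; 1D/2D coords padded to 3D."""
        with open(path, "w") as fh:
            for i, x in enumerate(self.frames):
                xyz = list(x) + [0.0] * (3 - len(x))
                fh.write(f"1\nframe {i}\n{element} "
                         f"{xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


# ---------------------------------------------------------------------------
# surface factories

def double_well(barrier: float = 5.0, a: float = 2.0) -> PotentialSurface:
    """Symmetric quartic double well w(x) = barrier ((x/a)^2 - 1)^2.

    Minima at x = ±a with w = 0; barrier at x = 0 with w = barrier.
    """
    if barrier <= 0 or a <= 0:
        raise ValueError("barrier and a must be positive")
    h, a2 = float(barrier), float(a) ** 2

    def energy(x):
        u = x[0] * x[0] / a2 - 1.0
        return h * u * u

    def force(x):
        u = x[0] * x[0] / a2 - 1.0
        return [-4.0 * h * u * x[0] / a2]

    return PotentialSurface(
        dimension=1, energy_core=energy, force_core=force,
        parameters={"barrier": h, "a": float(a)},
        domain=((-10.0 * a, 10.0 * a),), kind="double_well",
    )


def harmonic_well(kappa: float = 1.0, x0: float = 0.0) -> PotentialSurface:
    """Harmonic well V = kappa/2 (x - x0)^2 (kcal/mol/Å² force constant)."""
    k, c = float(kappa), float(x0)
    return PotentialSurface(
        dimension=1,
        energy_core=lambda x: 0.5 * k * (x[0] - c) ** 2,
        force_core=lambda x: [-k * (x[0] - c)],
        parameters={"kappa": k, "x0": c},
        kind="harmonic",
    )


def flat_surface() -> PotentialSurface:
    """Degenerate flat potential; boosting on it must be refused."""
    return PotentialSurface(
        dimension=1,
        energy_core=lambda x: 0.0,
        force_core=lambda x: [0.0],
        domain=((-50.0, 50.0),),
        kind="flat",
    )


def dual_term_surface(
    barrier: float = 5.0,
    a: float = 2.0,
    dihedral_amp: float = 2.0,
    periodicity: int = 3,
) -> PotentialSurface:
    """2D surface: double well in x plus a cosine 'dihedral' term in θ.

    V(x, θ) = barrier((x/a)² − 1)² + dihedral_amp (1 + cos(n θ)) / 2.
    Both terms are nonzero so dual boosting is nontrivial; θ is periodic
    with period 2π/n declared on axis 1.
    """
    dw = double_well(barrier, a)
    amp, n = float(dihedral_amp), int(periodicity)

    def e_dih(x):
        return 0.5 * amp * (1.0 + math.cos(n * x[1]))

    def f_dih(x):
        return [0.0, 0.5 * amp * n * math.sin(n * x[1])]

    return PotentialSurface(
        dimension=2,
        energy_core=lambda x: dw.energy_core(x),
        force_core=lambda x: [dw.force_core(x)[0], 0.0],
        energy_dihedral=e_dih,
        force_dihedral=f_dih,
        parameters={"barrier": float(barrier), "a": float(a),
                    "dihedral_amp": amp, "periodicity": n},
        domain=((-10.0 * a, 10.0 * a), (-math.inf, math.inf)),
        dihedral_period=2.0 * math.pi / n,
        dihedral_axis=1,
        kind="dual_term",
    )


_SURFACE_REGISTRY = {
    "double_well": double_well,
    "harmonic": harmonic_well,
    "dual_term": dual_term_surface,
    "flat": flat_surface,
}


def surface_from_config(config: dict) -> PotentialSurface:
    """Build a surface from a JSON-style dict: {"kind": ..., <params>}."""
    cfg = dict(config)
    kind = cfg.pop("kind")
    try:
        factory = _SURFACE_REGISTRY[kind]
    except KeyError:
        raise ValueError(f"unknown surface kind {kind!r}") from None
    return factory(**cfg)


# ---------------------------------------------------------------------------
# energy / force evaluation

def evaluate_energy(surface: PotentialSurface, x: Sequence[float]):
    """Return (total, dihedral) energy in kcal/mol at coordinates x."""
    x = tuple(x)
    if len(x) != surface.dimension:
        raise DomainError(f"expected {surface.dimension} coordinates, got {len(x)}")
    if not surface.in_domain(x):
        raise DomainError(f"coordinate {x} outside domain {surface.domain}")
    dih = surface.energy_dihedral(x)
    total = surface.energy_core(x) + dih
    if not (math.isfinite(total) and math.isfinite(dih)):
        raise DomainError(f"non-finite energy at {x}")
    return total, dih


def evaluate_force(surface: PotentialSurface, x: Sequence[float]):
    """Return (force_total, force_dihedral): negative gradients per term.

    force_total is the force of the full potential (core + dihedral).
    """
    x = tuple(x)
    fc = surface.force_core(x)
    fd = surface.force_dihedral(x)
    return [a + b for a, b in zip(fc, fd)], list(fd)


# ---------------------------------------------------------------------------
# Langevin dynamics

_SANITY_X = 1.0e4
_SANITY_V = 1.0e8


class _LangevinState:
    """Mutable integrator state shared across protocol stages."""

    __slots__ = ("x", "v", "rng", "f_total", "f_dih", "step_count")

    def __init__(self, surface, spec: LangevinSpec):
        self.rng = random.Random(spec.seed)
        self.x = [float(c) for c in spec.x0]
        if len(self.x) != surface.dimension:
            raise ValueError("x0 dimensionality mismatch")
        kbt = KB * spec.temperature
        sig_v = math.sqrt(kbt * FORCE_TO_ACC / spec.mass)
        self.v = [self.rng.gauss(0.0, sig_v) if sig_v > 0 else 0.0
                  for _ in self.x]
        self.f_total, self.f_dih = evaluate_force(surface, self.x)
        self.step_count = 0


def _integrate(
    surface: PotentialSurface,
    spec: LangevinSpec,
    n_steps: int,
    state: _LangevinState,
    boost: Optional[Callable] = None,
):
    """Advance ``state`` by n_steps with BAOAB splitting, recording frames.

    ``boost(v_total, v_dihedral) -> (dv_tot, dv_dih, s_full, s_dih)``
    supplies the boost energies and the force modification
    F* = s_full·F_full + s_dih·F_dih.

    Returns (frames, v_tot, v_dih, dv) lists; dv entries are (dv_tot, dv_dih).
    """
    dt = spec.timestep
    m = spec.mass
    c1 = math.exp(-spec.friction * dt)
    kbt = KB * spec.temperature
    sig_v = math.sqrt(kbt * FORCE_TO_ACC / m)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1)) * sig_v
    half_acc = 0.5 * dt * FORCE_TO_ACC / m
    half_dt = 0.5 * dt
    d = surface.dimension
    rng, x, v = state.rng, state.x, state.v

    frames, rec_vt, rec_vd, rec_dv = [], [], [], []

    e_core, e_dih = surface.energy_core, surface.energy_dihedral
    fr_core, fr_dih = surface.force_core, surface.force_dihedral

    def eff_force():
        fc = fr_core(x)
        fd = fr_dih(x)
        vdih = e_dih(x)
        vtot = e_core(x) + vdih
        if boost is None:
            f = [fc[j] + fd[j] for j in range(d)]
            return f, vtot, vdih, 0.0, 0.0
        dv_t, dv_d, s_full, s_dih = boost(vtot, vdih)
        f = [(fc[j] + fd[j]) * s_full + fd[j] * s_dih for j in range(d)]
        return f, vtot, vdih, dv_t, dv_d

    f, vtot, vdih, dv_t, dv_d = eff_force()

    for step in range(n_steps):
        for j in range(d):
            v[j] += half_acc * f[j]
            x[j] += half_dt * v[j]
            v[j] = c1 * v[j] + (c2 * rng.gauss(0.0, 1.0) if c2 > 0 else 0.0)
            x[j] += half_dt * v[j]
        f, vtot, vdih, dv_t, dv_d = eff_force()
        for j in range(d):
            v[j] += half_acc * f[j]
        state.step_count += 1
        if any(abs(xi) > _SANITY_X for xi in x) or abs(vtot) > _SANITY_V:
            raise IntegrationFailure(
                f"integration blew up at step {state.step_count}: x={x}, V={vtot}"
            )
        if state.step_count % spec.stride == 0:
            frames.append(tuple(x))
            rec_vt.append(vtot)
            rec_vd.append(vdih)
            rec_dv.append((dv_t, dv_d))
    return frames, rec_vt, rec_vd, rec_dv


def run_langevin(
    surface: PotentialSurface,
    spec: LangevinSpec,
    boost: Optional[Callable] = None,
    stage_label: Optional[str] = None,
) -> ToyTrajectory:
    """Integrate Langevin dynamics on ``surface`` and record a trajectory.

    With no boost the long-run histogram converges to exp(-V/kBT); a
    boost callback turns the run into sampling of the modified potential
    V* = V + ΔV with per-frame ΔV recorded.
    """
    state = _LangevinState(surface, spec)
    frames, vt, vd, dv = _integrate(surface, spec, spec.n_steps, state, boost)
    label = stage_label or ("cMD" if boost is None else "production")
    boosts = None if label == "cMD" else np.asarray(dv)
    return ToyTrajectory(
        frames=np.asarray(frames),
        energies_total=np.asarray(vt),
        energies_dihedral=np.asarray(vd),
        spec=spec,
        stage_label=label,
        boosts=boosts,
    )


# ---------------------------------------------------------------------------
# reference PMFs

def analytic_pmf(
    surface: PotentialSurface,
    grid: np.ndarray,
    temperature: float,
    axis: int = 0,
    n_quad: int = 400,
):
    """Reference free-energy curve F_ref on ``grid`` along ``axis``.

    1D surfaces: F_ref(x) = V(x) − min V (pointwise identity).  2D
    surfaces: the complementary coordinate is integrated out by
    quadrature, F_ref(x) = −kBT ln ∫ exp(−V/kBT) dy, minimum shifted
    to zero.
    """
    grid = np.asarray(grid, dtype=float)
    kbt = KB * temperature
    if surface.dimension == 1:
        vals = np.array([evaluate_energy(surface, (g,))[0] for g in grid])
        return vals - vals.min()
    if surface.dimension == 2:
        other = 1 - axis
        lo, hi = surface.domain[other]
        if not (math.isfinite(lo) and math.isfinite(hi)):
            if surface.dihedral_period and surface.dihedral_axis == other:
                lo, hi = 0.0, surface.dihedral_period
            else:
                raise OracleUnavailable(
                    "complementary coordinate has unbounded non-periodic domain"
                )
        ys = np.linspace(lo, hi, n_quad)
        F = np.empty_like(grid)
        for i, g in enumerate(grid):
            pt = [0.0, 0.0]
            energies = []
            for y in ys:
                pt[axis] = g
                pt[other] = y
                energies.append(evaluate_energy(surface, tuple(pt))[0])
            e = np.asarray(energies)
            emin = e.min()
            z = np.trapezoid(np.exp(-(e - emin) / kbt), ys)
            F[i] = emin - kbt * math.log(z)
        return F - F.min()
    raise OracleUnavailable("only 1D and 2D surfaces supported")


def binned_reference_pmf(
    surface: PotentialSurface,
    bin_edges: np.ndarray,
    temperature: float,
    axis: int = 0,
    n_quad: int = 200,
):
    """Exact Boltzmann free energy of each histogram bin.

    F_j = −kBT ln ∫_bin exp(−V/kBT), minimum shifted to 0 — the correct
    oracle for histogram-estimated PMFs, where within-bin energy
    variation matters.
    """
    edges = np.asarray(bin_edges, dtype=float)
    kbt = KB * temperature
    if surface.dimension != 1:
        raise OracleUnavailable("binned reference implemented for 1D surfaces")
    logs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        xs = np.linspace(lo, hi, n_quad)
        e = np.array([evaluate_energy(surface, (g,))[0] for g in xs])
        emin = e.min()
        z = np.trapezoid(np.exp(-(e - emin) / kbt), xs)
        logs.append(emin - kbt * math.log(z))
    F = np.asarray(logs)
    return F - F.min()
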