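"""Gaussian accelerated MD: boost construction and the staged protocol.

The boost adds a harmonic, Gaussian-distributed energy term
ΔV = ½ k (E − V)² whenever the instantaneous potential V falls below a
threshold E, flattening barriers while keeping ΔV narrow enough
(σ_ΔV ≤ σ0) for accurate cumulant-expansion reweighting.  Parameters are
determined from running statistics of the unbiased energies:

* lower-bound mode: E = Vmax and
  k0 = min(1, (σ0/σV) (Vmax−Vmin)/(Vmax−Vavg));
* upper-bound mode: k0″ = (1 − σ0/σV) (Vmax−Vmin)/(Vavg−Vmin) and
  E = Vmin + 1/k if 0 < k0″ ≤ 1, otherwise fall back to the lower-bound
  formula.

Always k = k0/(Vmax − Vmin), so Vmax ≤ E ≤ Vmin + 1/k holds by
construction.  Dual boost applies independent boosts to the total
potential energy and to the dihedral energy term.

The protocol mirrors production GaMD engines at toy scale: a
conventional-MD statistics stage, a boosted equilibration stage with
periodic parameter refreshes, then production under frozen parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model_systems import (
    LangevinSpec,
    PotentialSurface,
    ToyTrajectory,
    _LangevinState,
    _integrate,
)

__all__ = [
    "BoostSpec",
    "BoostStatistics",
    "BoostParams",
    "NoVariabilityError",
    "update_statistics",
    "compute_k0",
    "compute_boost",
    "boost_force_factor",
    "GaMDRun",
    "run_gamd_protocol",
]

TERMS = ("total", "dihedral")


class NoVariabilityError(RuntimeError):
    """Energy statistics are degenerate (σV = 0); boosting is undefined."""


@dataclass(frozen=True)
class BoostSpec:
    """Configuration of the staged dual-boost protocol.

    ``sigma0`` is the user upper limit on the boost standard deviation
    per term (kcal/mol); stage lengths are integrator steps.  Defaults
    preserve the stage ratios of a production protocol (cMD statistics
    stage : equilibration ≈ 10.4 : 32) at toy scale, with parameter
    refreshes every ``update_interval`` steps.
    """

    mode: str = "lower_bound"
    sigma0: dict = field(default_factory=lambda: {"total": 6.0, "dihedral": 6.0})
    boosted_terms: tuple = ("total", "dihedral")
    update_interval: int = 400
    cmd_length: int = 10_400
    equilibration_length: int = 32_000

    def __post_init__(self):
        if self.mode not in ("lower_bound", "upper_bound"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if isinstance(self.sigma0, (int, float)):
            object.__setattr__(
                self, "sigma0", {t: float(self.sigma0) for t in TERMS}
            )
        for t in self.boosted_terms:
            if t not in TERMS:
                raise ValueError(f"unknown boosted term {t!r}")
            if self.sigma0.get(t, 0.0) <= 0:
                raise ValueError("sigma0 must be > 0 for every boosted term")
        if self.update_interval <= 0 or self.cmd_length <= 0:
            raise ValueError("stage lengths and update_interval must be > 0")


@dataclass
class BoostStatistics:
    """Streaming Vmax/Vmin/Vavg/σV of one energy term (Welford update)."""

    v_max: float = -math.inf
    v_min: float = math.inf
    mean: float = 0.0
    m2: float = 0.0
    n_samples: int = 0

    @property
    def v_avg(self) -> float:
        return self.mean

    @property
    def sigma_v(self) -> float:
        if self.n_samples < 2:
            return 0.0
        return math.sqrt(self.m2 / self.n_samples)

    def copy(self) -> "BoostStatistics":
        return BoostStatistics(self.v_max, self.v_min, self.mean,
                               self.m2, self.n_samples)


def update_statistics(stats: BoostStatistics, v: float) -> BoostStatistics:
    """Fold one energy sample into the running statistics (in place)."""
    if not math.isfinite(v):
        raise ValueError(f"non-finite energy sample {v}")
    stats.n_samples += 1
    if v > stats.v_max:
        stats.v_max = v
    if v < stats.v_min:
        stats.v_min = v
    delta = v - stats.mean
    stats.mean += delta / stats.n_samples
    stats.m2 += delta * (v - stats.mean)
    return stats


@dataclass(frozen=True)
class BoostParams:
    """Threshold energy E, dimensionless k0 and force constant k of one term."""

    e_threshold: float
    k0: float
    k: float
    mode: str = "lower_bound"

    def __post_init__(self):
        if not (0.0 < self.k0 <= 1.0):
            raise ValueError(f"k0 must be in (0, 1], got {self.k0}")


def compute_k0(stats: BoostStatistics, sigma0: float, mode: str = "lower_bound") -> BoostParams:
    """Determine (k0, E, k) from energy statistics.

    Raises :class:`NoVariabilityError` when Vmax == Vmin or σV == 0
    (e.g. a flat potential), where no meaningful boost exists.
    """
    vmax, vmin, vavg = stats.v_max, stats.v_min, stats.v_avg
    sig = stats.sigma_v
    if stats.n_samples < 2 or vmax <= vmin or sig == 0.0:
        raise NoVariabilityError(
            "degenerate energy statistics: boosting undefined "
            f"(Vmax={vmax}, Vmin={vmin}, sigmaV={sig})"
        )
    span = vmax - vmin
    if mode == "upper_bound":
        k0_dd = (1.0 - sigma0 / sig) * span / (vavg - vmin)
        if 0.0 < k0_dd <= 1.0:
            k = k0_dd / span
            return BoostParams(e_threshold=vmin + 1.0 / k, k0=k0_dd, k=k,
                               mode="upper_bound")
        # stated fallback: use the lower-bound formula
        mode = "lower_bound"
    if mode != "lower_bound":
        raise ValueError(f"unknown mode {mode!r}")
    k0 = min(1.0, (sigma0 / sig) * span / (vmax - vavg))
    k = k0 / span
    return BoostParams(e_threshold=vmax, k0=k0, k=k, mode="lower_bound")


def compute_boost(params: BoostParams, v: float) -> float:
    """Boost energy ΔV = ½k(E−V)² for V < E, else 0 (always ≥ 0)."""
    if v >= params.e_threshold:
        return 0.0
    d = params.e_threshold - v
    return 0.5 * params.k * d * d


def boost_force_factor(params: BoostParams, v: float) -> float:
    """Force attenuation −k(E−V) of the boosted term's gradient (≤ 0).

    The modified force on the term is F·(1 + factor); at V = E the
    factor vanishes, so the modified force is continuous.
    """
    if v >= params.e_threshold:
        return 0.0
    return -params.k * (params.e_threshold - v)


def _make_callback(params: dict):
    """Build the integrator boost callback from per-term parameters.

    Returns (dv_total, dv_dihedral, s_full, s_dih) with modified force
    F* = s_full·F_full + s_dih·F_dihedral.
    """
    p_tot = params.get("total")
    p_dih = params.get("dihedral")

    def boost(v_total, v_dihedral):
        dv_t = compute_boost(p_tot, v_total) if p_tot else 0.0
        dv_d = compute_boost(p_dih, v_dihedral) if p_dih else 0.0
        s_full = 1.0 + (boost_force_factor(p_tot, v_total) if p_tot else 0.0)
        s_dih = boost_force_factor(p_dih, v_dihedral) if p_dih else 0.0
        return dv_t, dv_d, s_full, s_dih

    return boost


@dataclass
class GaMDRun:
    """Result of the staged protocol: one trajectory per stage plus the
    parameter history [(step, {term: BoostParams}), ...]."""

    cmd: ToyTrajectory
    equilibration: ToyTrajectory
    production: ToyTrajectory
    #: [(step, {term: BoostParams}, {term: BoostStatistics snapshot}), ...]
    params_history: list
    final_params: dict
    statistics: dict

    @property
    def stages(self):
        return {"cMD": self.cmd, "equilibration": self.equilibration,
                "production": self.production}


def _stage_traj(frames, vt, vd, dv, spec, label):
    boosts = None if label == "cMD" else np.asarray(dv).reshape(-1, 2)
    return ToyTrajectory(
        frames=np.asarray(frames), energies_total=np.asarray(vt),
        energies_dihedral=np.asarray(vd), spec=spec, stage_label=label,
        boosts=boosts,
    )


def run_gamd_protocol(
    surface: PotentialSurface,
    langevin_spec: LangevinSpec,
    boost_spec: BoostSpec,
    production_length: Optional[int] = None,
) -> GaMDRun:
    """Run cMD statistics → boosted equilibration → frozen production.

    Statistics are always accumulated from the *unmodified* term
    energies (V, not V*): the threshold and force constant are functions
    of the unbiased landscape.  Equilibration refreshes parameters every
    ``update_interval`` steps; production uses the final parameters and
    records per-frame boosts.  ``langevin_spec.n_steps`` is the
    production length unless overridden.
    """
    n_prod = production_length or langevin_spec.n_steps
    terms = tuple(boost_spec.boosted_terms)
    state = _LangevinState(surface, langevin_spec)
    stats = {t: BoostStatistics() for t in terms}
    history = []

    def feed(vt_list, vd_list):
        for t in terms:
            src = vt_list if t == "total" else vd_list
            s = stats[t]
            for v in src:
                update_statistics(s, v)

    # stage 1: conventional MD, statistics only
    out = _integrate(surface, langevin_spec, boost_spec.cmd_length, state)
    cmd_traj = _stage_traj(*out, langevin_spec, "cMD")
    feed(out[1], out[2])

    def refresh_params():
        return {
            t: compute_k0(stats[t], boost_spec.sigma0[t], boost_spec.mode)
            for t in terms
        }

    if not terms:
        # no boosted terms: remaining stages are plain cMD dynamics
        out_eq = _integrate(surface, langevin_spec,
                            boost_spec.equilibration_length, state)
        eq_traj = _stage_traj(*out_eq, langevin_spec, "equilibration")
        out_pr = _integrate(surface, langevin_spec, n_prod, state)
        prod_traj = _stage_traj(*out_pr, langevin_spec, "production")
        return GaMDRun(cmd_traj, eq_traj, prod_traj, [], {}, {})

    def snapshot():
        return {t: stats[t].copy() for t in terms}

    params = refresh_params()
    history.append((state.step_count, params, snapshot()))

    # stage 2: boosted equilibration with periodic parameter refresh
    eq_chunks = ([], [], [], [])
    remaining = boost_spec.equilibration_length
    while remaining > 0:
        chunk = min(boost_spec.update_interval, remaining)
        out = _integrate(surface, langevin_spec, chunk, state,
                         boost=_make_callback(params))
        for acc, part in zip(eq_chunks, out):
            acc.extend(part)
        feed(out[1], out[2])
        params = refresh_params()
        history.append((state.step_count, params, snapshot()))
        remaining -= chunk
    eq_traj = _stage_traj(*eq_chunks, langevin_spec, "equilibration")

    # stage 3: production under frozen final parameters
    out = _integrate(surface, langevin_spec, n_prod, state,
                     boost=_make_callback(params))
    prod_traj = _stage_traj(*out, langevin_spec, "production")

    return GaMDRun(cmd_traj, eq_traj, prod_traj, history, params,
                   {t: stats[t].copy() for t in terms})
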