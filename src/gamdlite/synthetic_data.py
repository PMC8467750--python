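"""Fixture generators with machine-readable answer keys.

Every generator is deterministic in (parameters, seed) and returns the
ground truth alongside the data: toy potentials with analytic PMFs, a
geometric receptor–mini-G scaffold with planted reaction-coordinate
dynamics, fluctuation amplitudes and interface contacts, and
luminescence plates with known four-parameter-logistic concentration
dependence and multiplicative drift.

The receptor scaffold is geometric, not physical: helices are straight
segments whose backbone triplets average exactly to designed centers,
so planted distances are reproduced to machine precision at zero
jitter.  The analyses under test are purely geometric/statistical, so
no force-field realism is needed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc

from .constants import KB
from . import model_systems as ms
from .structure_analysis import StructureModel

__all__ = [
    "make_double_well",
    "make_dual_term_surface",
    "synth_complex_trajectory",
    "synth_lumi_plate",
    "ComplexFixture",
    "PlateFixture",
]


# ---------------------------------------------------------------------------
# potentials

def make_double_well(barrier: float = 5.0, a: float = 2.0,
                     temperature: float = 300.0,
                     grid_step: float = 0.05):
    """Symmetric double well plus its analytic PMF answer key.

    w(x) = barrier((x/a)² − 1)², minima at ±a.  The key holds the
    reference free-energy curve on a standard grid spanning the
    thermally accessible region.
    """
    surface = ms.double_well(barrier, a)
    n = int(round(2.0 * a / grid_step))
    grid = grid_step * np.arange(-n, n + 1)  # exactly symmetric about 0
    pmf = ms.analytic_pmf(surface, grid, temperature)
    key = {
        "kind": "double_well", "barrier": barrier, "a": a,
        "temperature": temperature,
        "grid": grid.tolist(), "pmf": pmf.tolist(),
        "minima": [-a, a], "barrier_position": 0.0,
    }
    return surface, key


def make_dual_term_surface(barrier: float = 5.0, a: float = 2.0,
                           dihedral_amp: float = 2.0, periodicity: int = 3,
                           temperature: float = 300.0,
                           grid_step: float = 0.05):
    """2D double-well × cosine-dihedral surface with a marginal-PMF key."""
    surface = ms.dual_term_surface(barrier, a, dihedral_amp, periodicity)
    n = int(round(2.0 * a / grid_step))
    grid = grid_step * np.arange(-n, n + 1)
    pmf_x = ms.analytic_pmf(surface, grid, temperature, axis=0)
    key = {
        "kind": "dual_term", "barrier": barrier, "a": a,
        "dihedral_amp": dihedral_amp, "periodicity": periodicity,
        "temperature": temperature,
        "grid": grid.tolist(), "pmf_x": pmf_x.tolist(),
        "dihedral_period": surface.dihedral_period,
    }
    return surface, key


# ---------------------------------------------------------------------------
# receptor-mG complex

# backbone offsets whose mean is exactly zero, so a residue's backbone
# geometric center equals its designed center
_BB_OFFSETS = {"CA": (0.4, 0.0, 0.0), "N": (-0.2, 0.35, 0.0),
               "C": (-0.2, -0.35, 0.0)}

_RISE = 1.5  # Å per residue along a helix axis


def _helix(chain, first_res, n_res, origin, axis, resnames=None, segment=None):
    """Residue centers along a straight axis; yields atom records."""
    ax = np.asarray(axis, float)
    ax = ax / np.linalg.norm(ax)
    rows = []
    for k in range(n_res):
        resid = first_res + k
        center = np.asarray(origin, float) + _RISE * k * ax
        resname = (resnames or {}).get(resid, "ALA")
        for name, off in _BB_OFFSETS.items():
            rows.append((chain, resid, resname, name, name[0],
                         center + np.asarray(off)))
    return rows


#: planted interface contacts: (receptor resid, resname, atom), (mG resid,
#: resname, atom), pair distance Å, expected interaction class
_DEFAULT_CONTACTS = [
    ((312, "ARG", "NH1"), (913, "ASP", "OD1"), 3.2, "salt_bridge"),
    ((801, "LEU", "CD1"), (914, "VAL", "CG1"), 3.8, "vdW"),
    ((603, "ALA", "O"), (915, "SER", "OG"), 3.3, "hbond"),
    ((205, "THR", "CG2"), (911, "ALA", "CB"), 3.6, "vdW"),
    ((802, "LYS", "NZ"), (910, "GLU", "OE1"), 3.0, "salt_bridge"),
    ((604, "ALA", "O"), (909, "ASN", "ND2"), 3.4, "hbond"),
    ((803, "ALA", "CB"), (912, "ALA", "CB"), 4.5, "vdW"),
]


@dataclass
class ComplexFixture:
    """Synthetic receptor–mG complex: structure, trajectory, answer key."""

    structure: StructureModel
    trajectory: np.ndarray  # (n_frames, n_atoms, 3)
    key: dict

    def write(self, outdir):
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.structure.to_pdb(out / "complex.pdb")
        self.structure.write_bw_map(out / "bw_map.json")
        write_traj_csv(out / "trajectory.csv", self.trajectory)
        with open(out / "answer_key.json", "w") as fh:
            json.dump(self.key, fh, indent=1)
        return out


def write_traj_csv(path, traj):
    """Long-format trajectory CSV: frame, atom, x, y, z."""
    t = np.asarray(traj, float)
    n_frames, n_atoms, _ = t.shape
    frame = np.repeat(np.arange(n_frames), n_atoms)
    atom = np.tile(np.arange(n_atoms), n_frames)
    flat = t.reshape(-1, 3)
    df = pd.DataFrame({"frame": frame, "atom": atom,
                       "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]})
    df.to_csv(path, index=False, float_format="%.9f")


def read_traj_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    n_frames = int(df["frame"].max()) + 1
    n_atoms = int(df["atom"].max()) + 1
    return df[["x", "y", "z"]].to_numpy().reshape(n_frames, n_atoms, 3)


def _build_scaffold(orientation: str, contacts):
    """Static coordinates plus annotations of the toy complex."""
    resnames = {p[0][0]: p[0][1] for p in contacts}
    resnames.update({308: "ASP", 312: "ARG", 205: "THR", 709: "TYR",
                     705: "ASN", 706: "PRO"})
    mg_resnames = {p[1][0]: p[1][1] for p in contacts}

    rows = []
    # receptor helices; intracellular ends at z = 0, pocket side up
    rows += _helix("R", 301, 12, (0.0, 0.0, 16.5), (0, 0, -1),
                   resnames=resnames)                      # TM3: 3.50 = 312 at z 0
    rows += _helix("R", 603, 10, (19.0, 0.0, 0.0), (0, 0, 1),
                   resnames=resnames)                      # TM6: 6.30 = 603
    rows += _helix("R", 205, 10, (2.0, 14.0, 0.0), (0, 0, 1),
                   resnames=resnames)                      # TM2: 2.39 = 205
    rows += _helix("R", 705, 10, (7.0, 8.0, 0.0), (0, 0, 1),
                   resnames=resnames)                      # TM7: NPxxY = 705-709
    rows += _helix("R", 801, 3, (10.0, -4.0, 0.0), (1, 0, 0),
                   resnames=resnames)                      # H8, horizontal

    # mini-G alpha5 helix, horizontal, 5.6 Å below the receptor floor so
    # no backbone-backbone pair can fall inside a 5 Å contact cutoff
    c239 = np.array([2.0, 14.0, 0.0])
    depth = -5.6
    if orientation == "gi":
        lat = math.sqrt(8.0 ** 2 - depth ** 2)
        direction = np.array([6.0, -9.0, 0.0])
    elif orientation == "gs":
        lat = math.sqrt(14.0 ** 2 - depth ** 2)
        direction = np.array([17.0, -14.0, 0.0])
    else:
        raise ValueError("orientation must be 'gs' or 'gi'")
    direction = direction / np.linalg.norm(direction)
    hook_center = c239 + lat * direction + np.array([0.0, 0.0, depth])
    rows += _helix("G", 901, 15, hook_center + np.array([-18.0, 0.0, 0.0]),
                   (1, 0, 0), resnames=mg_resnames)        # hook = 911-915

    # ligand: amine N placed on the D3.32 Cγ axis; two carbons trail it
    c332 = np.array([0.0, 0.0, 6.0])
    cg = c332 + np.array([1.0, 0.0, 1.0])
    rows.append(("R", 308, "ASP", "CB", "C", c332 + np.array([0.7, 0.0, 0.5])))
    rows.append(("R", 308, "ASP", "CG", "C", cg))
    na0 = cg + np.array([3.0, 0.0, 0.0])
    rows.append(("L", 1, "HSM", "NA", "N", na0))
    rows.append(("L", 1, "HSM", "C1", "C", na0 + np.array([1.2, 0.8, 0.5])))
    rows.append(("L", 1, "HSM", "C2", "C", na0 + np.array([2.2, -0.5, 1.0])))

    # planted contact-pair side chains in a dedicated far region
    for j, ((r_res, r_name, r_atom), (g_res, g_name, g_atom), d, _cls) in \
            enumerate(contacts):
        base = np.array([14.0 * j, 40.0, 0.0])
        rows.append(("R", r_res, r_name, r_atom, r_atom[0], base))
        rows.append(("G", g_res, g_name, g_atom, g_atom[0],
                     base + np.array([d, 0.0, 0.0])))

    rows.sort(key=lambda r: ({"R": 0, "G": 1, "L": 2}[r[0]], r[1], r[3]))
    # keep a float64 copy: AtomArray coordinates are float32, too coarse
    # for the machine-precision planted-distance guarantees
    coords64 = np.array([r[5] for r in rows], dtype=np.float64)
    atoms = struc.AtomArray(len(rows))
    atoms.coord = coords64
    atoms.chain_id = np.array([r[0] for r in rows])
    atoms.res_id = np.array([r[1] for r in rows])
    atoms.res_name = np.array([r[2] for r in rows])
    atoms.atom_name = np.array([r[3] for r in rows])
    atoms.element = np.array([r[4] for r in rows])
    atoms.hetero = atoms.chain_id == "L"

    bw_labels = {"2.39": ("R", 205), "3.32": ("R", 308), "3.50": ("R", 312),
                 "6.30": ("R", 603), "7.49": ("R", 705), "7.50": ("R", 706),
                 "7.51": ("R", 707), "7.52": ("R", 708), "7.53": ("R", 709)}
    segments = {("R", 205 + k): "TM2" for k in range(10)}
    segments.update({("R", 301 + k): "TM3" for k in range(12)})
    segments.update({("R", 603 + k): "TM6" for k in range(10)})
    segments.update({("R", 705 + k): "TM7" for k in range(10)})
    segments.update({("R", 801 + k): "H8" for k in range(3)})
    segments.update({("G", 901 + k): "mG-a5" for k in range(15)})
    segments[("L", 1)] = "ligand"
    model = StructureModel(atoms, bw_labels, segments,
                           mg_chain="G", ligand_chain="L")

    # NPxxY center = mean of the N7.49, P7.50 and Y7.53 residue centers
    centers = {"3.50": np.array([0.0, 0.0, 0.0]),
               "6.30": np.array([19.0, 0.0, 0.0]),
               "2.39": c239,
               "npxxy": np.array([7.0, 8.0, 2.5]),
               "hook": hook_center, "cg332": cg}
    return model, centers, coords64


def synth_complex_trajectory(
    n_frames: int = 500,
    seed: int = 0,
    d_bound: float = 3.0,
    d_free: float = 8.0,
    p_unbind: float = 0.05,
    p_rebind: float = 0.15,
    jitter_sigma=0.0,
    orientation: str = "gs",
    distance_jitter: float = 0.0,
    contacts=None,
) -> ComplexFixture:
    """Toy receptor–mG trajectory with planted ground truth.

    The ligand–D3.32 distance follows a two-state Markov chain between
    ``d_bound`` and ``d_free`` (per-frame switching probabilities
    ``p_unbind``/``p_rebind``); every atom receives isotropic Gaussian
    jitter (scalar sigma or {(chain, resid): sigma}); the interface
    carries the planted contact pairs.  The answer key records exact
    per-frame distances, true RMSF values (σ√3), the expected bound-state
    occupancy and the planted contact edges with classes.
    """
    if n_frames < 100:
        raise ValueError("n_frames must be >= 100")
    contacts = contacts if contacts is not None else _DEFAULT_CONTACTS
    for (r_res, _, _), (g_res, _, _), d, _cls in contacts:
        if d <= 0:
            raise ValueError(
                f"planted contact ({r_res},{g_res}) has non-positive distance"
            )
    model, centers, base = _build_scaffold(orientation, contacts)
    rng = np.random.default_rng(seed)
    n_atoms = len(model.atoms)

    # two-state distance dynamics, bound start
    states = np.empty(n_frames, dtype=int)  # 1 = bound, 0 = free
    s = 1
    for t in range(n_frames):
        states[t] = s
        u = rng.random()
        if s == 1 and u < p_unbind:
            s = 0
        elif s == 0 and u < p_rebind:
            s = 1
    dists = np.where(states == 1, d_bound, d_free).astype(float)
    if distance_jitter > 0:
        dists = np.abs(dists + rng.normal(0.0, distance_jitter, n_frames))

    na_idx = model.atom_indices(model.ligand_residues(), names=["NA"])[0]
    lig_idx = model.atom_indices(model.ligand_residues())
    cg = centers["cg332"]
    lig_offsets = base[lig_idx] - base[na_idx]

    if isinstance(jitter_sigma, dict):
        sig = np.zeros(n_atoms)
        for i in range(n_atoms):
            sig[i] = jitter_sigma.get(model.residue_of_atom(i), 0.0)
    else:
        sig = np.full(n_atoms, float(jitter_sigma))

    traj = np.empty((n_frames, n_atoms, 3))
    for t in range(n_frames):
        frame = base.copy()
        na = cg + np.array([dists[t], 0.0, 0.0])
        frame[lig_idx] = na + lig_offsets
        if sig.any():
            frame += rng.normal(0.0, 1.0, (n_atoms, 3)) * sig[:, None]
        traj[t] = frame

    hook, c239 = centers["hook"], centers["2.39"]
    expected_bound = p_rebind / (p_unbind + p_rebind)
    rmsf_true = {}
    for cr in model.residues():
        if cr[0] == model.ligand_chain:
            continue
        i = model.atom_indices([cr], names=["CA"])[0]
        rmsf_true[f"{cr[0]}:{cr[1]}"] = sig[i] * math.sqrt(3.0)
    rmsf_true["L:-1"] = float(sig[lig_idx].mean() * math.sqrt(3.0))

    key = {
        "seed": seed, "n_frames": n_frames,
        "orientation": orientation,
        "d_bound": d_bound, "d_free": d_free,
        "p_unbind": p_unbind, "p_rebind": p_rebind,
        "expected_bound_fraction": expected_bound,
        "states": states.tolist(),
        "d332_ligand": dists.tolist(),
        "tm3_tm6": 19.0,
        "alpha5_tm2": float(np.linalg.norm(hook - c239)),
        "npxxy_alpha5": float(np.linalg.norm(hook - centers["npxxy"])),
        "alpha5_tm6": float(np.linalg.norm(hook - centers["6.30"])),
        "jitter_sigma": (jitter_sigma if not isinstance(jitter_sigma, dict)
                         else {f"{c}:{r}": v for (c, r), v in jitter_sigma.items()}),
        "rmsf_true": rmsf_true,
        "contacts": [
            {"res_a": ["R", p[0][0]], "res_b": ["G", p[1][0]],
             "distance": p[2], "class": p[3]}
            for p in contacts
        ],
    }
    return ComplexFixture(structure=model, trajectory=traj, key=key)


# ---------------------------------------------------------------------------
# luminescence plates

DEFAULT_CONCENTRATIONS = (1e-10, 1e-9, 1e-8, 1e-7, 3e-7, 1e-6, 1e-5, 1e-4)


@dataclass
class PlateFixture:
    plate: "PlateData"
    key: dict

    def write(self, outdir):
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.plate.to_csv(out / "plate.csv")
        with open(out / "answer_key.json", "w") as fh:
            json.dump(self.key, fh, indent=1)
        return out


def synth_lumi_plate(
    pec50: float = 6.86,
    emax: float = 100.0,
    hill: float = 1.0,
    bottom: float = 0.0,
    drift_tau: float = 45.0,
    noise_sigma: float = 0.0,
    concentrations=DEFAULT_CONCENTRATIONS,
    seed: int = 0,
    condition: str = "assay",
    n_replicates: int = 3,
    baseline_min: float = 15.0,
    post_min: float = 45.0,
    flat: bool = False,
) -> PlateFixture:
    """Synthetic luminescence plate with known 4PL parameters.

    RLU(t) = drift(t)·(baseline + response(c)·activation(t))·(1 + σξ)
    with multiplicative exponential drift exp(−t/τ) emulating substrate
    autooxidation, a saturating activation ramp after agonist addition,
    plus wild-type and vehicle (L-15) control wells.  ``flat`` zeroes
    the concentration dependence (an n.d. plate).
    """
    from .dose_response import PlateData, four_param_logistic, WILD_TYPE, L15

    if len(set(concentrations)) < 5:
        raise ValueError("need at least 5 distinct concentrations")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, baseline_min + post_min + 0.5, 1.0)
    drift = np.exp(-times / drift_tau) if drift_tau else np.ones_like(times)
    act = np.where(times >= baseline_min,
                   1.0 - np.exp(-(times - baseline_min) / 8.0), 0.0)
    b_cells, b_wt, scale = 1000.0, 800.0, 500.0

    rows = []

    def add_well(well, cond, conc, resp_frac):
        signal = drift * (b_cells + scale * resp_frac * act)
        if noise_sigma > 0:
            signal = signal * (1.0 + rng.normal(0.0, noise_sigma, len(times)))
        for t, v in zip(times, signal):
            rows.append((well, cond, conc, t, v))

    w = 0
    for conc in concentrations:
        resp = 0.0 if flat else four_param_logistic(
            math.log10(conc), bottom, emax, -pec50, hill) / 100.0
        for _ in range(n_replicates):
            add_well(f"W{w:03d}", condition, conc, resp)
            w += 1
    for _ in range(n_replicates):
        add_well(f"W{w:03d}", L15, np.nan, 0.0)
        w += 1
    for _ in range(n_replicates):
        # wild-type cells: no receptor construct, different baseline
        signal = drift * b_wt
        if noise_sigma > 0:
            signal = signal * (1.0 + rng.normal(0.0, noise_sigma, len(times)))
        for t, v in zip(times, signal):
            rows.append((f"W{w:03d}", WILD_TYPE, np.nan, t, v))
        w += 1

    table = pd.DataFrame(rows, columns=["well", "condition", "conc_molar",
                                        "time_min", "rlu"])
    plate = PlateData(table, baseline_min=baseline_min, post_min=post_min)
    key = {
        "pec50": pec50, "emax": emax, "hill": hill, "bottom": bottom,
        "drift_tau": drift_tau, "noise_sigma": noise_sigma,
        "concentrations": list(concentrations), "seed": seed,
        "condition": condition, "flat": flat,
    }
    return PlateFixture(plate=plate, key=key)
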