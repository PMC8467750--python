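"""Reaction coordinates, RMSF and interface contact networks.

Works on receptor–mini-G complexes addressed the way the GPCR field
addresses them: residues carry Ballesteros–Weinstein (BW) generic labels
(D3.32, R3.50, NPxxY = 7.49–7.53, ...) supplied as a JSON map alongside
the PDB file, the mini-G chain contributes its five C-terminal residues
as the "α5 hook", and the ligand is a separate chain.

Inter-selection distances use the unweighted geometric center of the
pooled backbone (Cα, C, N) atoms; Cα, C and N masses are near-equal, so
this differs from a mass-weighted center by <0.2%.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "StructureModel",
    "CoordinateSeries",
    "RMSFProfile",
    "ContactNetwork",
    "BindingEnergySummary",
    "SelectionError",
    "com_backbone_distance",
    "tm3_tm6_distance",
    "npxxy_alpha5_distance",
    "alpha5_tm2_distance",
    "d332_ligand_distance",
    "compute_rmsf",
    "detect_contacts",
    "classify_interaction",
    "classify_network",
    "representative_frame",
    "binding_energy_difference",
    "superpose",
]

BACKBONE = ("CA", "C", "N")

#: anionic side-chain oxygens per residue (plus any OXT carboxylate)
ANIONIC_ATOMS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
#: cationic side-chain nitrogens per residue (His only when protonated)
CATIONIC_ATOMS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIP": {"ND1", "NE2"},
    "HSP": {"ND1", "NE2"},
}


class SelectionError(KeyError):
    """A residue selection (e.g. a BW label) could not be resolved."""


class StructureModel:
    """Annotated structure: atoms plus BW labels and segment tags.

    ``atoms`` is a biotite :class:`AtomArray` holding the reference
    coordinates; ``bw_labels`` maps generic labels like "3.50" to
    (chain, residue number); ``segments`` tags residues with TM1–TM7,
    H8, ICL/ECL, mG-α5 or ligand.
    """

    def __init__(self, atoms: AtomArray, bw_labels: dict,
                 segments: Optional[dict] = None,
                 mg_chain: str = "G", ligand_chain: str = "L"):
        self.atoms = atoms
        self.bw_labels = {str(k): (str(v[0]), int(v[1]))
                          for k, v in bw_labels.items()}
        if len(set(self.bw_labels.values())) != len(self.bw_labels):
            raise ValueError("BW labels must map to distinct residues")
        self.segments = dict(segments or {})
        self.mg_chain = mg_chain
        self.ligand_chain = ligand_chain

    # -- construction / IO -------------------------------------------------
    @classmethod
    def from_pdb(cls, pdb_path, bw_map_path) -> "StructureModel":
        """Load a PDB file plus its JSON annotation map."""
        atoms = PDBFile.read(str(pdb_path)).get_structure(model=1)
        with open(bw_map_path) as fh:
            m = json.load(fh)
        return cls(atoms, m.get("labels", {}), m.get("segments"),
                   mg_chain=m.get("mg_chain", "G"),
                   ligand_chain=m.get("ligand_chain", "L"))

    def to_pdb(self, path):
        f = PDBFile()
        f.set_structure(self.atoms)
        f.write(str(path))

    def bw_map_dict(self) -> dict:
        return {
            "labels": {k: list(v) for k, v in self.bw_labels.items()},
            "segments": {f"{c}:{r}": s for (c, r), s in self.segments.items()},
            "mg_chain": self.mg_chain,
            "ligand_chain": self.ligand_chain,
        }

    def write_bw_map(self, path):
        with open(path, "w") as fh:
            json.dump(self.bw_map_dict(), fh, indent=1)

    # -- residue addressing -------------------------------------------------
    def residues(self) -> list:
        """All (chain, resid) pairs in order of appearance."""
        seen, out = set(), []
        for c, r in zip(self.atoms.chain_id, self.atoms.res_id):
            key = (str(c), int(r))
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def alpha5_hook(self) -> list:
        """The five C-terminal residues of the mini-G chain."""
        mg = [cr for cr in self.residues() if cr[0] == self.mg_chain]
        if len(mg) < 5:
            raise SelectionError("mini-G chain has fewer than 5 residues")
        return sorted(mg, key=lambda cr: cr[1])[-5:]

    def ligand_residues(self) -> list:
        lig = [cr for cr in self.residues() if cr[0] == self.ligand_chain]
        if not lig:
            raise SelectionError("no ligand chain present")
        return lig

    def resolve(self, selection) -> list:
        """Resolve a selection to a list of (chain, resid).

        Accepts a BW label ("3.50"), the keywords "alpha5_hook" /
        "ligand", an explicit (chain, resid) pair, or a sequence of any
        of these.
        """
        if isinstance(selection, str):
            if selection == "alpha5_hook":
                return self.alpha5_hook()
            if selection == "ligand":
                return self.ligand_residues()
            if selection in self.bw_labels:
                return [self.bw_labels[selection]]
            raise SelectionError(f"unresolvable BW label {selection!r}")
        if (isinstance(selection, tuple) and len(selection) == 2
                and isinstance(selection[1], int)):
            return [selection]
        out = []
        for item in selection:
            out.extend(self.resolve(item))
        return out

    def atom_indices(self, residues, names: Optional[Sequence[str]] = None,
                     heavy_only: bool = False) -> np.ndarray:
        """Indices of atoms in the given residues, optionally by name."""
        rset = set(residues)
        mask = np.array([
            (str(c), int(r)) in rset
            for c, r in zip(self.atoms.chain_id, self.atoms.res_id)
        ])
        if names is not None:
            nameset = set(names)
            mask &= np.isin(self.atoms.atom_name, list(nameset))
        if heavy_only:
            mask &= self.atoms.element != "H"
        return np.flatnonzero(mask)

    def backbone_indices(self, selection) -> np.ndarray:
        residues = self.resolve(selection)
        idx = self.atom_indices(residues, names=BACKBONE)
        if len(idx) < 3 * len(residues):
            raise SelectionError(
                f"incomplete backbone (Cα, C, N) for selection {selection!r}"
            )
        return idx

    def residue_of_atom(self, i: int):
        return (str(self.atoms.chain_id[i]), int(self.atoms.res_id[i]))


@dataclass
class CoordinateSeries:
    """Per-frame value of a named reaction coordinate (Å)."""

    name: str
    values: np.ndarray
    replica_id: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("distances must be >= 0")

    def __len__(self):
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self)),
                             "replica": self.replica_id,
                             self.name: self.values})


@dataclass
class RMSFProfile:
    """Per-residue (plus ligand) RMSF in Å."""

    residues: list  # (chain, resid) keys; ligand entry ("L", "ligand")
    values: np.ndarray
    replica_averaged: bool
    align_selection: str
    per_replica: Optional[np.ndarray] = None  # (n_replicas, n_residues)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chain": [c for c, _ in self.residues],
            "residue": [r for _, r in self.residues],
            "rmsf": self.values,
        })


@dataclass
class ContactNetwork:
    """Undirected residue-pair interface graph.

    Edge weights are atom-pair contact counts; ``classes`` (once
    assigned) label each edge vdW / hbond / salt_bridge.
    """

    graph: nx.Graph
    cutoff: float
    source: str = "frame"

    def edges(self) -> list:
        return sorted(
            (tuple(sorted((a, b))), d["count"], d.get("interaction"))
            for a, b, d in self.graph.edges(data=True)
        )

    def edge_set(self) -> set:
        return {tuple(sorted((a, b))) for a, b in self.graph.edges()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chain_a": a[0], "res_a": a[1], "chain_b": b[0], "res_b": b[1],
             "count": d["count"], "interaction": d.get("interaction", "")}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows)

    def to_graphml(self, path):
        g = nx.relabel_nodes(self.graph, {n: f"{n[0]}:{n[1]}" for n in self.graph})
        nx.write_graphml(g, str(path))


@dataclass
class BindingEnergySummary:
    """Per-complex mean ± SD binding energies and pairwise differences."""

    means: dict
    sds: dict
    n_frames: dict
    differences: dict  # (name_i, name_j) -> mean_i - mean_j

    def difference(self, a: str, b: str) -> float:
        return self.differences[(a, b)]


# ---------------------------------------------------------------------------
# distances

def _frames_of(traj) -> np.ndarray:
    a = np.asarray(traj, dtype=float)
    if a.ndim == 2:
        a = a[None]
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError("trajectory must be (n_frames, n_atoms, 3)")
    return a


def com_backbone_distance(traj, structure: StructureModel,
                          residues_a, residues_b) -> CoordinateSeries:
    """Distance between geometric centers of pooled backbone atoms.

    Each selection's Cα/C/N atoms are pooled and averaged without mass
    weighting; the per-frame Euclidean distance between the two centers
    is returned.
    """
    ia = structure.backbone_indices(residues_a)
    ib = structure.backbone_indices(residues_b)
    f = _frames_of(traj)
    ca = f[:, ia].mean(axis=1)
    cb = f[:, ib].mean(axis=1)
    d = np.linalg.norm(ca - cb, axis=1)
    return CoordinateSeries(name="com_backbone", values=d)


def tm3_tm6_distance(traj, structure, label_tm3: str = "3.50",
                     label_tm6: str = "6.30") -> CoordinateSeries:
    """TM3–TM6 intracellular spacing (GPCR activation metric).

    Defaults to the R3.50 ↔ E/A6.30 backbone centers; the TM3 label is a
    parameter because D3.50 is used by some conventions.
    """
    s = com_backbone_distance(traj, structure, label_tm3, label_tm6)
    s.name = "tm3_tm6"
    return s


def npxxy_alpha5_distance(traj, structure,
                          npxxy_labels=("7.49", "7.50", "7.53")) -> CoordinateSeries:
    """NPxxY motif ↔ mG α5-hook distance (α5 penetration depth)."""
    s = com_backbone_distance(traj, structure, list(npxxy_labels), "alpha5_hook")
    s.name = "npxxy_alpha5"
    return s


def alpha5_tm2_distance(traj, structure, label_tm2: str = "2.39") -> CoordinateSeries:
    """mG α5-hook ↔ TM2 (T/S2.39) distance (α5 sideward orientation)."""
    s = com_backbone_distance(traj, structure, "alpha5_hook", label_tm2)
    s.name = "alpha5_tm2"
    return s


def d332_ligand_distance(traj, structure, label: str = "3.32",
                         aspartate_atom: str = "CG",
                         ligand_atom: str = "NA") -> CoordinateSeries:
    """Single-atom distance D3.32 (Cγ) ↔ ligand amine nitrogen (Nα)."""
    res = structure.resolve(label)
    ia = structure.atom_indices(res, names=[aspartate_atom])
    il = structure.atom_indices(structure.ligand_residues(), names=[ligand_atom])
    if len(ia) != 1 or len(il) != 1:
        raise SelectionError(
            f"need exactly one {aspartate_atom} on {label} and one "
            f"{ligand_atom} on the ligand (got {len(ia)}, {len(il)})"
        )
    f = _frames_of(traj)
    d = np.linalg.norm(f[:, ia[0]] - f[:, il[0]], axis=1)
    return CoordinateSeries(name="d332_ligand", values=d)


# ---------------------------------------------------------------------------
# RMSF

def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple:
    """Optimal rotation R and translations mapping mobile onto ref
    (both (n, 3)); returns (R, mobile_center, ref_center)."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    h = (mobile - mc).T @ (ref - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, mc, rc


def superpose(frames: np.ndarray, align_idx: np.ndarray,
              n_iter: int = 3) -> np.ndarray:
    """Least-squares superpose all frames onto their iterative mean
    structure over the alignment atoms; returns transformed frames."""
    f = _frames_of(traj=frames).copy()
    ref = f[0, align_idx]
    for _ in range(n_iter):
        for t in range(len(f)):
            r, mc, rc = _kabsch(f[t, align_idx], ref)
            f[t] = (f[t] - mc) @ r.T + rc
        ref = f[:, align_idx].mean(axis=0)
    return f


def compute_rmsf(trajs, structure: StructureModel,
                 align_selection="receptor_backbone") -> RMSFProfile:
    """Replica-averaged per-residue RMSF after superposition.

    Each replica is superposed onto its own mean structure over the
    alignment selection (default: the receptor backbone, i.e. the
    transmembrane scaffold); RMSF is taken at Cα per residue and as the
    heavy-atom average for the ligand, then averaged arithmetically
    across replicas.
    """
    if isinstance(trajs, np.ndarray) and trajs.ndim == 3:
        trajs = [trajs]
    trajs = [_frames_of(t) for t in trajs]
    if any(len(t) < 2 for t in trajs):
        raise ValueError("RMSF needs at least 2 frames per replica")

    if align_selection == "receptor_backbone":
        rec = [cr for cr in structure.residues()
               if cr[0] not in (structure.mg_chain, structure.ligand_chain)]
        align_idx = structure.atom_indices(rec, names=BACKBONE)
        align_name = "receptor_backbone"
    else:
        align_idx = structure.backbone_indices(align_selection)
        align_name = str(align_selection)

    residues = [cr for cr in structure.residues()
                if cr[0] != structure.ligand_chain]
    ca_idx = []
    for cr in residues:
        idx = structure.atom_indices([cr], names=["CA"])
        if len(idx) != 1:
            raise SelectionError(f"residue {cr} lacks a unique Cα")
        ca_idx.append(idx[0])
    lig_idx = structure.atom_indices(structure.ligand_residues(),
                                     heavy_only=True)

    profiles = []
    for f in trajs:
        aligned = superpose(f, align_idx)

        def atom_rmsf(idx):
            x = aligned[:, idx]
            mean = x.mean(axis=0)
            return np.sqrt(((x - mean) ** 2).sum(axis=-1).mean(axis=0))

        vals = list(atom_rmsf(np.asarray(ca_idx)))
        vals.append(float(np.mean(atom_rmsf(lig_idx))))
        profiles.append(vals)

    per_replica = np.asarray(profiles)
    return RMSFProfile(
        residues=residues + [(structure.ligand_chain, -1)],
        values=per_replica.mean(axis=0),
        replica_averaged=len(trajs) > 1,
        align_selection=align_name,
        per_replica=per_replica,
    )


# ---------------------------------------------------------------------------
# contacts

def detect_contacts(traj, structure: StructureModel, groups,
                    cutoff: float = 5.0) -> ContactNetwork:
    """Residue-pair contacts between two disjoint selections.

    A residue pair is in contact when any inter-group heavy-atom pair is
    within ``cutoff`` Å; edge weight is the atom-pair contact count
    (summed over frames when a trajectory is given).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    sel_a, sel_b = groups
    res_a = structure.resolve(sel_a)
    res_b = structure.resolve(sel_b)
    if set(res_a) & set(res_b):
        raise ValueError("contact groups must be disjoint")
    ia = structure.atom_indices(res_a, heavy_only=True)
    ib = structure.atom_indices(res_b, heavy_only=True)
    f = _frames_of(traj)

    from scipy.spatial import cKDTree

    counts: dict = {}
    for t in range(len(f)):
        tree = cKDTree(f[t, ib])
        hits = tree.query_ball_point(f[t, ia], r=cutoff)
        for k, js in enumerate(hits):
            ra = structure.residue_of_atom(ia[k])
            for j in js:
                rb = structure.residue_of_atom(ib[j])
                key = (ra, rb)
                counts[key] = counts.get(key, 0) + 1

    g = nx.Graph()
    for (ra, rb), c in counts.items():
        g.add_edge(ra, rb, count=c)
    return ContactNetwork(graph=g, cutoff=cutoff,
                          source="frame" if len(f) == 1 else "trajectory")


def _atoms_by_category(structure, residue, frame):
    idx = structure.atom_indices([residue])
    resname = str(structure.atoms.res_name[idx[0]]) if len(idx) else ""
    anionic, cationic, polar = [], [], []
    for i in idx:
        name = str(structure.atoms.atom_name[i])
        elem = str(structure.atoms.element[i])
        if name in ANIONIC_ATOMS.get(resname, ()) or name == "OXT":
            anionic.append(i)
        if name in CATIONIC_ATOMS.get(resname, ()):
            cationic.append(i)
        if elem in ("N", "O"):
            polar.append(i)
    return anionic, cationic, polar


def classify_interaction(structure: StructureModel, frame, res_a, res_b,
                         salt_cutoff: float = 4.0,
                         hbond_cutoff: float = 3.5) -> str:
    """Assign one interaction class to a residue pair.

    salt_bridge: anionic side-chain O (Asp/Glu/OXT) within ``salt_cutoff``
    of a cationic side-chain N (Arg/Lys/His+); else hbond: any
    donor–acceptor N/O pair within ``hbond_cutoff``; else vdW.
    """
    f = _frames_of(frame)[0]
    an_a, cat_a, pol_a = _atoms_by_category(structure, res_a, f)
    an_b, cat_b, pol_b = _atoms_by_category(structure, res_b, f)

    def any_close(ii, jj, r):
        return any(
            np.linalg.norm(f[i] - f[j]) <= r
            for i, j in itertools.product(ii, jj)
        )

    if any_close(an_a, cat_b, salt_cutoff) or any_close(an_b, cat_a, salt_cutoff):
        return "salt_bridge"
    if any_close(pol_a, pol_b, hbond_cutoff):
        return "hbond"
    return "vdW"


def classify_network(network: ContactNetwork, structure: StructureModel,
                     frame, **kwargs) -> ContactNetwork:
    """Label every edge of a contact network with its interaction class."""
    for a, b in network.graph.edges():
        network.graph.edges[a, b]["interaction"] = classify_interaction(
            structure, frame, a, b, **kwargs
        )
    return network


def representative_frame(pmf, coord_values) -> int:
    """Frame for interface-network extraction: the one nearest (in
    reaction-coordinate space) to the center of the PMF's global-minimum
    bin.

    ``coord_values`` is (n_frames,) or (n_frames, d) matching the PMF's
    dimensionality.
    """
    f = pmf.free_energy
    j = int(np.nanargmin(f))
    if len(pmf.shape) == 2:
        jj = np.unravel_index(j, pmf.shape)
        center = np.array([pmf.bin_centers[k][jj[k]] for k in range(2)])
    else:
        center = np.array([pmf.bin_centers[0][j]])
    v = np.asarray(coord_values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    return int(np.argmin(np.linalg.norm(v - center, axis=1)))


# ---------------------------------------------------------------------------
# binding-energy aggregation

def binding_energy_difference(energies: dict) -> BindingEnergySummary:
    """Aggregate per-complex binding energies and their differences.

    ``energies`` maps a complex name to either per-frame values or a
    precomputed mean (scalar).  SDs are population SDs over frames where
    frames are supplied; differences are mean_i − mean_j for every
    ordered pair.
    """
    if len(energies) < 2:
        raise ValueError("need at least two complexes to compare")
    means, sds, nf = {}, {}, {}
    for name, v in energies.items():
        arr = np.atleast_1d(np.asarray(v, dtype=float))
        if arr.size == 0:
            raise ValueError(f"empty energy table for {name!r}")
        means[name] = float(arr.mean())
        sds[name] = float(arr.std()) if arr.size > 1 else 0.0
        nf[name] = int(arr.size)
    diffs = {
        (a, b): means[a] - means[b]
        for a in means for b in means if a != b
    }
    return BindingEnergySummary(means=means, sds=sds, n_frames=nf,
                                differences=diffs)
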