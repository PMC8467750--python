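"""Distances, RMSF, contact networks and binding-energy aggregation."""

import itertools
import math

import numpy as np
import pytest

from gamdlite import structure_analysis as sa
from gamdlite import synthetic_data as sd
from conftest import random_rotation


def brute_force_contacts(coords, structure, res_a, res_b, cutoff):
    """O(N^2) all-pairs oracle for residue contact detection."""
    ia = structure.atom_indices(res_a, heavy_only=True)
    ib = structure.atom_indices(res_b, heavy_only=True)
    edges = {}
    for i, j in itertools.product(ia, ib):
        if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
            key = (structure.residue_of_atom(i), structure.residue_of_atom(j))
            edges[key] = edges.get(key, 0) + 1
    return {tuple(sorted(k)): v for k, v in edges.items()}


def random_structure(rng, n_atoms=120):
    """Random two-chain point cloud for oracle comparisons."""
    import biotite.structure as struc

    atoms = struc.AtomArray(n_atoms)
    atoms.coord = rng.uniform(0, 25, (n_atoms, 3))
    half = n_atoms // 2
    atoms.chain_id = np.array(["A"] * half + ["B"] * (n_atoms - half))
    atoms.res_id = np.array([1 + i // 4 for i in range(n_atoms)])
    atoms.res_name = np.array(["ALA"] * n_atoms)
    atoms.atom_name = np.array(
        [f"C{i % 4}" if i % 4 else "CA" for i in range(n_atoms)])
    atoms.element = np.array(["C"] * n_atoms)
    return sa.StructureModel(atoms, {}, mg_chain="B", ligand_chain="Z")


class TestComBackboneDistance:
    def test_identical_selections_zero(self, complex_fixture):
        m, tr = complex_fixture.structure, complex_fixture.trajectory
        s = sa.com_backbone_distance(tr, m, "3.50", "3.50")
        assert np.all(s.values == 0.0)

    def test_three_four_five(self):
        """Two single backbone centers 3-4-5 apart give exactly 5 Å."""
        import biotite.structure as struc

        atoms = struc.AtomArray(6)
        base = np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
        coords = []
        for c in base:
            for off in ([0.4, 0, 0], [-0.2, 0.35, 0], [-0.2, -0.35, 0]):
                coords.append(c + np.array(off))
        atoms.chain_id = np.array(["A"] * 3 + ["B"] * 3)
        atoms.res_id = np.array([1] * 3 + [2] * 3)
        atoms.res_name = np.array(["GLY"] * 6)
        atoms.atom_name = np.array(["CA", "N", "C"] * 2)
        atoms.element = np.array(["C", "N", "C"] * 2)
        m = sa.StructureModel(atoms, {}, mg_chain="B", ligand_chain="Z")
        traj = np.asarray(coords, dtype=float)[None]
        s = sa.com_backbone_distance(traj, m, [("A", 1)], [("B", 2)])
        assert s.values[0] == pytest.approx(5.0, abs=1e-12)

    def test_matches_mean_coordinate_oracle(self, complex_fixture):
        m, tr = complex_fixture.structure, complex_fixture.trajectory
        s = sa.com_backbone_distance(tr, m, ["7.49", "7.50", "7.53"],
                                     "alpha5_hook")
        ia = m.backbone_indices(["7.49", "7.50", "7.53"])
        ib = m.backbone_indices("alpha5_hook")
        for t in (0, 50, 119):
            ca = np.array([tr[t, i] for i in ia]).mean(axis=0)
            cb = np.array([tr[t, i] for i in ib]).mean(axis=0)
            assert s.values[t] == pytest.approx(
                float(np.linalg.norm(ca - cb)), abs=1e-9)

    def test_unresolvable_label_raises(self, complex_fixture):
        m, tr = complex_fixture.structure, complex_fixture.trajectory
        with pytest.raises(sa.SelectionError, match="5.46"):
            sa.com_backbone_distance(tr, m, "5.46", "3.50")


class TestNamedDistances:
    def test_planted_tm3_tm6_geometry(self, complex_fixture):
        m, tr, key = (complex_fixture.structure, complex_fixture.trajectory,
                      complex_fixture.key)
        s = sa.tm3_tm6_distance(tr, m)
        assert np.allclose(s.values, key["tm3_tm6"], atol=1e-9)

    def test_bound_state_ligand_distance(self, complex_fixture):
        """Fully-bound fixture sits at the ~3 Å salt-bridge distance."""
        m, tr, key = (complex_fixture.structure, complex_fixture.trajectory,
                      complex_fixture.key)
        s = sa.d332_ligand_distance(tr, m)
        assert np.allclose(s.values, key["d332_ligand"], atol=1e-9)
        assert s.values[0] == pytest.approx(3.0, abs=1e-9)

    def test_gi_orientation_ordering(self):
        """Gi-like fixture: hook closer to TM2 than to TM6."""
        fx = sd.synth_complex_trajectory(n_frames=100, seed=3,
                                         orientation="gi")
        m, tr = fx.structure, fx.trajectory
        a5tm2 = sa.alpha5_tm2_distance(tr, m).values[0]
        a5tm6 = sa.com_backbone_distance(tr, m, "alpha5_hook", "6.30").values[0]
        assert a5tm2 == pytest.approx(fx.key["alpha5_tm2"], abs=1e-9)
        assert a5tm2 < a5tm6

    def test_npxxy_alpha5_matches_key(self, complex_fixture):
        m, tr, key = (complex_fixture.structure, complex_fixture.trajectory,
                      complex_fixture.key)
        s = sa.npxxy_alpha5_distance(tr, m)
        assert s.values[0] == pytest.approx(key["npxxy_alpha5"], abs=1e-9)

    def test_rigid_body_invariance(self, complex_fixture):
        """All distances invariant under per-frame rotation+translation."""
        m, tr = complex_fixture.structure, complex_fixture.trajectory
        rng = np.random.default_rng(12)
        moved = tr.copy()
        for t in range(len(moved)):
            q = random_rotation(rng)
            moved[t] = moved[t] @ q.T + rng.uniform(-40, 40, 3)
        for fn in (sa.tm3_tm6_distance, sa.d332_ligand_distance,
                   sa.npxxy_alpha5_distance, sa.alpha5_tm2_distance):
            ref = fn(tr, m).values
            got = fn(moved, m).values
            assert np.allclose(got, ref, atol=1e-9)


class TestRMSF:
    def test_static_trajectory_zero(self, complex_fixture):
        m, tr = complex_fixture.structure, complex_fixture.trajectory
        static = np.repeat(tr[:1], 10, axis=0)
        prof = sa.compute_rmsf([static], m)
        assert np.allclose(prof.values, 0.0, atol=1e-9)

    def test_isotropic_jitter_sigma_sqrt3(self):
        """Isotropic per-axis jitter sigma gives RMSF = sigma*sqrt(3)."""
        sigma = 0.4
        fx = sd.synth_complex_trajectory(n_frames=10_000, seed=21,
                                         jitter_sigma=sigma, p_unbind=0.0)
        prof = sa.compute_rmsf([fx.trajectory], fx.structure)
        expected = sigma * math.sqrt(3.0)
        # profile mean tight; individual residues pick up superposition
        # lever-arm noise proportional to their distance from the centroid
        assert prof.values.mean() == pytest.approx(expected, rel=0.02)
        assert np.all(np.abs(prof.values / expected - 1.0) < 0.05)

    def test_rigid_translation_removed_by_alignment(self, complex_fixture):
        m, tr = complex_fixture.structure, complex_fixture.trajectory
        rng = np.random.default_rng(13)
        fx = sd.synth_complex_trajectory(n_frames=200, seed=22,
                                         jitter_sigma=0.2, p_unbind=0.0)
        base = fx.trajectory
        shifted = base + rng.uniform(-30, 30, (len(base), 1, 3))
        ref = sa.compute_rmsf([base], fx.structure)
        got = sa.compute_rmsf([shifted], fx.structure)
        assert np.allclose(got.values, ref.values, atol=1e-6)

    def test_replica_average_is_mean_of_profiles(self):
        fxs = [sd.synth_complex_trajectory(n_frames=150, seed=s,
                                           jitter_sigma=0.3)
               for s in (31, 32, 33)]
        m = fxs[0].structure
        trajs = [fx.trajectory for fx in fxs]
        combined = sa.compute_rmsf(trajs, m)
        singles = [sa.compute_rmsf([t], m).values for t in trajs]
        assert np.allclose(combined.values, np.mean(singles, axis=0),
                           atol=1e-12)
        assert combined.replica_averaged

    def test_single_frame_rejected(self, complex_fixture):
        m, tr = complex_fixture.structure, complex_fixture.trajectory
        with pytest.raises(ValueError):
            sa.compute_rmsf([tr[:1]], m)


class TestContacts:
    def test_threshold_straddle(self):
        rng = np.random.default_rng(0)
        m = random_structure(rng, 8)
        coords = np.zeros((8, 3))
        coords[4:] += np.array([4.9, 0, 0])  # chain B block
        a = [( "A", r) for r in {1, 2}]
        b = [("B", r) for r in {2, 3}]
        a = [cr for cr in m.residues() if cr[0] == "A"]
        b = [cr for cr in m.residues() if cr[0] == "B"]
        net5 = sa.detect_contacts(coords, m, (a, b), 5.0)
        net4 = sa.detect_contacts(coords, m, (a, b), 4.0)
        assert len(net5.edge_set()) > 0
        assert len(net4.edge_set()) == 0

    def test_planted_interface_edges_exact(self, complex_fixture):
        m, tr, key = (complex_fixture.structure, complex_fixture.trajectory,
                      complex_fixture.key)
        rec = [cr for cr in m.residues() if cr[0] == "R"]
        mg = [cr for cr in m.residues() if cr[0] == "G"]
        net = sa.detect_contacts(tr[0], m, (rec, mg), 5.0)
        planted = {
            tuple(sorted(((c["res_a"][0], c["res_a"][1]),
                          (c["res_b"][0], c["res_b"][1]))))
            for c in key["contacts"]
        }
        assert net.edge_set() == planted
        assert len(planted) == 7

    def test_monotone_in_cutoff(self, complex_fixture):
        m, tr = complex_fixture.structure, complex_fixture.trajectory
        rec = [cr for cr in m.residues() if cr[0] == "R"]
        mg = [cr for cr in m.residues() if cr[0] == "G"]
        e4 = sa.detect_contacts(tr[0], m, (rec, mg), 4.0).edge_set()
        e5 = sa.detect_contacts(tr[0], m, (rec, mg), 5.0).edge_set()
        assert e4 <= e5
        assert len(e4) < len(e5)  # the 4.5 Å planted pair separates them

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_structure(rng, n_atoms=120)
        coords = m.atoms.coord.astype(float)
        a = [cr for cr in m.residues() if cr[0] == "A"]
        b = [cr for cr in m.residues() if cr[0] == "B"]
        cutoff = rng.uniform(3.0, 7.0)
        net = sa.detect_contacts(coords, m, (a, b), cutoff)
        oracle = brute_force_contacts(coords, m, a, b, cutoff)
        assert net.edge_set() == set(oracle)
        for edge, count, _cls in net.edges():
            assert count == oracle[edge]

    def test_overlapping_selections_rejected(self, complex_fixture):
        m, tr = complex_fixture.structure, complex_fixture.trajectory
        rec = [cr for cr in m.residues() if cr[0] == "R"]
        with pytest.raises(ValueError):
            sa.detect_contacts(tr[0], m, (rec, rec[:3]), 5.0)


class TestClassification:
    def test_planted_classes_recovered(self, complex_fixture):
        m, tr, key = (complex_fixture.structure, complex_fixture.trajectory,
                      complex_fixture.key)
        rec = [cr for cr in m.residues() if cr[0] == "R"]
        mg = [cr for cr in m.residues() if cr[0] == "G"]
        net = sa.detect_contacts(tr[0], m, (rec, mg), 5.0)
        sa.classify_network(net, m, tr[0])
        expected = {
            tuple(sorted(((c["res_a"][0], c["res_a"][1]),
                          (c["res_b"][0], c["res_b"][1])))): c["class"]
            for c in key["contacts"]
        }
        got = {edge: cls for edge, _count, cls in net.edges()}
        assert got == expected

    def test_every_edge_gets_exactly_one_class(self, complex_fixture):
        m, tr = complex_fixture.structure, complex_fixture.trajectory
        rec = [cr for cr in m.residues() if cr[0] == "R"]
        mg = [cr for cr in m.residues() if cr[0] == "G"]
        net = sa.classify_network(
            sa.detect_contacts(tr[0], m, (rec, mg), 5.0), m, tr[0])
        for _edge, _count, cls in net.edges():
            assert cls in ("vdW", "hbond", "salt_bridge")


class TestRepresentativeFrame:
    def test_frame_nearest_global_minimum_bin(self):
        from gamdlite import reweighting as rw

        rng = np.random.default_rng(4)
        coords = np.concatenate([rng.normal(3.0, 0.2, 900),
                                 rng.normal(8.0, 0.2, 100)])
        pmf = rw.reweight_pmf(coords, np.zeros(1000), 300.0,
                              bin_width=1.0, cutoff=10)
        idx = sa.representative_frame(pmf, coords)
        j = np.nanargmin(pmf.free_energy)
        center = pmf.bin_centers[0][j]
        assert abs(coords[idx] - center) == np.abs(coords - center).min()
        assert 2.0 < coords[idx] < 4.0  # dominant well


class TestBindingEnergies:
    # per-complex MM/GBSA means of histamine in receptor-miniG systems
    TABLE = {
        "H2R-mGs": -17.23, "H2R-mGsi": -16.57, "H2R-mGsq": -16.25,
        "H4R-mGs": -20.03, "H4R-mGsi": -27.91, "H4R-mGsq": -20.49,
    }

    def test_h4r_differences(self):
        """mGsi binds histamine 7.88 / 7.42 kcal/mol tighter than mGs/mGsq."""
        summary = sa.binding_energy_difference(self.TABLE)
        assert summary.difference("H4R-mGs", "H4R-mGsi") == pytest.approx(7.88)
        assert summary.difference("H4R-mGsq", "H4R-mGsi") == pytest.approx(7.42)

    def test_identical_complexes_zero_difference(self):
        s = sa.binding_energy_difference({"a": [-5.0, -6.0], "b": [-5.0, -6.0]})
        assert s.difference("a", "b") == 0.0
        assert s.sds["a"] == pytest.approx(0.5)
        assert s.n_frames["a"] == 2

    def test_difference_antisymmetry(self):
        s = sa.binding_energy_difference(self.TABLE)
        for a in self.TABLE:
            for b in self.TABLE:
                if a != b:
                    assert s.difference(a, b) == -s.difference(b, a)

    def test_single_complex_rejected(self):
        with pytest.raises(ValueError):
            sa.binding_energy_difference({"only": [-1.0]})
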