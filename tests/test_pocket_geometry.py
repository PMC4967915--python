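"""Structure analytics: PDB I/O, distances, RMSD/RMSF, gate, cavity, H-bonds."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import calyxsim as cs
from calyxsim.pocket_geometry import Structure

PDB_3ATOMS = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.100   1.400   0.000  1.00  0.00           C
END
"""

PDB_2MODELS = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.000   4.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       0.000   0.000   1.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.000   4.000   1.000  1.00  0.00           C
ENDMDL
END
"""


class TestStructureIO:
    def test_read_hand_written_pdb(self, tmp_path):
        path = tmp_path / "three.pdb"
        path.write_text(PDB_3ATOMS)
        s = cs.read_structure(path)
        assert s.n_atoms == 3 and s.n_models == 1
        np.testing.assert_allclose(s.coords[0, 1], [1.5, 0.0, 0.0])
        assert list(s.names) == ["N", "CA", "C"]

    def test_multi_model_becomes_frames(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(PDB_2MODELS)
        s = cs.read_structure(path)
        assert s.n_models == 2
        assert s.coords[1, 0, 2] == pytest.approx(1.0)

    def test_toy_calyx_round_trip(self, toy_calyx, tmp_path):
        path = tmp_path / "calyx.pdb"
        cs.write_structure(toy_calyx.structure, path)
        back = cs.read_structure(path)
        assert back.n_atoms == toy_calyx.structure.n_atoms
        np.testing.assert_allclose(back.coords, toy_calyx.structure.coords,
                                   atol=1e-3)

    def test_unparseable_file_raises(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("ATOM      1  N   ALA A   1  garbage\n")
        with pytest.raises(ValueError, match="bad.pdb"):
            cs.read_structure(path)

    def test_unknown_element_gets_default_radius(self):
        with pytest.warns(UserWarning, match="unknown element"):
            s = Structure.from_arrays(
                names=["Q1"], elements=["Xq"], resnames=["UNK"],
                resnums=[1], coords=np.zeros((1, 1, 3)))
        assert s.radii[0] == pytest.approx(1.70)


class TestCaDistance:
    def _two_ca(self):
        return Structure.from_arrays(
            names=["CA", "CA"], elements=["C", "C"],
            resnames=["GLY", "TYR"], resnums=[93, 141],
            coords=np.array([[[0.0, 0, 0], [3.0, 4.0, 0]]]))

    def test_three_four_five(self):
        assert cs.ca_distance(self._two_ca(), 93, 141) == pytest.approx(5.0)

    def test_same_residue_zero(self):
        assert cs.ca_distance(self._two_ca(), 93, 93) == 0.0

    def test_missing_ca_named(self):
        with pytest.raises(ValueError, match="999"):
            cs.ca_distance(self._two_ca(), 93, 999)


class TestSuperposeRMSD:
    def test_rigid_motion_gives_zero(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(50, 3))
        R = Rotation.random(random_state=1).as_matrix()
        mobile = ref @ R.T + [1.0, -2.0, 0.5]
        rmsd, _ = cs.superpose_rmsd(ref, mobile)
        assert rmsd < 1e-6

    def test_single_displaced_atom_closed_form(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(100, 3))
        mobile = ref.copy()
        mobile[0] += [1.0, 0.0, 0.0]
        rmsd, _ = cs.superpose_rmsd(ref, mobile)
        # sqrt(d^2/n) up to the (small) re-fit of centroid and rotation
        assert rmsd == pytest.approx(0.1, rel=0.02)

    def test_mirror_image_not_matched(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(30, 3))
        mirror = ref.copy()
        mirror[:, 0] *= -1
        rmsd, R = cs.superpose_rmsd(ref, mirror)
        assert rmsd > 0.1
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(40, 3))
        mobile = ref + 0.3 * rng.normal(size=(40, 3))
        rmsd, _ = cs.superpose_rmsd(ref, mobile)
        refc = ref - ref.mean(axis=0)
        mobc = mobile - mobile.mean(axis=0)
        _, rssd = Rotation.align_vectors(refc, mobc)
        assert rmsd == pytest.approx(rssd / np.sqrt(40), rel=1e-6)

    def test_too_few_atoms(self):
        with pytest.raises(ValueError):
            cs.superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestWindowedRMSF:
    def _traj(self, frames):
        n = frames.shape[1]
        return Structure.from_arrays(
            names=["CA"] * n, elements=["C"] * n, resnames=["GLY"] * n,
            resnums=list(range(1, n + 1)), coords=frames)

    def test_static_trajectory_zero(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(60, 3))
        frames = np.repeat(base[None], 8, axis=0)
        mean, se = cs.windowed_rmsf(self._traj(frames), n_windows=2)
        assert np.allclose(mean, 0.0, atol=1e-9)

    def test_square_wave_oscillation_equals_amplitude(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(100, 3)) * 5
        frames = np.repeat(base[None], 8, axis=0).copy()
        d = 0.7
        frames[::2, 0, 0] += d
        frames[1::2, 0, 0] -= d
        mean, _ = cs.windowed_rmsf(self._traj(frames), n_windows=1)
        assert mean[0] == pytest.approx(d, rel=0.02)

    def test_single_window_zero_se(self):
        rng = np.random.default_rng(6)
        frames = rng.normal(size=(4, 20, 3))
        _, se = cs.windowed_rmsf(self._traj(frames), n_windows=1)
        assert np.all(se == 0.0)

    def test_more_windows_than_frames(self):
        frames = np.zeros((3, 10, 3))
        with pytest.raises(ValueError):
            cs.windowed_rmsf(self._traj(frames), n_windows=5)


class TestGateMetrics:
    def test_toy_gate_gap_recovered(self):
        calyx = cs.make_toy_calyx(gate_gap=4.0)
        gm = cs.gate_metrics(calyx.structure,
                             cs.GateSpec(gate_residues=calyx.gate_residues))
        assert gm["min_distance"] == pytest.approx(4.0, abs=1e-9)

    def test_touching_gate_zero(self):
        calyx = cs.make_toy_calyx(gate_gap=0.0)
        gm = cs.gate_metrics(calyx.structure,
                             cs.GateSpec(gate_residues=calyx.gate_residues))
        assert gm["min_distance"] == 0.0

    def test_absent_gate_residue_raises(self, toy_calyx):
        with pytest.raises(ValueError, match="999"):
            cs.gate_metrics(toy_calyx.structure,
                            cs.GateSpec(gate_residues=(102, 999)))


class TestCavityVolumes:
    def _measure(self, calyx, **overrides):
        cfg = cs.CavityConfig(seed_point=tuple(calyx.seed_point), **overrides)
        return cs.cavity_volumes(
            calyx.structure, cs.GateSpec(gate_residues=calyx.gate_residues),
            cfg)

    def test_volume_matches_semi_analytic_oracle(self, toy_calyx):
        cav = self._measure(toy_calyx)
        assert cav.total == pytest.approx(toy_calyx.free_volume_total,
                                          rel=0.05)
        assert cav.upper == pytest.approx(toy_calyx.free_volume_upper,
                                          rel=0.07)
        assert cav.lower == pytest.approx(toy_calyx.free_volume_lower,
                                          rel=0.07)

    def test_recessed_gate_matches_cylinder_formula(self):
        calyx = cs.make_toy_calyx(gate_gap=2 * (4.0 + 1.52 + 1.4))
        cav = self._measure(calyx)
        assert cav.total == pytest.approx(calyx.cylinder_volume, rel=0.05)

    def test_sealed_gate_zero_lower_volume(self):
        calyx = cs.make_toy_calyx(gate_gap=0.0)
        cav = self._measure(calyx)
        assert cav.lower == 0.0
        assert cav.upper > 0.0

    def test_partition_is_exact_in_counts(self, toy_calyx):
        cav = self._measure(toy_calyx)
        assert cav.n_total == cav.n_upper + cav.n_lower
        assert cav.total == pytest.approx(cav.upper + cav.lower, abs=1e-9)

    def test_porous_wall_below_probe_still_closed(self):
        calyx = cs.make_toy_calyx(bead_spacing=2.5)
        cav = self._measure(calyx)
        assert cav.n_total < 10_000  # flood fill stayed inside the barrel

    def test_monotone_in_probe_radius(self, toy_calyx):
        vols = [self._measure(toy_calyx, probe=p).total
                for p in (1.2, 1.4, 1.6)]
        assert vols[0] >= vols[1] >= vols[2]

    def test_grid_refinement_reduces_error(self, toy_calyx):
        err = []
        for grid in (0.5, 0.25):
            cav = self._measure(toy_calyx, grid=grid)
            err.append(abs(cav.total - toy_calyx.free_volume_total))
        assert err[1] <= err[0]

    def test_rigid_motion_invariance(self, toy_calyx):
        cav0 = self._measure(toy_calyx)
        R = Rotation.random(random_state=8).as_matrix()
        shift = np.array([3.0, -2.0, 5.0])
        s = toy_calyx.structure
        moved = Structure.from_arrays(
            names=s.names, elements=s.elements, resnames=s.resnames,
            resnums=s.resnums, coords=s.coords @ R.T + shift)
        seed = np.asarray(toy_calyx.seed_point) @ R.T + shift
        cfg = cs.CavityConfig(seed_point=tuple(seed))
        cav1 = cs.cavity_volumes(
            moved, cs.GateSpec(gate_residues=toy_calyx.gate_residues), cfg)
        # distances are exactly invariant; grid counting re-aligns to the
        # world axes, so volumes agree only to a few grid cells
        gm0 = cs.gate_metrics(s, cs.GateSpec(gate_residues=(102, 147)))
        gm1 = cs.gate_metrics(moved, cs.GateSpec(gate_residues=(102, 147)))
        assert gm1["min_distance"] == pytest.approx(gm0["min_distance"],
                                                    rel=1e-6)
        assert cav1.total == pytest.approx(cav0.total, rel=0.05)

    def test_seed_inside_atom_rejected(self, toy_calyx):
        atom0 = tuple(toy_calyx.structure.coords[0, 0])
        cfg = cs.CavityConfig(seed_point=atom0)
        with pytest.raises(ValueError, match="seed"):
            cs.cavity_volumes(toy_calyx.structure,
                              cs.GateSpec(gate_residues=(102, 147)), cfg)

    def test_unenclosed_pocket_hits_cap(self):
        calyx = cs.make_toy_calyx()
        cfg = cs.CavityConfig(seed_point=tuple(calyx.seed_point),
                              buriedness_min=0, max_points=500)
        # without the buriedness filter the fill escapes into bulk
        with pytest.raises(RuntimeError, match="not enclosed"):
            cs.cavity_volumes(
                cs.make_toy_calyx(open_top=True).structure,
                cs.GateSpec(gate_residues=(102, 147)), cfg)


class TestHbondOccupancy:
    def _fixture(self, acceptor_x):
        """Donor O at origin with H towards +x; acceptor O per frame."""
        n_frames = len(acceptor_x)
        coords = np.zeros((n_frames, 3, 3))
        coords[:, 1, 0] = 1.0                      # H
        coords[:, 2, 0] = np.asarray(acceptor_x)   # acceptor
        return Structure.from_arrays(
            names=["OG", "HG", "O"], elements=["O", "H", "O"],
            resnames=["SER", "SER", "HOH"], resnums=[1, 1, 2],
            coords=coords)

    def test_ideal_geometry_always_bonded(self):
        s = self._fixture([2.8] * 10)
        out = cs.hbond_occupancy(s, donors=[0], acceptors=[2])
        assert out["occupancy"].iloc[0] == 100.0

    def test_far_pair_never_bonded(self):
        s = self._fixture([6.0] * 10)
        out = cs.hbond_occupancy(s, donors=[0], acceptors=[2])
        assert out["occupancy"].iloc[0] == 0.0

    def test_designed_schedule_recovered(self):
        xs = [2.8] * 9 + [6.0]
        s = self._fixture(xs)
        out = cs.hbond_occupancy(s, donors=[0], acceptors=[2])
        assert out["occupancy"].iloc[0] == pytest.approx(90.0)

    def test_angle_criterion_rejects_bent_bond(self):
        s = self._fixture([2.8] * 4)
        # move the acceptor sideways: D-A distance kept, D-H...A angle ~90
        coords = s.coords.copy()
        coords[:, 2] = [0.0, 2.8, 0.0]
        bent = Structure.from_arrays(
            names=s.names, elements=s.elements, resnames=s.resnames,
            resnums=s.resnums, coords=coords)
        out = cs.hbond_occupancy(bent, donors=[0], acceptors=[2])
        assert out["occupancy"].iloc[0] == 0.0

    def test_empty_selection_rejected(self):
        s = self._fixture([2.8])
        with pytest.raises(ValueError):
            cs.hbond_occupancy(s, donors=[], acceptors=[2])
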