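"""Descriptor operators vs brute-force oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from myoadp.constants import R_CAL
from myoadp.trajectory import (ADP_DIHEDRALS, DihedralMap, DihedralSpec, LieTable,
                               Trajectory, com_distance_series, compute_dihedrals,
                               conformational_entropy, dihedral_from_positions,
                               dihedral_map, group_vector_angle,
                               linear_interaction_energy, modal_distance,
                               occupancy_grid, percent_coverage,
                               residue_contact_fractions, rmsd_to_reference, rmsf,
                               salt_bridge_persistence, select_pocket_residues,
                               select_seed_frames)
from conftest import make_topology


def random_rigid_transform(rng):
    rot = Rotation.random(random_state=int(rng.integers(2 ** 16))).as_matrix()
    shift = rng.uniform(-5, 5, 3)
    return rot, shift


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------

class TestRmsd:
    def test_identical_frames_give_zero(self, random_trajectory):
        ref = random_trajectory.coords[3].copy()
        traj = Trajectory(np.repeat(ref[None], 5, axis=0), random_trajectory.topology)
        assert np.allclose(rmsd_to_reference(traj, ref), 0.0, atol=1e-10)

    def test_rigid_transform_is_removed_by_superposition(self, random_trajectory, rng):
        ref = random_trajectory.coords[0]
        frames = []
        for _ in range(4):
            rot, shift = random_rigid_transform(rng)
            frames.append(ref @ rot.T + shift)
        traj = Trajectory(np.array(frames), random_trajectory.topology)
        assert np.all(rmsd_to_reference(traj, ref) < 1e-6)

    def test_small_case_matches_independent_kabsch(self, rng):
        """3-atom toy vs scipy's align_vectors as independent superposition."""
        top = make_topology(3, [0, 0, 0])
        ref = rng.uniform(0, 5, (3, 3))
        frame = ref.copy()
        frame[0] += rng.normal(0, 1.0, 3)
        rot, shift = random_rigid_transform(rng)
        moved = frame @ rot.T + shift
        traj = Trajectory(moved[None], top)
        got = rmsd_to_reference(traj, ref)[0]
        # independent: scipy optimal rotation on centered clouds
        a = moved - moved.mean(axis=0)
        b = ref - ref.mean(axis=0)
        r_opt, _ = Rotation.align_vectors(b, a)
        d = r_opt.apply(a) - b
        expected = np.sqrt((d * d).sum() / 3)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_selection_mismatch_rejected(self, random_trajectory):
        with pytest.raises(ValueError):
            rmsd_to_reference(random_trajectory, random_trajectory.coords[0][:5])
        with pytest.raises(ValueError):
            rmsd_to_reference(random_trajectory, random_trajectory.coords[0],
                              selection=np.array([], dtype=int))


class TestRmsf:
    def test_static_trajectory_is_zero(self, random_trajectory):
        frame = random_trajectory.coords[0]
        traj = Trajectory(np.repeat(frame[None], 10, axis=0),
                          random_trajectory.topology)
        assert np.allclose(rmsf(traj), 0.0, atol=1e-10)

    def test_single_frame_rejected(self, random_trajectory):
        traj = Trajectory(random_trajectory.coords[:1], random_trajectory.topology)
        with pytest.raises(ValueError):
            rmsf(traj)

    def test_sinusoidal_atom_has_rms_amplitude_over_sqrt2(self):
        """One atom oscillating +/-a along x among many anchors -> a/sqrt(2)."""
        n_anchor, n_frames, a = 30, 400, 0.7
        rng = np.random.default_rng(1)
        anchors = rng.uniform(0, 20, (n_anchor, 3))
        coords = np.repeat(anchors[None], n_frames, axis=0)
        mobile = np.tile([25.0, 0.0, 0.0], (n_frames, 1))
        phase = 2 * np.pi * np.arange(n_frames) / n_frames
        mobile[:, 0] += a * np.sin(phase)
        coords = np.concatenate([coords, mobile[:, None, :]], axis=1)
        top = make_topology(n_anchor + 1, list(range(n_anchor + 1)))
        traj = Trajectory(coords, top)
        vals = rmsf(traj, align_selection=np.arange(n_anchor))
        assert vals[-1] == pytest.approx(a / np.sqrt(2), rel=0.02)
        assert np.all(vals[:-1] < 0.05)


# ---------------------------------------------------------------------------
# contacts & salt bridges
# ---------------------------------------------------------------------------

class TestContacts:
    def test_matches_brute_force_on_random_coordinates(self, random_trajectory):
        got = residue_contact_fractions(random_trajectory, cutoff=5.0)
        top = random_trajectory.topology
        for (ra, rb), frac in got.items():
            ia = top.index[(top["resid"] == ra) & (top["element"] != "H")].to_numpy()
            ib = top.index[(top["resid"] == rb) & (top["element"] != "H")].to_numpy()
            count = 0
            for f in range(random_trajectory.n_frames):
                dmin = min(np.linalg.norm(random_trajectory.coords[f, i]
                                          - random_trajectory.coords[f, j])
                           for i in ia for j in ib)
                count += dmin <= 5.0
            assert frac == pytest.approx(count / random_trajectory.n_frames)

    def test_always_within_cutoff_gives_one(self):
        top = make_topology(2, [0, 1])
        coords = np.zeros((8, 2, 3))
        coords[:, 1, 0] = 3.0
        traj = Trajectory(coords, top)
        assert residue_contact_fractions(traj)[(0, 1)] == 1.0

    def test_hydrogens_do_not_count(self):
        top = make_topology(3, [0, 0, 1], elements=["C", "H", "C"])
        coords = np.zeros((4, 3, 3))
        coords[:, 0, 0] = 0.0
        coords[:, 1, 0] = 8.0   # hydrogen close to residue 1
        coords[:, 2, 0] = 10.0  # heavy atoms 10 A apart
        traj = Trajectory(coords, top)
        assert residue_contact_fractions(traj)[(0, 1)] == 0.0


class TestSaltBridge:
    def _traj(self, dist_schedule):
        top = pd.DataFrame({
            "name": ["CB", "OD1", "CB", "NZ"],
            "element": ["C", "O", "C", "N"],
            "resid": [0, 0, 1, 1],
            "resname": ["ASP", "ASP", "LYS", "LYS"],
            "mass": [12.0] * 4,
            "charge": [0.0, -0.8, 0.0, 0.8],
        })
        coords = np.zeros((len(dist_schedule), 4, 3))
        coords[:, 0, 1] = 2.0
        coords[:, 2, 1] = -2.0
        for f, d in enumerate(dist_schedule):
            coords[f, 3, 0] = d
        return Trajectory(coords, top)

    def test_fixed_close_and_far(self):
        assert salt_bridge_persistence(self._traj([3.0] * 5), 0, 1) == 1.0
        assert salt_bridge_persistence(self._traj([6.0] * 5), 0, 1) == 0.0

    def test_schedule_fraction(self):
        sched = [3.0] * 30 + [6.0] * 70
        assert salt_bridge_persistence(self._traj(sched), 0, 1) == pytest.approx(0.30)

    def test_uncharged_residue_rejected(self):
        top = make_topology(2, [0, 1])
        traj = Trajectory(np.zeros((2, 2, 3)), top)
        with pytest.raises(ValueError):
            salt_bridge_persistence(traj, 0, 1)


# ---------------------------------------------------------------------------
# dihedrals / maps / entropy / coverage
# ---------------------------------------------------------------------------

class TestDihedrals:
    def test_planar_cis_is_zero(self):
        p = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]], dtype=float)
        assert dihedral_from_positions(p) == pytest.approx(0.0, abs=1e-10)

    def test_planar_trans_is_180(self):
        p = np.array([[-1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]], dtype=float)
        assert abs(dihedral_from_positions(p)) == pytest.approx(180.0, abs=1e-10)

    def test_random_points_match_independent_formula(self, rng):
        """Praxeolitic torsion formula as the independent oracle."""
        for _ in range(50):
            p = rng.uniform(-4, 4, (4, 3))
            b0 = p[0] - p[1]
            b1 = p[2] - p[1]
            b2 = p[3] - p[2]
            b1 = b1 / np.linalg.norm(b1)
            v = b0 - (b0 @ b1) * b1
            w = b2 - (b2 @ b1) * b1
            expected = -np.degrees(np.arctan2(np.cross(b1, v) @ w, v @ w))
            got = dihedral_from_positions(p)
            assert got == pytest.approx(expected, abs=1e-8)

    def test_collinear_flagged_nan(self):
        p = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], dtype=float)
        assert np.isnan(dihedral_from_positions(p))

    def test_compute_dihedrals_resolves_named_atoms(self):
        names = ["O1B", "PB", "O3A", "PA"]
        top = make_topology(4, [0] * 4, names=names)
        coords = np.array([[[1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]]], dtype=float)
        traj = Trajectory(coords, top)
        df = compute_dihedrals(traj, [ADP_DIHEDRALS[0]])
        assert df["theta1"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_missing_atom_rejected(self):
        top = make_topology(4, [0] * 4)
        traj = Trajectory(np.zeros((1, 4, 3)), top)
        with pytest.raises(ValueError):
            compute_dihedrals(traj, [DihedralSpec("x", ("A", "B", "C", "D"))])


class TestDihedralMap:
    def test_single_pair_occupies_one_bin(self):
        m = dihedral_map(np.full(9, 12.0), np.full(9, -33.0))
        assert (m.counts > 0).sum() == 1
        assert m.probability.max() == 1.0
        assert m.counts.shape == (72, 72)

    def test_two_state_70_30_masses(self):
        x = np.array([10.0] * 70 + [100.0] * 30)
        m = dihedral_map(x, x)
        assert sorted(m.probability[m.probability > 0]) == pytest.approx([0.3, 0.7])

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            dihedral_map(np.array([]), np.array([]))

    def test_bin_width_must_divide_360(self):
        with pytest.raises(ValueError):
            dihedral_map(np.zeros(5), np.zeros(5), bin_width=7.0)

    def test_uniform_sampling_near_uniform_probability(self, rng):
        x = rng.uniform(-180, 180, 200_000)
        y = rng.uniform(-180, 180, 200_000)
        m = dihedral_map(x, y)
        assert percent_coverage(m) == 100.0
        assert m.probability.max() < 5.0 / 5184


class TestEntropyCoverage:
    def test_single_bin_entropy_zero(self):
        m = dihedral_map(np.zeros(10), np.zeros(10))
        assert conformational_entropy(m) == 0.0
        assert percent_coverage(m) == pytest.approx(100.0 / 5184)

    def test_two_equal_bins_r_ln2(self):
        x = np.array([0.0] * 5 + [90.0] * 5)
        m = dihedral_map(x, x)
        assert conformational_entropy(m) == pytest.approx(R_CAL * np.log(2), rel=1e-12)

    def test_uniform_map_is_maximal(self):
        m = DihedralMap(labels=("a", "b"), bin_width=5.0,
                        counts=np.ones((72, 72), dtype=int))
        s_max = conformational_entropy(m)
        assert s_max == pytest.approx(R_CAL * np.log(5184), rel=1e-12)
        # perturbation strictly lowers entropy
        c = np.ones((72, 72), dtype=int)
        c[0, 0] = 30
        s_pert = conformational_entropy(DihedralMap(("a", "b"), 5.0, c))
        assert s_pert < s_max

    def test_entropy_invariant_under_bin_relabeling(self, rng):
        c = rng.integers(0, 50, (72, 72))
        c[0, 0] += 1
        m1 = DihedralMap(("a", "b"), 5.0, c)
        perm = rng.permutation(72)
        m2 = DihedralMap(("a", "b"), 5.0, c[perm][:, perm])
        assert conformational_entropy(m1) == pytest.approx(
            conformational_entropy(m2), rel=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.integers(min_value=0, max_value=1000), min_size=4,
                    max_size=36 * 36).filter(lambda v: sum(v) > 0))
    def test_entropy_bounds_property(self, flat):
        n = int(np.sqrt(len(flat)))
        c = np.zeros((36, 36), dtype=int)
        c.flat[:len(flat)] = flat
        m = DihedralMap(("a", "b"), 10.0, c)
        s = conformational_entropy(m)
        assert 0.0 <= s <= R_CAL * np.log(m.n_bins) + 1e-9
        assert 0.0 < percent_coverage(m) <= 100.0


# ---------------------------------------------------------------------------
# interaction energies & pocket selection
# ---------------------------------------------------------------------------

class TestLie:
    def _pair_traj(self, r, q1, q2, sigma=3.0, eps=0.1):
        top = make_topology(2, [0, 1], charges=[q1, q2], sigma=sigma, epsilon=eps)
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = r
        return Trajectory(coords, top)

    def test_zero_charges_zero_epsilon_gives_zero(self):
        traj = self._pair_traj(3.0, 0.0, 0.0, eps=0.0)
        e = linear_interaction_energy(traj, [0], [1])
        assert e["combined"] == 0.0

    def test_unit_charges_at_3p32_angstrom(self):
        traj = self._pair_traj(3.32, 1.0, -1.0, eps=0.0)
        e = linear_interaction_energy(traj, [0], [1])
        assert e["electrostatic"] == pytest.approx(-332.0636 / 3.32, rel=1e-12)
        assert e["electrostatic"] == pytest.approx(-100.0, rel=2e-3)

    def test_lj_zero_crossing_at_sigma(self):
        traj = self._pair_traj(3.0, 0.0, 0.0, sigma=3.0, eps=0.5)
        e = linear_interaction_energy(traj, [0], [1])
        assert e["vdw"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_system(self, random_trajectory):
        traj = random_trajectory
        top = traj.topology
        res0 = traj.residue_atoms(0)
        lig = traj.residue_atoms(2)
        got = linear_interaction_energy(traj, res0, lig)
        elec = vdw = 0.0
        for f in range(traj.n_frames):
            for i in res0:
                for j in lig:
                    r = np.linalg.norm(traj.coords[f, i] - traj.coords[f, j])
                    elec += 332.0636 * top["charge"][i] * top["charge"][j] / r
                    sig = 0.5 * (top["sigma"][i] + top["sigma"][j])
                    ep = np.sqrt(top["epsilon"][i] * top["epsilon"][j])
                    vdw += 4 * ep * ((sig / r) ** 12 - (sig / r) ** 6)
        assert got["electrostatic"] == pytest.approx(elec / traj.n_frames, rel=1e-9)
        assert got["vdw"] == pytest.approx(vdw / traj.n_frames, rel=1e-9)
        assert got["combined"] == pytest.approx(got["electrostatic"] + got["vdw"])

    def test_missing_charges_rejected(self, random_trajectory):
        traj = Trajectory(random_trajectory.coords,
                          random_trajectory.topology.assign(charge=np.nan))
        with pytest.raises(ValueError):
            linear_interaction_energy(traj, [0], [5])


class TestPocketSelection:
    def test_empty_table_empty_set(self):
        t = LieTable(pd.DataFrame(columns=["resid", "ligand", "electrostatic",
                                           "vdw", "combined"]))
        assert select_pocket_residues(t) == set()

    def test_threshold_at_3kT_310K(self):
        rows = [{"resid": r, "ligand": "ADP", "electrostatic": e, "vdw": 0.0,
                 "combined": e} for r, e in [(1, -2.0), (2, -1.0), (3, -0.5)]]
        t = LieTable(pd.DataFrame(rows), temperature=310.0)
        # 3 kT at 310 K = 1.848 kcal/mol -> only resid 1 passes
        assert select_pocket_residues(t, threshold_kT=3.0) == {1}

    def test_either_ligand_group_qualifies(self):
        rows = [{"resid": 7, "ligand": "ADP", "electrostatic": -0.2, "vdw": 0.0,
                 "combined": -0.2},
                {"resid": 7, "ligand": "MG", "electrostatic": -5.0, "vdw": 0.0,
                 "combined": -5.0}]
        t = LieTable(pd.DataFrame(rows))
        assert select_pocket_residues(t) == {7}


# ---------------------------------------------------------------------------
# COM distances, modal distance, seed frames
# ---------------------------------------------------------------------------

class TestComDistance:
    def test_three_four_five(self):
        top = make_topology(2, [0, 1], masses=[1.0, 1.0])
        coords = np.array([[[0, 0, 0], [3, 4, 0]]], dtype=float)
        traj = Trajectory(coords, top)
        assert com_distance_series(traj, [0], [1])[0] == pytest.approx(5.0)

    def test_coincident_groups_zero(self, random_trajectory):
        idx = random_trajectory.residue_atoms(1)
        assert np.allclose(com_distance_series(random_trajectory, idx, idx), 0.0)

    def test_matches_explicit_mass_weighting(self, random_trajectory):
        traj = random_trajectory
        a, b = traj.residue_atoms(0), traj.residue_atoms(2)
        got = com_distance_series(traj, a, b)
        m = traj.topology["mass"].to_numpy()
        for f in range(traj.n_frames):
            ca = (traj.coords[f, a] * m[a, None]).sum(axis=0) / m[a].sum()
            cb = (traj.coords[f, b] * m[b, None]).sum(axis=0) / m[b].sum()
            assert got[f] == pytest.approx(np.linalg.norm(ca - cb), rel=1e-12)

    def test_zero_mass_rejected(self):
        top = make_topology(2, [0, 1], masses=[0.0, 1.0])
        traj = Trajectory(np.zeros((1, 2, 3)), top)
        with pytest.raises(ValueError):
            com_distance_series(traj, [0], [1])


class TestModalDistance:
    def test_constant_series(self):
        assert modal_distance(np.full(50, 3.6)) == pytest.approx(3.65)

    def test_bimodal_majority_wins(self):
        s = np.array([3.6] * 70 + [4.4] * 30)
        assert modal_distance(s) == pytest.approx(3.65)

    def test_exact_tie_takes_smaller_distance(self):
        s = np.array([3.6] * 50 + [4.4] * 50)
        assert modal_distance(s) == pytest.approx(3.65)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            modal_distance(np.array([]))


class TestSeedFrames:
    def test_six_replicates_yield_120(self, rng):
        series = {}
        for g, target in (("WT", 3.6), ("G256E", 4.4)):
            for rep in range(3):
                s = rng.uniform(target + 0.5, target + 3.0, 500)
                s[rng.choice(500, 60, replace=False)] = target + rng.uniform(
                    -0.09, 0.09, 60)
                series[(g, rep)] = s
        total = 0
        for key, s in series.items():
            target = 3.6 if key[0] == "WT" else 4.4
            picked = select_seed_frames({key: s}, target=target)[key]
            assert len(picked) == 20
            total += len(picked)
        assert total == 120

    def test_no_qualifying_frames_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            out = select_seed_frames({"r0": np.full(100, 9.0)}, target=3.6)
        assert out["r0"].size == 0

    def test_fewer_qualifying_than_requested_returns_all(self):
        s = np.full(50, 9.0)
        s[[3, 8, 15, 22, 31, 40, 44]] = 3.6
        out = select_seed_frames({"r0": s}, target=3.6, per_replicate=20)
        assert sorted(out["r0"]) == [3, 8, 15, 22, 31, 40, 44]

    def test_selected_frames_all_qualify_and_are_spread(self, rng):
        s = rng.uniform(3.5, 3.7, 300)
        out = select_seed_frames({"r": s}, target=3.6, per_replicate=20)["r"]
        assert len(out) == 20
        assert np.all(np.abs(s[out] - 3.6) <= 0.1)
        assert out[0] < 30 and out[-1] > 270  # evenly spread, not clustered


# ---------------------------------------------------------------------------
# occupancy grid & vector angles
# ---------------------------------------------------------------------------

class TestOccupancy:
    def test_static_ligand_single_voxel(self):
        top = make_topology(1, [0])
        coords = np.tile([1.2, 3.4, -0.7], (20, 1, 1))
        grid = occupancy_grid(Trajectory(coords, top), [0])
        assert grid.counts.sum() == 20
        assert (grid.counts > 0).sum() == 1
        # with a single occupied voxel the nonzero SD is 0, so the
        # mean + 2 SD display level coincides with the count
        assert grid.iso_level <= grid.counts.max()

    def test_two_site_ligand_equal_voxels(self):
        top = make_topology(1, [0])
        coords = np.zeros((40, 1, 3))
        coords[20:, 0, 0] = 5.0
        grid = occupancy_grid(Trajectory(coords, top), [0])
        nz = np.sort(grid.counts[grid.counts > 0])
        assert list(nz) == [20, 20]

    def test_empty_group_rejected(self, random_trajectory):
        with pytest.raises(ValueError):
            occupancy_grid(random_trajectory, np.array([], dtype=int))


class TestGroupVectorAngle:
    def _traj(self, v1, v2):
        top = make_topology(4, [0, 1, 2, 3], masses=[1.0] * 4)
        coords = np.zeros((1, 4, 3))
        coords[0, 1] = v1
        coords[0, 3] = np.asarray(v2) + coords[0, 2]
        return Trajectory(coords, top)

    def test_parallel_and_orthogonal(self):
        t = self._traj([1, 0, 0], [2, 0, 0])
        assert group_vector_angle(t, ([0], [1]), ([2], [3]))[0] == pytest.approx(0.0)
        t = self._traj([1, 0, 0], [0, 3, 0])
        assert group_vector_angle(t, ([0], [1]), ([2], [3]))[0] == pytest.approx(90.0)

    def test_random_matches_arccos_dot(self, rng):
        for _ in range(20):
            v1, v2 = rng.uniform(-3, 3, 3), rng.uniform(-3, 3, 3)
            t = self._traj(v1, v2)
            expected = np.degrees(np.arccos(np.clip(
                v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1)))
            got = group_vector_angle(t, ([0], [1]), ([2], [3]))[0]
            assert got == pytest.approx(expected, abs=1e-8)

    def test_zero_length_vector_flagged(self):
        t = self._traj([0, 0, 0], [1, 0, 0])
        assert np.isnan(group_vector_angle(t, ([0], [1]), ([2], [3]))[0])
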