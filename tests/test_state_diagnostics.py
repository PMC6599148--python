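"""Gate distances, χ1 dihedrals, helix tilts, RMSD series, histograms."""

import numpy as np
import pytest

from leutfold.geometry import dihedral, rotation_about_axis
from leutfold.state_diagnostics import (
    DistanceSeries,
    Trajectory,
    chi1,
    helix_tilt,
    min_distance,
    normalized_histogram,
    pair_series,
    replica_mean_sem,
    rmsd_series,
)
from leutfold.structures_io import select
from leutfold.superpose import RigidTransform
from leutfold.synthetic_fixtures import (
    FixtureSpec,
    ideal_helix,
    place_atom,
    toy_trajectory,
    toy_transporter,
)

from conftest import make_structure


class TestMinDistance:
    def test_closest_pair_value(self):
        st_ = make_structure([
            ("C1", "C", "AAA", 1, "A", (0.0, 0, 0)),
            ("C2", "C", "AAA", 1, "A", (1.0, 0, 0)),
            ("C3", "C", "BBB", 2, "A", (4.0, 0, 0)),
        ])
        a = select(st_, "resid 1")
        b = select(st_, "resid 2")
        assert min_distance(st_, a, b) == pytest.approx(3.0)

    def test_single_atoms_translated(self):
        st_ = make_structure([
            ("C1", "C", "AAA", 1, "A", (0.0, 0, 0)),
            ("C2", "C", "BBB", 2, "A", (5.0, 0, 0)),
        ])
        assert min_distance(st_, select(st_, "resid 1"),
                            select(st_, "resid 2")) == pytest.approx(5.0)

    def test_symmetric_and_matches_double_loop(self, rng):
        recs = [(f"C{i}", "C", "AAA", 1, "A", tuple(rng.uniform(-5, 5, 3)))
                for i in range(10)]
        recs += [(f"D{i}", "C", "BBB", 2, "A", tuple(rng.uniform(-5, 5, 3)))
                 for i in range(10)]
        st_ = make_structure(recs)
        a, b = select(st_, "resid 1"), select(st_, "resid 2")
        expected = min(
            np.linalg.norm(x.coords - y.coords)
            for x in a.atoms for y in b.atoms
        )
        assert min_distance(st_, a, b) == pytest.approx(expected, abs=1e-12)
        assert min_distance(st_, b, a) == pytest.approx(expected, abs=1e-12)

    def test_hydrogens_ignored_by_default(self):
        st_ = make_structure([
            ("C1", "C", "AAA", 1, "A", (0.0, 0, 0)),
            ("H1", "H", "BBB", 2, "A", (1.0, 0, 0)),
            ("C2", "C", "BBB", 2, "A", (4.0, 0, 0)),
        ])
        assert min_distance(st_, select(st_, "resid 1"),
                            select(st_, "resid 2")) == pytest.approx(4.0)

    def test_empty_selection_errors(self, two_residue_structure):
        a = select(two_residue_structure, "resid 334")
        empty = select(two_residue_structure, "resid 999")
        with pytest.raises(ValueError, match="empty"):
            min_distance(two_residue_structure, a, empty)


class TestPairSeries:
    def test_planted_square_wave_exact(self):
        planted = np.where(np.arange(10) % 2 == 0, 3.0, 8.0)
        traj, ledger = toy_trajectory(FixtureSpec(seed=0),
                                      gate_distances=planted)
        series = pair_series(traj, [(1, 2)])
        np.testing.assert_allclose(series[0].values, planted, atol=1e-12)
        np.testing.assert_allclose(series[0].values,
                                   ledger["gate_distances"], atol=1e-12)

    def test_stride(self):
        traj, _ = toy_trajectory(FixtureSpec(seed=0),
                                 gate_distances=np.linspace(3, 6, 10))
        series = pair_series(traj, [(1, 2)], stride=2)
        assert len(series[0].values) == 5

    def test_identical_replicas_zero_sem(self):
        traj, _ = toy_trajectory(FixtureSpec(seed=0),
                                 gate_distances=np.linspace(3, 6, 8))
        s = pair_series(traj, [(1, 2)])[0]
        agg = replica_mean_sem([s, DistanceSeries(s.label, s.times,
                                                  s.values.copy())])
        np.testing.assert_allclose(agg.sem, 0.0)
        np.testing.assert_allclose(agg.values, s.values)

    def test_unresolvable_pair_errors(self):
        traj, _ = toy_trajectory(FixtureSpec(seed=0),
                                 gate_distances=np.full(4, 5.0))
        with pytest.raises(ValueError, match="unresolvable"):
            pair_series(traj, [(1, 77)])


class TestChi1:
    def _phe_with_chi(self, target):
        n = np.array([0.0, 0.0, 0.0])
        ca = np.array([1.46, 0.0, 0.0])
        cb = place_atom(np.array([0.0, -1.0, 1.0]), n, ca, 1.53, 110.5, -120.0)
        cg = place_atom(n, ca, cb, 1.52, 113.8, target)
        return make_structure([
            ("N", "N", "PHE", 10, "A", tuple(n)),
            ("CA", "C", "PHE", 10, "A", tuple(ca)),
            ("CB", "C", "PHE", 10, "A", tuple(cb)),
            ("CG", "C", "PHE", 10, "A", tuple(cg)),
        ])

    def test_constructed_angle_recovered(self):
        st_ = self._phe_with_chi(60.0)
        assert chi1(st_, 10) == pytest.approx(60.0, abs=1e-6)

    def test_matches_rotation_matrix_oracle(self, rng):
        # independent oracle: rotate CG about the CA-CB axis by a known
        # increment and check chi1 changes by exactly that increment
        for _ in range(100):
            base = rng.uniform(-179.0, 179.0)
            delta = rng.uniform(-170.0, 170.0)
            st_ = self._phe_with_chi(base)
            ca = st_.atom("A", 10, "CA").coords
            cb = st_.atom("A", 10, "CB").coords
            R = rotation_about_axis(cb - ca, delta)
            rotated = st_.with_coords(
                np.array([
                    R @ (a.coords - cb) + cb if a.name == "CG" else a.coords
                    for a in st_.atoms
                ])
            )
            expected = (base + delta + 180.0) % 360.0 - 180.0
            if expected <= -180.0:
                expected += 360.0
            assert chi1(rotated, 10) == pytest.approx(expected, abs=1e-6)

    def test_invariant_under_global_rigid_motion(self, rng):
        st_ = self._phe_with_chi(-75.0)
        tf = RigidTransform(rotation_about_axis(rng.normal(size=3), 123.0),
                            rng.normal(size=3) * 20)
        moved = tf.apply_structure(st_)
        assert chi1(moved, 10) == pytest.approx(chi1(st_, 10), abs=1e-9)

    def test_negative_branch_option(self):
        st_ = self._phe_with_chi(173.0)
        assert chi1(st_, 10) == pytest.approx(173.0, abs=1e-6)
        assert chi1(st_, 10, branch="negative") == pytest.approx(-187.0,
                                                                 abs=1e-6)

    def test_unevaluable_cases(self):
        st_ = make_structure([
            ("N", "N", "GLY", 5, "A", (0.0, 0, 0)),
            ("CA", "C", "GLY", 5, "A", (1.46, 0, 0)),
        ])
        assert chi1(st_, 5) is None  # GLY has no chi1
        partial = make_structure([
            ("N", "N", "PHE", 6, "A", (0.0, 0, 0)),
            ("CA", "C", "PHE", 6, "A", (1.46, 0, 0)),
            ("CB", "C", "PHE", 6, "A", (2.0, 1.2, 0.5)),
        ])
        assert chi1(partial, 6) is None  # missing CG: never guessed

    def test_planted_schedule_recovered(self):
        sched = np.linspace(-170.0, 170.0, 12)
        traj, _ = toy_trajectory(FixtureSpec(seed=0), chi1_schedule=sched)
        got = [chi1(f, 10) for f in traj.frames]
        np.testing.assert_allclose(got, sched, atol=1e-6)


class TestHelixTilt:
    def test_self_tilt_zero(self, toy_pair):
        open_st, _, roles, _, _ = toy_pair
        assert helix_tilt(open_st, open_st, "TM1b", roles) == pytest.approx(
            0.0, abs=1e-9)

    def test_explicit_rotation_recovered(self):
        # rotating a helix rigidly about an axis perpendicular to its own
        # principal axis tilts that axis by exactly the rotation angle
        from leutfold.state_diagnostics import _helix_axis

        h = ideal_helix(15)
        ca = np.stack([a.coords for a in h.atoms if a.name == "CA"])
        ax_ref = _helix_axis(ca)
        perp = np.cross(ax_ref, [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        R = rotation_about_axis(perp, 17.0)
        rotated = h.with_coords(h.coords @ R.T)
        ax_rot = _helix_axis(np.stack(
            [a.coords for a in rotated.atoms if a.name == "CA"]))
        ang = np.degrees(np.arccos(np.clip(np.dot(ax_ref, ax_rot), -1, 1)))
        assert ang == pytest.approx(17.0, abs=1e-6)

    def test_planted_angles_recovered_over_range(self):
        for angle in (1.0, 5.0, 12.5, 30.0):
            open_st, occ, roles, _, ledger = toy_transporter(
                FixtureSpec(seed=11, planted_angles={"TM1b": angle})
            )
            got = helix_tilt(occ, open_st, "TM1b", roles)
            assert got == pytest.approx(
                ledger["planted_angles"]["TM1b"], abs=0.1)

    def test_symmetric_in_frame_and_reference(self, toy_pair):
        open_st, occ, roles, _, _ = toy_pair
        a = helix_tilt(occ, open_st, "TM1b", roles)
        b = helix_tilt(open_st, occ, "TM1b", roles)
        assert a == pytest.approx(b, abs=1e-6)

    def test_translation_invariant(self, toy_pair):
        open_st, occ, roles, _, _ = toy_pair
        shifted = occ.with_coords(occ.coords + np.array([30.0, -4.0, 12.0]))
        assert helix_tilt(shifted, open_st, "TM1b", roles) == pytest.approx(
            helix_tilt(occ, open_st, "TM1b", roles), abs=1e-9)

    def test_short_helix_rejected(self, toy_pair):
        open_st, occ, roles, _, _ = toy_pair
        from leutfold.structures_io import RoleMap

        stub = RoleMap({**{k: v for k, v in roles.roles.items()},
                        "stub": [[201, 204]]})
        with pytest.raises(ValueError, match="6 CA"):
            helix_tilt(occ, open_st, "stub", stub)


class TestRmsdSeries:
    def _traj_of(self, frames, dt=0.02):
        return Trajectory(frames, dt * np.arange(len(frames)))

    def test_copies_of_reference_all_zero(self):
        ref = ideal_helix(12)
        traj = self._traj_of([ref.with_coords(ref.coords) for _ in range(4)])
        s = rmsd_series(traj, ref, "backbone")
        np.testing.assert_allclose(s.values, 0.0, atol=1e-9)

    def test_rigid_translation_removed_by_fit(self):
        ref = ideal_helix(12)
        moved = ref.with_coords(ref.coords + np.array([9.0, 2.0, -4.0]))
        s = rmsd_series(self._traj_of([moved]), ref, "backbone")
        assert s.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_noise_mean_matches_analytic_expectation(self, rng):
        # isotropic per-atom Gaussian noise sigma: E[RMSD] ~= sqrt(3)*sigma
        # (the rigid-body fit removes 6 of 3N degrees of freedom)
        sigma = 1.2 / np.sqrt(3)
        ref = ideal_helix(40)  # 200 atoms
        frames = [
            ref.with_coords(ref.coords + rng.normal(0, sigma,
                                                    ref.coords.shape))
            for _ in range(25)
        ]
        s = rmsd_series(self._traj_of(frames), ref, "all")
        n_atoms = len(ref.atoms)
        expected = np.sqrt(3) * sigma * np.sqrt((3 * n_atoms - 6)
                                                / (3 * n_atoms))
        assert s.values.mean() == pytest.approx(expected, rel=0.05)

    def test_ligand_mode_reports_unfitted_site_rmsd(self):
        # fit on the helix, report the displaced "ligand" residue unfitted
        ref = ideal_helix(12)
        lig = make_structure([("C1", "C", "LIG", 900, "A", (8.0, 0.0, 0.0))])
        combined = ref.atoms + lig.atoms
        from leutfold.structures_io import Structure

        ref_c = Structure(combined, source="ref")
        moved = ref_c.with_coords(
            np.vstack([ref.coords, [[10.0, 0.0, 0.0]]]))
        s = rmsd_series(self._traj_of([moved]), ref_c, "resname LIG",
                        fit_selection="backbone")
        assert s.values[0] == pytest.approx(2.0, abs=1e-9)

    def test_exclusions_and_units(self, toy_pair):
        open_st, occ, roles, _, _ = toy_pair
        traj = self._traj_of([occ])
        full = rmsd_series(traj, open_st, "backbone")
        excl = rmsd_series(traj, open_st, "backbone",
                           exclusions=["TM1b", "TM6a"], roles=roles)
        assert excl.values[0] == pytest.approx(0.0, abs=1e-9)
        assert full.values[0] > 0.5
        nm = rmsd_series(traj, open_st, "backbone", unit="nm")
        assert nm.unit == "nm"
        assert nm.values[0] == pytest.approx(full.values[0] / 10.0)

    def test_empty_selection_after_exclusion_errors(self, toy_pair):
        open_st, occ, roles, _, _ = toy_pair
        with pytest.raises(ValueError, match="empty"):
            rmsd_series(self._traj_of([occ]), open_st,
                        "resid 201-215 and backbone",
                        exclusions=["TM1b"], roles=roles)


class TestNormalizedHistogram:
    def test_constant_series_single_bin(self):
        s = DistanceSeries("x", np.arange(5.0), np.full(5, 3.2))
        h = normalized_histogram(s, bin_width=0.5)
        occupied = h.densities[h.densities > 0]
        assert len(occupied) == 1
        assert occupied[0] == pytest.approx(1 / 0.5)

    def test_pooling_equals_concatenation(self, rng):
        a = DistanceSeries("x", np.arange(50.0), rng.uniform(2, 8, 50))
        b = DistanceSeries("x", np.arange(50.0), rng.uniform(2, 8, 50))
        pooled = normalized_histogram([a, b], 0.5)
        concat = normalized_histogram(
            np.concatenate([a.values, b.values]), 0.5)
        np.testing.assert_allclose(pooled.densities, concat.densities)

    def test_uniform_values_flat_within_sampling_error(self, rng):
        n = 20000
        vals = rng.uniform(0.0, 10.0, n)
        h = normalized_histogram(vals, 1.0)
        inner = h.densities[1:-1]
        # each bin holds ~n/10 counts; 4-sigma sampling band on the density
        se = np.sqrt(0.1 * 0.9 / n) / 1.0
        assert np.all(np.abs(inner - 0.1) < 4 * se + 1e-12)

    def test_unit_integral_invariant(self, rng):
        vals = rng.normal(5, 1, 500)
        h = normalized_histogram(vals, 0.25)
        assert np.sum(h.densities * np.diff(h.edges)) == pytest.approx(1.0)

    def test_bad_bin_width_errors(self):
        with pytest.raises(ValueError):
            normalized_histogram(np.array([1.0, 2.0]), 0.0)


def test_trajectory_invariants():
    h = ideal_helix(6)
    with pytest.raises(ValueError, match="strictly increasing"):
        Trajectory([h, h], np.array([0.0, 0.0]))
    short = ideal_helix(5)
    with pytest.raises(ValueError, match="atom count"):
        Trajectory([h, short], np.array([0.0, 1.0]))
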