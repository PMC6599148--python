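"""Chimeric template assembly, rotamer setting, ion transfer, restraints."""

import numpy as np
import pytest

from leutfold.chimera_builder import (
    RestraintList,
    build_template,
    emit_pir_alignment,
    emit_restraints,
    junction_bond_lengths,
    parse_pir,
    parse_restraints,
    set_chi,
    transfer_ions,
)
from leutfold.geometry import rotation_about_axis
from leutfold.state_diagnostics import chi1
from leutfold.structures_io import AtomRecord, Structure, select
from leutfold.superpose import RigidTransform, hash_superpose

from conftest import make_structure


class TestBuildTemplate:
    def test_donor_equals_target_is_noop(self, toy_pair):
        open_st, _, roles, segments, _ = toy_pair
        rec = build_template(open_st, open_st, segments, roles)
        np.testing.assert_allclose(
            rec.structure.coords, open_st.coords, atol=1e-8
        )

    def test_repositioned_segments_overlay_donor(self, toy_pair):
        open_st, occluded, roles, segments, _ = toy_pair
        rec = build_template(open_st, occluded, segments, roles)
        for seg in segments:
            idx = [
                i for i, a in enumerate(open_st.atoms)
                if seg.target_range[0] <= a.resid <= seg.target_range[1]
                and a.name in ("N", "CA", "C", "O")
            ]
            diff = rec.structure.coords[idx] - occluded.coords[idx]
            rmsd = np.sqrt((diff ** 2).sum(axis=1).mean())
            assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_non_segment_atoms_bit_identical(self, toy_pair):
        open_st, occluded, roles, segments, _ = toy_pair
        rec = build_template(open_st, occluded, segments, roles)
        moved_resids = set()
        for seg in segments:
            moved_resids |= set(range(seg.target_range[0],
                                      seg.target_range[1] + 1))
        for a, b, tag in zip(open_st.atoms, rec.structure.atoms,
                             rec.provenance):
            if a.resid in moved_resids:
                assert tag == "repositioned_target"
            else:
                assert tag == "unchanged_target"
                assert a.coords is b.coords or np.array_equal(a.coords, b.coords)

    def test_hash_superpose_after_build_is_identity(self, toy_pair):
        open_st, occluded, roles, segments, _ = toy_pair
        rec = build_template(open_st, occluded, segments, roles)
        assert hash_superpose(rec.structure, open_st, roles).is_identity()

    def test_missing_segment_errors(self, toy_pair):
        from leutfold.superpose import Segment, SegmentMap

        open_st, occluded, roles, _, _ = toy_pair
        ghost = SegmentMap([Segment("ghost", (900, 905), (900, 905))])
        with pytest.raises(ValueError, match="ghost"):
            build_template(open_st, occluded, ghost, roles)

    def test_provenance_roundtrip_through_pdb(self, toy_pair, tmp_path):
        from leutfold.structures_io import read_structure

        open_st, occluded, roles, segments, _ = toy_pair
        rec = build_template(open_st, occluded, segments, roles)
        p = tmp_path / "chimera.pdb"
        rec.write_pdb(p)
        back = read_structure(p)
        flags = [a.bfactor for a in back.atoms]
        expected = [0.0 if t == "unchanged_target" else 1.0
                    for t in rec.provenance]
        assert flags == expected
        assert (tmp_path / "chimera.pdb.yaml").exists()

    def test_junction_bonds_reported(self, toy_pair):
        open_st, occluded, roles, segments, _ = toy_pair
        rec = build_template(open_st, occluded, segments, roles)
        bonds = junction_bond_lengths(rec)
        # toy helices are disconnected, so no peptide junctions exist
        assert bonds == []


class TestPir:
    def _penta(self, missing=None):
        seq = "ARNDC"
        three = {"A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS"}
        recs = []
        for i, letter in enumerate(seq, start=1):
            if missing and i in missing:
                continue
            recs.append(("CA", "C", three[letter], i, "A", (i * 3.8, 0, 0)))
        return make_structure(recs), seq

    def test_full_coverage_no_gaps(self):
        st_, seq = self._penta()
        text = emit_pir_alignment(st_, seq)
        entries = parse_pir(text)
        assert entries == {"template": "ARNDC", "target": "ARNDC"}

    def test_missing_residue_becomes_gap(self):
        st_, seq = self._penta(missing={3})
        entries = parse_pir(emit_pir_alignment(st_, seq))
        assert entries["template"] == "AR-DC"
        assert entries["target"] == "ARNDC"

    def test_mismatched_residue_errors(self):
        st_, _ = self._penta()
        with pytest.raises(ValueError, match="residue 1"):
            emit_pir_alignment(st_, "RRNDC")

    def test_out_of_range_residue_errors(self):
        st_, _ = self._penta()
        with pytest.raises(ValueError, match="mapped"):
            emit_pir_alignment(st_, "ARN")


class TestTransferIons:
    def _site(self):
        recs = []
        rng = np.random.default_rng(5)
        for resid in (1, 2, 3):
            base = rng.normal(scale=3.0, size=3)
            for name, off in (("N", (0, 0, 0)), ("CA", (1.4, 0.2, 0)),
                              ("C", (2.1, 1.2, 0.3)), ("O", (1.8, 2.3, 0))):
                recs.append((name, name[0], "GLY", resid, "A",
                             tuple(base + np.array(off))))
        recs.append(("NA", "NA", "NA", 90, "A", (1.0, 1.0, 1.0)))
        st_ = make_structure(recs)
        st_.atoms[-1] = st_.atoms[-1].__class__(
            **{**st_.atoms[-1].__dict__, "het": True})
        return st_

    def test_source_equals_dest_unchanged(self):
        src = self._site()
        dest = make_structure([])
        dest = Structure([a for a in src.atoms if a.resname != "NA"],
                         source="dest")
        out = transfer_ions(src, dest, ["resname NA"])
        ion = [a for a in out.atoms if a.resname == "NA"]
        assert len(ion) == 1
        np.testing.assert_allclose(ion[0].coords, [1.0, 1.0, 1.0], atol=1e-8)

    def test_translated_dest_translates_ion(self):
        src = self._site()
        shift = np.array([5.0, 0.0, 0.0])
        dest = Structure(
            [a.__class__(**{**a.__dict__, "coords": a.coords + shift})
             for a in src.atoms if a.resname != "NA"],
            source="dest",
        )
        out = transfer_ions(src, dest, ["resname NA"])
        ion = [a for a in out.atoms if a.resname == "NA"][0]
        np.testing.assert_allclose(ion.coords, [6.0, 1.0, 1.0], atol=1e-8)

    def test_rotated_dest_rotates_ion(self):
        src = self._site()
        R = rotation_about_axis([0.3, 1.0, 0.2], 40.0)
        t = np.array([2.0, -1.0, 4.0])
        tf = RigidTransform(R, t)
        dest = Structure(
            [a.__class__(**{**a.__dict__, "coords": tf.apply(a.coords)})
             for a in src.atoms if a.resname != "NA"],
            source="dest",
        )
        out = transfer_ions(src, dest, ["resname NA"])
        ion = [a for a in out.atoms if a.resname == "NA"][0]
        np.testing.assert_allclose(
            ion.coords, tf.apply(np.array([1.0, 1.0, 1.0])), atol=1e-6
        )

    def test_absent_site_errors(self):
        src = self._site()
        dest = Structure([a for a in src.atoms if a.resid == 99], source="d")
        with pytest.raises(ValueError):
            transfer_ions(src, dest, ["resname NA"])


class TestSetChi:
    def _phe(self):
        # full aromatic side chain so distal-group rigidity can be checked
        recs = [
            ("N", "N", "PHE", 10, "A", (0.0, 0.0, 0.0)),
            ("CA", "C", "PHE", 10, "A", (1.46, 0.0, 0.0)),
            ("C", "C", "PHE", 10, "A", (2.0, 1.42, 0.0)),
            ("O", "O", "PHE", 10, "A", (1.4, 2.4, 0.4)),
            ("CB", "C", "PHE", 10, "A", (2.1, -0.9, 1.05)),
            ("CG", "C", "PHE", 10, "A", (3.6, -0.9, 1.1)),
            ("CD1", "C", "PHE", 10, "A", (4.3, -2.1, 1.2)),
            ("CD2", "C", "PHE", 10, "A", (4.35, 0.3, 1.05)),
            ("CE1", "C", "PHE", 10, "A", (5.7, -2.1, 1.25)),
            ("CE2", "C", "PHE", 10, "A", (5.75, 0.3, 1.1)),
            ("CZ", "C", "PHE", 10, "A", (6.4, -0.9, 1.2)),
        ]
        return make_structure(recs)

    def test_set_then_measure_closed_loop(self):
        st_ = self._phe()
        out = set_chi(st_, "A", 10, 1, -166.0)
        assert chi1(out, 10) == pytest.approx(-166.0, abs=1e-6)

    def test_set_to_current_value_is_noop(self):
        st_ = self._phe()
        cur = chi1(st_, 10)
        out = set_chi(st_, "A", 10, 1, cur)
        np.testing.assert_allclose(out.coords, st_.coords, atol=1e-9)

    def test_absolute_setting_idempotent(self):
        st_ = self._phe()
        twice = set_chi(set_chi(st_, "A", 10, 1, 60.0), "A", 10, 1, -70.0)
        once = set_chi(st_, "A", 10, 1, -70.0)
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-8)

    def test_rigid_group_distances_preserved(self):
        st_ = self._phe()
        out = set_chi(st_, "A", 10, 1, 120.0)
        ring = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        before = np.stack([st_.atom("A", 10, n).coords for n in ring])
        after = np.stack([out.atom("A", 10, n).coords for n in ring])
        d_before = np.linalg.norm(
            before[:, None, :] - before[None, :, :], axis=-1)
        d_after = np.linalg.norm(
            after[:, None, :] - after[None, :, :], axis=-1)
        np.testing.assert_allclose(d_after, d_before, atol=1e-8)
        # CB must not move: it sits on the rotation axis side
        np.testing.assert_allclose(
            out.atom("A", 10, "CB").coords, st_.atom("A", 10, "CB").coords)

    def test_missing_atoms_error(self, two_residue_structure):
        with pytest.raises(ValueError, match="missing"):
            set_chi(two_residue_structure, "A", 335, 1, 60.0)


class TestRestraints:
    def test_single_pair_literals(self):
        rl = RestraintList()
        rl.add("A/104/NH1", "A/493/OE1", 2.3, 10.0)
        text = emit_restraints(rl)
        lines = text.strip().splitlines()
        assert lines[0].startswith("#")
        assert lines[1] == "A/104/NH1\tA/493/OE1\t2.3\t10"

    def test_empty_list_header_only(self):
        text = emit_restraints(RestraintList())
        assert text.strip().splitlines() == [
            "#atom_a\tatom_b\tdistance_A\tforce_kcal_mol_A2"]

    def test_tsv_round_trip(self):
        rl = RestraintList()
        rl.add("A/176/OH", "A/335/CZ", 3.5, RestraintList.EQUILIBRATION_K)
        rl.add("A/104/NH1", "A/493/OE1", 2.85, RestraintList.MINIMIZATION_K)
        back = parse_restraints(emit_restraints(rl))
        assert back.entries == rl.entries

    def test_dangling_reference_errors(self, two_residue_structure):
        rl = RestraintList()
        rl.add("A/335/CA", "A/999/CA", 3.0, 10.0)
        with pytest.raises(ValueError, match="dangling"):
            emit_restraints(rl, structure=two_residue_structure)

    def test_plumed_dialect_units(self, two_residue_structure):
        rl = RestraintList()
        rl.add("A/334/CA", "A/335/CA", 10.0, 10.0)
        text = emit_restraints(rl, dialect="plumed_style",
                               structure=two_residue_structure)
        assert "AT=1" in text  # 10 Å = 1 nm
        assert "KAPPA=4184" in text  # 10 kcal/mol/Å² in kJ/mol/nm²

    def test_invalid_values_rejected(self):
        rl = RestraintList()
        with pytest.raises(ValueError):
            rl.add("a", "b", -1.0, 10.0)
        with pytest.raises(ValueError):
            rl.add("a", "b", 2.0, 0.0)
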