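import numpy as np
import pytest

from bolakit.structure_io import (
    DistanceRestraint,
    ParseError,
    ResidueRange,
    RestraintCategory,
    SequenceRecord,
    StructureEnsemble,
    average_mass,
    classify_restraint,
    extract_sequence,
    parse_ranges,
    read_pdb_ensemble,
    read_restraints,
    restraint_counts,
    write_pdb_ensemble,
)


class TestReadPdbEnsemble:
    def test_two_model_file(self, tiny_pdb):
        ens = read_pdb_ensemble(tiny_pdb)
        assert ens.n_models == 2
        assert all(len(m) == 3 for m in ens.models)
        assert ens.residue_span == (24, 24)

    def test_model_order_follows_model_records(self, tiny_pdb):
        ens = read_pdb_ensemble(tiny_pdb)
        # model 1 x-offset is 0.1, model 2 is 0.2 (see fixture)
        assert ens.model(1)["x"].iloc[0] < ens.model(2)["x"].iloc[0]

    def test_no_model_records_gives_one_model(self, tmp_path):
        path = tmp_path / "single.pdb"
        path.write_text(
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\nEND\n"
        )
        assert read_pdb_ensemble(path).n_models == 1

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(ParseError, match="no ATOM records"):
            read_pdb_ensemble(path)

    def test_malformed_atom_line_cites_line_number(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   2       xxxxx   0.000   0.000  1.00  0.00           C\n"
        )
        with pytest.raises(ParseError, match="line 2"):
            read_pdb_ensemble(path)

    def test_waters_and_hetatm_excluded(self, tmp_path):
        path = tmp_path / "het.pdb"
        path.write_text(
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  O   HOH A 200       5.000   5.000   5.000  1.00  0.00           O\n"
            "END\n"
        )
        ens = read_pdb_ensemble(path)
        assert len(ens.model(1)) == 1


def test_pdb_round_trip_preserves_records(tmp_path):
    rng = np.random.default_rng(7)
    from tests.conftest import ensemble_from_coords

    stack = rng.normal(0, 5, size=(3, 4, 3)).round(3)
    ens = ensemble_from_coords(stack, atom_names=["N", "CA", "C", "O"], res_per_atom=[1, 1, 1, 1])
    out = tmp_path / "rt.pdb"
    write_pdb_ensemble(ens, out)
    back = read_pdb_ensemble(out)
    assert back.n_models == 3
    for m1, m2 in zip(ens.models, back.models):
        assert list(m1["atom_name"]) == list(m2["atom_name"])
        assert list(m1["res_seq"]) == list(m2["res_seq"])
        np.testing.assert_allclose(
            m1[["x", "y", "z"]].to_numpy(), m2[["x", "y", "z"]].to_numpy(), atol=1.5e-3
        )


class TestResidueRange:
    def test_inclusive_length(self):
        assert len(ResidueRange(33, 53)) == 21
        assert 53 in ResidueRange(33, 53)
        assert 54 not in ResidueRange(33, 53)

    def test_reversed_range_rejected(self):
        with pytest.raises(ValueError):
            ResidueRange(10, 5)

    def test_parse_list(self):
        rr = parse_ranges("33-53,76-122")
        assert [(r.start, r.end) for r in rr] == [(33, 53), (76, 122)]


class TestClassifyRestraint:
    @pytest.mark.parametrize(
        "i,j,expected",
        [
            (50, 50, RestraintCategory.INTRARESIDUE),
            (50, 51, RestraintCategory.SEQUENTIAL),
            (51, 50, RestraintCategory.SEQUENTIAL),
            (48, 50, RestraintCategory.MEDIUM),
            (48, 52, RestraintCategory.MEDIUM),
            (48, 53, RestraintCategory.LONG),
            (48, 77, RestraintCategory.LONG),
        ],
    )
    def test_separation_rules(self, i, j, expected):
        assert classify_restraint(i, j) is expected

    def test_counts_partition_total(self, tmp_path):
        rng = np.random.default_rng(11)
        lines = []
        for _ in range(200):
            i = int(rng.integers(24, 124))
            j = int(np.clip(i + rng.integers(-30, 31), 24, 123))
            lines.append(f"{i} ALA HA {j} LEU HN {rng.uniform(2.5, 6.0):.2f}")
        path = tmp_path / "rand.upl"
        path.write_text("\n".join(lines) + "\n")
        counts = restraint_counts(read_restraints(path))
        assert (
            counts["intraresidue"] + counts["sequential"] + counts["medium"] + counts["long"]
            == counts["total_distance"]
            == 200
        )


class TestReadRestraints:
    def test_three_line_fixture(self, tmp_path):
        path = tmp_path / "three.upl"
        path.write_text(
            "# comment\n"
            "50 ALA HA 50 ALA HN 3.0\n"
            "50 ALA HA 51 GLY HN 4.2\n"
            "54 ASP HA 76 HIS HN 5.0\n"
        )
        rs = read_restraints(path)
        assert len(rs) == 3
        assert rs[2].category is RestraintCategory.LONG
        assert abs(rs[2].res_i - rs[2].res_j) == 22

    def test_comment_only_body_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.upl"
        path.write_text("# nothing here\n\n# still nothing\n")
        assert read_restraints(path) == []

    def test_negative_bound_rejected(self, tmp_path):
        path = tmp_path / "neg.upl"
        path.write_text("50 ALA HA 51 GLY HN -1.0\n")
        with pytest.raises(ParseError, match="bound"):
            read_restraints(path)

    def test_unknown_residue_token_rejected(self, tmp_path):
        path = tmp_path / "bad.upl"
        path.write_text("50 ZZZ HA 51 GLY HN 4.0\n")
        with pytest.raises(ParseError, match="ZZZ"):
            read_restraints(path)

    def test_hbond_comment_keeps_category(self, tmp_path):
        path = tmp_path / "hb.upl"
        path.write_text("48 ALA O 52 GLY HN 2.0 #hbond\n")
        (r,) = read_restraints(path)
        assert r.category is RestraintCategory.HBOND

    def test_pdb_mr_dialect_extracts_upl_lines(self, tmp_path):
        path = tmp_path / "dep.mr"
        path.write_text(
            "*HEADER restraint block\n"
            "Some free text that is not a restraint\n"
            "50 ALA HA 51 GLY HN 4.2\n"
            "assign (resid 1 and name HA) (resid 2 and name HN) 4.0 0.2 0.2\n"
            "54 ASP HA 76 HIS HN 5.0\n"
        )
        rs = read_restraints(path, dialect="pdb_mr")
        assert len(rs) == 2


class TestSequence:
    def test_three_residue_fixture(self):
        from tests.conftest import ensemble_from_coords

        ens = ensemble_from_coords(
            np.zeros((1, 3, 3)) + np.arange(3)[None, :, None] * 4.0,
            atom_names=["CA", "CA", "CA"],
            res_per_atom=[24, 25, 26],
        )
        for m, name in zip([ens.models[0]], [None]):
            m.loc[0, "res_name"] = "ALA"
            m.loc[1, "res_name"] = "GLY"
            m.loc[2, "res_name"] = "SER"
        seq = extract_sequence(ens)
        assert seq.one_letter == "AGS"
        assert seq.span == (24, 26)

    def test_gap_warns(self):
        from tests.conftest import ensemble_from_coords

        ens = ensemble_from_coords(
            np.zeros((1, 2, 3)), atom_names=["CA", "CA"], res_per_atom=[24, 26]
        )
        with pytest.warns(UserWarning, match="gap"):
            seq = extract_sequence(ens)
        assert len(seq) == 2

    def test_nonstandard_residue_becomes_x(self):
        from tests.conftest import ensemble_from_coords

        ens = ensemble_from_coords(np.zeros((1, 1, 3)), atom_names=["CA"], res_per_atom=[1])
        ens.models[0].loc[0, "res_name"] = "MSE"
        with pytest.warns(UserWarning, match="MSE"):
            seq = extract_sequence(ens)
        assert seq.one_letter == "X"


class TestAverageMass:
    def test_diglycine(self):
        assert average_mass("GG") == pytest.approx(132.12, abs=0.01)

    def test_ser_vs_ala_is_one_oxygen(self):
        diff = average_mass("GSG") - average_mass("GAG")
        assert diff == pytest.approx(16.00, abs=0.01)
        assert diff < 16.0  # one O: 15.999 Da

    def test_additive_minus_water(self):
        a, b = "ACDEFG", "HIKLMN"
        assert average_mass(a + b) == pytest.approx(
            average_mass(a) + average_mass(b) - 18.02, abs=0.02
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            average_mass("")

    def test_nonstandard_residue_named_in_error(self):
        with pytest.raises(ValueError, match="X"):
            average_mass("GXG")
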