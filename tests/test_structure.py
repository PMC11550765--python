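import numpy as np
import pytest

from fodm.errors import ParseError, ResidueError, SelectionError
from fodm.structure import (
    effective_atom_position,
    load_structure,
    parse_selection,
)
from fodm.synthetic import FixtureSpec, generate, write_pdb

PDB_TWO_RES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       5.000   1.000   0.000  1.00  0.00           C
ATOM      4  HA  GLY A   2       9.000   9.000   9.000  1.00  0.00           H
END
"""

PDB_NONSTANDARD = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  XXX A   2       3.000   0.000   0.000  1.00  0.00           C
END
"""

PDB_ALTLOC = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1      10.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA  GLY A   2       3.000   0.000   0.000  1.00  0.00           C
END
"""


class TestEffectiveAtomPosition:
    @pytest.mark.parametrize(
        "coords, expected",
        [
            ([(1.0, 2.0, 3.0)], (1.0, 2.0, 3.0)),
            ([(0, 0, 0), (2, 0, 0)], (1.0, 0.0, 0.0)),
            ([(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)], (0.25, 0.25, 0.25)),
        ],
    )
    def test_mean_of_atom_positions(self, coords, expected):
        assert effective_atom_position(coords) == pytest.approx(expected)

    def test_empty_residue_is_an_error(self):
        with pytest.raises(ResidueError):
            effective_atom_position([])


class TestLoadStructure:
    def test_three_residue_fixture_matches_hand_parse(self, tmp_path, kd_scale):
        model, _ = generate(FixtureSpec(n_residues=3, mode="uniform", seed=3))
        path = write_pdb(model, tmp_path / "three.pdb")

        # independent line-by-line parse of the written text
        records = []
        for line in path.read_text().splitlines():
            if line.startswith("ATOM"):
                records.append(
                    (
                        line[17:20].strip(),
                        line[21],
                        int(line[22:26]),
                        float(line[30:38]),
                        float(line[38:46]),
                        float(line[46:54]),
                    )
                )
        assert len(records) == 3

        loaded = load_structure(path, scale=kd_scale)
        assert len(loaded) == 3
        for atom, (aa, chain, seq, x, y, z) in zip(loaded.atoms, records):
            assert atom.ref.aa_code == aa
            assert atom.ref.chain_id == chain
            assert atom.ref.seq_number == seq
            # PDB coordinates are read back at single precision
            assert atom.position == pytest.approx([x, y, z], abs=1e-5)
            assert atom.intrinsic_h == pytest.approx(kd_scale.level(aa))

    def test_effective_atom_averages_heavy_atoms_and_skips_hydrogens(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(PDB_TWO_RES)
        model = load_structure(path)
        assert len(model) == 2
        # residue 1: mean of N and CA
        assert model.atoms[0].position == pytest.approx([1.0, 0.0, 0.0])
        # residue 2: the HA hydrogen must not shift the centroid
        assert model.atoms[1].position == pytest.approx([5.0, 1.0, 0.0])

    def test_single_residue_selection_is_an_error(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(PDB_TWO_RES)
        with pytest.raises(SelectionError):
            load_structure(path, selection="A:1-1")

    def test_selection_matching_nothing_is_an_error(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(PDB_TWO_RES)
        with pytest.raises(SelectionError):
            load_structure(path, selection="B")

    def test_nonstandard_residue_error_names_the_residue(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(PDB_NONSTANDARD)
        with pytest.raises(ResidueError, match="XXX"):
            load_structure(path)

    def test_nonstandard_residue_mapping(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(PDB_NONSTANDARD)
        model = load_structure(path, residue_map={"XXX": "GLY"})
        assert model.atoms[1].ref.aa_code == "GLY"

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(PDB_ALTLOC)
        model = load_structure(path)
        assert len(model) == 2
        assert model.atoms[0].position == pytest.approx([10.0, 0.0, 0.0])

    def test_missing_file_is_a_parse_error(self, tmp_path):
        with pytest.raises(ParseError):
            load_structure(tmp_path / "nope.pdb")

    def test_loading_is_deterministic(self, tmp_path):
        model, _ = generate(FixtureSpec(n_residues=25, mode="ideal-micelle", seed=11))
        path = write_pdb(model, tmp_path / "m.pdb")
        a = load_structure(path)
        b = load_structure(path)
        assert a.refs == b.refs
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.hydrophobicities, b.hydrophobicities)

    def test_rigid_motion_preserves_identity_fields(self, tmp_path):
        model, _ = generate(FixtureSpec(n_residues=25, mode="ideal-micelle", seed=11))
        path = write_pdb(model, tmp_path / "orig.pdb")
        orig = load_structure(path)

        rng = np.random.default_rng(5)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        moved_atoms = tuple(
            type(a)(ref=a.ref, position=a.position @ q.T + 20.0, intrinsic_h=a.intrinsic_h)
            for a in orig.atoms
        )
        moved_model = type(orig)(id="moved", atoms=moved_atoms, source_format="synthetic")
        path2 = write_pdb(moved_model, tmp_path / "moved.pdb")
        moved = load_structure(path2)

        assert len(moved) == len(orig)
        assert moved.refs == orig.refs
        assert np.array_equal(moved.hydrophobicities, orig.hydrophobicities)


class TestSelectionSyntax:
    def test_whole_chain_and_ranges(self):
        sel = parse_selection("A B:10-20,30 C:5-5")
        assert sel["A"] is None
        assert sel["B"] == [(10, 20), (30, 30)]
        assert sel["C"] == [(5, 5)]

    def test_inverted_range_rejected(self):
        with pytest.raises(SelectionError):
            parse_selection("A:20-10")

    def test_empty_expression_rejected(self):
        with pytest.raises(SelectionError):
            parse_selection("   ")
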