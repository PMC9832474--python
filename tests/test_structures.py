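"""Structure IO, state pairing, and shell selection."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from tsscan.structures import (
    REACT,
    TS1,
    AtomRecord,
    StateStructure,
    StructureError,
    pair_states,
    parse_atom_selector,
    read_structure,
    select_shell,
    write_charge_table,
    write_pdb,
    write_pqr,
)
from tsscan.synthetic import ToySystemSpec, make_toy_pair


def _tiny_atoms(n=5, charge=0.1):
    return [
        AtomRecord(atom_name=f"C{i+1}", element="C", residue_name="LIG",
                   chain="A", residue_number=1, coords=(float(i), 0.0, 0.0),
                   charge=charge)
        for i in range(n)
    ]


class TestReadStructure:
    def test_pdb_pqr_roundtrip_identity(self, tmp_path):
        atoms = _tiny_atoms(5)
        write_pdb(atoms, tmp_path / "t.pdb")
        write_pqr(atoms, tmp_path / "t.pqr")
        state = read_structure(tmp_path / "t.pdb", tmp_path / "t.pqr", REACT)
        assert len(state) == 5
        assert all(a.charge == pytest.approx(0.1, abs=1e-6)
                   for a in state.atoms)

    def test_plain_xyzq_table(self, tmp_path):
        atoms = _tiny_atoms(3)
        write_pdb(atoms, tmp_path / "t.pdb")
        with open(tmp_path / "t.q", "w") as fh:
            for a in atoms:
                x, y, z = a.coords
                fh.write(f"{x:.3f} {y:.3f} {z:.3f} {a.charge:.4f}\n")
        state = read_structure(tmp_path / "t.pdb", tmp_path / "t.q", REACT)
        assert [a.charge for a in state.atoms] == pytest.approx([0.1] * 3)

    def test_keyed_table(self, tmp_path):
        atoms = _tiny_atoms(3)
        write_pdb(atoms, tmp_path / "t.pdb")
        write_charge_table(atoms, tmp_path / "t.q")
        state = read_structure(tmp_path / "t.pdb", tmp_path / "t.q", REACT)
        assert [a.key for a in state.atoms] == [a.key for a in atoms]

    def test_row_count_mismatch_is_error(self, tmp_path):
        write_pdb(_tiny_atoms(5), tmp_path / "t.pdb")
        write_pqr(_tiny_atoms(4), tmp_path / "t.pqr")
        with pytest.raises(StructureError, match="charge table mismatch"):
            read_structure(tmp_path / "t.pdb", tmp_path / "t.pqr", REACT)

    def test_name_mismatch_is_error(self, tmp_path):
        atoms = _tiny_atoms(3)
        write_pdb(atoms, tmp_path / "t.pdb")
        renamed = [AtomRecord(atom_name="XX", element="C", residue_name="LIG",
                              chain="A", residue_number=1,
                              coords=a.coords, charge=a.charge)
                   for a in atoms]
        write_pqr(renamed, tmp_path / "t.pqr")
        with pytest.raises(StructureError, match="mismatch"):
            read_structure(tmp_path / "t.pdb", tmp_path / "t.pqr", REACT)

    def test_missing_file_is_error(self, tmp_path):
        with pytest.raises(StructureError, match="not found"):
            read_structure(tmp_path / "no.pdb", tmp_path / "no.pqr", REACT)

    def test_synthetic_fixture_roundtrip(self, toy_pair, tmp_path):
        """Writer and reader are inverse up to PDB precision."""
        react = toy_pair.react
        write_pdb(react.atoms, tmp_path / "r.pdb")
        write_pqr(react.atoms, tmp_path / "r.pqr")
        qm_sel = [f"{c}:{r}:{n}" for c, r, n in sorted(react.qm_selection)]
        back = read_structure(tmp_path / "r.pdb", tmp_path / "r.pqr", REACT,
                              qm_selection=qm_sel)
        assert back.keys == react.keys
        assert back.qm_selection == react.qm_selection
        np.testing.assert_allclose(back.coords, react.coords, atol=1e-3)
        np.testing.assert_allclose(back.charges, react.charges, atol=1e-4)


class TestStateStructure:
    def test_duplicate_atom_keys_rejected(self):
        atoms = _tiny_atoms(2) + [_tiny_atoms(1)[0]]
        with pytest.raises(StructureError, match="duplicate"):
            StateStructure(REACT, atoms)

    def test_excessive_charge_rejected(self):
        with pytest.raises(StructureError, match="exceeds"):
            AtomRecord(atom_name="C1", element="C", residue_name="LIG",
                       chain="A", residue_number=1, coords=(0, 0, 0),
                       charge=3.0)

    def test_qm_selection_must_resolve(self):
        with pytest.raises(StructureError, match="absent"):
            StateStructure(REACT, _tiny_atoms(2),
                           qm_selection=frozenset({("A", 9, "XX")}))


class TestPairStates:
    def test_identical_structures_identity_correspondence(self, toy_pair):
        assert all(k == v for k, v in toy_pair.correspondence.items())
        assert not toy_pair.react_only and not toy_pair.ts_only

    def test_orphan_atom_recorded_not_fatal(self, toy_pair):
        """A hydrogen transferred (renamed host) leaves a logged orphan."""
        react = toy_pair.react
        renamed = []
        for a in react.atoms:
            if a.key == toy_pair.o_d_key:
                from dataclasses import replace
                a = replace(a, atom_name="ODH")
            renamed.append(a)
        qm_sel = frozenset(
            k if k != toy_pair.o_d_key else (k[0], k[1], "ODH")
            for k in react.qm_selection)
        ts = StateStructure(TS1, renamed, qm_selection=qm_sel)
        pair = pair_states(react, ts, "X:900:OP", "X:901:SD")
        assert toy_pair.o_d_key in pair.react_only
        assert (toy_pair.o_d_key[0], toy_pair.o_d_key[1], "ODH") in pair.ts_only
        assert len(pair.correspondence) == len(react) - 1

    def test_missing_reference_atom_is_error(self, toy_pair):
        with pytest.raises(StructureError, match="absent"):
            pair_states(toy_pair.react, toy_pair.ts, "X:900:OP1", "X:901:SD")


class TestSelectShell:
    def test_planted_distances_recovered_by_brute_force(self):
        """Shell equals the brute-force min-distance rule exactly."""
        layout = (("SER", 4.0, 6.0), ("LEU", 8.0, 9.5), ("ASP", 11.0, 12.5),
                  ("LYS", 9.8, 12.0), ("THR", 12.5, 10.5), ("PHE", 5.0, 7.0),
                  ("GLY", 5.0, 6.0), ("ALA", 5.5, 6.5), ("PRO", 6.0, 7.0),
                  ("ARG", 13.5, 11.8), ("GLN", 7.5, 9.0), ("VAL", 12.8, 13.5))
        pair, _ = make_toy_pair(ToySystemSpec(shell_layout=layout, seed=4),
                                resolve_clashes=True)
        shell = select_shell(pair, cutoff=10.0)

        react = pair.react
        site = react.coords_of(react.qm_selection)
        expected = set()
        for rid in react.residue_ids():
            atoms = react.residue_atoms(rid)
            if atoms[0].residue_name in ("GLY", "ALA", "PRO", "FLV", "DBT"):
                continue
            coords = np.array([a.coords for a in atoms])
            if cdist(coords, site).min() <= 10.0:
                expected.add(rid)
        assert set(shell.residues) == expected
        assert len(expected) > 0

    def test_gly_nearby_is_excluded(self):
        layout = (("GLY", 5.0, 6.5), ("SER", 5.0, 6.5))
        pair, _ = make_toy_pair(ToySystemSpec(shell_layout=layout, seed=1))
        shell = select_shell(pair, cutoff=10.0)
        names = {pair.react.residue_name(rid) for rid in shell}
        assert names == {"SER"}

    def test_monotone_in_cutoff(self, toy_pair):
        shells = [set(select_shell(toy_pair, cutoff=c).residues)
                  for c in (4.0, 7.0, 10.0, 15.0)]
        for smaller, larger in zip(shells, shells[1:]):
            assert smaller <= larger

    def test_invariant_under_rigid_motion_and_reordering(self, toy_pair):
        rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True)
        t = np.array([5.0, -3.0, 12.0])
        react = toy_pair.react.transformed(rot.as_matrix(), t)
        ts = toy_pair.ts.transformed(rot.as_matrix(), t)
        # reorder atoms too
        order = np.random.default_rng(0).permutation(len(react))
        react = StateStructure(REACT, [react.atoms[i] for i in order],
                               react.qm_selection)
        ts = StateStructure(TS1, [ts.atoms[i] for i in order],
                            ts.qm_selection)
        moved = pair_states(react, ts, "X:900:OP", "X:901:SD")
        assert (set(select_shell(moved, cutoff=10.0).residues)
                == set(select_shell(toy_pair, cutoff=10.0).residues))

    def test_empty_shell_warns(self, toy_pair):
        with pytest.warns(UserWarning, match="empty"):
            select_shell(toy_pair, cutoff=0.5)


def test_selector_parsing():
    assert parse_atom_selector("A:12") == ("A", 12)
    assert parse_atom_selector("X:900:OP") == ("X", 900, "OP")
    with pytest.raises(StructureError):
        parse_atom_selector("A")
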