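import numpy as np
import pytest

from helixmd.builder import build_chain, place_waters
from helixmd.core import (MolecularSystem, PDBParseError, RegionAnnotation,
                          TopologyMismatchError, combine_systems, read_annotation,
                          read_pdb, read_trajectory, select_atoms, write_annotation,
                          write_pdb, write_trajectory)


@pytest.fixture()
def two_chain_system():
    a = build_chain(["ALA", "GLY", "SER"], [(-60, -50)] * 3, chain_id="A")
    b = build_chain(["LEU", "VAL", "GLY"], [(-80, 80)] * 3, chain_id="B")
    return combine_systems(a, b)


class TestPDBRoundTrip:
    def test_roundtrip_preserves_identity_and_coordinates(self, tmp_path, two_chain_system):
        p = tmp_path / "sys.pdb"
        write_pdb(two_chain_system, p)
        back = read_pdb(p)
        assert len(back) == len(two_chain_system)
        assert back.chains == ["A", "B"]
        for a, b in zip(two_chain_system.atoms, back.atoms):
            assert (a.name, a.res_index, a.res_name, a.chain_id) == \
                   (b.name, b.res_index, b.res_name, b.chain_id)
        # PDB stores 3 decimals in Angstrom -> 1e-4 nm resolution
        assert np.abs(two_chain_system.coords() - back.coords()).max() <= 1e-4 + 1e-12

    def test_angstrom_to_nm_conversion(self, tmp_path):
        line = ("ATOM      1  CA  ALA A   1      15.000   0.000  -7.500"
                "  1.00  0.00           C")
        p = tmp_path / "one.pdb"
        p.write_text(line + "\nEND\n")
        s = read_pdb(p)
        assert np.allclose(s.atoms[0].position, [1.5, 0.0, -0.75])

    def test_ter_records_one_per_chain(self, tmp_path, two_chain_system):
        p = tmp_path / "sys.pdb"
        write_pdb(two_chain_system, p)
        text = p.read_text()
        assert text.count("TER") == 2
        assert text.rstrip().endswith("END")
        assert "ATOM" in text and "0.000" in text

    def test_malformed_atom_line_errors_with_line_number(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  CA  ALA A   1      xx.yyy   0.000   0.000\n")
        with pytest.raises(PDBParseError, match="line 1"):
            read_pdb(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(PDBParseError):
            read_pdb(p)

    def test_altloc_b_dropped_and_insertion_code_rejected(self, tmp_path):
        base = ("ATOM      1  CA  ALA A   1{ic}     1.000   0.000   0.000"
                "  1.00  0.00           C")
        p = tmp_path / "alt.pdb"
        p.write_text(
            "ATOM      1  CA AALA A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA BALA A   1       2.000   0.000   0.000  1.00  0.00           C\n"
        )
        s = read_pdb(p)
        assert len(s) == 1 and np.isclose(s.atoms[0].position[0], 0.1)
        p.write_text(base.format(ic="A") + "\n")
        with pytest.raises(PDBParseError, match="insertion"):
            read_pdb(p)

    def test_biopython_reads_written_file_identically(self, tmp_path, two_chain_system):
        """Independent cross-check of our writer against Bio.PDB's parser."""
        Bio = pytest.importorskip("Bio.PDB")
        p = tmp_path / "sys.pdb"
        write_pdb(two_chain_system, p)
        parser = Bio.PDBParser(QUIET=True)
        structure = parser.get_structure("x", str(p))
        atoms = list(structure.get_atoms())
        assert len(atoms) == len(two_chain_system)
        ours = two_chain_system.coords() * 10.0  # nm -> A
        theirs = np.array([a.get_coord() for a in atoms])
        assert np.abs(ours - theirs).max() < 2e-3


class TestTrajectoryIO:
    def test_multi_model_roundtrip(self, tmp_path, two_chain_system):
        from helixmd.builder import NoiseModel, generate_trajectory

        traj = generate_trajectory(two_chain_system, 3, NoiseModel(sigma=0.01, seed=4))
        p = tmp_path / "traj.pdb"
        write_trajectory(traj, p)
        back = read_trajectory(p, dt=1.0)
        assert back.n_frames == 3
        assert np.abs(back.frames - traj.frames).max() <= 1e-4 + 1e-12

    def test_single_model_file_equals_read_pdb(self, tmp_path, two_chain_system):
        p = tmp_path / "one.pdb"
        write_pdb(two_chain_system, p)
        traj = read_trajectory(p)
        assert traj.n_frames == 1
        assert np.allclose(traj.frames[0], read_pdb(p).coords())

    def test_mismatched_model_sizes_error(self, tmp_path):
        atom = ("ATOM      1  CA  ALA A   1       1.000   0.000   0.000"
                "  1.00  0.00           C")
        p = tmp_path / "bad.pdb"
        p.write_text(f"MODEL     1\n{atom}\nENDMDL\nMODEL     2\n{atom}\n{atom[:13]}"
                     f"N   ALA A   1       1.000   0.000   0.000  1.00  0.00           N\n"
                     "ENDMDL\nEND\n")
        with pytest.raises(TopologyMismatchError):
            read_trajectory(p)

    def test_times_strictly_increasing_enforced(self, two_chain_system):
        from helixmd.core import Trajectory

        frames = np.repeat(two_chain_system.coords()[None], 2, axis=0)
        with pytest.raises(ValueError):
            Trajectory(two_chain_system, frames, times=[1.0, 1.0])


class TestSelection:
    def test_tail_exclusions_match_chain_arithmetic(self):
        """63-residue chain minus 7-residue tail leaves 56 CA; a 58-residue
        chain with both tail7 and head4 leaves 47."""
        c63 = build_chain(["ALA"] * 63, [(-60, -50)] * 63)
        sel = select_atoms(c63, atoms=("CA",), exclude=("tail7",))
        assert len(sel) == 56
        c58 = build_chain(["ALA"] * 58, [(-60, -50)] * 58)
        sel = select_atoms(c58, atoms=("CA",), exclude=("tail7", "head4"))
        assert len(sel) == 47

    def test_glycine_chain_has_no_cb(self):
        g = build_chain(["GLY"] * 6, [(-60, -50)] * 6)
        assert len(select_atoms(g, atoms=("CB",))) == 0

    def test_unknown_chain_errors(self, two_chain_system):
        with pytest.raises(ValueError, match="unknown chain"):
            select_atoms(two_chain_system, chains=["Z"])

    def test_selection_is_order_stable_and_idempotent(self, two_chain_system):
        s1 = select_atoms(two_chain_system, atoms=("CA", "N"))
        s2 = select_atoms(two_chain_system, atoms=("N", "CA"))
        assert s1.refs == s2.refs
        # ordered by chain, then residue, then file order of atoms
        chains = [r[0] for r in s1.refs]
        assert chains == sorted(chains)


class TestAnnotation:
    def test_file_roundtrip(self, tmp_path, wtrop_bundle):
        _system, ann = wtrop_bundle
        p = tmp_path / "ann.tsv"
        write_annotation(ann, p)
        back = read_annotation(p)
        assert back.labels == ann.labels
        assert {k: bool(v) for k, v in back.hydrophobic.items()} == \
               {k: bool(v) for k, v in ann.hydrophobic.items()}

    def test_hairpin_without_loop_rejected(self):
        c = build_chain(["ALA"] * 10, [(-60, -50)] * 10)
        labels = {("A", r): ("HELIX1" if r <= 5 else "HELIX2") for r in range(1, 11)}
        ann = RegionAnnotation(labels=labels)
        with pytest.raises(ValueError, match="LOOP"):
            ann.validate(c)

    def test_residues_must_be_contiguous(self):
        a = build_chain(["ALA"] * 3, [(-60, -50)] * 3)
        atoms = [at for at in a.atoms if at.res_index != 2]
        with pytest.raises(ValueError, match="contiguous"):
            MolecularSystem(atoms)


def test_water_system_roundtrip_preserves_names(tmp_path):
    w = place_waters(np.array([2.0, 2.0, 2.0]), 5, min_dist=0.3, seed=1)
    p = tmp_path / "w.pdb"
    write_pdb(w, p)
    back = read_pdb(p)
    assert [a.name for a in back.atoms] == [a.name for a in w.atoms]
    assert len(back.water_residues()) == 5
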