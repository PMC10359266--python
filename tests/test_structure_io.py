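"""Parsing, writing, entity classification and censuses."""

import numpy as np
import pytest

from poregraph import (
    Atom,
    EntityClass,
    Residue,
    Structure,
    classify_entities,
    entity_census,
    parse_structure,
    write_structure,
)
from poregraph.synthetic import FixtureSpec, PlantedBond, make_fixture

THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       1.300   2.480   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       1.800   3.850   0.000  1.00  0.00           C
ATOM      6  N   SER A   3       0.900   4.900   0.500  1.00  0.00           N
ATOM      7  CA  SER A   3       1.300   6.300   0.600  1.00  0.00           C
ATOM      8  OG  SER A   3       0.200   7.100   1.200  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  SER A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  OG ASER A   1       2.000   1.000   0.000  0.60  0.00           O
ATOM      4  OG BSER A   1       2.000  -1.000   0.000  0.40  0.00           O
ATOM      5  CB ASER A   1       2.100   0.500   0.500  0.50  0.00           C
ATOM      6  CB BSER A   1       2.100  -0.500   0.500  0.50  0.00           C
ATOM      7  O   SER A   1       3.000   0.000   0.000  0.00  0.00           O
END
"""


def test_parse_small_pdb_roundtrips_counts(tmp_path):
    src = tmp_path / "three.pdb"
    src.write_text(THREE_RESIDUE_PDB)
    s = parse_structure(src)
    assert len(s.residues) == 3
    assert s.n_atoms() == 8
    assert [r.comp_id for r in s.residues] == ["ALA", "GLY", "SER"]
    assert s.residues[0].seq_num == 1

    out = tmp_path / "copy.pdb"
    write_structure(s, out, "PDB")
    s2 = parse_structure(out)
    assert s2.n_atoms() == s.n_atoms()
    assert [r.key for r in s2.residues] == [r.key for r in s.residues]
    assert np.allclose(s2.atom_coords(), s.atom_coords(), atol=1.5e-3)


def test_mmcif_roundtrip(tmp_path, basic_fixture):
    s, _ = basic_fixture
    out = tmp_path / "fixture.cif"
    write_structure(s, out)
    s2 = parse_structure(out, "mmCIF")
    assert s2.n_atoms() == s.n_atoms()
    assert sorted(r.key for r in s2.residues) == sorted(r.key for r in s.residues)
    assert np.allclose(
        np.sort(s2.atom_coords(), axis=0), np.sort(s.atom_coords(), axis=0), atol=1.5e-3
    )


def test_altloc_policy_keeps_highest_occupancy(tmp_path):
    src = tmp_path / "alt.pdb"
    src.write_text(ALTLOC_PDB)
    s = parse_structure(src)
    res = s.residues[0]
    og = res.get_atom("OG")
    assert og is not None and og.altloc == "A"  # 0.6 beats 0.4
    cb = res.get_atom("CB")
    assert cb is not None and cb.altloc == "A"  # tie broken alphabetically
    assert res.get_atom("O") is None  # zero occupancy dropped
    assert len(res.atoms) == 4


def test_parse_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        parse_structure(tmp_path / "missing.pdb")
    empty = tmp_path / "empty.pdb"
    empty.write_text("END\n")
    with pytest.raises(ValueError):
        parse_structure(empty)


def _het(chain, num, comp, atoms):
    return Residue(chain, num, "", comp, atoms)


def _single(chain, num, comp, element, xyz):
    return _het(chain, num, comp, [Atom(1, element, element, np.array(xyz))])


def test_classification_rules(basic_fixture):
    s, _ = basic_fixture
    extra = [
        _single("Q", 1, "HOH", "O", [50.0, 0, 0]),
        _single("Q", 2, "NA", "NA", [55.0, 0, 0]),
        _single("Q", 3, "XQZ", "FE", [60.0, 0, 0]),  # unknown single atom
        _het("Q", 4, "ZZZ", [Atom(1, "C1", "C", np.array([65.0, 0, 0])),
                             Atom(2, "C2", "C", np.array([66.0, 0, 0]))]),
        _single("Q", 5, "CLR", "C", [70.0, 0, 0]),
        _single("Q", 6, "PEE", "P", [75.0, 0, 0]),
        _single("Q", 7, "RET", "C", [80.0, 0, 0]),
    ]
    s2 = Structure(id="cls", residues=s.residues + extra)
    s2.assembly = {ch: 0 for ch in s2.chains()}
    cls = classify_entities(s2)
    get = lambda num: cls[("Q", num, "")]
    assert get(1) == EntityClass.WATER
    assert get(2) == EntityClass.MONATOMIC_ION
    assert get(3) == EntityClass.MONATOMIC_ION
    assert get(4) == EntityClass.OTHER_HET
    assert get(5) == EntityClass.STEROL
    assert get(6) == EntityClass.PHOSPHOLIPID
    assert get(7) == EntityClass.RETINAL
    # total function: every residue classified
    assert len(cls) == len(s2.residues)


def test_classification_override(basic_fixture):
    s, _ = basic_fixture
    extra = [_single("Q", 4, "ZZZ", "C", [65.0, 0, 0])]
    s2 = Structure(id="ovr", residues=s.residues + extra)
    cls = classify_entities(s2, overrides={EntityClass.PHOSPHOLIPID: {"ZZZ"}})
    assert cls[("Q", 4, "")] == EntityClass.PHOSPHOLIPID


def test_census_counts_planted_decoys():
    spec = FixtureSpec(
        seed=5,
        planted_hbonds=[PlantedBond(2, 21, 2.8)],
        n_decoy_waters=4,
        n_decoy_ions=2,
    )
    s, truth = make_fixture(spec)
    counts = entity_census(s)
    assert counts[EntityClass.WATER] == 4
    assert counts[EntityClass.MONATOMIC_ION] == 2
    assert counts[EntityClass.PROTEIN] == spec.n_residues
    # classification is total: class counts sum to residue count
    assert sum(counts.values()) == len(s.residues)


def test_census_protomer_sums_to_total(basic_fixture):
    """Two separated protomers: per-protomer censuses partition the total."""
    s, _ = basic_fixture
    shifted = []
    for r in s.residues:
        atoms = [
            Atom(a.serial, a.name, a.element, a.coords + np.array([80.0, 0, 0]),
                 a.occupancy, a.altloc)
            for a in r.atoms
        ]
        shifted.append(Residue(chr(ord(r.chain_id) + 1), r.seq_num, r.icode, r.comp_id, atoms))
    s2 = Structure(id="dimer", residues=s.residues + shifted)
    chains_a = set(s.chains())
    s2.assembly = {ch: (0 if ch in chains_a else 1) for ch in s2.chains()}
    total = entity_census(s2)
    p0 = entity_census(s2, 0)
    p1 = entity_census(s2, 1)
    for label in EntityClass.ALL:
        assert p0[label] + p1[label] == total[label]
    # het groups attach to the nearest protomer: the copy is symmetric
    assert p0 == p1
    with pytest.raises(ValueError):
        entity_census(s2, 5)
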