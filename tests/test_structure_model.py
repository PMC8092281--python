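"""Structure container, PDB/mmCIF round trips, selections, threading, identity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msring.model import (
    AtomRecord,
    DomainAnnotation,
    EmptySelectionError,
    StructureModel,
    ThreadingError,
    gapless_identity,
    read_structure,
    select,
    thread_sequence,
    write_structure,
)

ONE_ATOM_PDB = (
    "ATOM      1  CA  ALA A  58      12.345   6.789  -3.210  1.00 20.00           C\n"
    "END\n"
)

ALTLOC_PDB = (
    "ATOM      1  CA AALA A  58      10.000   0.000   0.000  0.40 20.00           C\n"
    "ATOM      2  CA BALA A  58      11.000   0.000   0.000  0.60 20.00           C\n"
    "ATOM      3  CA ASER A  59       0.000   1.000   0.000  0.50 20.00           C\n"
    "ATOM      4  CA BSER A  59       0.000   2.000   0.000  0.50 20.00           C\n"
    "HETATM    5  O   HOH A 201       5.000   5.000   5.000  1.00 30.00           O\n"
    "END\n"
)


def test_minimal_pdb_read(tmp_path):
    p = tmp_path / "one.pdb"
    p.write_text(ONE_ATOM_PDB)
    m = read_structure(p)
    assert len(m) == 1
    a = m.atoms[0]
    assert a.atom_name == "CA" and a.residue_index == 58 and a.chain_id == "A"
    np.testing.assert_allclose(a.position, [12.345, 6.789, -3.210])


@pytest.mark.parametrize("suffix", [".pdb", ".cif"])
def test_roundtrip_preserves_everything(tmp_path, subunit, suffix):
    p = tmp_path / ("ring" + suffix)
    write_structure(subunit, p)
    back = read_structure(p)
    assert len(back) == len(subunit)
    assert back.chain_ids == subunit.chain_ids
    assert [a.residue_index for a in back.atoms] == [a.residue_index for a in subunit.atoms]
    assert [a.atom_name for a in back.atoms] == [a.atom_name for a in subunit.atoms]
    # PDB coordinates carry 3 decimals
    np.testing.assert_allclose(back.coords(), subunit.coords(), atol=5e-4)


def test_unknown_format_and_missing_file(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_structure(tmp_path / "absent.pdb")
    p = tmp_path / "x.pdb"
    p.write_text("not a structure\n")
    with pytest.raises(ValueError):
        read_structure(p)
    p.write_text(ONE_ATOM_PDB)
    with pytest.raises(ValueError, match="format"):
        read_structure(p, format="xyz")


def test_altloc_keeps_highest_occupancy_tie_first(tmp_path):
    p = tmp_path / "alt.pdb"
    p.write_text(ALTLOC_PDB)
    m = read_structure(p)
    cas = [a for a in m.atoms if a.atom_name == "CA"]
    assert len(cas) == 2
    assert cas[0].position[0] == pytest.approx(11.0)  # occupancy 0.6 wins
    assert cas[1].position[1] == pytest.approx(1.0)  # tie -> first encountered
    het = [a for a in m.atoms if a.hetero]
    assert len(het) == 1 and het[0].residue_name == "HOH"


def test_atomrecord_invariants():
    with pytest.raises(ValueError):
        AtomRecord("C", "CA", 1, "ALA", "A", np.array([np.nan, 0, 0]))
    with pytest.raises(ValueError):
        AtomRecord("C", "CA", 1, "ALA", "A", np.zeros(3), occupancy=1.5)
    with pytest.raises(ValueError, match="duplicate"):
        a = AtomRecord("C", "CA", 1, "ALA", "A", np.zeros(3))
        StructureModel([a, a])


def test_select_ca_and_ranges(subunit):
    d1 = next(d for d in subunit.domains if d.name == "D1")
    cas = select(subunit, chain="A", residue_range=d1, atom_filter="CA")
    assert len(cas) == len(d1)
    assert all(a.atom_name == "CA" for a in cas.atoms)
    # original untouched, ordering preserved
    assert [a.residue_index for a in cas.atoms] == sorted(
        a.residue_index for a in cas.atoms
    )


def test_select_empty_is_an_error(subunit):
    d1 = next(d for d in subunit.domains if d.name == "D1")
    d1_only = select(subunit, residue_range=d1)
    d2 = next(d for d in subunit.domains if d.name == "D2")
    with pytest.raises(EmptySelectionError):
        select(d1_only, residue_range=d2)


def test_domain_annotation_scheme_offset():
    aa = DomainAnnotation("frag", 58, 213, "Aa")
    st_ = aa.to_scheme("St")
    assert (st_.residue_start, st_.residue_end) == (60, 215)
    assert st_.to_scheme("Aa") == aa
    with pytest.raises(ValueError):
        DomainAnnotation("bad", 10, 5)


def test_thread_identity_is_identity(subunit):
    seq = subunit.sequence("A")
    out = thread_sequence(subunit, seq, offset=0)
    assert len(out) == len(subunit)
    np.testing.assert_array_equal(out.coords(), subunit.coords())


def test_thread_polyglycine_strips_to_backbone(subunit):
    n = len(subunit.residue_indices())
    out = thread_sequence(subunit, "G" * n)
    assert all(a.atom_name in ("N", "CA", "C", "O", "OXT") for a in out.atoms)


def test_thread_offset_relabels_and_keeps_backbone(subunit):
    seq = subunit.sequence("A")
    # mutate a few positions so substitution paths are exercised
    mutated = "W" + seq[1:-1] + "W"
    out = thread_sequence(subunit, mutated, offset=2)
    first = subunit.residue_indices()[0]
    assert out.residue_indices()[0] == first + 2
    # backbone never moves: CA coordinates identical in order
    ca_in = [a.position for a in subunit.atoms if a.atom_name == "CA"]
    ca_out = [a.position for a in out.atoms if a.atom_name == "CA"]
    np.testing.assert_array_equal(np.stack(ca_in), np.stack(ca_out))


def test_thread_errors(subunit):
    with pytest.raises(ThreadingError, match="gapless"):
        thread_sequence(subunit, "AAA")
    n = len(subunit.residue_indices())
    with pytest.raises(ThreadingError, match="non-standard"):
        thread_sequence(subunit, "B" * n)


def test_gapless_identity_basics():
    assert gapless_identity("ACDEF", "ACDEF") == 100.0
    assert gapless_identity("ACDE", "WYFH") == 0.0
    with pytest.raises(ValueError, match="undefined"):
        gapless_identity("ACD", "AC")


@settings(deadline=None, max_examples=50)
@given(
    st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60),
    st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60),
)
def test_gapless_identity_symmetric(a, b):
    if len(a) != len(b):
        b = (b * (len(a) // len(b) + 1))[: len(a)]
    assert gapless_identity(a, b) == gapless_identity(b, a)
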