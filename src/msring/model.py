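"""Atomic-structure data model and I/O.

The universal coordinate container for every object in the pipeline — a
single two-domain subunit, a pruned domain, a full multi-chain ring, or the
assembled periplasmic MS-ring model.  Atoms keep the author residue
numbering of the source file because every residue cited in the literature
on FliF (H156, S200, C147, C182, the i-loop 157–170) is given in author
numbering.

Parsing and serialization of PDB/mmCIF go through :mod:`gemmi`; the
in-memory representation is a flat, ordered list of atom records plus a
derived chain index, which is all the downstream geometry needs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "DomainAnnotation",
    "EmptySelectionError",
    "ThreadingError",
    "read_structure",
    "write_structure",
    "read_fasta",
    "select",
    "thread_sequence",
    "gapless_identity",
]

# Standard amino acids, 1-letter -> 3-letter.
AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_3TO1 = {v: k for k, v in AA_1TO3.items()}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class EmptySelectionError(ValueError):
    """Raised when a selection matches no atoms."""


class ThreadingError(ValueError):
    """Raised when a target sequence cannot be threaded gaplessly."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom with author numbering and Cartesian coordinates in Å."""

    element: str
    atom_name: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    b_factor: float = 0.0
    hetero: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom position must be a finite 3-vector, got {pos!r}")
        object.__setattr__(self, "position", pos)
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    def moved_to(self, position: np.ndarray) -> "AtomRecord":
        return replace(self, position=np.asarray(position, dtype=float))


@dataclass(frozen=True)
class DomainAnnotation:
    """Named residue range under one of the two FliF numbering schemes.

    The Aquifex (Aa) and Salmonella (St) numbering schemes for the
    N-terminal periplasmic fragment are related by a fixed offset of +2
    (Aa 58–213 corresponds to St 60–215, with no insertions or deletions).
    """

    name: str
    residue_start: int
    residue_end: int
    numbering_scheme: str = "Aa"

    #: offset added to an Aa residue index to obtain the St index
    AA_TO_ST_OFFSET = 2

    def __post_init__(self) -> None:
        if self.residue_start > self.residue_end:
            raise ValueError(
                f"residue_start {self.residue_start} > residue_end {self.residue_end}"
            )
        if self.numbering_scheme not in ("Aa", "St"):
            raise ValueError(f"unknown numbering scheme {self.numbering_scheme!r}")

    def to_scheme(self, scheme: str) -> "DomainAnnotation":
        if scheme == self.numbering_scheme:
            return self
        off = self.AA_TO_ST_OFFSET if scheme == "St" else -self.AA_TO_ST_OFFSET
        return DomainAnnotation(
            self.name, self.residue_start + off, self.residue_end + off, scheme
        )

    def __len__(self) -> int:
        return self.residue_end - self.residue_start + 1


# Canonical FliF domain boundaries (Aquifex numbering): the fragment spans
# 58–213 and splits into a compact D1 (RBM1) and an elongated D2 (RBM2).
D1_AA = DomainAnnotation("D1", 58, 122, "Aa")
D2_AA = DomainAnnotation("D2", 123, 213, "Aa")
ILOOP_AA = DomainAnnotation("i-loop", 157, 170, "Aa")


class StructureModel:
    """Ordered collection of atom records grouped into chains and residues.

    Invariant: ``(chain_id, residue_index, atom_name)`` is unique; chain
    iteration order follows input order.
    """

    def __init__(
        self,
        atoms: Iterable[AtomRecord],
        metadata: str = "",
        domains: Sequence[DomainAnnotation] = (),
    ) -> None:
        self.atoms: list[AtomRecord] = list(atoms)
        self.metadata = metadata
        self.domains: list[DomainAnnotation] = list(domains)
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_index, a.atom_name)
            if key in seen:
                raise ValueError(f"duplicate atom record {key}")
            seen.add(key)

    # -- basic introspection -------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    @property
    def chains(self) -> dict[str, tuple[int, int]]:
        """chain_id -> (min residue_index, max residue_index)."""
        out: dict[str, tuple[int, int]] = {}
        for a in self.atoms:
            lo, hi = out.get(a.chain_id, (a.residue_index, a.residue_index))
            out[a.chain_id] = (min(lo, a.residue_index), max(hi, a.residue_index))
        return out

    def residue_indices(self, chain_id: str | None = None) -> list[int]:
        seen: list[int] = []
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if a.residue_index not in seen:
                seen.append(a.residue_index)
        return seen

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain in residue order (X for non-standard)."""
        letters: list[str] = []
        last = None
        for a in self.atoms:
            if a.chain_id != chain_id or a.hetero:
                continue
            if a.residue_index != last:
                letters.append(AA_3TO1.get(a.residue_name, "X"))
                last = a.residue_index
        return "".join(letters)

    # -- coordinates ---------------------------------------------------------

    def coords(self) -> np.ndarray:
        """All atom positions as an (N, 3) array (a copy)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.position for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(self.atoms)}, 3)")
        atoms = [a.moved_to(c) for a, c in zip(self.atoms, coords)]
        return StructureModel(atoms, self.metadata, self.domains)

    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)

    def radius_of_gyration(self) -> float:
        c = self.coords()
        return float(np.sqrt(np.mean(np.sum((c - c.mean(axis=0)) ** 2, axis=1))))

    # -- editing -------------------------------------------------------------

    def renamed_chains(self, mapping: dict[str, str]) -> "StructureModel":
        atoms = [
            replace(a, chain_id=mapping.get(a.chain_id, a.chain_id))
            for a in self.atoms
        ]
        return StructureModel(atoms, self.metadata, self.domains)

    def merged_with(self, other: "StructureModel") -> "StructureModel":
        overlap = set(self.chain_ids) & set(other.chain_ids)
        if overlap:
            raise ValueError(f"chain id collision: {sorted(overlap)}")
        return StructureModel(
            self.atoms + other.atoms,
            self.metadata,
            list(self.domains) + list(other.domains),
        )

    def copy(self) -> "StructureModel":
        return StructureModel(list(self.atoms), self.metadata, list(self.domains))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _from_gemmi(st: gemmi.Structure) -> StructureModel:
    st.setup_entities()
    atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            # altloc policy: keep the highest-occupancy conformer, ties ->
            # first encountered (deterministic).
            by_name: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = by_name.get(at.name)
                if prev is None or at.occ > prev.occ:
                    by_name[at.name] = at
            for at in res:
                if by_name.get(at.name) is not at:
                    continue
                atoms.append(
                    AtomRecord(
                        element=at.element.name,
                        atom_name=at.name,
                        residue_index=res.seqid.num,
                        residue_name=res.name,
                        chain_id=chain.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        b_factor=at.b_iso,
                        hetero=het,
                    )
                )
    return StructureModel(atoms, metadata=st.name)


def _to_gemmi(model: StructureModel, name: str = "msring") -> gemmi.Structure:
    # gemmi's add_chain/add_residue copy their argument, so the hierarchy is
    # assembled bottom-up: residues -> chains -> model -> structure.
    grouped: dict[str, list[tuple[int, list[AtomRecord]]]] = {}
    for a in model.atoms:
        runs = grouped.setdefault(a.chain_id, [])
        if not runs or runs[-1][0] != a.residue_index:
            runs.append((a.residue_index, []))
        runs[-1][1].append(a)

    st = gemmi.Structure()
    st.name = name
    md = gemmi.Model("1")
    for chain_id, runs in grouped.items():
        ch = gemmi.Chain(chain_id)
        for residue_index, recs in runs:
            res = gemmi.Residue()
            res.name = recs[0].residue_name
            res.seqid = gemmi.SeqId(residue_index, " ")
            res.het_flag = "H" if recs[0].hetero else "A"
            for a in recs:
                at = gemmi.Atom()
                at.name = a.atom_name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.position)
                at.occ = a.occupancy
                at.b_iso = a.b_factor
                res.add_atom(at)
            ch.add_residue(res)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    return st


def read_structure(path: str | Path, format: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``format`` is ``"pdb"`` or ``"mmcif"``; when omitted it is inferred from
    the file extension.  Hetero/solvent records are retained but flagged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown structure format {format!r}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
    except (RuntimeError, ValueError, IndexError) as exc:
        raise ValueError(f"cannot parse {path} as {format}: {exc}") from exc
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise ValueError(f"{path}: no atoms found")
    return _from_gemmi(st)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as PDB or mmCIF, by extension (.pdb / .cif)."""
    path = Path(path)
    st = _to_gemmi(model)
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences from a FASTA file: id -> sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def select(
    model: StructureModel,
    chain: str | None = None,
    residue_range: DomainAnnotation | tuple[int, int] | None = None,
    atom_filter: str = "all",
) -> StructureModel:
    """Subset a model by chain, author-residue range and atom class.

    ``atom_filter`` is one of ``all``, ``CA``, ``heavy``.  Ordering and
    numbering are preserved; the input model is untouched.  An empty result
    raises :class:`EmptySelectionError` rather than returning silently.
    """
    if atom_filter not in ("all", "CA", "heavy"):
        raise ValueError(f"unknown atom_filter {atom_filter!r}")
    if isinstance(residue_range, tuple):
        residue_range = DomainAnnotation("range", *residue_range)
    out: list[AtomRecord] = []
    for a in model.atoms:
        if chain is not None and a.chain_id != chain:
            continue
        if residue_range is not None and not (
            residue_range.residue_start <= a.residue_index <= residue_range.residue_end
        ):
            continue
        if atom_filter == "CA" and a.atom_name != "CA":
            continue
        if atom_filter == "heavy" and not a.is_heavy:
            continue
        out.append(a)
    if not out:
        raise EmptySelectionError(
            f"selection (chain={chain}, range={residue_range}, filter={atom_filter}) "
            "matched no atoms"
        )
    doms = list(model.domains)
    if residue_range is not None and residue_range not in doms:
        doms.append(residue_range)
    return StructureModel(out, model.metadata, doms)


# ---------------------------------------------------------------------------
# Gapless threading and identity
# ---------------------------------------------------------------------------

def thread_sequence(
    template: StructureModel, target_sequence: str, offset: int = 0
) -> StructureModel:
    """Thread a homologous sequence onto a template backbone, gaplessly.

    Residue *i* of the template becomes residue *i + offset* of the target,
    with the target residue name.  Backbone coordinates are copied verbatim
    (backbone RMSD to the template is exactly zero); side-chain atoms beyond
    CB are dropped for substituted residues, since the downstream use is
    rigid fitting into 6–9 Å density where side chains are unresolved.
    """
    target_sequence = target_sequence.strip().upper()
    for letter in target_sequence:
        if letter not in AA_1TO3:
            raise ThreadingError(f"non-standard residue code {letter!r}")
    res_idx = model_residues(template)
    if len(res_idx) != len(target_sequence):
        raise ThreadingError(
            f"gapless threading undefined: template has {len(res_idx)} residues, "
            f"target sequence has {len(target_sequence)}"
        )
    new_name = {
        idx: AA_1TO3[target_sequence[k]] for k, (_, idx) in enumerate(res_idx)
    }
    old_name = {idx: name for (name, idx) in res_idx}
    atoms: list[AtomRecord] = []
    for a in template.atoms:
        if a.hetero:
            continue
        substituted = new_name[a.residue_index] != old_name[a.residue_index]
        if substituted and a.atom_name not in BACKBONE_ATOMS | {"CB"}:
            continue
        # CB is kept only if the target residue has one (glycine does not)
        if substituted and a.atom_name == "CB" and new_name[a.residue_index] == "GLY":
            continue
        atoms.append(
            replace(
                a,
                residue_index=a.residue_index + offset,
                residue_name=new_name[a.residue_index],
            )
        )
    doms = [d.to_scheme(d.numbering_scheme) for d in template.domains]
    return StructureModel(atoms, template.metadata + " [threaded]", doms)


def model_residues(model: StructureModel) -> list[tuple[str, int]]:
    """Ordered (residue_name, residue_index) pairs of non-hetero residues."""
    out: list[tuple[str, int]] = []
    last: int | None = None
    for a in model.atoms:
        if a.hetero:
            continue
        if a.residue_index != last:
            out.append((a.residue_name, a.residue_index))
            last = a.residue_index
    return out


def gapless_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of two equal-length sequences, no alignment.

    Returns 100 × matches / length, rounded to 1 decimal.  Unequal lengths
    are an error: gapless identity is undefined when an alignment would be
    needed.
    """
    seq_a, seq_b = seq_a.strip().upper(), seq_b.strip().upper()
    if len(seq_a) != len(seq_b):
        raise ValueError(
            "gapless identity is undefined for unequal lengths "
            f"({len(seq_a)} vs {len(seq_b)}); align the sequences first"
        )
    if not seq_a:
        raise ValueError("empty sequences")
    matches = sum(1 for x, y in zip(seq_a, seq_b) if x == y)
    return round(100.0 * matches / len(seq_a), 1)
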