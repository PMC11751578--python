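"""Structure I/O and the shared hierarchical data model.

The in-memory model is deliberately small: chains of residues of atoms, with
Angstrom coordinates in numpy arrays.  Parsing and serialization of PDB and
mmCIF go through gemmi; this module owns filtering (protein only, first
model), altloc collapse, hydrogen removal and non-standard residue mapping.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

from .errors import EmptyStructureError, FormatCapacityError, StructureParseError
from .idealgeom import (
    NONSTANDARD_ATOM_RENAME,
    NONSTANDARD_MAP,
    STANDARD_AA,
    THREE_TO_ONE,
    element_of,
)

logger = logging.getLogger("templateprobe.structio")

# PDB fixed-width coordinate field is %8.3f: |x| must stay below 10^4
_PDB_COORD_LIMIT = 9999.999


@dataclass
class Atom:
    """One heavy atom: PDB-style name, element, coordinate in Angstrom."""

    name: str
    element: str
    coord: np.ndarray
    bfactor: float = 0.0
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: non-finite coordinate")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coord.copy(),
                    self.bfactor, self.altloc, self.occupancy)


@dataclass
class Residue:
    """One amino-acid residue with an ordered atom list."""

    resname: str
    seqnum: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def get(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.get(name)
        return None if a is None else a.coord

    @property
    def backbone_complete(self) -> bool:
        return all(self.get(n) is not None for n in ("N", "CA", "C"))

    @property
    def key(self) -> tuple[int, str]:
        return (self.seqnum, self.icode)

    def copy(self) -> "Residue":
        return Residue(self.resname, self.seqnum, self.icode,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class Structure:
    """An all-atom protein structure: ordered chains of ordered residues."""

    chains: list[Chain] = field(default_factory=list)
    source: str = ""

    # -- iteration helpers -------------------------------------------------
    def iter_residues(self) -> Iterator[tuple[str, Residue]]:
        for ch in self.chains:
            for res in ch.residues:
                yield ch.chain_id, res

    def iter_atoms(self) -> Iterator[tuple[str, Residue, Atom]]:
        for ch in self.chains:
            for res in ch.residues:
                for atom in res.atoms:
                    yield ch.chain_id, res, atom

    @property
    def residues(self) -> list[Residue]:
        return [r for _, r in self.iter_residues()]

    @property
    def n_residues(self) -> int:
        return sum(len(ch.residues) for ch in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for _, r in self.iter_residues())

    def coords(self) -> np.ndarray:
        """All atomic coordinates, file order, shape (n_atoms, 3)."""
        if self.n_atoms == 0:
            return np.zeros((0, 3))
        return np.array([a.coord for _, _, a in self.iter_atoms()])

    def set_coords(self, xyz: np.ndarray) -> None:
        """Overwrite all atomic coordinates in file order."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise ValueError(f"expected shape {(self.n_atoms, 3)}, got {xyz.shape}")
        for i, (_, _, atom) in enumerate(self.iter_atoms()):
            atom.coord = xyz[i].copy()

    def copy(self) -> "Structure":
        return Structure([ch.copy() for ch in self.chains], self.source)


@dataclass
class SequenceRecord:
    id: str
    sequence: str


# ------------------------------------------------------------------ reading

def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    # sniff: mmCIF files start with 'data_'
    try:
        head = path.read_text(errors="ignore")[:512]
    except OSError:
        return "pdb"
    return "mmcif" if head.lstrip().startswith("data_") else "pdb"


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a protein structure from PDB or mmCIF.

    Keeps the first model only; drops waters, ligands and other hetero
    molecules; keeps every protein chain.  Raises
    :class:`StructureParseError` on malformed input and
    :class:`EmptyStructureError` when no protein residue survives.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = _detect_format(path) if format == "auto" else format
    try:
        if fmt == "mmcif":
            gst = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        elif fmt == "pdb":
            gst = gemmi.read_pdb(str(path))
        else:
            raise StructureParseError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path} as {fmt}: {exc}") from exc

    gst.setup_entities()
    structure = Structure(source=str(path))
    if len(gst) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = gst[0]
    for gchain in model:
        chain = Chain(gchain.name)
        for gres in gchain:
            info = gemmi.find_tabulated_residue(gres.name)
            is_aa = (info is not None and info.is_amino_acid()) or gres.name in STANDARD_AA
            if not is_aa:
                continue
            res = Residue(gres.name, gres.seqid.num, gres.seqid.icode.strip())
            for gatom in gres:
                res.atoms.append(Atom(
                    name=gatom.name,
                    element=gatom.element.name,
                    coord=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    bfactor=gatom.b_iso,
                    altloc=gatom.altloc.strip() if gatom.altloc != "\x00" else "",
                    occupancy=gatom.occ,
                ))
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            structure.chains.append(chain)
    if structure.n_residues == 0:
        raise EmptyStructureError(f"{path}: no protein residues after filtering")
    return structure


# ------------------------------------------------------------------ writing

def _to_gemmi(s: Structure) -> gemmi.Structure:
    gst = gemmi.Structure()
    gst.name = "templateprobe"
    model = gemmi.Model("1")
    for chain in s.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.resname
            gres.seqid = gemmi.SeqId(res.seqnum, res.icode if res.icode else " ")
            gres.het_flag = "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.b_iso = atom.bfactor
                ga.occ = atom.occupancy
                if atom.altloc:
                    ga.altloc = atom.altloc
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    gst.add_model(model)
    gst.setup_entities()
    return gst


def write_structure(s: Structure, path: str | Path, format: str = "auto") -> None:
    """Write a structure as PDB or mmCIF (format inferred from suffix if auto)."""
    path = Path(path)
    if s.n_residues == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "pdb":
        xyz = s.coords()
        if np.abs(xyz).max() > _PDB_COORD_LIMIT:
            raise FormatCapacityError(
                "coordinates exceed the fixed-width PDB field (|x| <= 9999.999 A); "
                "write mmCIF instead")
    gst = _to_gemmi(s)
    if fmt == "pdb":
        gst.write_pdb(str(path))
    elif fmt == "mmcif":
        gst.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


# ------------------------------------------------------------- standardize

def standardize(s: Structure) -> Structure:
    """Normalize a parsed structure for metric evaluation.

    * keep a single altloc per atom (highest occupancy; ties -> blank/'A'
      first, i.e. lexicographically smallest label);
    * remove hydrogens (and deuterium);
    * map supported non-standard residues to their standard parent (with
      atom renames, e.g. MSE SE->SD); drop unmappable residues with a log
      entry;
    * sort residues within each chain by (seqnum, icode).

    Idempotent; never adds atoms.
    """
    out = Structure(source=s.source)
    for chain in s.chains:
        new_chain = Chain(chain.chain_id)
        for res in chain.residues:
            resname = res.resname
            rename: dict[str, str] = {}
            if resname not in STANDARD_AA:
                if resname in NONSTANDARD_MAP:
                    rename = NONSTANDARD_ATOM_RENAME.get(resname, {})
                    logger.info("mapping non-standard residue %s%s -> %s",
                                resname, res.seqnum, NONSTANDARD_MAP[resname])
                    resname = NONSTANDARD_MAP[resname]
                else:
                    logger.warning("dropping unmappable residue %s %s%s",
                                   resname, chain.chain_id, res.seqnum)
                    continue
            new_res = Residue(resname, res.seqnum, res.icode)
            best: dict[str, Atom] = {}
            for atom in res.atoms:
                if atom.element.upper() in ("H", "D"):
                    continue
                name = rename.get(atom.name, atom.name)
                prev = best.get(name)
                if prev is None or (atom.occupancy, _altloc_rank(atom.altloc)) > (
                        prev.occupancy, _altloc_rank(prev.altloc)):
                    a = atom.copy()
                    a.name = name
                    a.element = element_of(name) if atom.name in rename else a.element
                    a.altloc = ""
                    best[name] = a
            # preserve original atom order
            seen = set()
            for atom in res.atoms:
                name = rename.get(atom.name, atom.name)
                if name in best and name not in seen:
                    new_res.atoms.append(best[name])
                    seen.add(name)
            if new_res.atoms:
                new_chain.residues.append(new_res)
        new_chain.residues.sort(key=lambda r: (r.seqnum, r.icode))
        if new_chain.residues:
            out.chains.append(new_chain)
    return out


def _altloc_rank(altloc: str) -> float:
    # higher rank wins at equal occupancy; blank/'A' preferred -> rank by
    # negative lexicographic position
    return -ord(altloc) if altloc else 0.0


# --------------------------------------------------------------- sequences

def extract_sequence(s: Structure) -> list[SequenceRecord]:
    """One gapless sequence record per chain.

    Numbering gaps insert nothing: the sequence is exactly one letter per
    resolved residue, in chain order.  Unknown residue types emit 'X'.
    """
    records = []
    for chain in s.chains:
        letters = []
        for res in chain.residues:
            letter = THREE_TO_ONE.get(res.resname)
            if letter is None:
                mapped = NONSTANDARD_MAP.get(res.resname)
                letter = THREE_TO_ONE.get(mapped, "X") if mapped else "X"
                if letter == "X":
                    logger.warning("unknown residue %s -> 'X'", res.resname)
            letters.append(letter)
        records.append(SequenceRecord(chain.chain_id, "".join(letters)))
    return records
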