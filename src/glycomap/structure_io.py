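"""Macromolecular structure I/O and residue categorisation.

Reads and writes coordinate files in the fixed-column PDB dialect and
assigns each residue to one of four categories (protein, saccharide,
water, other) from a shipped, user-extensible component table.  The
parser is backed by :mod:`biotite`; the in-memory model is a small
residue/atom hierarchy tailored to the downstream geometry operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureModel",
    "parse_structure",
    "classify_residues",
    "write_structure",
    "load_component_table",
    "AMINO_ACIDS",
    "SACCHARIDES",
]

#: The 20 standard amino acids (3-letter component codes).
AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


def load_component_table(extra: Path | str | None = None) -> dict[str, str]:
    """Return the comp_name -> category table.

    The built-in table ships as ``data/components.tsv`` inside the package;
    *extra* may point to a user file in the same two-column TSV format whose
    entries override the defaults.
    """
    table: dict[str, str] = {}

    def _read(text: str) -> None:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            comp, category = line.split("\t")[:2]
            table[comp.strip().upper()] = category.strip()

    _read(resources.files("glycomap").joinpath("data/components.tsv").read_text())
    if extra is not None:
        _read(Path(extra).read_text())
    return table


SACCHARIDES = frozenset(
    comp for comp, cat in load_component_table().items() if cat == "saccharide"
)


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


@dataclass
class AtomRecord:
    """A single heavy atom (PDB naming convention)."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    b_iso: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class ResidueRecord:
    chain_id: str
    seq_num: int
    icode: str
    comp_name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    category: str = "other"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.element not in ("H", "D")]

    def __repr__(self) -> str:  # compact, used in warnings
        return f"{self.comp_name} {self.chain_id}{self.seq_num}{self.icode.strip()}"


@dataclass
class StructureModel:
    id: str
    residues: list[ResidueRecord] = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"{self.id}: duplicate (chain, seq_num, icode) residue keys")

    def __iter__(self) -> Iterator[ResidueRecord]:
        return iter(self.residues)

    def find(self, chain_id: str, seq_num: int, icode: str = "") -> ResidueRecord | None:
        for r in self.residues:
            if r.key == (chain_id, seq_num, icode):
                return r
        return None

    def by_category(self, category: str) -> list[ResidueRecord]:
        return [r for r in self.residues if r.category == category]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def copy(self) -> "StructureModel":
        residues = [
            replace(r, atoms=[replace(a, position=a.position.copy()) for a in r.atoms])
            for r in self.residues
        ]
        return StructureModel(id=self.id, residues=residues, source_path=self.source_path)


def parse_structure(
    path: Path | str, altloc_policy: str = "occupancy", model_id: str | None = None
) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    ``altloc_policy='occupancy'`` (the default) keeps, per atom site, the
    alternate conformer with the highest occupancy, ties broken by altloc
    character order; ``'all'`` keeps every conformer.
    """
    path = Path(path)
    if altloc_policy not in ("occupancy", "all"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(
            model=1, altloc="all", extra_fields=["occupancy", "b_factor"]
        )
    except Exception as exc:  # biotite raises various types; unify
        raise StructureParseError(f"{path}: cannot parse PDB file: {exc}") from exc
    if atoms.array_length() == 0:
        raise StructureParseError(f"{path}: empty model (no ATOM/HETATM records)")

    model = StructureModel(
        id=model_id if model_id is not None else path.stem.upper(),
        source_path=str(path),
    )
    current: ResidueRecord | None = None
    for i in range(atoms.array_length()):
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]), str(atoms.ins_code[i]).strip())
        if current is None or current.key != key or current.comp_name != str(atoms.res_name[i]):
            current = ResidueRecord(
                chain_id=key[0], seq_num=key[1], icode=key[2], comp_name=str(atoms.res_name[i])
            )
            model.residues.append(current)
        current.atoms.append(
            AtomRecord(
                name=str(atoms.atom_name[i]),
                element=str(atoms.element[i]).capitalize(),
                position=np.array(atoms.coord[i], dtype=float),
                occupancy=float(np.clip(atoms.occupancy[i], 0.0, 1.0)),
                altloc=str(atoms.altloc_id[i]).strip() if hasattr(atoms, "altloc_id") else "",
                b_iso=float(atoms.b_factor[i]),
            )
        )
    # dedupe residues that re-raised the same key (biotite keeps file order)
    model = _merge_residue_fragments(model)
    if altloc_policy == "occupancy":
        model = _resolve_altlocs(model)
    return classify_residues(model)


def _merge_residue_fragments(model: StructureModel) -> StructureModel:
    merged: dict[tuple, ResidueRecord] = {}
    order: list[tuple] = []
    for r in model.residues:
        k = (*r.key, r.comp_name)
        if k in merged:
            merged[k].atoms.extend(r.atoms)
        else:
            merged[k] = r
            order.append(k)
    return StructureModel(id=model.id, residues=[merged[k] for k in order], source_path=model.source_path)


def _resolve_altlocs(model: StructureModel) -> StructureModel:
    for res in model.residues:
        best: dict[str, AtomRecord] = {}
        for a in res.atoms:
            prev = best.get(a.name)
            if prev is None:
                best[a.name] = a
            elif (a.occupancy, _altloc_rank(a.altloc)) > (
                prev.occupancy,
                _altloc_rank(prev.altloc),
            ):
                best[a.name] = a
        res.atoms = [best[a.name] for a in res.atoms if best.get(a.name) is a]
    return model


def _altloc_rank(altloc: str) -> float:
    # higher rank wins; blank beats any letter, 'A' beats 'B', ...
    if not altloc:
        return 0.0
    return -ord(altloc)


def classify_residues(
    model: StructureModel, table: dict[str, str] | None = None
) -> StructureModel:
    """Assign a category to every residue (total and idempotent)."""
    table = table if table is not None else load_component_table()
    for res in model.residues:
        res.category = table.get(res.comp_name.upper(), "other")
    return model


_PDB_ATOM_FMT = (
    "{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{res:<3s} {chain:1s}"
    "{seq:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2s}"
)


def write_structure(model: StructureModel, path: Path | str) -> None:
    """Write *model* as fixed-column PDB text (re-parseable by parse_structure)."""
    if not model.residues or model.n_atoms == 0:
        raise ValueError("refusing to write an empty model")
    lines: list[str] = []
    serial = 0
    prev_chain = None
    for res in model.residues:
        record = "ATOM" if res.category == "protein" else "HETATM"
        if prev_chain is not None and res.chain_id != prev_chain and lines:
            lines.append("TER")
        prev_chain = res.chain_id
        for a in res.atoms:
            serial += 1
            if not all(math.isfinite(v) and abs(v) < 9999.0 for v in a.position):
                raise ValueError(f"atom {a.name} in {res!r}: coordinate out of PDB range")
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                _PDB_ATOM_FMT.format(
                    record=record,
                    serial=serial,
                    name=name,
                    altloc=a.altloc or " ",
                    res=res.comp_name,
                    chain=res.chain_id or "A",
                    seq=res.seq_num,
                    icode=res.icode or " ",
                    x=a.position[0],
                    y=a.position[1],
                    z=a.position[2],
                    occ=a.occupancy,
                    b=a.b_iso,
                    element=a.element.upper(),
                )
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def concat_models(models: Sequence[StructureModel], model_id: str) -> StructureModel:
    """Concatenate residues from several models, re-keying clashes onto new chains."""
    out = StructureModel(id=model_id)
    used: set[tuple[str, int, str]] = set()
    spare = iter("abcdefghijklmnopqrstuvwxyz0123456789")
    remap: dict[str, str] = {}
    for m in models:
        for res in m.residues:
            r = replace(res, atoms=[replace(a, position=a.position.copy()) for a in res.atoms])
            if r.key in used:
                new_chain = remap.get(m.id + r.chain_id)
                if new_chain is None:
                    new_chain = next(spare)
                    remap[m.id + r.chain_id] = new_chain
                r = replace(r, chain_id=new_chain)
            used.add(r.key)
            out.residues.append(r)
    return out
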