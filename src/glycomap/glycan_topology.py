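"""Pyranose ring detection, glycosidic linkage typing, and glycan graphs.

Covalent bonds are inferred from a single heavy-atom distance cutoff
(1.8 Å); deposited HETATM connectivity records are ignored on purpose.
Anomeric configuration is assigned geometrically from signed displacements
relative to the donor ring's oriented mean plane, which is robust to
structures without hydrogens and to distorted (non-chair) rings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .structure_io import AtomRecord, ResidueRecord, StructureModel

__all__ = [
    "SugarRing",
    "GlycosidicBond",
    "GlycanGraph",
    "detect_rings",
    "detect_linkages",
    "assign_anomericity",
    "build_glycan_graph",
    "BOND_CUTOFF",
    "ANOMER_DEADZONE",
]

#: Single covalent heavy-atom bond cutoff, Å.
BOND_CUTOFF = 1.8
#: Signed mean-plane displacements below this (Å) leave anomericity undetermined.
ANOMER_DEADZONE = 0.15

_CANONICAL_RING_NAMES = ("O5", "C1", "C2", "C3", "C4", "C5")


@dataclass
class SugarRing:
    """A six-membered 5C+1O ring, ordered (ring O, anomeric C, C2..C5)."""

    residue: ResidueRecord
    ring_atoms: list[AtomRecord]
    anomeric_carbon: AtomRecord
    centroid: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ring_atoms) != 6:
            raise ValueError("a sugar ring has exactly 6 atoms")
        if sum(a.element == "O" for a in self.ring_atoms) != 1:
            raise ValueError("a pyranose ring has exactly one ring oxygen")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.ring_atoms], dtype=float)

    def ring_atom(self, name: str) -> AtomRecord | None:
        for a in self.ring_atoms:
            if a.name == name:
                return a
        return None

    def label(self) -> str:
        return f"{self.residue.comp_name}:{self.residue.chain_id}{self.residue.seq_num}"


@dataclass
class GlycosidicBond:
    donor_ring: SugarRing
    acceptor_ring: SugarRing
    donor_position: int
    acceptor_position: int
    anomericity: str  # alpha | beta | undetermined
    bridge_oxygen: AtomRecord

    def __post_init__(self) -> None:
        if self.donor_ring is self.acceptor_ring:
            raise ValueError("donor and acceptor must differ")

    def notation(self) -> str:
        a = {"alpha": "a", "beta": "b", "undetermined": "?"}[self.anomericity]
        return f"{a}{self.donor_position}-{self.acceptor_position}"


@dataclass
class GlycanGraph:
    rings: list[SugarRing]
    bonds: list[GlycosidicBond]
    entities: list[list[SugarRing]] = field(default_factory=list)
    reducing_ends: list[SugarRing | None] = field(default_factory=list)

    def to_json(self) -> str:
        idx = {id(r): i for i, r in enumerate(self.rings)}
        return json.dumps(
            {
                "rings": [
                    {
                        "index": i,
                        "residue": r.label(),
                        "comp_name": r.residue.comp_name,
                        "centroid": [round(float(v), 3) for v in r.centroid],
                    }
                    for i, r in enumerate(self.rings)
                ],
                "bonds": [
                    {
                        "donor": idx[id(b.donor_ring)],
                        "acceptor": idx[id(b.acceptor_ring)],
                        "linkage": b.notation(),
                    }
                    for b in self.bonds
                ],
                "entities": [[idx[id(r)] for r in ent] for ent in self.entities],
                "reducing_ends": [
                    idx[id(r)] if r is not None else None for r in self.reducing_ends
                ],
            },
            indent=2,
        )

    def entity_notation(self, entity_index: int) -> str:
        """One-line text notation, e.g. ``Man(a1-6)Man(a1-4)GlcN`` (linear chains)."""
        ent = self.entities[entity_index]
        names = {"MAN": "Man", "BMA": "Man", "GLC": "Glc", "BGC": "Glc", "GCS": "GlcN",
                 "PA1": "GlcN", "GCN": "GlcN", "NAG": "GlcNAc", "GAL": "Gal"}
        red = self.reducing_ends[entity_index]
        if red is None:
            red = ent[0]
        chain: list[str] = [names.get(red.residue.comp_name, red.residue.comp_name)]
        seen = {id(red)}
        current = red
        while True:
            incoming = [b for b in self.bonds if b.acceptor_ring is current and id(b.donor_ring) not in seen]
            onto = [b for b in self.bonds if b.donor_ring is current and id(b.acceptor_ring) not in seen]
            nxt = incoming + onto
            if not nxt:
                break
            b = nxt[0]
            other = b.donor_ring if b.acceptor_ring is current else b.acceptor_ring
            chain.insert(0, f"({b.notation()})")
            chain.insert(0, names.get(other.residue.comp_name, other.residue.comp_name))
            seen.add(id(other))
            current = other
        return "".join(chain)


def _bonded(a: AtomRecord, b: AtomRecord, cutoff: float = BOND_CUTOFF) -> bool:
    return float(np.linalg.norm(a.position - b.position)) <= cutoff


def _residue_bond_graph(res: ResidueRecord, cutoff: float = BOND_CUTOFF) -> nx.Graph:
    g = nx.Graph()
    atoms = [a for a in res.heavy_atoms()]
    g.add_nodes_from(range(len(atoms)))
    pos = np.array([a.position for a in atoms]) if atoms else np.empty((0, 3))
    for i in range(len(atoms)):
        d = np.linalg.norm(pos[i + 1:] - pos[i], axis=1)
        for j in np.nonzero(d <= cutoff)[0]:
            g.add_edge(i, int(i + 1 + j))
    g.graph["atoms"] = atoms
    return g


def _find_pyranose_cycle(res: ResidueRecord) -> list[AtomRecord] | None:
    """Return the 5C+1O six-cycle of *res* in bond order, or None."""
    g = _residue_bond_graph(res)
    atoms: list[AtomRecord] = g.graph["atoms"]
    for cycle in nx.cycle_basis(g):
        if len(cycle) != 6:
            continue
        elems = [atoms[i].element for i in cycle]
        if elems.count("C") == 5 and elems.count("O") == 1:
            return [atoms[i] for i in cycle]
    return None


def _exocyclic_oxygen(res: ResidueRecord, carbon: AtomRecord, ring: Sequence[AtomRecord]) -> AtomRecord | None:
    ring_ids = {id(a) for a in ring}
    for a in res.heavy_atoms():
        if a.element == "O" and id(a) not in ring_ids and _bonded(a, carbon):
            return a
    return None


def detect_rings(model: StructureModel) -> list[SugarRing]:
    """Detect one pyranose ring per saccharide residue of a classified model.

    Saccharide residues without a detectable 5C+1O six-cycle are skipped with
    a warning.  Ring atom order is canonicalized to start at the ring oxygen
    and run toward the anomeric carbon (the ring-O neighbour carrying an
    exocyclic oxygen substituent; falls back to the neighbour named C1).
    """
    rings: list[SugarRing] = []
    for res in model.by_category("saccharide"):
        cycle = _find_pyranose_cycle(res)
        if cycle is None:
            warnings.warn(f"saccharide residue {res!r}: no pyranose ring detected; skipped")
            continue
        o_idx = next(i for i, a in enumerate(cycle) if a.element == "O")
        cycle = cycle[o_idx:] + cycle[:o_idx]
        nb_fwd, nb_rev = cycle[1], cycle[5]

        def _anomeric_score(c: AtomRecord) -> tuple[int, int]:
            has_exo_o = _exocyclic_oxygen(res, c, cycle) is not None
            return (int(has_exo_o), int(c.name == "C1"))

        if _anomeric_score(nb_rev) > _anomeric_score(nb_fwd):
            cycle = [cycle[0]] + cycle[:0:-1]
        rings.append(
            SugarRing(
                residue=res,
                ring_atoms=cycle,
                anomeric_carbon=cycle[1],
                centroid=np.mean([a.position for a in cycle], axis=0),
            )
        )
    return rings


def _acceptor_position(carbon: AtomRecord) -> int | None:
    name = carbon.name
    if len(name) >= 2 and name[0] == "C" and name[1:].isdigit():
        pos = int(name[1:])
        if pos in (2, 3, 4, 6):
            return pos
    return None


def detect_linkages(rings: Sequence[SugarRing], model: StructureModel) -> list[GlycosidicBond]:
    """Find glycosidic bonds: an oxygen bridging the anomeric carbon of one
    ring and a C2/C3/C4/C6 carbon of another."""
    oxygens: list[tuple[ResidueRecord, AtomRecord]] = [
        (res, a)
        for res in model.by_category("saccharide")
        for a in res.heavy_atoms()
        if a.element == "O"
    ]
    ring_atom_ids = {id(a) for r in rings for a in r.ring_atoms}
    carbons = [
        (ring, a) for ring in rings for a in ring.residue.heavy_atoms() if a.element == "C"
    ]
    bonds: list[GlycosidicBond] = []
    seen: set[tuple[int, int]] = set()
    for _, oxy in oxygens:
        if id(oxy) in ring_atom_ids:
            continue
        bonded = [(ring, c) for ring, c in carbons if _bonded(oxy, c)]
        # a CH2OH carbon (C6) and its own ring may both register; keep unique atoms
        uniq: dict[int, tuple[SugarRing, AtomRecord]] = {id(c): (r, c) for r, c in bonded}
        if len(uniq) > 2:
            raise ValueError(
                f"bridge oxygen {oxy.name} bonded to {len(uniq)} carbons: chemically invalid input"
            )
        if len(uniq) != 2:
            continue
        (ring_a, c_a), (ring_b, c_b) = uniq.values()
        if ring_a is ring_b:
            continue
        for donor, d_c, acceptor, a_c in ((ring_a, c_a, ring_b, c_b), (ring_b, c_b, ring_a, c_a)):
            if d_c is not donor.anomeric_carbon:
                continue
            pos = _acceptor_position(a_c)
            if pos is None:
                continue
            key = (id(d_c), id(a_c))
            if key in seen:
                continue
            seen.add(key)
            bond = GlycosidicBond(
                donor_ring=donor,
                acceptor_ring=acceptor,
                donor_position=1,
                acceptor_position=pos,
                anomericity="undetermined",
                bridge_oxygen=oxy,
            )
            bond.anomericity = assign_anomericity(bond)
            bonds.append(bond)
    return bonds


def _oriented_normal(ring: SugarRing) -> tuple[np.ndarray, np.ndarray]:
    """Cremer–Pople oriented mean-plane normal and geometric centre."""
    coords = ring.coords
    center = coords.mean(axis=0)
    centered = coords - center
    j = np.arange(6)
    ang = 2.0 * np.pi * j / 6.0
    r_prime = (centered * np.sin(ang)[:, None]).sum(axis=0)
    r_dprime = (centered * np.cos(ang)[:, None]).sum(axis=0)
    n = np.cross(r_prime, r_dprime)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("degenerate ring plane")
    return n / norm, center


def _reference_substituent(ring: SugarRing) -> AtomRecord | None:
    """The exocyclic heavy atom at C5 (C6 for hexoses), defining the D-sugar side."""
    c5 = ring.ring_atoms[5]
    ring_ids = {id(a) for a in ring.ring_atoms}
    for a in ring.residue.heavy_atoms():
        if id(a) not in ring_ids and a.element in ("C", "O", "N") and _bonded(a, c5):
            return a
    return None


def anomeric_oxygen(ring: SugarRing) -> AtomRecord | None:
    """The exocyclic oxygen on the anomeric carbon (O1 or a bridge oxygen)."""
    return _exocyclic_oxygen(ring.residue, ring.anomeric_carbon, ring.ring_atoms)


def assign_anomericity(bond: GlycosidicBond, deadzone: float = ANOMER_DEADZONE) -> str:
    """Alpha/beta assignment by signed mean-plane displacements (D-sugars).

    The anomeric exocyclic oxygen and the C5 reference substituent are
    projected onto the donor ring's oriented normal; opposite sides mean
    alpha, the same side beta.  Distorted-but-resolvable rings still classify;
    near-planar displacements (< *deadzone* Å) return "undetermined".
    """
    donor = bond.donor_ring
    from .ring_puckering import PLANARITY_THRESHOLD, cremer_pople

    try:
        if cremer_pople(donor).Q < PLANARITY_THRESHOLD:
            return "undetermined"
        normal, center = _oriented_normal(donor)
    except ValueError:
        return "undetermined"
    ref = _reference_substituent(donor)
    oxy = bond.bridge_oxygen
    if ref is None or oxy is None:
        return "undetermined"
    anomeric_c = donor.anomeric_carbon
    c5 = donor.ring_atoms[5]
    # displacement of each substituent relative to its ring carbon, along the normal
    z_oxy = float((oxy.position - anomeric_c.position) @ normal)
    z_ref = float((ref.position - c5.position) @ normal)
    if abs(z_oxy) < deadzone or abs(z_ref) < deadzone:
        return "undetermined"
    return "alpha" if z_oxy * z_ref < 0 else "beta"


def anomericity_of_free_ring(ring: SugarRing, deadzone: float = ANOMER_DEADZONE) -> str:
    """Anomericity of a free (unlinked) sugar from its O1 hydroxyl."""
    oxy = anomeric_oxygen(ring)
    if oxy is None:
        return "undetermined"
    shadow = GlycosidicBond.__new__(GlycosidicBond)
    shadow.donor_ring = ring
    shadow.acceptor_ring = None  # type: ignore[assignment]
    shadow.donor_position = 1
    shadow.acceptor_position = 0
    shadow.anomericity = "undetermined"
    shadow.bridge_oxygen = oxy
    return assign_anomericity(shadow, deadzone=deadzone)


def build_glycan_graph(rings: Sequence[SugarRing], bonds: Sequence[GlycosidicBond]) -> GlycanGraph:
    """Partition rings into entities (connected components) and find the
    reducing end of each (the ring whose anomeric carbon donates no bond)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(rings)))
    index = {id(r): i for i, r in enumerate(rings)}
    donors = {id(b.donor_ring) for b in bonds}
    for b in bonds:
        g.add_edge(index[id(b.donor_ring)], index[id(b.acceptor_ring)])
    entities: list[list[SugarRing]] = []
    reducing: list[SugarRing | None] = []
    for comp in sorted(nx.connected_components(g), key=min):
        ent = [rings[i] for i in sorted(comp)]
        entities.append(ent)
        free = [r for r in ent if id(r) not in donors]
        reducing.append(free[0] if len(free) == 1 else (free[0] if free else None))
    return GlycanGraph(rings=list(rings), bonds=list(bonds), entities=entities, reducing_ends=reducing)
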