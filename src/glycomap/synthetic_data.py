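"""Seeded generators for every fixture the pipeline consumes.

All generators are deterministic functions of (spec, seed): ideal pyranoses
at requested Cremer-Pople states, linked glycans with typed linkages and
set torsions, toy canyon complexes with sugars planted at known subsite
centroids, sequence families with controlled identities and paralog counts,
and MSAs with designed conserved columns.  Geometry uses ideal bond lengths
(C-C 1.52 Å, C-O 1.41 Å, C-N 1.47 Å) and tetrahedral angles; heavy atoms
only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .family_analysis import AMINO, SequenceRecord, pairwise_stats
from .ring_puckering import invert_cremer_pople
from .structure_io import AtomRecord, ResidueRecord, StructureModel, classify_residues

__all__ = [
    "GlycanSpec",
    "ComplexSpec",
    "FamilySpec",
    "make_sugar",
    "make_glycan",
    "make_scaffold",
    "make_complex",
    "make_family",
    "make_msa",
    "tune_end_to_end",
    "CHAIR_4C1",
]

CC = 1.52
CO = 1.41
CN = 1.47
TETRAHEDRAL = math.radians(109.47)
RING_RADIUS = 1.43

#: A regular 4C1 chair pucker (Q ~ crystal-typical amplitude).
CHAIR_4C1 = (0.57, 0.0, 0.0)

SUGAR_COMP = {"Man": "MAN", "Glc": "GLC", "GlcN": "GCS"}

# side of the mean plane (True = same side as C6, the D-sugar reference) for
# each exocyclic substituent, Haworth-style; O1 side is set by the anomer
_SUBSTITUENT_SIDE: dict[str, dict[str, bool]] = {
    "Man": {"O2": True, "O3": True, "O4": False},
    "Glc": {"O2": False, "O3": True, "O4": False},
    "GlcN": {"N2": False, "O3": True, "O4": False},
}
_SUB_ELEMENT = {"O": "O", "N": "N"}
_SUB_LENGTH = {"O": CO, "N": CN}


# ---------------------------------------------------------------------------
# small vector helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1u = _unit(b1)
    v = b0 - (b0 @ b1u) * b1u
    w = b2 - (b2 @ b1u) * b1u
    return math.degrees(math.atan2(np.cross(v, w) @ b1u, v @ w))


def _place_atom(
    b: np.ndarray, a: np.ndarray, r: np.ndarray, length: float, angle_deg: float, torsion_deg: float
) -> np.ndarray:
    """NeRF placement: new atom X with |X-b| = length, angle X-b-a, torsion X-b-a-r."""
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg)
    ab = _unit(b - a)
    n = _unit(np.cross(a - r, ab))
    m = np.cross(n, ab)
    d = np.array(
        [
            -length * math.cos(ang),
            length * math.sin(ang) * math.cos(tor),
            length * math.sin(ang) * math.sin(tor),
        ]
    )
    return b + d[0] * ab + d[1] * m + d[2] * n


def _exocyclic_slots(
    p: np.ndarray, prev_atom: np.ndarray, next_atom: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The two tetrahedral exocyclic unit directions at ring atom *p* and the
    chirality axis w; slot +1 lies along +w, slot -1 along -w."""
    va, vb = _unit(prev_atom - p), _unit(next_atom - p)
    u = _unit(va + vb)
    w = _unit(np.cross(va, vb))
    beta = TETRAHEDRAL / 2.0
    d_plus = _unit(-u * math.cos(beta) + w * math.sin(beta))
    d_minus = _unit(-u * math.cos(beta) - w * math.sin(beta))
    return d_plus, d_minus, w


def _chirality_table() -> dict[tuple[str, str], int]:
    """Map (sugar type, substituent) -> chirality slot sign, derived once from
    an ideal 4C1 template where the mean-plane side of each substituent is
    known (pucker-independent thereafter)."""
    ring = invert_cremer_pople(*CHAIR_4C1, radius=RING_RADIUS)
    normal = np.array([0.0, 0.0, 1.0])  # by construction of invert_cremer_pople
    table: dict[tuple[str, str], int] = {}

    def slot_for_side(i: int, up: bool) -> int:
        d_plus, d_minus, _ = _exocyclic_slots(ring[i], ring[(i - 1) % 6], ring[(i + 1) % 6])
        z_plus, z_minus = d_plus @ normal, d_minus @ normal
        return 1 if (z_plus > z_minus) == up else -1

    for sugar, sides in _SUBSTITUENT_SIDE.items():
        for name, up in sides.items():
            pos = int(name[1])  # C2 -> ring index 2, C3 -> 3, C4 -> 4
            table[(sugar, name)] = slot_for_side(pos, up)
    # anomeric O1 at C1 (ring index 1): alpha = opposite side of C6, beta = same
    for sugar in _SUBSTITUENT_SIDE:
        table[(sugar, "O1:alpha")] = slot_for_side(1, False)
        table[(sugar, "O1:beta")] = slot_for_side(1, True)
    # C6 at C5 (ring index 5): always the reference "up" side
    for sugar in _SUBSTITUENT_SIDE:
        table[(sugar, "C6")] = slot_for_side(5, True)
    return table


_CHIRALITY = _chirality_table()


def _attach(
    ring: np.ndarray, ring_index: int, slot_sign: int, length: float
) -> np.ndarray:
    p = ring[ring_index]
    d_plus, d_minus, _ = _exocyclic_slots(
        p, ring[(ring_index - 1) % 6], ring[(ring_index + 1) % 6]
    )
    return p + length * (d_plus if slot_sign > 0 else d_minus)


def make_sugar(
    sugar_type: str,
    pucker: tuple[float, float, float] = CHAIR_4C1,
    anomer: str = "alpha",
    with_anomeric_oxygen: bool = True,
    chain_id: str = "B",
    seq_num: int = 1,
) -> ResidueRecord:
    """An ideal D-pyranose residue (Man/Glc/GlcN) at the requested
    Cremer-Pople state, PDB atom names, heavy atoms only."""
    if sugar_type not in _SUBSTITUENT_SIDE:
        raise ValueError(f"unknown sugar type {sugar_type!r} (use Man, Glc or GlcN)")
    if anomer not in ("alpha", "beta"):
        raise ValueError(f"anomer must be alpha or beta, not {anomer!r}")
    q, theta, phi = pucker
    if q < 0:
        raise ValueError("invalid pucker: Q must be >= 0")
    ring = invert_cremer_pople(q, theta, phi, radius=RING_RADIUS)

    atoms = [
        AtomRecord(name="O5", element="O", position=ring[0]),
        AtomRecord(name="C1", element="C", position=ring[1]),
        AtomRecord(name="C2", element="C", position=ring[2]),
        AtomRecord(name="C3", element="C", position=ring[3]),
        AtomRecord(name="C4", element="C", position=ring[4]),
        AtomRecord(name="C5", element="C", position=ring[5]),
    ]
    if with_anomeric_oxygen:
        pos = _attach(ring, 1, _CHIRALITY[(sugar_type, f"O1:{anomer}")], CO)
        atoms.append(AtomRecord(name="O1", element="O", position=pos))
    for name in _SUBSTITUENT_SIDE[sugar_type]:
        ring_index = int(name[1])  # C2 -> ring index 2 ... C4 -> 4
        element = _SUB_ELEMENT[name[0]]
        pos = _attach(ring, ring_index, _CHIRALITY[(sugar_type, name)], _SUB_LENGTH[element])
        atoms.append(AtomRecord(name=name, element=element, position=pos))
    c6 = _attach(ring, 5, _CHIRALITY[(sugar_type, "C6")], CC)
    atoms.append(AtomRecord(name="C6", element="C", position=c6))
    # O6 anti to the ring from C6
    o6 = _place_atom(c6, ring[5], ring[0], CO, math.degrees(TETRAHEDRAL), 180.0)
    atoms.append(AtomRecord(name="O6", element="O", position=o6))

    res = ResidueRecord(
        chain_id=chain_id,
        seq_num=seq_num,
        icode="",
        comp_name=SUGAR_COMP[sugar_type],
        atoms=atoms,
        category="saccharide",
    )
    return res


# ---------------------------------------------------------------------------
# glycans
# ---------------------------------------------------------------------------

@dataclass
class GlycanSpec:
    residues: list[str]
    linkages: list[tuple[int, int, int, str]]  # (donor, acceptor, acceptor_pos, anomer)
    torsions: list[tuple[float, float]] | None = None  # per linkage (phi, psi), degrees
    puckers: list[tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        n = len(self.residues)
        for d, a, pos, anomer in self.linkages:
            if not (0 <= d < n and 0 <= a < n) or d == a:
                raise ValueError(f"linkage index out of range: {(d, a)}")
            if pos not in (2, 3, 4, 6):
                raise ValueError(f"acceptor position must be 2/3/4/6, got {pos}")
        donors = [d for d, *_ in self.linkages]
        if len(donors) != len(set(donors)):
            raise ValueError("a residue can donate its anomeric carbon only once")
        # acyclicity
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from([(d, a) for d, a, *_ in self.linkages])
        if len(g.edges) != len(self.linkages) or len(list(nx.cycle_basis(g))):
            raise ValueError("linkage graph must be acyclic")


DEFAULT_TORSION = (-80.0, 140.0)

_ACCEPTOR_OXYGEN = {2: "O2", 3: "O3", 4: "O4", 6: "O6"}
_PSI_REFERENCE = {2: "C1", 3: "C2", 4: "C3", 6: "C5"}


def make_glycan(
    spec: GlycanSpec, model_id: str = "GLYCAN", clash_limit: float = 2.0, max_retries: int = 24
) -> StructureModel:
    """Build a 3-D glycan realizing *spec*: each linkage gets anomeric
    C -> bridge O -> acceptor C geometry at ideal bond lengths and the
    requested (phi, psi) torsions, with automatic torsion nudging on steric
    clash and an error after bounded retries."""
    n = len(spec.residues)
    torsions = list(spec.torsions) if spec.torsions else [DEFAULT_TORSION] * len(spec.linkages)
    puckers = list(spec.puckers) if spec.puckers else [CHAIR_4C1] * n
    donors = {d for d, *_ in spec.linkages}
    residues: list[ResidueRecord] = []
    for i, name in enumerate(spec.residues):
        anomers = [lk[3] for lk in spec.linkages if lk[0] == i]
        residues.append(
            make_sugar(
                name,
                pucker=puckers[i],
                anomer=anomers[0] if anomers else "alpha",
                with_anomeric_oxygen=True,
                seq_num=i + 1,
            )
        )

    placed = {i for i in range(n) if i not in donors}
    if len(placed) != 1:
        # pick one reducing end; any non-donor works, others stay disconnected roots
        if not placed:
            raise ValueError("spec has no reducing end (cycle?)")
    pending = list(spec.linkages)
    order: list[int] = []
    while pending:
        progress = False
        for k, (d, a, pos, anomer) in enumerate(pending):
            if a in placed:
                order.append(spec.linkages.index(pending.pop(k)))
                _attach_donor(residues, spec.linkages[order[-1]], torsions[order[-1]],
                              clash_limit, max_retries, residues_placed=placed)
                placed.add(d)
                progress = True
                break
        if not progress:
            raise ValueError("linkage graph cannot be built acceptor-first (check indices)")

    model = StructureModel(id=model_id, residues=residues)
    return classify_residues(model)


def _attach_donor(
    residues: list[ResidueRecord],
    linkage: tuple[int, int, int, str],
    torsion: tuple[float, float],
    clash_limit: float,
    max_retries: int,
    residues_placed: set[int],
) -> None:
    d_idx, a_idx, pos, anomer = linkage
    donor, acceptor = residues[d_idx], residues[a_idx]
    bridge = acceptor.atom(_ACCEPTOR_OXYGEN[pos])
    if bridge is None:
        raise ValueError(
            f"linkage {d_idx}->{a_idx}: acceptor {acceptor.comp_name} has no "
            f"{_ACCEPTOR_OXYGEN[pos]} to accept a 1->{pos} bond"
        )
    cx = acceptor.atom(f"C{pos}")
    ref = acceptor.atom(_PSI_REFERENCE[pos])
    if cx is None or ref is None:
        raise ValueError(f"linkage {d_idx}->{a_idx}: acceptor lacks C{pos} frame atoms")

    phi0, psi0 = torsion
    for attempt in range(max_retries + 1):
        nudge = 15.0 * ((attempt + 1) // 2) * (1 if attempt % 2 else -1)
        phi, psi = phi0 + (nudge if attempt else 0.0), psi0 + (nudge if attempt else 0.0)
        coords = _donor_coords(donor, bridge.position, cx.position, ref.position, phi, psi)
        if not _clashes(coords, donor, residues, residues_placed, d_idx, bridge, clash_limit):
            o1 = donor.atom("O1")
            kept = [a for a in donor.atoms if a is not o1]
            for atom, xyz in zip(kept, coords):
                atom.position = xyz
            donor.atoms = kept
            return
    raise ValueError(
        f"unsatisfiable linkage {d_idx}->{a_idx} (1->{pos}): persistent clash "
        f"after {max_retries} torsion nudges"
    )


def _donor_coords(
    donor: ResidueRecord,
    bridge: np.ndarray,
    cx: np.ndarray,
    psi_ref: np.ndarray,
    phi: float,
    psi: float,
) -> np.ndarray:
    """Rigid-body placement of the donor so that its (deleted) O1 becomes the
    bridge oxygen with the requested phi/psi glycosidic torsions."""
    o1 = donor.atom("O1")
    c1 = donor.atom("C1")
    o5 = donor.atom("O5")
    if o1 is None:
        raise ValueError("donor built without anomeric oxygen")
    # target C1 position from psi = C1-O-Cx-ref
    c1_target = _place_atom(bridge, cx, psi_ref, CO, 112.0, psi)
    bond_dir = _unit(bridge - c1_target)

    names_kept = [a for a in donor.atoms if a is not o1]
    local = np.array([a.position for a in names_kept]) - c1.position
    d_anom = _unit(o1.position - c1.position)
    # rotate d_anom onto bond_dir
    axis = np.cross(d_anom, bond_dir)
    if np.linalg.norm(axis) < 1e-9:
        rot1 = np.eye(3) if d_anom @ bond_dir > 0 else _rotation(_perp(d_anom), math.pi)
    else:
        rot1 = _rotation(axis, math.acos(np.clip(d_anom @ bond_dir, -1, 1)))
    coords = local @ rot1.T + c1_target
    # fix phi = O5-C1-O-Cx by spinning about the C1-O bond
    o5_now = coords[names_kept.index(o5)]
    current = dihedral(o5_now, c1_target, bridge, cx)
    rot2 = _rotation(bond_dir, math.radians(phi - current))
    return (coords - c1_target) @ rot2.T + c1_target


def _perp(v: np.ndarray) -> np.ndarray:
    probe = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, probe))


def _clashes(
    coords: np.ndarray,
    donor: ResidueRecord,
    residues: list[ResidueRecord],
    placed: set[int],
    d_idx: int,
    bridge: AtomRecord,
    limit: float,
) -> bool:
    others = [
        a
        for i in placed
        if i != d_idx
        for a in residues[i].atoms
    ]
    if not others:
        return False
    pos = np.array([a.position for a in others])
    names_kept = [a for a in donor.atoms if a.name != "O1"]
    for atom, xyz in zip(names_kept, coords):
        d = np.linalg.norm(pos - xyz, axis=1)
        # the anomeric carbon is covalently bonded to the bridge oxygen
        for k, other in enumerate(others):
            if other is bridge and atom.name == "C1":
                d[k] = np.inf
        if np.min(d) < limit:
            return True
    return False


def tune_end_to_end(
    spec: GlycanSpec,
    target: float,
    measure: Callable[[StructureModel], float],
    max_iter: int = 200,
) -> tuple[GlycanSpec, float]:
    """Adjust the spec's torsions so that measure(make_glycan(spec)) hits
    *target* (Å); returns the tuned spec and the achieved value."""
    from dataclasses import replace as _replace

    from scipy.optimize import minimize

    n_link = len(spec.linkages)

    def objective(x: np.ndarray) -> float:
        torsions = [(x[2 * i], x[2 * i + 1]) for i in range(n_link)]
        try:
            value = measure(make_glycan(_replace(spec, torsions=torsions)))
        except ValueError:
            return 1e6
        return (value - target) ** 2

    starts = [np.array([v for t in (spec.torsions or [DEFAULT_TORSION] * n_link) for v in t])]
    starts += [
        np.array([phi, psi] * n_link, dtype=float)
        for phi in (-100.0, -80.0, 60.0)
        for psi in (-120.0, -60.0, 60.0, 140.0)
    ]
    best_x, best_f = starts[0], objective(starts[0])
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxiter": max_iter, "xatol": 0.01, "fatol": 1e-8})
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
        if best_f < 1e-6:
            break
    torsions = [(best_x[2 * i], best_x[2 * i + 1]) for i in range(n_link)]
    tuned = _replace(spec, torsions=torsions)
    return tuned, measure(make_glycan(tuned))


# ---------------------------------------------------------------------------
# toy canyon scaffold and planted complexes
# ---------------------------------------------------------------------------

@dataclass
class Scaffold:
    model: StructureModel
    centroids: np.ndarray  # (n_subsites, 3), ordered +3 ... -6 style
    labels: list[int]
    dd_motif: tuple[tuple[str, int], tuple[str, int]]
    wr1: tuple[str, int, int]


def make_scaffold(
    n_subsites: int = 9,
    spacing: float = 6.5,
    arc_radius: float = 25.0,
    anchor_index: int = 2,
) -> Scaffold:
    """A rigid concave poly-peptide "canyon": subsite centroids on an arc,
    walls of residues flanking them, an adjacent Asp-Asp motif under the
    anchor subsite, Trp wall residues, and a wing region near the minus end.

    Subsite index *anchor_index* is the +1 site; sites before it get labels
    +2, +3, ... (donor side) and sites after it -1, -2, ... (acceptor side).
    """
    dtheta = spacing / arc_radius
    angles = np.array([(i - anchor_index) * dtheta for i in range(n_subsites)])
    centroids = np.stack(
        [arc_radius * np.sin(angles), arc_radius * (np.cos(angles) - 1.0), np.zeros(n_subsites)],
        axis=1,
    )
    labels = [anchor_index - i + 1 if i <= anchor_index else anchor_index - i for i in
              range(n_subsites)]

    # deterministic varied sequence; DD motif + Trp lining inserted below
    seq_len = 4 * n_subsites + 24  # enough Calphas for the >= 50 retained-pair gate
    comp_cycle = [
        "ALA", "ASP", "GLU", "PHE", "GLY", "HIS", "ILE", "LYS", "LEU", "MET",
        "ASN", "PRO", "GLN", "ARG", "SER", "THR", "VAL", "TRP", "TYR", "CYS",
    ]
    model = StructureModel(id="SCAFFOLD")
    seq = 0

    def add_residue(comp: str, ca: np.ndarray, cb_dir: np.ndarray) -> ResidueRecord:
        nonlocal seq
        seq += 1
        atoms = [
            AtomRecord(name="N", element="N", position=ca + np.array([-1.2, 0.0, -0.4])),
            AtomRecord(name="CA", element="C", position=ca),
            AtomRecord(name="C", element="C", position=ca + np.array([1.2, 0.0, -0.4])),
            AtomRecord(name="O", element="O", position=ca + np.array([1.2, 0.0, -1.6])),
        ]
        if comp != "GLY":
            atoms.append(AtomRecord(name="CB", element="C", position=ca + 1.53 * cb_dir))
            if comp == "TRP":
                atoms.append(
                    AtomRecord(name="CG", element="C", position=ca + 2.9 * cb_dir)
                )
        res = ResidueRecord(chain_id="A", seq_num=seq, icode="", comp_name=comp,
                            atoms=atoms, category="protein")
        model.residues.append(res)
        return res

    # wall 1 (below the canyon): one residue under each subsite; DD under anchor
    dd_keys: list[tuple[str, int]] = []
    for i, c in enumerate(centroids):
        toward = _unit(np.array([0.0, 0.0, 1.0]))
        base = c + np.array([0.0, 0.0, -7.0])
        if i == anchor_index:
            r1 = add_residue("ASP", base + np.array([-0.7, 0.0, 0.0]), toward)
            r2 = add_residue("ASP", base + np.array([0.7, 0.0, 0.0]), toward)
            dd_keys = [(r1.chain_id, r1.seq_num), (r2.chain_id, r2.seq_num)]
        else:
            comp = "TRP" if i % 2 else comp_cycle[i % 20]
            add_residue(comp, base, toward)

    # wall 2 (side wall): varied residues giving the aligner an unambiguous trace
    for i in range(seq_len - len(model.residues)):
        t = i / max(seq_len - len(model.residues) - 1, 1)
        ang = angles[0] + t * (angles[-1] - angles[0])
        r_in = arc_radius - 7.0  # inner wall, radially inside the centroid arc
        ca = np.array(
            [r_in * math.sin(ang), r_in * math.cos(ang) - arc_radius, 3.0]
        )
        add_residue(comp_cycle[(3 * i + 1) % 20], ca,
                    np.array([math.sin(ang), math.cos(ang), 0.0]))

    wr1_first = None
    # wing region: three residues past the minus end of the arc
    for k in range(3):
        ang = angles[-1] + (k + 1) * dtheta
        ca = np.array(
            [arc_radius * math.sin(ang), arc_radius * (math.cos(ang) - 1.0), -2.5]
        )
        res = add_residue(comp_cycle[(7 * k + 5) % 20], ca, np.array([0.0, 0.0, 1.0]))
        if wr1_first is None:
            wr1_first = res.seq_num
    wr1 = ("A", int(wr1_first), int(wr1_first) + 2)

    classify_residues(model)
    return Scaffold(model=model, centroids=centroids, labels=labels,
                    dd_motif=(dd_keys[0], dd_keys[1]), wr1=wr1)


@dataclass
class ComplexSpec:
    placements: list[tuple[object, int, float]]  # (GlycanSpec | sugar type str, subsite index, jitter sigma)
    n_soaks: int = 1
    seed: int = 0
    scaffold: Scaffold | None = None

    def __post_init__(self) -> None:
        for _, _, sigma in self.placements:
            if sigma < 0:
                raise ValueError("jitter sigma must be >= 0")


def make_complex(spec: ComplexSpec) -> tuple[list[StructureModel], list[dict]]:
    """Soaked-complex emulation: for each soak, every placement's glycan is
    randomly oriented and translated so its first ring centroid sits at the
    target subsite centroid plus isotropic Gaussian jitter (rigid-body
    translation only).  Returns the models and a ground-truth table of
    (soak, residue key, subsite index/label)."""
    scaffold = spec.scaffold if spec.scaffold is not None else make_scaffold()
    rng = np.random.default_rng(spec.seed)
    models: list[StructureModel] = []
    truth: list[dict] = []
    scaffold_pos = np.array(
        [a.position for r in scaffold.model.residues for a in r.atoms]
    )
    for soak in range(spec.n_soaks):
        model = scaffold.model.copy()
        model.id = f"SOAK{soak}"
        chain = iter("BCDEFGHIJKLMNOPQRSTUV")
        occupied = scaffold_pos  # grows with each placed ligand
        for p_idx, (what, site_idx, sigma) in enumerate(spec.placements):
            if isinstance(what, GlycanSpec):
                glycan = make_glycan(what)
            else:
                glycan = StructureModel(
                    id="SUGAR", residues=[make_sugar(str(what))]
                )
                classify_residues(glycan)
            target = scaffold.centroids[site_idx]
            ch = next(chain)
            for attempt in range(200):
                # isotropic Gaussian, truncated at 1.5 sigma: bounds the
                # worst-case spread of co-planted observations to the default
                # merge radius so that subsite recovery is deterministic
                if sigma > 0:
                    jitter = rng.normal(0.0, sigma, size=3)
                    norm = float(np.linalg.norm(jitter))
                    if norm > 1.5 * sigma:
                        jitter *= 1.5 * sigma / norm
                else:
                    jitter = np.zeros(3)
                rot = _random_rotation(rng)
                coords_list = [
                    np.array([a.position for a in res.atoms]) for res in glycan.residues
                ]
                first_ring = coords_list[0][:6]
                pivot = first_ring.mean(axis=0)
                moved = [
                    (c - pivot) @ rot.T + target + jitter for c in coords_list
                ]
                flat = np.concatenate(moved)
                dmin = np.min(
                    np.linalg.norm(occupied[None, :, :] - flat[:, None, :], axis=-1)
                )
                if dmin >= 2.0:
                    occupied = np.concatenate([occupied, flat])
                    break
            else:
                raise ValueError(
                    f"placement {p_idx} at subsite index {site_idx}: cannot avoid scaffold clash"
                )
            for r_idx, (res, xyz) in enumerate(zip(glycan.residues, moved)):
                new = ResidueRecord(
                    chain_id=ch,
                    seq_num=r_idx + 1,
                    icode="",
                    comp_name=res.comp_name,
                    atoms=[
                        AtomRecord(name=a.name, element=a.element, position=pos)
                        for a, pos in zip(res.atoms, xyz)
                    ],
                    category="saccharide",
                )
                model.residues.append(new)
                ring_centroid = xyz[:6].mean(axis=0)
                site = int(
                    np.argmin(np.linalg.norm(scaffold.centroids - ring_centroid, axis=1))
                )
                truth.append(
                    {
                        "soak": soak,
                        "model_id": model.id,
                        "residue": (new.chain_id, new.seq_num),
                        "subsite_index": site if r_idx > 0 else site_idx,
                        "subsite_label": scaffold.labels[site if r_idx > 0 else site_idx],
                    }
                )
        models.append(model)
    return models, truth


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


# ---------------------------------------------------------------------------
# sequence families and MSAs
# ---------------------------------------------------------------------------

@dataclass
class FamilySpec:
    founder_length: int = 120
    n_species: int = 10
    families: Sequence[str] = ("A", "B")
    paralogs_per_species: Mapping[str, int] | None = None  # family -> fixed count
    within_family_identity: float = 0.92
    between_family_identity: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.between_family_identity < self.within_family_identity <= 1):
            raise ValueError("require 0 < between < within <= 1")


def _mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    chars = list(seq)
    sites = rng.choice(len(chars), size=min(n_mut, len(chars)), replace=False)
    for s in sites:
        choices = [a for a in AMINO if a != chars[s]]
        chars[s] = choices[rng.integers(len(choices))]
    return "".join(chars)


def make_family(spec: FamilySpec) -> tuple[list[SequenceRecord], dict]:
    """Sequence families with controlled identities and paralog counts.

    Returns the records plus a truth table: family membership, per-species
    per-family counts, and the per-family mean paralog count over species
    with at least one member.
    """
    rng = np.random.default_rng(spec.seed)
    length = spec.founder_length
    base = "".join(AMINO[i] for i in rng.integers(0, 20, size=length))
    founders: dict[str, str] = {}
    for k, fam in enumerate(spec.families):
        if k == 0:
            founders[fam] = base
        else:
            founders[fam] = _mutate(
                base, round((1.0 - spec.between_family_identity) * length), rng
            )
    counts = spec.paralogs_per_species or {f: 2 for f in spec.families}
    records: list[SequenceRecord] = []
    membership: dict[str, str] = {}
    per_species: dict[str, dict[str, int]] = {}
    n_within = round((1.0 - spec.within_family_identity) * length)
    for s in range(spec.n_species):
        species = f"sp{s:03d}"
        per_species[species] = {}
        for fam in spec.families:
            k = int(counts.get(fam, 0))
            per_species[species][fam] = k
            for p in range(k):
                seq = _mutate(founders[fam], n_within, rng)
                rec = SequenceRecord(id=f"{species}_{fam}{p}", sequence=seq, species=species)
                records.append(rec)
                membership[rec.id] = fam

    # verify within-family identity targets (±3 percentage points)
    for fam in spec.families:
        sample = next(r for r in records if membership[r.id] == fam)
        founder_rec = SequenceRecord(id=f"founder_{fam}", sequence=founders[fam])
        ident = pairwise_stats(sample, founder_rec).identity
        if abs(ident - spec.within_family_identity) > 0.03:
            raise ValueError(
                f"family {fam}: achieved identity {ident:.3f} misses target "
                f"{spec.within_family_identity:.3f} by > 3 points (infeasible spec?)"
            )
    truth = {
        "membership": membership,
        "founders": founders,
        "per_species_counts": per_species,
        "mean_paralogs": {
            f: float(
                np.mean([v[f] for v in per_species.values() if v.get(f, 0) > 0] or [0.0])
            )
            for f in spec.families
        },
    }
    return records, truth


def make_msa(
    n_rows: int,
    length: int,
    conserved_columns: Sequence[int],
    seed: int = 0,
    background: np.ndarray | None = None,
) -> list[SequenceRecord]:
    """An MSA whose designated columns are invariant and whose remaining
    columns are drawn from the background (redrawn until non-invariant)."""
    if any(not 0 <= c < length for c in conserved_columns):
        raise ValueError("conserved column index out of range")
    if n_rows < 5:
        raise ValueError("make_msa requires n_rows >= 5 (profile precondition)")
    rng = np.random.default_rng(seed)
    bg = np.full(20, 0.05) if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    conserved = set(conserved_columns)
    cols: list[list[str]] = []
    for c in range(length):
        if c in conserved:
            aa = AMINO[rng.integers(20)]
            cols.append([aa] * n_rows)
        else:
            while True:
                draw = [AMINO[i] for i in rng.choice(20, size=n_rows, p=bg)]
                if len(set(draw)) > 1:
                    break
            cols.append(draw)
    return [
        SequenceRecord(id=f"row{r:03d}", sequence="".join(cols[c][r] for c in range(length)))
        for r in range(n_rows)
    ]
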