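"""Consensus subsite mapping of a glycan-binding groove.

Ligand sugars observed in many soaked complexes are transferred into one
reference frame, clustered into consensus subsites, labelled with the
glycosidase subsite nomenclature (+n donor side, -n acceptor side, the site
over the catalytic DD motif being +1), and reassembled into composite
glycans whose overall shape is classified from the end-to-end span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from . import glycan_topology as gt
from .glycan_topology import GlycanGraph, SugarRing
from .structure_io import ResidueRecord, StructureModel
from .superposition import SuperpositionResult, apply_transform, sequence_guided_align

__all__ = [
    "SugarObservation",
    "Composite",
    "SubsiteDefinition",
    "ActiveSiteAnnotation",
    "SubsiteMap",
    "ShapeDescriptor",
    "transfer_ligands",
    "cluster_subsites",
    "assign_labels",
    "build_subsite_map",
    "occupancy_matrix",
    "reassemble_glycan",
    "classify_shape",
    "canyon_lining",
    "detect_disulfides",
    "contact_table",
    "compare_occupancy",
]

MERGE_RADIUS = 1.8  # Å, single-linkage merge radius for ring centroids
CANYON_ASSIGN_RADIUS = 3.5  # Å, max centroid distance for assigning an external sugar
LINEAR_THRESHOLD = 4.0  # Å per residue
U_THRESHOLD = 2.5  # Å per residue
SS_CUTOFF = 2.5  # Å, SG-SG
CONTACT_CUTOFF = 3.6  # Å, hydrogen-bond-range heavy-atom contacts
LINING_CUTOFF = 4.5  # Å, side chain to sugar

AROMATIC = frozenset({"TRP", "TYR", "PHE", "HIS"})
BACKBONE = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class SugarObservation:
    """One sugar ring from one source complex, in the reference frame."""

    source_id: str
    ring: SugarRing
    species: str  # one-line glycan notation of the whole source entity
    entity_index: int
    occupancy: float

    @property
    def centroid(self) -> np.ndarray:
        return self.ring.centroid


@dataclass
class Composite:
    """Merged reference-frame model plus the individual sugar observations."""

    reference_id: str
    model: StructureModel
    observations: list[SugarObservation]
    skipped: list[str] = field(default_factory=list)


@dataclass
class SubsiteDefinition:
    label: int | None
    centroid: np.ndarray
    member_count: int
    provenance: list[tuple[str, str]]
    members: list[int] = field(default_factory=list)  # observation indices


@dataclass
class ActiveSiteAnnotation:
    dd_motif: tuple[tuple[str, int], tuple[str, int]]
    aromatic_lining: list[tuple[str, int]] = field(default_factory=list)
    disulfides: list[tuple[tuple[str, int], tuple[str, int]]] = field(default_factory=list)
    wing_regions: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    @classmethod
    def detect(
        cls,
        model: StructureModel,
        wing_regions: dict[str, tuple[str, int, int]] | None = None,
    ) -> "ActiveSiteAnnotation":
        """Locate the catalytic DD motif (adjacent Asp-Asp) and disulfides."""
        protein = [r for r in model.residues if r.category == "protein"]
        dd = None
        for a, b in zip(protein, protein[1:]):
            if (
                a.comp_name == "ASP"
                and b.comp_name == "ASP"
                and a.chain_id == b.chain_id
                and b.seq_num == a.seq_num + 1
            ):
                dd = ((a.chain_id, a.seq_num), (b.chain_id, b.seq_num))
                break
        if dd is None:
            raise ValueError("no adjacent Asp-Asp (DD) motif found in the model")
        ss = detect_disulfides(model)
        return cls(dd_motif=dd, disulfides=ss, wing_regions=dict(wing_regions or {}))


@dataclass
class SubsiteMap:
    reference_id: str
    subsites: list[SubsiteDefinition]
    observations: list[SugarObservation]
    assignments: dict[int, int]  # observation index -> subsite label
    unassigned: list[int] = field(default_factory=list)

    def subsite(self, label: int) -> SubsiteDefinition:
        for s in self.subsites:
            if s.label == label:
                return s
        raise KeyError(f"no subsite labelled {label:+d}")

    def to_json_dict(self) -> dict:
        return {
            "reference": self.reference_id,
            "subsites": [
                {
                    "label": s.label,
                    "centroid": [round(float(v), 3) for v in s.centroid],
                    "member_count": s.member_count,
                    "provenance": [list(p) for p in s.provenance],
                }
                for s in sorted(self.subsites, key=lambda s: -(s.label or 0))
            ],
        }


@dataclass
class ShapeDescriptor:
    n_residues: int
    end_to_end: float
    per_residue: float
    shape_class: str


# ---------------------------------------------------------------------------
# merging complexes
# ---------------------------------------------------------------------------

def _sugar_observations(model: StructureModel, source_id: str) -> list[SugarObservation]:
    rings = gt.detect_rings(model)
    if not rings:
        return []
    bonds = gt.detect_linkages(rings, model)
    graph = gt.build_glycan_graph(rings, bonds)
    obs = []
    for ent_idx, ent in enumerate(graph.entities):
        species = graph.entity_notation(ent_idx)
        for ring in ent:
            occ = float(np.mean([a.occupancy for a in ring.ring_atoms]))
            obs.append(
                SugarObservation(
                    source_id=source_id,
                    ring=ring,
                    species=species,
                    entity_index=ent_idx,
                    occupancy=occ,
                )
            )
    return obs


def transfer_ligands(
    complexes: Sequence[StructureModel],
    reference: StructureModel,
    min_pairs: int = 50,
    max_cycles: int = 5,
    reject_cutoff: float = 2.0,
) -> Composite:
    """Superpose each complex onto *reference* and pool all saccharide
    residues, tagged by source, into a single reference-frame composite."""
    ref_copy = reference.copy()
    # the reference protein is retained once; its own ligands enter the
    # composite only through its appearance in the complex list
    merged = StructureModel(
        id=f"{reference.id}-composite",
        residues=[r for r in ref_copy.residues if r.category != "saccharide"],
        source_path=reference.source_path,
    )
    observations: list[SugarObservation] = []
    skipped: list[str] = []
    chain_pool = "abcdefghijklmnopqrstuvwxyz0123456789"
    n_ligand = 0
    for cx in complexes:
        if cx.id == reference.id:
            moved = cx.copy()
        else:
            try:
                fit = sequence_guided_align(cx, reference, max_cycles=max_cycles,
                                            reject_cutoff=reject_cutoff)
            except ValueError as exc:
                warnings.warn(f"complex {cx.id}: alignment failed ({exc}); skipped")
                skipped.append(cx.id)
                continue
            if fit.n_pairs < min_pairs:
                warnings.warn(
                    f"complex {cx.id}: only {fit.n_pairs} retained Calpha pairs; skipped"
                )
                skipped.append(cx.id)
                continue
            moved = apply_transform(cx, fit)
        obs = _sugar_observations(moved, cx.id)
        observations.extend(obs)
        sugar_keys = {o.ring.residue.key for o in obs}
        for res in moved.residues:
            if res.key in sugar_keys:
                # re-key onto a fresh (chain, seq) so sources never collide
                new = replace(
                    res,
                    chain_id=chain_pool[n_ligand % len(chain_pool)],
                    seq_num=n_ligand // len(chain_pool) + 1,
                    icode="",
                    atoms=res.atoms,
                )
                n_ligand += 1
                merged.residues.append(new)
    merged = StructureModel(id=merged.id, residues=merged.residues, source_path=merged.source_path)
    return Composite(reference_id=reference.id, model=merged, observations=observations,
                     skipped=skipped)


def cluster_subsites(
    composite: Composite, merge_radius: float = MERGE_RADIUS
) -> list[SubsiteDefinition]:
    """Single-linkage clustering of observed ring centroids into subsites."""
    obs = composite.observations
    if not obs:
        return []
    centroids = np.array([o.centroid for o in obs])
    if len(obs) == 1:
        labels = np.array([1])
    else:
        z = linkage(pdist(centroids), method="single")
        labels = fcluster(z, t=merge_radius, criterion="distance")
    subsites: list[SubsiteDefinition] = []
    for cl in sorted(set(labels)):
        members = [i for i, l in enumerate(labels) if l == cl]
        subsites.append(
            SubsiteDefinition(
                label=None,
                centroid=centroids[members].mean(axis=0),
                member_count=len(members),
                provenance=[(obs[i].source_id, obs[i].ring.label()) for i in members],
                members=members,
            )
        )
    return subsites


# ---------------------------------------------------------------------------
# labelling
# ---------------------------------------------------------------------------

def _sidechain_centroid(res: ResidueRecord) -> np.ndarray:
    side = [a for a in res.heavy_atoms() if a.name not in BACKBONE]
    atoms = side if side else res.heavy_atoms()
    return np.mean([a.position for a in atoms], axis=0)


def _dd_midpoint(reference: StructureModel, annotation: ActiveSiteAnnotation) -> np.ndarray:
    points = []
    for chain, num in annotation.dd_motif:
        res = reference.find(chain, num)
        if res is None:
            raise ValueError(f"DD-motif residue {chain}{num} absent from reference")
        carboxyl = [a for a in res.heavy_atoms() if a.name in ("CG", "OD1", "OD2")]
        points.append(
            np.mean([a.position for a in carboxyl], axis=0)
            if carboxyl
            else _sidechain_centroid(res)
        )
    return np.mean(points, axis=0)


def _wing_centroid(reference: StructureModel, annotation: ActiveSiteAnnotation) -> np.ndarray | None:
    region = annotation.wing_regions.get("WR1")
    if region is None:
        return None
    chain, start, end = region
    pts = [
        _sidechain_centroid(r)
        for r in reference.residues
        if r.chain_id == chain and start <= r.seq_num <= end and r.category == "protein"
    ]
    return np.mean(pts, axis=0) if pts else None


def assign_labels(
    subsites: Sequence[SubsiteDefinition],
    reference: StructureModel,
    annotation: ActiveSiteAnnotation,
    glcn_anchor: SugarRing | np.ndarray | None = None,
) -> list[SubsiteDefinition]:
    """Label subsites -6..+3 style: +1 at the catalytic site, then
    nearest-neighbour chaining outward, negative on the acceptor/mannose side.

    The +1 subsite is the one containing the glucosamine anchor when given,
    otherwise the one nearest the DD-motif carboxylate midpoint.  Of the two
    chain directions away from +1, the negative side is the one whose far end
    approaches WR1 (which extends the canyon's minus subsites); without a WR1
    annotation the longer branch is taken as the minus side.
    """
    if len(subsites) < 2:
        raise ValueError("need at least 2 subsites to establish a canyon ordering")
    centroids = np.array([s.centroid for s in subsites])
    if glcn_anchor is not None:
        anchor = (
            glcn_anchor.centroid if isinstance(glcn_anchor, SugarRing) else np.asarray(glcn_anchor)
        )
    else:
        anchor = _dd_midpoint(reference, annotation)
    plus_one = int(np.argmin(np.linalg.norm(centroids - anchor, axis=1)))

    # nearest-neighbour chaining from +1 outwards, growing two branches
    unvisited = set(range(len(subsites))) - {plus_one}
    branches: list[list[int]] = [[], []]
    ends = [plus_one, plus_one]
    while unvisited:
        best = None  # (distance, branch, node)
        for b in (0, 1):
            d = np.linalg.norm(centroids[list(unvisited)] - centroids[ends[b]], axis=1)
            order = sorted(zip(d, unvisited))
            if order:
                cand = (order[0][0], b, order[0][1])
                if best is None or cand[0] < best[0] - 1e-9:
                    best = cand
                elif (
                    abs(cand[0] - best[0]) <= 1e-9
                    and cand[2] != best[2]
                    and ends[0] != ends[1]
                ):
                    warnings.warn("ambiguous canyon chaining: tie between branch ends")
        assert best is not None
        _, b, node = best
        branches[b].append(node)
        ends[b] = node
        unvisited.discard(node)

    wing = _wing_centroid(reference, annotation)
    if not branches[0] or not branches[1]:
        minus = branches[0] if branches[0] else branches[1]
        plus: list[int] = branches[1] if branches[0] else branches[0]
    elif wing is not None:
        d0 = np.linalg.norm(centroids[branches[0][-1]] - wing)
        d1 = np.linalg.norm(centroids[branches[1][-1]] - wing)
        minus, plus = (branches[0], branches[1]) if d0 < d1 else (branches[1], branches[0])
    else:
        minus, plus = sorted(branches, key=len, reverse=True)

    labelled = [replace(s, centroid=s.centroid.copy()) for s in subsites]
    labelled[plus_one].label = 1
    for i, idx in enumerate(minus, start=1):
        labelled[idx].label = -i
    for i, idx in enumerate(plus, start=2):
        labelled[idx].label = i
    return labelled


def build_subsite_map(
    composite: Composite,
    reference: StructureModel,
    annotation: ActiveSiteAnnotation,
    merge_radius: float = MERGE_RADIUS,
    glcn_anchor: SugarRing | np.ndarray | None = None,
) -> SubsiteMap:
    """cluster_subsites + assign_labels + per-observation assignment table."""
    subsites = cluster_subsites(composite, merge_radius=merge_radius)
    if glcn_anchor is None:
        for o in composite.observations:
            if o.ring.residue.comp_name in ("GCS", "PA1", "GCN", "NDG"):
                glcn_anchor = o.ring
                break
    labelled = assign_labels(subsites, reference, annotation, glcn_anchor=glcn_anchor)
    assignments = {
        i: s.label for s in labelled for i in s.members  # type: ignore[misc]
    }
    return SubsiteMap(
        reference_id=composite.reference_id,
        subsites=labelled,
        observations=composite.observations,
        assignments=assignments,
        unassigned=[i for i in range(len(composite.observations)) if i not in assignments],
    )


def occupancy_matrix(map_: SubsiteMap) -> pd.DataFrame:
    """0/1 matrix: one row per (glycan species, source structure), one
    column per subsite label (descending, +n first)."""
    labels = sorted((s.label for s in map_.subsites if s.label is not None), reverse=True)
    rows: dict[str, dict[int, int]] = {}
    for i, obs in enumerate(map_.observations):
        if i not in map_.assignments:
            continue
        key = f"{obs.species}@{obs.source_id}"
        rows.setdefault(key, {l: 0 for l in labels})[map_.assignments[i]] = 1
    frame = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    if frame.empty:
        return pd.DataFrame(columns=labels, dtype=int)
    return frame.reindex(columns=labels, fill_value=0).sort_index()


# ---------------------------------------------------------------------------
# reassembly and shape
# ---------------------------------------------------------------------------

def classify_shape(
    n_residues: int,
    end_to_end: float,
    linear_threshold: float = LINEAR_THRESHOLD,
    u_threshold: float = U_THRESHOLD,
) -> str:
    if n_residues < 3:
        return "undefined"
    per_residue = end_to_end / (n_residues - 1)
    if per_residue >= linear_threshold:
        return "linear"
    if per_residue <= u_threshold:
        return "U"
    return "C"


def shape_descriptor(first_ring: SugarRing, last_ring: SugarRing, n_residues: int) -> ShapeDescriptor:
    c1 = first_ring.ring_atom("C1") or first_ring.anomeric_carbon
    c4 = last_ring.ring_atom("C4")
    if c1 is None or c4 is None:
        raise ValueError("terminal rings lack C1/C4 atoms")
    e2e = float(np.linalg.norm(c1.position - c4.position))
    per = e2e / (n_residues - 1) if n_residues > 1 else 0.0
    return ShapeDescriptor(
        n_residues=n_residues,
        end_to_end=e2e,
        per_residue=per,
        shape_class=classify_shape(n_residues, e2e),
    )


def reassemble_glycan(
    map_: SubsiteMap, path: Sequence[int], linkage_distance: float = 4.5
) -> tuple[GlycanGraph, ShapeDescriptor, StructureModel]:
    """Chain one representative sugar per subsite along *path* into a
    composite glycan; returns its connectivity graph, shape descriptor, and
    a writable model of the chosen sugars."""
    reps: list[SugarObservation] = []
    for label in path:
        site = map_.subsite(label)
        if not site.members:
            raise ValueError(f"path subsite {label:+d} is unoccupied")
        candidates = sorted(
            (map_.observations[i] for i in site.members),
            key=lambda o: (-o.occupancy, o.source_id),
        )
        reps.append(candidates[0])
    for a, b in zip(reps, reps[1:]):
        cand_names = ("C2", "C3", "C4", "C6")
        dists = [
            np.linalg.norm(a.ring.anomeric_carbon.position - atom.position)
            for atom in b.ring.residue.heavy_atoms()
            if atom.name in cand_names
        ] + [
            np.linalg.norm(b.ring.anomeric_carbon.position - atom.position)
            for atom in a.ring.residue.heavy_atoms()
            if atom.name in cand_names
        ]
        if not dists or min(dists) > linkage_distance:
            warnings.warn(
                f"subsites {a!r}->{b!r}: no linkage-plausible carbon pair "
                f"within {linkage_distance} Å"
            )
    model = StructureModel(id=f"{map_.reference_id}-reassembly")
    for i, rep in enumerate(reps):
        model.residues.append(replace(rep.ring.residue, chain_id="X", seq_num=i + 1, icode=""))
    rings = [r.ring for r in reps]
    bonds = []
    try:
        bonds = gt.detect_linkages(rings, _as_classified(model))
    except ValueError:
        pass
    graph = gt.build_glycan_graph(rings, bonds)
    desc = shape_descriptor(rings[0], rings[-1], len(reps))
    return graph, desc, model


def _as_classified(model: StructureModel) -> StructureModel:
    from .structure_io import classify_residues

    return classify_residues(model)


# ---------------------------------------------------------------------------
# annotation geometry
# ---------------------------------------------------------------------------

def canyon_lining(
    reference: StructureModel,
    composite_model: StructureModel,
    cutoff: float = LINING_CUTOFF,
    aromatic_only: bool = False,
) -> list[ResidueRecord]:
    """Protein residues with a side-chain heavy atom within *cutoff* of any
    composite sugar heavy atom."""
    sugar_pos = np.array(
        [
            a.position
            for r in composite_model.by_category("saccharide")
            for a in r.heavy_atoms()
        ]
    )
    if sugar_pos.size == 0:
        return []
    out = []
    for res in reference.by_category("protein"):
        if aromatic_only and res.comp_name not in AROMATIC:
            continue
        side = [a for a in res.heavy_atoms() if a.name not in BACKBONE]
        if not side:
            continue
        pos = np.array([a.position for a in side])
        d = np.linalg.norm(sugar_pos[None, :, :] - pos[:, None, :], axis=-1)
        if np.min(d) <= cutoff:
            out.append(res)
    return out


def detect_disulfides(
    model: StructureModel, ss_cutoff: float = SS_CUTOFF
) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    cys_sg = [
        (res, res.atom("SG"))
        for res in model.residues
        if res.comp_name == "CYS" and res.atom("SG") is not None
    ]
    pairs = []
    for i, (res_a, sg_a) in enumerate(cys_sg):
        for res_b, sg_b in cys_sg[i + 1:]:
            if np.linalg.norm(sg_a.position - sg_b.position) <= ss_cutoff:
                pairs.append(((res_a.chain_id, res_a.seq_num), (res_b.chain_id, res_b.seq_num)))
    return pairs


def contact_table(
    sugar: SugarRing, model: StructureModel, cutoff: float = CONTACT_CUTOFF
) -> list[tuple[str, str, str, float]]:
    """Protein-sugar heavy-atom pairs within *cutoff*, nearest first.

    Rows are (protein residue, protein atom, sugar atom, distance Å).
    """
    rows = []
    sugar_atoms = sugar.residue.heavy_atoms()
    for res in model.by_category("protein"):
        for pa in res.heavy_atoms():
            for sa in sugar_atoms:
                d = float(np.linalg.norm(pa.position - sa.position))
                if d <= cutoff:
                    rows.append((repr(res), pa.name, sa.name, d))
    return sorted(rows, key=lambda r: r[3])


def compare_occupancy(
    observed: SubsiteMap,
    predicted_models: Sequence[StructureModel],
    reference: StructureModel,
    assign_radius: float = CANYON_ASSIGN_RADIUS,
) -> pd.DataFrame:
    """Assign each predicted ligand sugar to the observed subsites.

    Returns one row per predicted model: counts of sugars inside vs outside
    the canyon plus per-subsite hit counts.
    """
    labels = sorted((s.label for s in observed.subsites if s.label is not None), reverse=True)
    centroids = np.array([observed.subsite(l).centroid for l in labels])
    records = []
    for model in predicted_models:
        if model.id == reference.id:
            moved = model.copy()
        else:
            try:
                fit = sequence_guided_align(model, reference)
                moved = apply_transform(model, fit)
            except ValueError as exc:
                warnings.warn(f"predicted model {model.id}: unalignable ({exc}); skipped")
                continue
        rings = gt.detect_rings(moved)
        row = {"model": model.id, "inside": 0, "outside": 0}
        row.update({l: 0 for l in labels})
        for ring in rings:
            d = np.linalg.norm(centroids - ring.centroid, axis=1)
            if d.min() <= assign_radius:
                row["inside"] += 1
                row[labels[int(d.argmin())]] += 1
            else:
                row["outside"] += 1
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("model") if records else pd.DataFrame()
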