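"""High-level analyses of a locally available deposited-structure series.

These functions compose the core pipeline into the measurements reported for
the CtGH76 complex series and its comparators.  They operate strictly on
local files (PDB-format coordinates, FASTA sequences) supplied by the user —
nothing is downloaded.  Expected file names are lower-case PDB accessions
(e.g. ``9r4k.pdb``) in a single directory.

Catalytic-motif and wing-region residue numbers are inputs here, not
detected, so that the subsite frame matches the published annotation:
DD motif D163/D164, WR1 D268-R283 (reference chain A).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from . import glycan_topology as gt
from . import subsite_mapping as sm
from .family_analysis import SequenceRecord, pairwise_stats
from .structure_io import StructureModel, parse_structure
from .superposition import SuperpositionResult, sequence_guided_align

REFERENCE_ENTRY = "9R4K"
COMPLEX_SERIES = ("9R4K", "9R4M", "9R4N", "9R4O", "9R4P", "9R4R", "9R4S")
DD_MOTIF = (("A", 163), ("A", 164))
WR1_REGION = ("A", 268, 283)


def load_entry(data_dir: Path | str, entry: str) -> StructureModel:
    path = Path(data_dir) / f"{entry.lower()}.pdb"
    if not path.exists():
        raise FileNotFoundError(f"deposited entry {entry}: {path} not found")
    model = parse_structure(path, model_id=entry.upper())
    return model


def reference_annotation(chain: str = "A") -> sm.ActiveSiteAnnotation:
    return sm.ActiveSiteAnnotation(
        dd_motif=DD_MOTIF, wing_regions={"WR1": WR1_REGION}
    )


def build_composite_map(
    data_dir: Path | str, entries: tuple[str, ...] = COMPLEX_SERIES
) -> tuple[sm.SubsiteMap, sm.Composite, StructureModel]:
    """Merge the complex series onto the apo reference and label subsites."""
    reference = load_entry(data_dir, REFERENCE_ENTRY)
    complexes = [load_entry(data_dir, e) for e in entries]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        composite = sm.transfer_ligands(complexes, reference)
    annotation = reference_annotation()
    smap = sm.build_subsite_map(composite, reference, annotation)
    return smap, composite, reference


def gpi_core_end_to_end(data_dir: Path | str) -> tuple[float, int]:
    """End-to-end span (GlcN C1 -> third-Man C4) of the reassembled
    tetrasaccharide chained through subsites +1, -1, -2, -3."""
    smap, _, _ = build_composite_map(data_dir)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, descriptor, _ = sm.reassemble_glycan(smap, [1, -1, -2, -3])
    return descriptor.end_to_end, descriptor.n_residues


def ligand_end_to_end(data_dir: Path | str, entry: str) -> tuple[float, int]:
    """C1 of the reducing-end ring to C4 of the chain-terminal ring of the
    largest bound glycan in *entry*."""
    model = load_entry(data_dir, entry)
    rings = gt.detect_rings(model)
    bonds = gt.detect_linkages(rings, model)
    graph = gt.build_glycan_graph(rings, bonds)
    sizes = [len(e) for e in graph.entities]
    idx = int(np.argmax(sizes))
    entity = graph.entities[idx]
    first = graph.reducing_ends[idx] or entity[0]
    # walk to the far end of the chain
    chain = [first]
    while True:
        nxt = [
            b.donor_ring
            for b in bonds
            if b.acceptor_ring is chain[-1] and b.donor_ring not in chain
        ] + [
            b.acceptor_ring
            for b in bonds
            if b.donor_ring is chain[-1] and b.acceptor_ring not in chain
        ]
        if not nxt:
            break
        chain.append(nxt[0])
    descriptor = sm.shape_descriptor(chain[0], chain[-1], len(chain))
    return descriptor.end_to_end, len(chain)


def homolog_rmsd(data_dir: Path | str, entry_a: str, entry_b: str) -> SuperpositionResult:
    a = load_entry(data_dir, entry_a)
    b = load_entry(data_dir, entry_b)
    return sequence_guided_align(a, b)


def apo_disulfides(data_dir: Path | str) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    return sm.detect_disulfides(load_entry(data_dir, REFERENCE_ENTRY))


def aromatic_canyon(data_dir: Path | str, cutoff: float = 4.5) -> list[str]:
    smap, composite, reference = build_composite_map(data_dir)
    lining = sm.canyon_lining(reference, composite.model, cutoff=cutoff, aromatic_only=True)
    return [f"{r.comp_name}{r.seq_num}" for r in lining]


def _entity_labels(smap: sm.SubsiteMap, source_id: str, species_contains: str) -> dict:
    """Subsite labels of each glycan entity of one source complex."""
    out: dict[str, list[int]] = {}
    for i, obs in enumerate(smap.observations):
        if obs.source_id != source_id or species_contains not in obs.species:
            continue
        key = f"{obs.species}#{obs.entity_index}"
        out.setdefault(key, []).append(smap.assignments[i])
    return out


def mannobiose_o1_o2_contact(data_dir: Path | str) -> float:
    """O1 of the subsite -4 mannose to O2 of the subsite -3 mannose in the
    alpha-1,2-mannobiose complex, measured in the merged reference frame."""
    smap, _, _ = build_composite_map(data_dir)
    # locate a source whose a1-2 mannobiose entity sits at -3/-4
    candidates: dict[tuple[str, int], gt.SugarRing] = {}
    for i, obs in enumerate(smap.observations):
        if "a1-2" in obs.species:
            candidates[(obs.source_id, smap.assignments[i])] = obs.ring
    for (source, label), ring in candidates.items():
        if label == -4 and (source, -3) in candidates:
            o1 = gt.anomeric_oxygen(ring)
            other = candidates[(source, -3)]
            o2 = other.residue.atom("O2")
            if o1 is None or o2 is None:
                continue
            return float(np.linalg.norm(o1.position - o2.position))
    raise ValueError("no a1-2 mannobiose spanning subsites -4/-3 found")


def mutant_mannobiose_subsites(data_dir: Path | str, entry: str = "9R4P") -> list[int]:
    """Subsites occupied by the intact mannobiose in a DD-mutant soak."""
    smap, _, _ = build_composite_map(data_dir)
    for key, labels in _entity_labels(smap, entry, "Man(a1-6)Man").items():
        if len(labels) == 2:
            return sorted(labels)
    raise ValueError(f"no two-ring mannobiose entity found in {entry}")


def domain_identity(
    fasta_a: Path | str,
    fasta_b: Path | str,
    range_a: tuple[int, int] | None = (61, None),
    range_b: tuple[int, int] | None = (20, 384),
) -> float:
    """Pairwise identity between two domain sequences (1-based inclusive
    ranges; None = to the end).  Defaults select the mature region of the
    first sequence and the N20-L384 domain of the second."""

    def _read(path: Path | str, rng) -> str:
        seq = "".join(
            l.strip() for l in Path(path).read_text().splitlines() if not l.startswith(">")
        )
        if rng is None:
            return seq
        start, end = rng
        return seq[(start - 1): (end if end is not None else len(seq))]

    a = SequenceRecord(id="a", sequence=_read(fasta_a, range_a))
    b = SequenceRecord(id="b", sequence=_read(fasta_b, range_b))
    return pairwise_stats(a, b).identity
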