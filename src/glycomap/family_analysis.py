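"""Desk-scale sequence similarity networks, co-distribution statistics, and
conservation profiling.

Pairwise statistics use a deterministic re-implementation of the usual
search-tool pipeline: global alignment (BLOSUM62, affine 10/0.5) for the
identity fraction and a separate local alignment whose score is converted
to a Karlin-Altschul E-value with fixed gapped parameters (lambda = 0.267,
K = 0.041) and search space m*n.  Conservation is scored per MSA column by
Jensen-Shannon divergence against a background distribution, normalized so
that a fully conserved column of the rarest background residue scores 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .structure_io import StructureModel
from .superposition import THREE_TO_ONE

__all__ = [
    "SequenceRecord",
    "SimilarityEdge",
    "SSNGraph",
    "CoDistributionStats",
    "ConservationProfile",
    "pairwise_stats",
    "collapse_nodes",
    "build_ssn",
    "co_distribution",
    "conservation_profile",
    "map_conservation",
    "EVALUE_CUTOFF",
    "IDENTITY_THRESHOLD",
]

AMINO = "ACDEFGHIKLMNPQRSTVWY"
EVALUE_CUTOFF = 1e-40
IDENTITY_THRESHOLD = 0.9
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set(AMINO + "X")
        if bad:
            raise ValueError(f"{self.id}: non-amino-acid letters {sorted(bad)}")
        self.sequence = self.sequence.upper()


@dataclass(frozen=True)
class SimilarityEdge:
    a: str
    b: str
    score: float
    evalue: float
    identity: float


@dataclass
class SSNNode:
    representative: SequenceRecord
    members: list[SequenceRecord] = field(default_factory=list)

    @property
    def id(self) -> str:
        return self.representative.id


@dataclass
class SSNGraph:
    nodes: list[SSNNode]
    edges: list[SimilarityEdge] = field(default_factory=list)
    components: list[list[str]] = field(default_factory=list)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.id, size=len(n.members))
        for e in self.edges:
            g.add_edge(e.a, e.b, evalue=e.evalue, identity=e.identity, score=e.score)
        return g

    def edge_table(self) -> list[tuple[str, str, float, float, float]]:
        return [(e.a, e.b, e.score, e.evalue, e.identity) for e in self.edges]


@dataclass
class CoDistributionStats:
    per_species_counts: dict[str, dict[str, int]]
    venn: dict[frozenset, int]
    mean_paralogs: dict[str, float]

    def venn_str(self) -> dict[str, int]:
        return {"+".join(sorted(k)): v for k, v in self.venn.items()}


@dataclass
class ConservationProfile:
    per_column: np.ndarray
    low_confidence: np.ndarray  # bool mask: > 50% gaps
    column_to_residue: dict[int, int] = field(default_factory=dict)


_global_aligner: PairwiseAligner | None = None
_local_aligner: PairwiseAligner | None = None


def _aligners() -> tuple[PairwiseAligner, PairwiseAligner]:
    global _global_aligner, _local_aligner
    if _global_aligner is None:
        mat = substitution_matrices.load("BLOSUM62")
        _global_aligner = PairwiseAligner()
        _global_aligner.substitution_matrix = mat
        _global_aligner.open_gap_score = -10.0
        _global_aligner.extend_gap_score = -0.5
        _global_aligner.mode = "global"
        _local_aligner = PairwiseAligner()
        _local_aligner.substitution_matrix = mat
        _local_aligner.open_gap_score = -10.0
        _local_aligner.extend_gap_score = -0.5
        _local_aligner.mode = "local"
    return _global_aligner, _local_aligner


def pairwise_stats(a: SequenceRecord, b: SequenceRecord) -> SimilarityEdge:
    """Identity from global alignment; E-value from a local alignment score."""
    if not a.sequence or not b.sequence:
        raise ValueError("empty sequence")
    global_aln, local_aln = _aligners()
    sa, sb = a.sequence.replace("X", "A"), b.sequence.replace("X", "A")
    aln = global_aln.align(sa, sb)[0]
    ident = aligned = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        aligned += e1 - s1
        ident += sum(1 for i, j in zip(range(s1, e1), range(s2, e2)) if sa[i] == sb[j])
    # non-double-gap columns = aligned columns + gapped columns of the global path
    total_cols = len(sa) + len(sb) - aligned
    identity = ident / total_cols if total_cols else 0.0
    score = float(local_aln.score(sa, sb))
    evalue = KA_K * len(sa) * len(sb) * math.exp(-KA_LAMBDA * score)
    return SimilarityEdge(a=a.id, b=b.id, score=score, evalue=evalue, identity=identity)


def collapse_nodes(
    seqs: Sequence[SequenceRecord], identity_threshold: float = IDENTITY_THRESHOLD
) -> list[SSNNode]:
    """Greedy length-sorted clustering: each sequence joins the first existing
    representative it matches at >= *identity_threshold*, else founds a node."""
    if not seqs:
        raise ValueError("no sequences")
    nodes: list[SSNNode] = []
    for seq in sorted(seqs, key=lambda s: -len(s.sequence)):
        for node in nodes:
            if pairwise_stats(seq, node.representative).identity >= identity_threshold:
                node.members.append(seq)
                break
        else:
            nodes.append(SSNNode(representative=seq, members=[seq]))
    return nodes


def build_ssn(nodes: Sequence[SSNNode], evalue_cutoff: float = EVALUE_CUTOFF) -> SSNGraph:
    """All-vs-all pairwise statistics between representatives; edges where
    the E-value passes the cutoff; connected components computed."""
    edges = []
    for i, na in enumerate(nodes):
        for nb in nodes[i + 1:]:
            e = pairwise_stats(na.representative, nb.representative)
            if e.evalue <= evalue_cutoff:
                edges.append(e)
    ssn = SSNGraph(nodes=list(nodes), edges=edges)
    ssn.components = [sorted(c) for c in nx.connected_components(ssn.graph())]
    ssn.components.sort(key=lambda c: c[0])
    return ssn


def co_distribution(
    graph: SSNGraph,
    cluster_labels: Mapping[str, str],
    species_of: Mapping[str, str] | None = None,
) -> CoDistributionStats:
    """Per-species member counts per cluster, Venn subset counts over
    clusters, and mean paralog count per cluster (over species with >= 1)."""
    missing = []
    per_species: dict[str, dict[str, int]] = {}
    for node in graph.nodes:
        cluster = cluster_labels.get(node.id)
        if cluster is None:
            continue
        for member in node.members:
            species = (
                species_of.get(member.id) if species_of is not None else member.species
            )
            if not species:
                missing.append(member.id)
                continue
            per_species.setdefault(species, {})
            per_species[species][cluster] = per_species[species].get(cluster, 0) + 1
    if missing:
        raise ValueError(f"members without species tag: {missing}")
    venn: dict[frozenset, int] = {}
    for counts in per_species.values():
        key = frozenset(c for c, n in counts.items() if n > 0)
        if key:
            venn[key] = venn.get(key, 0) + 1
    clusters = sorted({c for counts in per_species.values() for c in counts})
    mean_paralogs = {}
    for c in clusters:
        counts = [v[c] for v in per_species.values() if v.get(c, 0) > 0]
        mean_paralogs[c] = float(np.mean(counts)) if counts else 0.0
    return CoDistributionStats(
        per_species_counts=per_species, venn=venn, mean_paralogs=mean_paralogs
    )


def _jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence, natural log base, in [0, ln 2]."""

    def _kl(x: np.ndarray, y: np.ndarray) -> float:
        mask = x > 0
        return float(np.sum(x[mask] * np.log(x[mask] / y[mask])))

    m = 0.5 * (p + q)
    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def conservation_profile(
    msa: Sequence[str] | Sequence[SequenceRecord],
    background: np.ndarray | None = None,
) -> ConservationProfile:
    """Per-column conservation scores in [0, 1] for an MSA.

    Gap characters are excluded from column frequency vectors; columns with
    more than 50% gaps are flagged low-confidence.  The default background is
    uniform over the 20 amino acids, making every invariant column score 1.
    """
    rows = [s.sequence if isinstance(s, SequenceRecord) else s.upper() for s in msa]
    if len(rows) < 5:
        raise ValueError("conservation profile requires >= 5 aligned sequences")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("ragged alignment: rows differ in length")
    bg = (
        np.full(20, 1.0 / 20)
        if background is None
        else np.asarray(background, dtype=float)
    )
    bg = bg / bg.sum()
    norm = max(_jsd(_point_mass(i), bg) for i in range(20))
    index = {aa: i for i, aa in enumerate(AMINO)}
    scores = np.zeros(length)
    lowconf = np.zeros(length, dtype=bool)
    for col in range(length):
        letters = [r[col] for r in rows]
        residues = [index[c] for c in letters if c in index]
        lowconf[col] = (len(rows) - len(residues)) > 0.5 * len(rows)
        if not residues:
            scores[col] = 0.0
            continue
        freq = np.bincount(residues, minlength=20).astype(float)
        freq /= freq.sum()
        scores[col] = _jsd(freq, bg) / norm
    return ConservationProfile(per_column=np.clip(scores, 0.0, 1.0), low_confidence=lowconf)


def _point_mass(i: int) -> np.ndarray:
    p = np.zeros(20)
    p[i] = 1.0
    return p


def map_conservation(
    profile: ConservationProfile,
    msa: Sequence[SequenceRecord],
    query_row: str,
    reference: StructureModel,
    min_identity: float = 0.95,
) -> dict[tuple[str, int], float]:
    """Attach column scores to reference residues via the query MSA row.

    Non-gap columns of *query_row* are mapped, in order, onto the protein
    residues of *reference*; the ungapped query must match the modelled
    sequence at >= *min_identity* over the modelled residues.
    """
    row = next((s for s in msa if s.id == query_row), None)
    if row is None:
        raise ValueError(f"query row {query_row!r} not in MSA")
    residues = [r for r in reference.residues if r.category == "protein"]
    ungapped = [(col, c) for col, c in enumerate(row.sequence) if c in set(AMINO + "X")]
    if len(ungapped) < len(residues):
        raise ValueError(
            f"profile row ({len(ungapped)} residues) shorter than structure ({len(residues)})"
        )
    matches = sum(
        1
        for (_, c), res in zip(ungapped, residues)
        if THREE_TO_ONE.get(res.comp_name, "X") == c
    )
    if residues and matches / len(residues) < min_identity:
        raise ValueError(
            f"query/structure mismatch: {matches}/{len(residues)} identical "
            f"(< {min_identity:.0%})"
        )
    out: dict[tuple[str, int], float] = {}
    for (col, _), res in zip(ungapped, residues):
        out[(res.chain_id, res.seq_num)] = float(profile.per_column[col])
        profile.column_to_residue[col] = res.seq_num
    return out
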