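"""Rigid-body superposition.

kabsch() is the exact closed-form least-squares fit of paired points;
sequence_guided_align() pairs Calpha atoms of two homologous models via a
global sequence alignment (BLOSUM62, affine gaps 10/0.5) and then iterates
Kabsch fits with distance-based outlier rejection, emulating the common
interactive "align" behaviour of molecular-graphics programs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .structure_io import ResidueRecord, StructureModel

__all__ = ["SuperpositionResult", "kabsch", "sequence_guided_align", "apply_transform"]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

DEFAULT_MAX_CYCLES = 5
DEFAULT_REJECT_CUTOFF = 2.0  # Å


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int
    n_cycles: int = 1
    rejected: list[tuple] = field(default_factory=list)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def to_json(self) -> str:
        return json.dumps(
            {
                "rotation": self.rotation.tolist(),
                "translation": self.translation.tolist(),
                "rmsd": round(self.rmsd, 6),
                "n_pairs": self.n_pairs,
                "n_cycles": self.n_cycles,
            },
            indent=2,
        )


def kabsch(
    points_a: np.ndarray, points_b: np.ndarray, weights: np.ndarray | None = None
) -> SuperpositionResult:
    """Optimal proper rotation + translation mapping *points_a* onto *points_b*.

    Minimizes the (optionally weighted) sum of squared deviations; the
    determinant correction enforces a proper rotation even for reflective
    optima.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must both be N x 3")
    n = a.shape[0]
    if n < 3:
        raise ValueError("at least 3 point pairs are required")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    cen_a = w @ a
    cen_b = w @ b
    aa = a - cen_a
    bb = b - cen_b
    # degenerate (collinear / coincident) configurations have rank < 2
    if np.linalg.matrix_rank(aa * w[:, None], tol=1e-9) < 2:
        raise ValueError("degenerate point set: points are collinear or coincident")
    h = (aa * w[:, None]).T @ bb
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cen_b - rot @ cen_a
    moved = a @ rot.T + trans
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - b) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_pairs=n)


def _ca_trace(model: StructureModel) -> tuple[str, list[ResidueRecord], np.ndarray]:
    residues = [
        r for r in model.residues if r.category == "protein" and r.atom("CA") is not None
    ]
    seq = "".join(THREE_TO_ONE.get(r.comp_name, "X") for r in residues)
    coords = np.array([r.atom("CA").position for r in residues], dtype=float)
    return seq, residues, coords


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def sequence_guided_align(
    model_a: StructureModel,
    model_b: StructureModel,
    max_cycles: int = DEFAULT_MAX_CYCLES,
    reject_cutoff: float = DEFAULT_REJECT_CUTOFF,
) -> SuperpositionResult:
    """Superpose *model_a* onto *model_b* via aligned Calpha pairs with
    iterative outlier rejection (pairs deviating > *reject_cutoff* Å are
    dropped, at most *max_cycles* times, until stable)."""
    seq_a, res_a, ca_a = _ca_trace(model_a)
    seq_b, res_b, ca_b = _ca_trace(model_b)
    if len(res_a) < 20 or len(res_b) < 20:
        raise ValueError("both models need >= 20 protein residues with CA atoms")
    aligner = _make_aligner()
    aln = aligner.align(seq_a.replace("X", "A"), seq_b.replace("X", "A"))[0]
    pairs: list[tuple[int, int]] = []
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        pairs.extend(zip(range(sa, ea), range(sb, eb)))

    rejected: list[tuple] = []
    result: SuperpositionResult | None = None
    for cycle in range(1, max_cycles + 1):
        if len(pairs) < 3:
            raise ValueError("fewer than 3 Calpha pairs survive rejection")
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        result = kabsch(ca_a[ia], ca_b[ib])
        result.n_cycles = cycle
        moved = result.transform(ca_a[ia])
        dev = np.linalg.norm(moved - ca_b[ib], axis=1)
        bad = dev > reject_cutoff
        if not np.any(bad):
            break
        for k in np.nonzero(bad)[0]:
            rejected.append((res_a[pairs[k][0]].key, res_b[pairs[k][1]].key))
        pairs = [p for p, is_bad in zip(pairs, bad) if not is_bad]
    assert result is not None
    result.rejected = rejected
    return result


def apply_transform(model: StructureModel, result: SuperpositionResult) -> StructureModel:
    """Return a copy of *model* with all atoms moved by the fitted transform."""
    out = model.copy()
    for res in out.residues:
        for atom in res.atoms:
            atom.position = result.rotation @ atom.position + result.translation
    return out
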