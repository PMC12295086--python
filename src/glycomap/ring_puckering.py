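"""Cremer–Pople puckering of six-membered rings.

Atom-order convention: the ring oxygen is atom j=1, followed by C1..C5 in
ring-bond order (O5, C1, C2, C3, C4, C5).  Under this convention, together
with the sign conventions of the standard N=6 formulas implemented here, an
ideal chair with O5/C2/C4 above the mean plane maps to theta = 0 and is
labelled "4C1"; the full 38-conformer itinerary (2 chairs, 6 boats, 6
skew-boats, 12 envelopes, 12 half-chairs) is generated from idealized
displacement patterns rather than hard-coded, so labels can never drift out
of sync with the transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .glycan_topology import SugarRing

__all__ = [
    "PuckerState",
    "cremer_pople",
    "cremer_pople_coords",
    "classify_conformer",
    "invert_cremer_pople",
    "canonical_conformers",
    "PLANARITY_THRESHOLD",
    "LIKE_THRESHOLD",
]

#: Rings with total amplitude below this (Å) are reported as "planar".
PLANARITY_THRESHOLD = 0.05
#: Angular distance (degrees) beyond which the conformer label gets a "-like" suffix.
LIKE_THRESHOLD = 15.0

_N = 6
_J = np.arange(_N)  # j-1 in the 1-based formulas


@dataclass
class PuckerState:
    """Total amplitude Q (Å), polar angle theta and phase phi (degrees)."""

    Q: float
    theta: float
    phi: float
    conformer: str = ""
    conformer_distance: float = float("nan")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.Q, self.theta, self.phi)


def _ring_coords(ring) -> np.ndarray:
    if hasattr(ring, "ring_atoms"):
        return np.array([a.position for a in ring.ring_atoms], dtype=float)
    return np.asarray(ring, dtype=float)


def cremer_pople_coords(coords: np.ndarray) -> PuckerState:
    """Puckering parameters from a 6x3 coordinate array in canonical ring order."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (6, 3):
        raise ValueError(f"expected 6 ring atoms, got shape {coords.shape}")
    centered = coords - coords.mean(axis=0)
    if np.min(
        np.linalg.norm(centered[:, None, :] - centered[None, :, :], axis=-1)
        + np.eye(6) * 1e6
    ) < 1e-6:
        raise ValueError("coincident ring atoms")

    ang = 2.0 * np.pi * _J / _N
    r_prime = (centered * np.sin(ang)[:, None]).sum(axis=0)
    r_dprime = (centered * np.cos(ang)[:, None]).sum(axis=0)
    normal = np.cross(r_prime, r_dprime)
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        raise ValueError("degenerate ring: mean plane undefined")
    normal /= nn
    z = centered @ normal

    cos2 = math.sqrt(2.0 / _N) * float(z @ np.cos(2.0 * ang))
    sin2 = -math.sqrt(2.0 / _N) * float(z @ np.sin(2.0 * ang))
    q2 = math.hypot(cos2, sin2)
    q3 = float(z @ np.power(-1.0, _J)) / math.sqrt(_N)
    Q = math.sqrt(float(z @ z))

    if Q < 1e-12:
        return PuckerState(Q=0.0, theta=0.0, phi=0.0, conformer="planar", conformer_distance=0.0)
    theta = math.degrees(math.atan2(q2, q3))
    phi = math.degrees(math.atan2(sin2, cos2)) % 360.0 if q2 > 1e-10 else 0.0
    if q2 <= 1e-10 or 360.0 - phi < 1e-9:
        phi = 0.0
    state = PuckerState(Q=Q, theta=theta, phi=phi)
    if Q < PLANARITY_THRESHOLD:
        state.conformer = "planar"
        state.conformer_distance = 0.0
    return state


def cremer_pople(ring: "SugarRing | np.ndarray") -> PuckerState:
    """Puckering parameters of a detected sugar ring (or raw 6x3 coordinates)."""
    return cremer_pople_coords(_ring_coords(ring))


def invert_cremer_pople(
    Q: float, theta: float, phi: float, radius: float = 1.43
) -> np.ndarray:
    """Ideal 6x3 ring coordinates realizing the given puckering parameters.

    Atoms are placed clockwise (viewed from +z) on a circle of *radius* so
    that the oriented mean-plane normal of the forward transform is +z, which
    makes ``cremer_pople(invert_cremer_pople(...))`` the identity.
    """
    if Q < 0:
        raise ValueError("amplitude Q must be non-negative")
    if radius <= 0:
        raise ValueError("radius must be positive")
    th, ph = math.radians(theta), math.radians(phi)
    q2, q3 = Q * math.sin(th), Q * math.cos(th)
    ang = 2.0 * np.pi * _J / _N
    z = math.sqrt(2.0 / _N) * q2 * np.cos(ph + 2.0 * ang) + q3 / math.sqrt(_N) * np.power(-1.0, _J)
    xy_ang = -ang  # clockwise: orients the CP normal along +z
    coords = np.stack(
        [radius * np.cos(xy_ang), radius * np.sin(xy_ang), z], axis=1
    )
    return coords - coords.mean(axis=0)


# ---------------------------------------------------------------------------
# Canonical conformer itinerary
# ---------------------------------------------------------------------------

_ATOM_LABELS = ("O", "1", "2", "3", "4", "5")  # ring positions O5, C1..C5


def _group_label(indices: Sequence[int]) -> str:
    labels = sorted((_ATOM_LABELS[i] for i in indices), key=lambda s: (s == "O", s))
    return "".join(labels)


def _pattern_angles(z: np.ndarray) -> tuple[float, float]:
    ang = 2.0 * np.pi * _J / _N
    cos2 = float(z @ np.cos(2.0 * ang))
    sin2 = -float(z @ np.sin(2.0 * ang))
    q2 = math.hypot(cos2, sin2) * math.sqrt(2.0 / _N)
    q3 = float(z @ np.power(-1.0, _J)) / math.sqrt(_N)
    theta = math.degrees(math.atan2(q2, q3))
    phi = math.degrees(math.atan2(sin2, cos2)) % 360.0 if q2 > 1e-12 else 0.0
    return (round(theta, 6), round(phi, 6))


def canonical_conformers() -> Mapping[str, tuple[float, float]]:
    """The 38 canonical pyranose conformers as {label: (theta, phi) degrees}.

    Derived from pure displacement patterns: chairs (full alternation), boats
    (para pair displaced one side), skew-boats (the six itinerary twist pairs),
    envelopes (single atom) and half-chairs (adjacent pair, opposite sides).
    """
    refs: dict[str, tuple[float, float]] = {}

    chair = np.power(-1.0, _J)  # O5, C2, C4 up
    refs["4C1"] = _pattern_angles(chair)
    refs["1C4"] = _pattern_angles(-chair)

    for p in range(3):
        pair = (p, p + 3)
        z = np.full(_N, -0.5)
        z[list(pair)] = 1.0
        refs[f"{_group_label(pair)}B"] = _pattern_angles(z)
        refs[f"B{_group_label(pair)}"] = _pattern_angles(-z)

    # itinerary twist-boats: O5/C2, C1/C3, C1/C5 axes (each twist-boat has two
    # equivalent reference-plane names; these are the conventional six)
    for up, down in ((0, 2), (2, 0), (1, 3), (3, 1), (1, 5), (5, 1)):
        z = np.zeros(_N)
        z[up], z[down] = 1.0, -1.0
        refs[f"{_ATOM_LABELS[up]}S{_ATOM_LABELS[down]}"] = _pattern_angles(z)

    for i in range(_N):
        z = np.zeros(_N)
        z[i] = 1.0
        refs[f"{_ATOM_LABELS[i]}E"] = _pattern_angles(z)
        refs[f"E{_ATOM_LABELS[i]}"] = _pattern_angles(-z)

    for i in range(_N):
        for j in ((i + 1) % _N, (i - 1) % _N):
            z = np.zeros(_N)
            z[i], z[j] = 1.0, -1.0
            refs[f"{_ATOM_LABELS[i]}H{_ATOM_LABELS[j]}"] = _pattern_angles(z)

    assert len(refs) == 38
    return refs


_CANONICAL = canonical_conformers()


def _sphere_distance(t1: float, p1: float, t2: float, p2: float) -> float:
    """Great-circle distance (degrees) between two (theta, phi) points."""
    t1, p1, t2, p2 = map(math.radians, (t1, p1, t2, p2))
    c = math.sin(t1) * math.sin(t2) * math.cos(p1 - p2) + math.cos(t1) * math.cos(t2)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def classify_conformer(
    state: PuckerState, like_threshold: float = LIKE_THRESHOLD
) -> PuckerState:
    """Fill in the nearest canonical conformer label on the puckering sphere."""
    if state.Q < PLANARITY_THRESHOLD:
        state.conformer = "planar"
        state.conformer_distance = 0.0
        return state
    best_label, best_dist = "", float("inf")
    for label, (t, p) in _CANONICAL.items():
        d = _sphere_distance(state.theta, state.phi, t, p)
        if d < best_dist:
            best_label, best_dist = label, d
    state.conformer = best_label + ("-like" if best_dist > like_threshold else "")
    state.conformer_distance = best_dist
    return state
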