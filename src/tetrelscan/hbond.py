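"""Idealized methyl hydrogens and the competing CH...X hydrogen-bond geometry.

X-ray structures in the survey's resolution range carry no reliable hydrogen
positions, so the three methyl hydrogens are constructed with ideal
tetrahedral geometry (C-H = 1.09 A, H on the cone opposite the sulfur).
Measuring d(H...X) and the C-H...X angle for each hydrogen quantifies how
hydrogen-bond-like a contact is: an acceptor sitting on the S-C axis
extension sees all three hydrogens at equally acute C-H...X angles, which is
the geometric signature distinguishing a tetrel bond from a trifurcated
CH...X hydrogen bond.

The methyl torsion is a free parameter; ``closest-approach`` mode rotates it
to minimize d(H...X) toward a reference acceptor, giving the most
conservative (strongest possible) estimate of hydrogen-bond competition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .detect import MethylDonorSite, TetrelContact
from .geometry import DegenerateGeometryError, distance, vertex_angle
from .structure_io import AtomRecord

__all__ = [
    "TETRAHEDRAL_ANGLE",
    "MethylHydrogenSet",
    "HbondGeometryReport",
    "place_methyl_hydrogens",
    "hbond_report",
    "hbond_label",
]

# arccos(-1/3): the ideal S-C-H angle for a tetrahedral methyl carbon.
TETRAHEDRAL_ANGLE = math.degrees(math.acos(-1.0 / 3.0))

DEFAULT_CH_LENGTH = 1.09


@dataclass(frozen=True)
class MethylHydrogenSet:
    h_positions: tuple[np.ndarray, np.ndarray, np.ndarray]
    rotamer_mode: str
    ch_length: float = DEFAULT_CH_LENGTH


@dataclass(frozen=True)
class HbondGeometryReport:
    """Per-hydrogen distance/angle to one acceptor; best = shortest d_HX."""

    per_h: tuple[tuple[float, float], ...]  # (d_HX in A, angle_CHX in deg)
    best_h_index: int

    @property
    def d_hx_min(self) -> float:
        return self.per_h[self.best_h_index][0]

    @property
    def angle_chx_best(self) -> float:
        return self.per_h[self.best_h_index][1]


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic right-handed (e1, e2) basis perpendicular to axis."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(axis, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def place_methyl_hydrogens(
    site: MethylDonorSite,
    mode: str = "staggered",
    reference: AtomRecord | None = None,
    seed_azimuth: float = 0.0,
    ch_length: float = DEFAULT_CH_LENGTH,
) -> MethylHydrogenSet:
    """Construct three ideal methyl hydrogens about the S-CH3 axis.

    Each hydrogen satisfies |H - C| = ch_length and angle(S, C, H) equal to
    the tetrahedral value (109.471 deg), arranged three-fold about the axis.
    ``staggered`` fixes the torsion from seed_azimuth; ``closest-approach``
    chooses the torsion minimizing d(H...X) for the reference acceptor
    (closed form: the in-plane hydrogen component is aligned with the
    in-plane component of the acceptor).
    """
    s = np.asarray(site.sulfur.position, dtype=float)
    c = np.asarray(site.methyl_carbon.position, dtype=float)
    axis = c - s
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise DegenerateGeometryError("S and C coincide; no methyl axis")
    u = axis / norm
    e1, e2 = _orthonormal_frame(u)

    if mode == "closest-approach":
        if reference is None:
            raise ValueError("closest-approach mode requires a reference acceptor")
        v = np.asarray(reference.position, dtype=float) - c
        w = v - np.dot(v, u) * u
        if np.linalg.norm(w) < 1e-12:
            phi0 = math.radians(seed_azimuth)  # axial acceptor: torsion moot
        else:
            phi0 = math.atan2(np.dot(w, e2), np.dot(w, e1))
    elif mode == "staggered":
        phi0 = math.radians(seed_azimuth)
    else:
        raise ValueError(f"unknown rotamer mode {mode!r}")

    # angle(S, C, H) tetrahedral means (H - C) . (-u) = L * cos(109.471) = -L/3,
    # so H = C + L * ( (1/3) u + (sqrt(8)/3) radial ).
    sin_a = math.sqrt(8.0) / 3.0
    positions = []
    for k in range(3):
        phi = phi0 + k * 2.0 * math.pi / 3.0
        radial = math.cos(phi) * e1 + math.sin(phi) * e2
        positions.append(c + ch_length * ((1.0 / 3.0) * u + sin_a * radial))
    return MethylHydrogenSet(
        h_positions=tuple(positions), rotamer_mode=mode, ch_length=ch_length
    )


def hbond_report(
    hset: MethylHydrogenSet, acceptor: AtomRecord, methyl_carbon: AtomRecord
) -> HbondGeometryReport:
    """Distance and C-H...X angle for each constructed hydrogen."""
    x = np.asarray(acceptor.position, dtype=float)
    c = np.asarray(methyl_carbon.position, dtype=float)
    per_h = []
    for h in hset.h_positions:
        d_hx = distance(h, x)
        angle_chx = vertex_angle(c, h, x)
        per_h.append((d_hx, angle_chx))
    best = min(range(3), key=lambda i: per_h[i][0])
    return HbondGeometryReport(per_h=tuple(per_h), best_h_index=best)


def hbond_label(theta: float, report: HbondGeometryReport, theta_min: float = 160.0) -> str:
    """Heuristic label for a contact's character (a package convention).

    "tetrel-consistent" when the S-C...X angle is in the sigma-hole window
    and every C-H...X angle is under 120 deg (too bent for a conventional
    hydrogen bond); otherwise "hbond-competitive".
    """
    angles = [a for _, a in report.per_h]
    if theta >= theta_min and all(a < 120.0 for a in angles):
        return "tetrel-consistent"
    return "hbond-competitive"
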