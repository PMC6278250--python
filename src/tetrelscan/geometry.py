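"""Geometric primitives for sigma-hole contact analysis.

Distances, vertex angles, van der Waals contact cutoffs and radius-neighbor
search.  Everything here is pure computation on coordinates in Angstrom;
angles are in degrees throughout the package.

The default van der Waals radius table pins carbon, oxygen and chlorine to
the values used by the survey criteria (C 1.75, O 1.50, Cl 1.75 A, giving
the contact cutoffs R(C...O) <= 3.25 A and R(C...Cl) <= 3.50 A).  Radii for
other elements come from the Bondi compilation and are only consulted when
the detector is configured to scan additional acceptor elements; every entry
carries a provenance label and can be overridden from the config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "VdwRadiusTable",
    "ContactGeometry",
    "DegenerateGeometryError",
    "MissingRadiusError",
    "distance",
    "vertex_angle",
    "vdw_cutoff",
    "neighbor_search",
]


class DegenerateGeometryError(ValueError):
    """An angle was requested with a zero-length arm."""


class MissingRadiusError(KeyError):
    """An element has no entry in the van der Waals radius table."""

    def __init__(self, element: str):
        super().__init__(element)
        self.element = element

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"no van der Waals radius for element {self.element!r}"


# Survey-defining radii for the three elements the contact criteria cover.
_SURVEY_RADII = {"C": 1.75, "O": 1.50, "CL": 1.75}

# Bondi (1964) radii for the optional extra acceptor elements.
_BONDI_RADII = {
    "H": 1.20,
    "N": 1.55,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "BR": 1.85,
    "I": 1.98,
}


@dataclass(frozen=True)
class VdwRadiusTable:
    """Element -> van der Waals radius (A), with per-entry provenance."""

    radii: Mapping[str, float]
    provenance: Mapping[str, str]

    @classmethod
    def default(cls, overrides: Mapping[str, float] | None = None) -> "VdwRadiusTable":
        radii = dict(_SURVEY_RADII)
        prov = {el: "survey-criteria" for el in _SURVEY_RADII}
        for el, r in _BONDI_RADII.items():
            radii.setdefault(el, r)
            prov.setdefault(el, "bondi")
        if overrides:
            for el, r in overrides.items():
                key = el.upper()
                if r <= 0:
                    raise ValueError(f"radius for {el!r} must be positive, got {r}")
                radii[key] = float(r)
                prov[key] = "override"
        return cls(radii=radii, provenance=prov)

    def radius(self, element: str) -> float:
        try:
            return self.radii[element.upper()]
        except KeyError:
            raise MissingRadiusError(element) from None

    def __contains__(self, element: str) -> bool:
        return element.upper() in self.radii


@dataclass(frozen=True)
class ContactGeometry:
    """Measured geometry of one donor-site/acceptor pair.

    r       -- C...X distance, A
    theta   -- S-C...X angle at the methyl carbon, degrees
    cutoff  -- sum of the two van der Waals radii, A
    """

    r: float
    theta: float
    cutoff: float
    normalized_r: float = field(init=False)

    def __post_init__(self):
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError(f"theta out of [0, 180]: {self.theta}")
        object.__setattr__(self, "normalized_r", self.r / self.cutoff)


def distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two points (A)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(b - a))


def vertex_angle(p: Sequence[float], vertex: Sequence[float], q: Sequence[float]) -> float:
    """Angle p-vertex-q in degrees, in [0, 180].

    The cosine is clamped to [-1, 1] so collinear arrangements at the edge of
    floating-point precision return exactly 0 or 180.
    """
    p = np.asarray(p, dtype=float)
    v = np.asarray(vertex, dtype=float)
    q = np.asarray(q, dtype=float)
    u1 = p - v
    u2 = q - v
    n1 = np.linalg.norm(u1)
    n2 = np.linalg.norm(u2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateGeometryError("vertex angle with zero-length arm")
    cosang = float(np.dot(u1, u2) / (n1 * n2))
    cosang = max(-1.0, min(1.0, cosang))
    return float(np.degrees(np.arccos(cosang)))


def vdw_cutoff(elem1: str, elem2: str, table: VdwRadiusTable | None = None) -> float:
    """Contact cutoff: sum of the two elements' van der Waals radii (A)."""
    if table is None:
        table = VdwRadiusTable.default()
    return table.radius(elem1) + table.radius(elem2)


def neighbor_search(atoms, center: Sequence[float], radius: float) -> list:
    """All atoms with distance(center, atom) <= radius, boundary inclusive.

    Accepts any iterable of objects exposing a ``position`` attribute (or raw
    3-vectors).  Uses a k-d tree; contractually identical to the all-pairs
    scan, which the test suite enforces.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    atoms = list(atoms)
    if not atoms:
        return []
    coords = np.array([_pos(a) for a in atoms], dtype=float)
    tree = cKDTree(coords)
    # cKDTree uses <= for query_ball_point, matching the inclusive criterion.
    idx = tree.query_ball_point(np.asarray(center, dtype=float), r=radius)
    return [atoms[i] for i in sorted(idx)]


def brute_force_neighbors(atoms, center: Sequence[float], radius: float) -> list:
    """Reference all-pairs implementation of :func:`neighbor_search`."""
    center = np.asarray(center, dtype=float)
    return [a for a in atoms if distance(center, _pos(a)) <= radius]


def _pos(atom) -> np.ndarray:
    pos = getattr(atom, "position", atom)
    return np.asarray(pos, dtype=float)
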