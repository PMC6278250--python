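"""Detection of methyl tetrel bonds at sulfonium S-CH3 donor sites.

A tetrel bond is a sigma-hole interaction in which a Lewis base donates lone
pair density into the sigma* orbital of a carbon-group atom.  At a sulfonium
methyl group (such as the S-adenosylmethionine cofactor, atoms SD/CE in PDB
component SAM) the sigma-hole lies on the extension of the S-CH3 bond, so a
contact qualifies when

  (1) the angle theta(S-C...X) at the methyl carbon is within [160, 180]
      degrees (both ends inclusive), and
  (2) the C...X distance is at or below the sum of the van der Waals radii
      of carbon and the acceptor element (3.25 A for C...O, 3.50 A for
      C...Cl with the default radius table).

Both passing and near-miss contacts are retained, flagged, so that reports
can show near-threshold geometry.  Polymer-atom acceptors are scanned and
flagged rather than skipped, which keeps the "no protein-residue acceptor"
observation checkable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .geometry import (
    ContactGeometry,
    VdwRadiusTable,
    distance,
    neighbor_search,
    vdw_cutoff,
    vertex_angle,
)
from .structure_io import AtomRecord, ResidueRecord, StructureModel

__all__ = [
    "MethylDonorSite",
    "DetectionParams",
    "TetrelContact",
    "find_methyl_donor_sites",
    "enumerate_candidates",
    "evaluate_contact",
    "scan_structure",
]

logger = logging.getLogger(__name__)

# Plausible S-C single bond range used to reject corrupt donor geometry.
_SC_BOND_RANGE = (1.6, 2.0)


@dataclass(frozen=True)
class MethylDonorSite:
    """A sulfonium S-CH3 pair that can accept a tetrel bond at the carbon."""

    sulfur: AtomRecord
    methyl_carbon: AtomRecord
    residue: ResidueRecord
    chain_id: str

    @property
    def sc_bond_length(self) -> float:
        return distance(self.sulfur.position, self.methyl_carbon.position)


@dataclass(frozen=True)
class DetectionParams:
    """Tunable survey criteria; defaults reproduce the standard screen."""

    theta_min: float = 160.0
    theta_max: float = 180.0
    acceptor_elements: frozenset[str] = frozenset({"O", "CL"})
    radius_table: VdwRadiusTable = field(default_factory=VdwRadiusTable.default)
    max_search_radius: float = 3.6
    donor_residue_names: frozenset[str] = frozenset({"SAM"})
    sulfur_atom_name: str = "SD"
    methyl_atom_name: str = "CE"
    min_occupancy: float = 0.0
    altloc_mode: str = "best"  # "best" or "all"

    def __post_init__(self):
        if not 0.0 <= self.theta_min < self.theta_max <= 180.0:
            raise ValueError("require 0 <= theta_min < theta_max <= 180")
        max_cutoff = max(
            vdw_cutoff("C", el, self.radius_table) for el in self.acceptor_elements
        )
        if self.max_search_radius < max_cutoff:
            raise ValueError(
                f"max_search_radius {self.max_search_radius} smaller than the "
                f"largest configured vdW cutoff {max_cutoff}"
            )

    def replace(self, **kwargs) -> "DetectionParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TetrelContact:
    """One donor-site/acceptor pair with measured geometry and pass flags."""

    site: MethylDonorSite
    acceptor: AtomRecord
    acceptor_residue: ResidueRecord
    geometry: ContactGeometry
    donor_class: str
    passes_distance: bool
    passes_angle: bool

    @property
    def passes(self) -> bool:
        return self.passes_distance and self.passes_angle


def _select_altloc(atoms: list[AtomRecord]) -> AtomRecord:
    """Highest-occupancy alternate location; ties broken by altloc letter."""
    return min(atoms, key=lambda a: (-a.occupancy, a.altloc or "A"))


def find_methyl_donor_sites(
    model: StructureModel, params: DetectionParams | None = None
) -> list[MethylDonorSite]:
    """Locate sulfonium S-CH3 donor sites by residue and atom name.

    One site per donor-named residue containing both the sulfur and the
    methyl-carbon atom (after altloc selection).  Sites whose S-C distance
    falls outside the plausible bond range are dropped with a warning.
    """
    params = params or DetectionParams()
    sites: list[MethylDonorSite] = []
    for residue in model.residues:
        if residue.name.strip().upper() not in params.donor_residue_names:
            continue
        sulfurs = [a for a in residue.atoms if a.name == params.sulfur_atom_name]
        carbons = [a for a in residue.atoms if a.name == params.methyl_atom_name]
        if not sulfurs or not carbons:
            continue
        if params.altloc_mode == "all":
            pairs = [(s, c) for s in sulfurs for c in carbons]
        else:
            pairs = [(_select_altloc(sulfurs), _select_altloc(carbons))]
        for sulfur, carbon in pairs:
            site = MethylDonorSite(
                sulfur=sulfur, methyl_carbon=carbon, residue=residue, chain_id=residue.chain_id
            )
            lo, hi = _SC_BOND_RANGE
            if not lo <= site.sc_bond_length <= hi:
                logger.warning(
                    "dropping donor site %s %s%d: S-C distance %.2f A outside [%.1f, %.1f]",
                    residue.name,
                    residue.chain_id,
                    residue.seq_id,
                    site.sc_bond_length,
                    lo,
                    hi,
                )
                continue
            sites.append(site)
    return sites


def enumerate_candidates(
    model: StructureModel, site: MethylDonorSite, params: DetectionParams | None = None
) -> list[AtomRecord]:
    """Candidate acceptor atoms near a donor site.

    Atoms of a configured acceptor element within the search radius of the
    methyl carbon, excluding the donor residue's own atoms, hydrogens, and
    atoms below the occupancy threshold.  Polymer atoms are included (they
    are flagged by donor class downstream, never silently skipped).
    """
    params = params or DetectionParams()
    elements = {e.upper() for e in params.acceptor_elements} - {"H"}
    pool: list[AtomRecord] = []
    for residue in model.residues:
        if residue is site.residue:
            continue
        matching = [
            a
            for a in residue.atoms
            if a.element.upper() in elements and a.occupancy >= params.min_occupancy
        ]
        if params.altloc_mode == "all":
            pool.extend(matching)
        else:
            # one atom per name: highest-occupancy alternate location
            by_name: dict[str, list[AtomRecord]] = {}
            for a in matching:
                by_name.setdefault(a.name, []).append(a)
            pool.extend(_select_altloc(group) for group in by_name.values())
    return neighbor_search(pool, site.methyl_carbon.position, params.max_search_radius)


def evaluate_contact(
    site: MethylDonorSite, acceptor: AtomRecord, params: DetectionParams | None = None
) -> TetrelContact:
    """Measure one donor/acceptor pair and apply the two criteria.

    r is the C...X distance, theta the S-C...X angle at the methyl carbon,
    and the cutoff the C + acceptor-element van der Waals sum.  Both
    boundaries are inclusive.
    """
    params = params or DetectionParams()
    r = distance(site.methyl_carbon.position, acceptor.position)
    theta = vertex_angle(
        site.sulfur.position, site.methyl_carbon.position, acceptor.position
    )
    cutoff = vdw_cutoff("C", acceptor.element, params.radius_table)
    geometry = ContactGeometry(r=r, theta=theta, cutoff=cutoff)
    acceptor_residue = acceptor.parent_residue
    if acceptor_residue is None:
        raise ValueError("acceptor atom has no parent residue")
    return TetrelContact(
        site=site,
        acceptor=acceptor,
        acceptor_residue=acceptor_residue,
        geometry=geometry,
        donor_class=acceptor_residue.category,
        passes_distance=r <= cutoff,
        passes_angle=params.theta_min <= theta <= params.theta_max,
    )


def scan_structure(
    model: StructureModel, params: DetectionParams | None = None
) -> list[TetrelContact]:
    """Evaluate every candidate acceptor for every donor site in a model.

    Each candidate is evaluated exactly once; results are sorted by
    (chain, passing first, increasing r) so the strongest contacts lead.
    """
    params = params or DetectionParams()
    contacts: list[TetrelContact] = []
    for site in find_methyl_donor_sites(model, params):
        for acceptor in enumerate_candidates(model, site, params):
            contacts.append(evaluate_contact(site, acceptor, params))
    contacts.sort(key=lambda c: (c.site.chain_id, not c.passes, c.geometry.r))
    return contacts
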