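"""Ground-truth synthetic structures for testing the detection pipeline.

Builds a minimal sulfonium fragment with S-adenosylmethionine atom naming
(SD sulfur, CE methyl carbon, plus two ethyl arms) and places probe acceptor
atoms at exactly controlled distance r, angle theta and azimuth about the
S-CH3 axis.  Batches mix planted-pass placements (inside the contact
criteria) with planted-fail decoys sampling all three violation modes
(distance only, angle only, both) so each criterion is exercised
independently.  Everything is deterministic under a seed.

These fixtures emulate only the local geometry the detector reasons about;
they contain no protein environment, crystallographic noise, B-factor
variation or altloc disorder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detect import DetectionParams
from .geometry import vdw_cutoff
from .structure_io import AtomRecord, ResidueRecord, StructureModel, classify_residue, write_pdb

__all__ = [
    "PlacementSpec",
    "FixtureBatch",
    "build_sulfonium_fragment",
    "place_probe",
    "generate_batch",
]

# Construction constants: standard sulfonium internal geometry.
SC_BOND = 1.81  # S-C bond length, A
CC_BOND = 1.53  # C-C bond length, A
CSC_ANGLE = 100.0  # C-S-C angle, deg
SCC_ANGLE = 109.471  # S-C-C angle for the ethyl arms, deg

_PROBE_RESIDUE = {"O": "HOH", "CL": "CL"}
_PROBE_ATOM = {"O": "O", "CL": "CL"}


@dataclass(frozen=True)
class PlacementSpec:
    """One probe placement: target geometry plus its planted label."""

    r: float
    theta: float
    azimuth: float
    probe_element: str = "O"
    probe_residue_name: str | None = None
    label: str = "planted-pass"  # or "planted-fail"

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError(f"r must be positive, got {self.r}")
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError(f"theta out of [0, 180]: {self.theta}")
        if not 0.0 <= self.azimuth < 360.0:
            raise ValueError(f"azimuth out of [0, 360): {self.azimuth}")
        if self.probe_residue_name is None:
            object.__setattr__(
                self, "probe_residue_name", _PROBE_RESIDUE[self.probe_element.upper()]
            )

    def expected_pass(self, params: DetectionParams | None = None) -> bool:
        params = params or DetectionParams()
        cutoff = vdw_cutoff("C", self.probe_element, params.radius_table)
        return self.r <= cutoff and params.theta_min <= self.theta <= params.theta_max


@dataclass
class FixtureBatch:
    seed: int
    specs: list[PlacementSpec]
    models: list[StructureModel]
    truth: list[str]  # label per model, aligned with models


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    a = math.radians(angle_deg)
    return (
        v * math.cos(a)
        + np.cross(axis, v) * math.sin(a)
        + axis * np.dot(axis, v) * (1.0 - math.cos(a))
    )


def build_sulfonium_fragment(residue_name: str = "SAM") -> ResidueRecord:
    """Deterministic MeS+(Et)2-like fragment with SAM atom naming.

    SD at the origin, CE (the methyl carbon) at +x, and two ethyl arms
    (CG-CB, C5'-C4') at the C-S-C construction angle.  Only heavy atoms;
    coordinates are exact construction values.
    """
    sd = np.zeros(3)
    ce = np.array([SC_BOND, 0.0, 0.0])
    x = np.array([1.0, 0.0, 0.0])

    def arm_root(azimuth: float) -> np.ndarray:
        # unit vector at CSC_ANGLE from +x, rotated about x by azimuth
        v = _rotate_about(x, np.array([0.0, 0.0, 1.0]), CSC_ANGLE)
        return _rotate_about(v, x, azimuth)

    cg_dir = arm_root(120.0)
    c5_dir = arm_root(240.0)
    cg = sd + SC_BOND * cg_dir
    c5 = sd + SC_BOND * c5_dir

    def arm_tip(root: np.ndarray, root_dir: np.ndarray) -> np.ndarray:
        # second arm carbon: S-C-C angle SCC_ANGLE, torsion anti to CE
        axis = np.cross(root_dir, x)
        n = np.linalg.norm(axis)
        axis = axis / n
        tip_dir = _rotate_about(-root_dir, axis, SCC_ANGLE)
        return root + CC_BOND * tip_dir

    cb = arm_tip(cg, cg_dir)
    c4 = arm_tip(c5, c5_dir)

    atoms = [
        AtomRecord(serial=1, name="SD", element="S", position=sd),
        AtomRecord(serial=2, name="CE", element="C", position=ce),
        AtomRecord(serial=3, name="CG", element="C", position=cg),
        AtomRecord(serial=4, name="CB", element="C", position=cb),
        AtomRecord(serial=5, name="C5'", element="C", position=c5),
        AtomRecord(serial=6, name="C4'", element="C", position=c4),
    ]
    residue = ResidueRecord(
        name=residue_name, chain_id="A", seq_id=1, category="ligand", atoms=atoms
    )
    return residue


def place_probe(
    fragment: ResidueRecord,
    spec: PlacementSpec,
    entry_id: str = "synthetic",
    resolution: float | None = 1.50,
    probe_seq_id: int = 101,
) -> StructureModel:
    """Embed a probe acceptor at exact (r, theta, azimuth) about the S-C axis.

    The probe is its own residue (water-named for O probes, chloride-named
    for Cl) so residue classification is exercised alongside detection.
    """
    sd = fragment.find_atom("SD")
    ce = fragment.find_atom("CE")
    if sd is None or ce is None:
        raise ValueError("fragment lacks SD/CE atoms")
    u = (ce.position - sd.position) / np.linalg.norm(ce.position - sd.position)
    # theta is the angle between (SD - CE) and (X - CE); theta=180 puts X on
    # the S->C extension (the sigma-hole position).
    e1 = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(e1, u)) > 0.9:
        e1 = np.array([0.0, 1.0, 0.0])
    e1 = e1 - np.dot(e1, u) * u
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    t = math.radians(spec.theta)
    phi = math.radians(spec.azimuth)
    direction = -math.cos(t) * u + math.sin(t) * (math.cos(phi) * e1 + math.sin(phi) * e2)
    pos = ce.position + spec.r * direction

    element = spec.probe_element.capitalize()
    probe_atom = AtomRecord(
        serial=len(fragment.atoms) + 1,
        name=_PROBE_ATOM[spec.probe_element.upper()],
        element=element,
        position=pos,
    )
    probe_residue = ResidueRecord(
        name=spec.probe_residue_name,
        chain_id="A",
        seq_id=probe_seq_id,
        atoms=[probe_atom],
    )
    probe_residue.category = classify_residue(probe_residue)

    # fresh copy of the fragment so callers can reuse it
    frag_copy = ResidueRecord(
        name=fragment.name,
        chain_id=fragment.chain_id,
        seq_id=fragment.seq_id,
        insertion_code=fragment.insertion_code,
        category=fragment.category,
        atoms=[
            AtomRecord(
                serial=a.serial,
                name=a.name,
                element=a.element,
                position=a.position.copy(),
                occupancy=a.occupancy,
                altloc=a.altloc,
                b_factor=a.b_factor,
            )
            for a in fragment.atoms
        ],
    )
    return StructureModel(
        entry_id=entry_id, residues=[frag_copy, probe_residue], resolution=resolution
    )


def _sample_pass(rng: np.random.Generator, params: DetectionParams) -> PlacementSpec:
    element = rng.choice(["O", "CL"])
    cutoff = vdw_cutoff("C", element, params.radius_table)
    return PlacementSpec(
        r=float(rng.uniform(2.4, cutoff)),
        theta=float(rng.uniform(params.theta_min, params.theta_max)),
        azimuth=float(rng.uniform(0.0, 360.0)),
        probe_element=str(element),
        label="planted-pass",
    )


def _sample_fail(rng: np.random.Generator, params: DetectionParams, mode: int) -> PlacementSpec:
    element = rng.choice(["O", "CL"])
    cutoff = vdw_cutoff("C", element, params.radius_table)
    good_r = float(rng.uniform(2.4, cutoff))
    # beyond the cutoff but inside the search radius, so it stays a near-miss
    bad_r = float(rng.uniform(cutoff + 0.01, params.max_search_radius))
    good_theta = float(rng.uniform(params.theta_min, params.theta_max))
    bad_theta = float(rng.uniform(90.0, params.theta_min - 0.5))
    r, theta = [(bad_r, good_theta), (good_r, bad_theta), (bad_r, bad_theta)][mode]
    return PlacementSpec(
        r=r,
        theta=theta,
        azimuth=float(rng.uniform(0.0, 360.0)),
        probe_element=str(element),
        label="planted-fail",
    )


def generate_batch(
    seed: int,
    n_pass: int,
    n_fail: int,
    params: DetectionParams | None = None,
    outdir: str | Path | None = None,
) -> FixtureBatch:
    """Seeded batch of single-probe models with planted pass/fail labels.

    Failing placements cycle through the three violation modes (distance
    only, angle only, both) in equal proportion.  With ``outdir`` set, each
    model is also written as a PDB file plus a truth table TSV; output is
    byte-identical across runs with the same seed.
    """
    params = params or DetectionParams()
    rng = np.random.default_rng(seed)
    fragment = build_sulfonium_fragment()
    specs: list[PlacementSpec] = []
    for _ in range(n_pass):
        specs.append(_sample_pass(rng, params))
    for i in range(n_fail):
        specs.append(_sample_fail(rng, params, i % 3))

    models = [
        place_probe(fragment, spec, entry_id=f"synth{idx:04d}")
        for idx, spec in enumerate(specs)
    ]
    truth = [spec.label for spec in specs]
    batch = FixtureBatch(seed=seed, specs=specs, models=models, truth=truth)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = ["file\tlabel\tr\ttheta\telement"]
        for model, spec in zip(models, specs):
            fname = f"{model.entry_id}.pdb"
            write_pdb(model, outdir / fname)
            rows.append(
                f"{fname}\t{spec.label}\t{spec.r:.6f}\t{spec.theta:.6f}\t{spec.probe_element}"
            )
        (outdir / "truth.tsv").write_text("\n".join(rows) + "\n")
    return batch
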