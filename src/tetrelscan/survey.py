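"""Survey of methyl tetrel bonding across a manifest of structures.

Runs detection over a user-curated corpus, applies the resolution screen
(<= 2.50 A by default) and the redundancy rule (for structures of the same
enzyme with the same donor, keep only the highest-resolution wild-type
structure), and emits a survey table: one row per nonredundant
enzyme/donor pair with per-chain R(C...X) and theta(S-C...X) values.

Enzyme identity and wild-type status come from the manifest rather than from
structure metadata, because grouping orthologs and constructs of "the same
enzyme" is biological curation a coordinate parser cannot do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .detect import DetectionParams, TetrelContact, scan_structure
from .structure_io import StructureParseError, parse_structure

__all__ = [
    "ManifestEntry",
    "SurveyRecord",
    "SurveyReport",
    "read_manifest",
    "filter_resolution",
    "run_survey",
    "deduplicate",
    "emit_table",
    "round_half_away",
]

logger = logging.getLogger(__name__)

MAX_RESOLUTION = 2.50

# Printed display names for common solvent/ion donors.
_DEFAULT_DISPLAY = {"HOH": "H2O", "WAT": "H2O", "DOD": "D2O", "SO4": "Sulfate",
                    "GOL": "Glycerol", "EDO": "Ethylene glycol"}


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    entry_id: str
    enzyme_name: str
    is_wild_type: bool = True
    ligand_names: dict[str, str] = field(default_factory=dict)
    resolution: float | None = None  # header value used when absent
    expect_mismatch: bool = False  # remodeled entries exempt from validation

    def __post_init__(self):
        if not self.entry_id:
            raise ValueError("entry_id must be non-empty")


@dataclass(frozen=True)
class SurveyRecord:
    """One enzyme/donor pair: passing contacts aggregated across chains."""

    entry_id: str
    enzyme_name: str
    resolution: float
    ligand_display: str
    donor_residue_name: str
    donor_element: str
    donor_class: str
    per_chain_geometries: dict[str, tuple[float, float]]  # chain -> (r, theta)
    is_wild_type: bool = True

    @property
    def dedup_key(self) -> tuple[str, str]:
        # Ligand donors are distinguished by component code; water/ion donors
        # by class (all waters compete as one donor kind).
        descriptor = (
            self.donor_residue_name if self.donor_class == "ligand" else self.donor_class
        )
        return (self.enzyme_name, descriptor)


@dataclass
class SurveyReport:
    records: list[SurveyRecord]
    excluded: list[tuple[str, str]]  # (entry_id, reason)
    params_used: DetectionParams


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a tab-separated manifest (path, entry_id, enzyme, wild_type,
    ligand_map[, resolution]); ligand_map is ';'-separated CODE=Display pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"path", "entry_id", "enzyme"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    entries = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        entry_id = row["entry_id"].strip()
        if entry_id in seen:
            raise ValueError(f"duplicate entry_id in manifest: {entry_id}")
        seen.add(entry_id)
        ligand_map = {}
        for pair in row.get("ligand_map", "").split(";"):
            if "=" in pair:
                code, display = pair.split("=", 1)
                ligand_map[code.strip().upper()] = display.strip()
        res_text = str(row.get("resolution", "")).strip()
        entries.append(
            ManifestEntry(
                path=row["path"].strip(),
                entry_id=entry_id,
                enzyme_name=row["enzyme"].strip(),
                is_wild_type=str(row.get("wild_type", "true")).strip().lower()
                not in {"false", "0", "no"},
                ligand_names=ligand_map,
                resolution=float(res_text) if res_text else None,
                expect_mismatch=str(row.get("expect_mismatch", "")).strip().lower()
                in {"true", "1", "yes"},
            )
        )
    return entries


def filter_resolution(
    entries: list[tuple[ManifestEntry, float | None]],
    max_resolution: float = MAX_RESOLUTION,
) -> tuple[list[tuple[ManifestEntry, float]], list[tuple[str, str]]]:
    """Resolution screen, boundary inclusive (2.50 A is kept).

    Takes (entry, resolution) pairs; entries with unknown resolution are
    excluded with reason "no-resolution".
    """
    kept: list[tuple[ManifestEntry, float]] = []
    excluded: list[tuple[str, str]] = []
    for entry, resolution in entries:
        if resolution is None:
            logger.warning("excluding %s: no resolution available", entry.entry_id)
            excluded.append((entry.entry_id, "no-resolution"))
        elif resolution <= max_resolution:
            kept.append((entry, resolution))
        else:
            excluded.append((entry.entry_id, "resolution"))
    return kept, excluded


def _group_contacts(
    contacts: list[TetrelContact], entry: ManifestEntry, resolution: float
) -> list[SurveyRecord]:
    """Aggregate passing contacts into per-donor records across chains.

    Grouping key is the acceptor residue name; within a chain, the shortest
    passing contact represents that chain.
    """
    groups: dict[str, dict[str, TetrelContact]] = {}
    for contact in contacts:
        if not contact.passes:
            continue
        key = contact.acceptor_residue.name.strip().upper()
        chain = contact.site.chain_id
        best = groups.setdefault(key, {})
        if chain not in best or contact.geometry.r < best[chain].geometry.r:
            best[chain] = contact
    records = []
    for resname, per_chain in sorted(groups.items()):
        representative = next(iter(per_chain.values()))
        display = entry.ligand_names.get(resname) or _DEFAULT_DISPLAY.get(resname, resname)
        records.append(
            SurveyRecord(
                entry_id=entry.entry_id,
                enzyme_name=entry.enzyme_name,
                resolution=resolution,
                ligand_display=display,
                donor_residue_name=resname,
                donor_element=representative.acceptor.element.capitalize(),
                donor_class=representative.donor_class,
                per_chain_geometries={
                    chain: (c.geometry.r, c.geometry.theta)
                    for chain, c in sorted(per_chain.items())
                },
                is_wild_type=entry.is_wild_type,
            )
        )
    return records


def run_survey(
    entries: list[ManifestEntry],
    params: DetectionParams | None = None,
    max_resolution: float = MAX_RESOLUTION,
) -> SurveyReport:
    """Parse, screen and scan every manifest entry.

    Unparseable files and entries failing the resolution screen are recorded
    in ``excluded`` with a reason and the survey continues.  Entries with no
    passing contacts contribute no records (logged).  Entry count is
    conserved: every manifest entry appears either as >=0 records or in the
    exclusion list.
    """
    params = params or DetectionParams()
    parsed: list[tuple[ManifestEntry, float | None]] = []
    models = {}
    excluded: list[tuple[str, str]] = []
    for entry in entries:
        try:
            model = parse_structure(entry.path)
        except StructureParseError as exc:
            logger.warning("excluding %s: %s", entry.entry_id, exc)
            excluded.append((entry.entry_id, "parse-error"))
            continue
        resolution = entry.resolution if entry.resolution is not None else model.resolution
        parsed.append((entry, resolution))
        models[entry.entry_id] = model

    kept, res_excluded = filter_resolution(parsed, max_resolution)
    excluded.extend(res_excluded)

    records: list[SurveyRecord] = []
    for entry, resolution in kept:
        contacts = scan_structure(models[entry.entry_id], params)
        entry_records = _group_contacts(contacts, entry, resolution)
        if not entry_records:
            logger.info("%s: no passing contacts", entry.entry_id)
        records.extend(entry_records)
    return SurveyReport(records=records, excluded=excluded, params_used=params)


def deduplicate(records: list[SurveyRecord]) -> list[SurveyRecord]:
    """Redundancy rule: one record per (enzyme, donor descriptor).

    Within a key group, non-wild-type records are dropped when any wild-type
    record exists; the survivor is the record with the numerically smallest
    resolution, ties broken by lexicographically smallest entry_id.
    Idempotent.
    """
    groups: dict[tuple[str, str], list[SurveyRecord]] = {}
    for record in records:
        groups.setdefault(record.dedup_key, []).append(record)
    survivors = []
    for key in sorted(groups):
        group = groups[key]
        if any(r.is_wild_type for r in group):
            group = [r for r in group if r.is_wild_type]
        survivors.append(min(group, key=lambda r: (r.resolution, r.entry_id)))
    return survivors


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (so 2.715 -> 2.72, 166.5 -> 167)."""
    quant = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quant, rounding=ROUND_HALF_UP))


def _format_per_chain(per_chain: dict[str, tuple[float, float]], index: int, ndigits: int) -> str:
    values = []
    annotate = len(per_chain) > 1 or set(per_chain) != {"A"}
    for chain, geom in sorted(per_chain.items()):
        value = round_half_away(geom[index], ndigits)
        text = f"{value:.{ndigits}f}" if ndigits else f"{value:.0f}"
        values.append(f"{text} ({chain})" if annotate else text)
    return ", ".join(values)


PRINTED_COLUMNS = [
    "Enzyme",
    "PDB Code",
    "Resolution (A)",
    "Ligand",
    "Electron Donor (X)",
    "R(C...X) Length (A)",
    "theta(S-C...X) Angle (deg)",
]


def emit_table(
    report: SurveyReport,
    path: str | Path,
    full_precision_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the survey table as TSV (r to 2 decimals, theta to the degree,
    half rounded away from zero; multi-chain cells like "3.14 (A), 3.17 (B)").

    A second machine-readable TSV with full-precision per-chain rows is
    written when ``full_precision_path`` is given.
    """
    rows = []
    for record in report.records:
        rows.append(
            {
                "Enzyme": record.enzyme_name,
                "PDB Code": record.entry_id,
                "Resolution (A)": record.resolution,
                "Ligand": record.ligand_display,
                "Electron Donor (X)": record.donor_element,
                "R(C...X) Length (A)": _format_per_chain(record.per_chain_geometries, 0, 2),
                "theta(S-C...X) Angle (deg)": _format_per_chain(record.per_chain_geometries, 1, 0),
            }
        )
    df = pd.DataFrame(rows, columns=PRINTED_COLUMNS)
    df.to_csv(path, sep="\t", index=False)

    if full_precision_path is not None:
        full_rows = []
        for record in report.records:
            for chain, (r, theta) in sorted(record.per_chain_geometries.items()):
                full_rows.append(
                    {
                        "entry_id": record.entry_id,
                        "enzyme": record.enzyme_name,
                        "resolution": repr(record.resolution),
                        "ligand": record.ligand_display,
                        "donor_residue": record.donor_residue_name,
                        "donor_element": record.donor_element,
                        "donor_class": record.donor_class,
                        "chain": chain,
                        "r": repr(r),
                        "theta": repr(theta),
                    }
                )
        pd.DataFrame(
            full_rows,
            columns=["entry_id", "enzyme", "resolution", "ligand", "donor_residue",
                     "donor_element", "donor_class", "chain", "r", "theta"],
        ).to_csv(full_precision_path, sep="\t", index=False)
    return df
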