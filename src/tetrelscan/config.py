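"""Configuration file handling.

A flat YAML file overrides detection thresholds, acceptor elements, van der
Waals radii, donor residue/atom names and residue classification sets.  Any
key not present keeps its package default.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .detect import DetectionParams
from .geometry import VdwRadiusTable
from .structure_io import ClassificationConfig

__all__ = ["load_config", "detection_params_from_config", "classification_from_config"]

_PARAM_KEYS = {
    "theta_min",
    "theta_max",
    "acceptor_elements",
    "radius_overrides",
    "max_search_radius",
    "donor_residue_names",
    "sulfur_atom_name",
    "methyl_atom_name",
    "min_occupancy",
    "altloc_mode",
    "water_names",
    "ion_names",
}


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a flat key/value mapping")
    unknown = set(data) - _PARAM_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return data


def detection_params_from_config(config: dict) -> DetectionParams:
    kwargs = {}
    if "theta_min" in config:
        kwargs["theta_min"] = float(config["theta_min"])
    if "theta_max" in config:
        kwargs["theta_max"] = float(config["theta_max"])
    if "acceptor_elements" in config:
        kwargs["acceptor_elements"] = frozenset(
            str(e).upper() for e in config["acceptor_elements"]
        )
    kwargs["radius_table"] = VdwRadiusTable.default(config.get("radius_overrides"))
    if "max_search_radius" in config:
        kwargs["max_search_radius"] = float(config["max_search_radius"])
    if "donor_residue_names" in config:
        kwargs["donor_residue_names"] = frozenset(
            str(n).upper() for n in config["donor_residue_names"]
        )
    for key in ("sulfur_atom_name", "methyl_atom_name", "altloc_mode"):
        if key in config:
            kwargs[key] = str(config[key])
    if "min_occupancy" in config:
        kwargs["min_occupancy"] = float(config["min_occupancy"])
    return DetectionParams(**kwargs)


def classification_from_config(config: dict) -> ClassificationConfig:
    kwargs = {}
    if "water_names" in config:
        kwargs["water_names"] = frozenset(str(n).upper() for n in config["water_names"])
    if "ion_names" in config:
        kwargs["ion_names"] = frozenset(str(n).upper() for n in config["ion_names"])
    return ClassificationConfig(**kwargs)
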