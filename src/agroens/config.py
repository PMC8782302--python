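"""Structured (YAML) configuration files for cultivars, management and scenarios.

A config file can carry any of three top-level keys::

    genotype:
      crop: wheat            # wheat | maize; selects the pathway defaults
      tt_flowering: 1000
      tt_maturity: 1800
      # ... any GenotypeParams field
    management:
      planting_window: [150, 190]
      kc: 1.05
      fertilizer_splits: [[0, 0.5], [30, 0.5]]
      # ... any ManagementPlan field
    scenarios:
      - {dT: 0, dP: 0, co2: 360, n_fert: 100}
      - {dT: 2, dP: -0.25, co2: 540, n_fert: 160}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .climate import PerturbationSpec
from .crop import GenotypeParams, maize_genotype, wheat_genotype
from .management import ManagementPlan


def _read(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def load_genotype(path) -> GenotypeParams:
    section = _read(path).get("genotype", {})
    crop = section.pop("crop", "wheat")
    if crop not in ("wheat", "maize"):
        raise ValueError("genotype.crop must be 'wheat' or 'maize'")
    if "t_assim" in section:
        section["t_assim"] = tuple(section["t_assim"])
    base = wheat_genotype if crop == "wheat" else maize_genotype
    return base(**section)


def load_management(path) -> ManagementPlan:
    section = _read(path).get("management", {})
    if "planting_window" in section:
        section["planting_window"] = tuple(section["planting_window"])
    if "fertilizer_splits" in section:
        section["fertilizer_splits"] = tuple(
            (int(off), float(frac)) for off, frac in section["fertilizer_splits"])
    return ManagementPlan(**section)


def load_scenarios(path) -> list[PerturbationSpec]:
    entries = _read(path).get("scenarios", [])
    return [PerturbationSpec(**e) for e in entries]
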