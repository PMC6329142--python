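"""Reading and writing the package's flat-file formats.

Long-format phenotype records travel as CSV with the header
family_id, individual_id, zygosity, sex, visit, age_months, bmi,
genotype, exposure. Scenario configurations round-trip through YAML/JSON
mirroring the ScenarioConfig field names.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .cohort_sim import InteractionMatrix, ScenarioConfig, interaction_preset

__all__ = [
    "read_long_records",
    "write_long_records",
    "scenario_to_yaml",
    "scenario_from_dict",
    "read_scenario",
]

RECORD_COLUMNS = [
    "family_id", "individual_id", "zygosity", "sex", "visit",
    "age_months", "bmi", "genotype", "exposure",
]


def write_long_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, columns=RECORD_COLUMNS)


def read_long_records(path) -> pd.DataFrame:
    rec = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in rec.columns]
    if missing:
        raise ValueError(f"records file is missing columns {missing}")
    return rec


def scenario_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    inter = d.pop("interaction", None)
    if isinstance(inter, str):
        d["interaction"] = interaction_preset(inter)
    elif isinstance(inter, dict):
        name = inter.get("name", "custom")
        if "m" in inter:
            d["interaction"] = InteractionMatrix(inter["m"], name=name)
        else:
            d["interaction"] = interaction_preset(name)
    return ScenarioConfig(**d)


def scenario_to_yaml(scenario: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)


def read_scenario(path) -> ScenarioConfig:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return scenario_from_dict(d)
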