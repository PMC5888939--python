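"""Reading and writing cohorts and simulation configs.

Cohorts are plain CSV with header ``w1,w2,w3,w4,a,y`` (optionally
``sex`` and ``er``), UTF-8, '.' decimal separator.  Generating-process
configs are JSON or YAML mappings with keys ``covariate_laws``,
``alpha``, ``beta``, ``scenario_id`` and ``positivity_severity``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .datagen import DGPConfig, validate_cohort

REQUIRED_COLUMNS = ("w1", "w2", "w3", "w4", "a", "y")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks columns {missing}")
    validate_cohort(df)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def load_dgp_config(path) -> DGPConfig:
    """Load a DGP config from JSON or YAML (by extension)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    kwargs = {}
    for key in ("covariate_laws", "alpha", "beta", "scenario_id", "positivity_severity"):
        if key in data:
            kwargs[key] = data[key]
    return DGPConfig(**kwargs)


def dump_dgp_config(config: DGPConfig, path) -> None:
    path = Path(path)
    data = {
        "covariate_laws": config.covariate_laws,
        "alpha": config.alpha,
        "beta": config.beta,
        "scenario_id": config.scenario_id,
        "positivity_severity": config.positivity_severity,
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
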