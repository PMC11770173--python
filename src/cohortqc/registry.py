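"""Machine-readable metric catalogues, scoring standards and contaminant panels.

The package ships three editable registry files under ``cohortqc/data``:

* ``metrics_intra.tsv`` — the per-run metric catalogue (metric_id, workflow
  category, first-level scoring factor, unit, direction-of-goodness,
  description).  It is an extensible registry: metrics whose exact
  definition depends on vendor-specific supplementary material are simply
  additional rows users can append.
* ``metrics_inter.tsv`` — the 23 cohort-level metrics (SP1–SP3, LC1–LC2,
  MS1–MS18) with their bad directions.
* ``standards.yaml`` / ``panels.yaml`` — default scoring standards and
  contaminant panels; both overridable from files with the same layout.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "intra_registry",
    "inter_registry",
    "inter_metric_ids",
    "default_hierarchy",
    "load_standards_config",
    "load_panels_config",
]


def _data_path(name: str):
    return resources.files("cohortqc.data").joinpath(name)


@lru_cache(maxsize=None)
def intra_registry() -> pd.DataFrame:
    """Per-run metric catalogue indexed by metric_id."""
    with resources.as_file(_data_path("metrics_intra.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return df.set_index("metric_id")


@lru_cache(maxsize=None)
def inter_registry() -> pd.DataFrame:
    """Cohort-level metric catalogue (23 rows) indexed by metric_id."""
    with resources.as_file(_data_path("metrics_inter.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return df.set_index("metric_id")


def inter_metric_ids() -> list[str]:
    return list(inter_registry().index)


def default_hierarchy() -> dict[str, str]:
    """metric_id -> first-level scoring factor for per-run score cards.

    The factors are the five terms of the DIA scoring decomposition:
    identified_precursors, acquired_ms2, q_ms2, spectra_complexity and
    dup_rate.  Metrics with direction ``none`` are excluded (unscored).
    """
    reg = intra_registry()
    return {
        mid: row["factor"]
        for mid, row in reg.iterrows()
        if row["direction"] != "none"
    }


def load_standards_config(path: str | Path | None = None) -> dict:
    """Parse a scoring-standards YAML (instrument_class -> metric -> best/worst)."""
    if path is None:
        with resources.as_file(_data_path("standards.yaml")) as p:
            raw = yaml.safe_load(Path(p).read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("standards config must map instrument classes to metric tables")
    return raw


def load_panels_config(path: str | Path | None = None) -> dict[str, list[str]]:
    """Parse a contaminant-panels YAML (panel_id -> accession list)."""
    if path is None:
        with resources.as_file(_data_path("panels.yaml")) as p:
            raw = yaml.safe_load(Path(p).read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or not raw:
        raise ValueError("panels config must be a non-empty mapping")
    return {str(k): [str(m) for m in v] for k, v in raw.items()}
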