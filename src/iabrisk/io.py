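"""Cohort table schemas, readers/writers, configuration and manifests.

Two plain UTF-8 CSV tables define a cohort on disk: ``children.csv`` (one
row per child with static covariates and outcome ages) and ``visits.csv``
(one row per antibody-measurement visit). Ages are stored to 3 decimals
(about day resolution); an empty ``diagnosis_age_years`` means no diagnosis.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd
import yaml

from .preprocess import ANTIBODIES
from .synthetic import CohortConfig, GeneratedCohort, LevelParams, RiskBetas

CHILDREN_COLUMNS = [
    "child_id",
    "source",
    "sex",
    "family_history",
    "hla_group",
    "diagnosis_age_years",
    "last_followup_age_years",
]
VISITS_COLUMNS = ["child_id", "age_years"] + [f"{ab}_mULN" for ab in ANTIBODIES]


class SchemaError(ValueError):
    """A cohort table violates its schema or validation rules."""


def _check_columns(df: pd.DataFrame, expected, path) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{path}: schema mismatch (missing columns: {missing or 'none'}, "
            f"unexpected columns: {extra or 'none'})"
        )


def read_cohort(children_path, visits_path) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the two cohort tables.

    Hard errors (naming the offending rows) on duplicate child ids,
    duplicate or non-increasing visit ages within a child, negative levels,
    visits referencing unknown children, and diagnosis after last follow-up.
    """
    children_path, visits_path = Path(children_path), Path(visits_path)
    for p in (children_path, visits_path):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    children = pd.read_csv(children_path)
    visits = pd.read_csv(visits_path)
    _check_columns(children, CHILDREN_COLUMNS, children_path)
    _check_columns(visits, VISITS_COLUMNS, visits_path)

    dup = children["child_id"][children["child_id"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"{children_path}: duplicate child ids: {sorted(dup.unique())}")
    dup_v = visits[visits.duplicated(["child_id", "age_years"], keep=False)]
    if not dup_v.empty:
        raise SchemaError(
            f"{visits_path}: duplicate (child_id, age_years) rows at index "
            f"{dup_v.index.tolist()}"
        )
    unknown = set(visits["child_id"]) - set(children["child_id"])
    if unknown:
        raise SchemaError(f"{visits_path}: visits for unknown children: {sorted(unknown)}")
    lv = visits[[f"{ab}_mULN" for ab in ANTIBODIES]]
    neg = visits[(lv < 0).any(axis=1)]
    if not neg.empty:
        raise SchemaError(f"{visits_path}: negative levels at index {neg.index.tolist()}")
    if (visits["age_years"] < 0).any() or (children["last_followup_age_years"] < 0).any():
        raise SchemaError("ages must be non-negative")
    bad_diag = children[
        children["diagnosis_age_years"].notna()
        & (children["diagnosis_age_years"] > children["last_followup_age_years"])
    ]
    if not bad_diag.empty:
        raise SchemaError(
            f"{children_path}: diagnosis after last follow-up for "
            f"{bad_diag['child_id'].tolist()}"
        )
    visits = visits.sort_values(["child_id", "age_years"], kind="stable").reset_index(drop=True)
    children["family_history"] = children["family_history"].astype(int)
    return children, visits


def write_cohort(cohort: GeneratedCohort, outdir, write_truth: bool = True) -> None:
    """Write children.csv, visits.csv and (optionally) truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    children = cohort.children.copy()
    visits = cohort.visits.copy()
    for col in ("diagnosis_age_years", "last_followup_age_years"):
        children[col] = children[col].astype(float).round(3)
    visits["age_years"] = visits["age_years"].round(3)
    children.to_csv(outdir / "children.csv", index=False)
    visits.to_csv(outdir / "visits.csv", index=False, float_format="%.6g")
    if write_truth:
        truth = {k: v for k, v in cohort.truth.items() if k != "latent"}
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def load_cohort_config(path) -> CohortConfig:
    """Load a CohortConfig from a YAML/JSON file (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config keys: {sorted(unknown)}")
    if "level_params" in raw:
        raw["level_params"] = {
            ab: LevelParams(**params) for ab, params in raw["level_params"].items()
        }
    if "risk_betas" in raw:
        raw["risk_betas"] = RiskBetas(**raw["risk_betas"])
    for key in ("source_probs", "hla_probs", "serocon_age_dist", "serocon_age_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    config = CohortConfig(**raw)
    config.validate()
    return config


def write_manifest(outdir, **entries) -> None:
    """Write a run manifest (seeds, config, versions) for reproducibility."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"iabrisk_version": __version__}
    for k, v in entries.items():
        payload[k] = _jsonable(v)
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(v):
    if dataclasses.is_dataclass(v) and not isinstance(v, type):
        return _jsonable(dataclasses.asdict(v))
    if isinstance(v, dict):
        return {str(k): _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v
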