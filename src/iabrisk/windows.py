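"""Fixed-horizon outcome labelling and third-visit feature selection.

Prediction starts at 'time 0' — the seroconversion confirmatory visit, or
W years after it in the third-test design — and asks whether diabetes is
diagnosed within the following T years. Children diagnosed at or before
time 0, or lost to follow-up before time 0, are excluded; a diagnosis after
time 0 + T counts as "not diagnosed"; children last seen event-free at or
before time 0 + T are censored and handled downstream by IPCW.

Boundary conventions (config-free, fixed): the follow-up interval is the
half-open (time0, time0 + T], so a diagnosis exactly at time 0 excludes the
child and one exactly at time 0 + T is an event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocess import ANTIBODIES, DEFAULT_LOG_FLOOR, log_level

logger = logging.getLogger(__name__)

#: follow-up periods swept in the horizon analysis (years)
T_GRID: Tuple[int, ...] = tuple(range(1, 16))

#: intervals from confirmatory visit to third test (years); W = 0 is the
#: confirmatory visit itself
W_GRID: Tuple[float, ...] = (0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0)

EXCLUDED = "excluded"


@dataclass(frozen=True)
class PredictionWindow:
    """A (T, W) cell of the experimental grid."""

    T: float
    W: float = 0.0

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("follow-up period T must be >= 1 year")
        if self.W < 0:
            raise ValueError("test interval W must be >= 0")


def label_outcome(
    diagnosis_age: Optional[float],
    last_followup_age: float,
    time0: float,
    T: float,
) -> Tuple[str, Optional[float], Optional[bool]]:
    """Classify one child relative to a (time0, T) window.

    Returns ``(status, followup_years, event)`` where status is one of
    ``"excluded"``, ``"event"`` (diagnosed within T), ``"event_free"``
    (known diabetes-free through time0 + T, including late diagnoses) or
    ``"censored"`` (lost event-free at or before time0 + T). ``followup_years``
    is X = min(diagnosis, last contact) − time0.
    """
    has_diag = diagnosis_age is not None and not pd.isna(diagnosis_age)
    if has_diag and diagnosis_age <= time0:
        return EXCLUDED, None, None
    if not has_diag and last_followup_age < time0:
        return EXCLUDED, None, None
    end_age = float(diagnosis_age) if has_diag else float(last_followup_age)
    x = end_age - time0
    if x < 0:
        raise ValueError("follow-up ends before time0 despite later diagnosis")
    if has_diag:
        status = "event" if x <= T else "event_free"
    else:
        status = "event_free" if x > T else "censored"
    return status, x, has_diag


def select_third_visit(
    confirm_age: float, visit_ages: Sequence[float], W: float
) -> Optional[float]:
    """Age of the feature visit for a third test W years after confirmation.

    Time 0 is ``confirm_age + W`` and the levels used are those from the
    visit immediately prior to (or at) time 0; when no visit falls after the
    confirmatory visit the confirmatory visit itself is used. Returns None
    when no recorded visit qualifies.
    """
    if W <= 0:
        raise ValueError("W must be positive; W = 0 is the confirmatory visit")
    time0 = confirm_age + W
    ages = np.asarray(visit_ages, dtype=float)
    ok = ages[(ages >= confirm_age) & (ages <= time0)]
    if ok.size == 0:
        return None
    return float(ok.max())


def build_instances(
    sero: pd.DataFrame,
    visits: pd.DataFrame,
    window: PredictionWindow,
    log_floor: float = DEFAULT_LOG_FLOOR,
) -> pd.DataFrame:
    """One prediction instance per retained child for a (T, W) window.

    Each row carries the full covariate vocabulary (baseline covariates,
    positivity flags and log levels at the initial/confirmatory visits, and
    log levels from the time-0 feature visit), the follow-up time X, the
    event flag, and the horizon label (1 event within T, 0 known event-free,
    NaN censored). The IPCW weight column is filled later by the ipcw module.
    """
    if sero.empty:
        return pd.DataFrame(columns=_instance_columns())
    df = sero.reset_index(drop=True).copy()
    time0 = df["confirm_age"].to_numpy(dtype=float) + window.W

    if window.W > 0:
        # feature visit = latest recorded visit at or before time 0
        # (at least the confirmatory visit itself always qualifies)
        left = pd.DataFrame({"child_id": df["child_id"], "time0": time0}).sort_values(
            "time0", kind="stable"
        )
        right = visits.sort_values("age_years", kind="stable")[
            ["child_id", "age_years"] + [f"{ab}_mULN" for ab in ANTIBODIES]
        ]
        matched = pd.merge_asof(
            left,
            right,
            left_on="time0",
            right_on="age_years",
            by="child_id",
            direction="backward",
        ).set_index(left.index).sort_index()
        feature_age = matched["age_years"].to_numpy(dtype=float)
        third_mULN = {ab: matched[f"{ab}_mULN"].to_numpy(dtype=float) for ab in ANTIBODIES}
    else:
        feature_age = df["confirm_age"].to_numpy(dtype=float)
        third_mULN = {ab: df[f"{ab}_conf_mULN"].to_numpy(dtype=float) for ab in ANTIBODIES}

    diag = df["diagnosis_age_years"].to_numpy(dtype=float)
    last_fu = df["last_followup_age_years"].to_numpy(dtype=float)
    has_diag = ~np.isnan(diag)

    # diagnosed at/before time 0, or lost event-free before time 0: excluded
    excluded = (has_diag & (diag <= time0)) | (~has_diag & (last_fu < time0))
    x = np.where(has_diag, diag, last_fu) - time0
    label = np.where(
        has_diag & (x <= window.T),
        1.0,
        np.where(x > window.T, 0.0, np.nan),
    )

    keep = ~excluded
    out = pd.DataFrame(
        {
            "child_id": df["child_id"],
            "time0_age": time0,
            "feature_visit_age": feature_age,
            "followup_years": x,
            "event": has_diag,
            "label": label,
            "source": df["source"],
            "sex": df["sex"],
            "family_history": df["family_history"].astype(int),
            "hla_group": df["hla_group"],
            "age_initial": df["initial_age"].astype(float),
            "age_confirm": df["confirm_age"].astype(float),
        }
    )
    for ab in ANTIBODIES:
        out[f"pos_init_{ab}"] = df[f"pos_init_{ab}"].astype(int)
        out[f"pos_conf_{ab}"] = df[f"pos_conf_{ab}"].astype(int)
        out[f"lnlvl_init_{ab}"] = df[f"lnlvl_init_{ab}"].astype(float)
        out[f"lnlvl_conf_{ab}"] = df[f"lnlvl_conf_{ab}"].astype(float)
        out[f"lnlvl_t0_{ab}"] = log_level(third_mULN[ab], log_floor)
    out = out[keep].reset_index(drop=True)
    logger.info(
        "window T=%s W=%s: %d instances (%d events, %d censored, %d excluded)",
        window.T,
        window.W,
        len(out),
        int((out["label"] == 1.0).sum()),
        int(out["label"].isna().sum()),
        int(excluded.sum()),
    )
    return out[_instance_columns()]


def _instance_columns():
    cols = [
        "child_id",
        "time0_age",
        "feature_visit_age",
        "followup_years",
        "event",
        "label",
        "source",
        "sex",
        "family_history",
        "hla_group",
        "age_initial",
        "age_confirm",
    ]
    for ab in ANTIBODIES:
        cols += [f"pos_init_{ab}", f"pos_conf_{ab}"]
    for ab in ANTIBODIES:
        cols += [f"lnlvl_init_{ab}", f"lnlvl_conf_{ab}", f"lnlvl_t0_{ab}"]
    return cols


def grid_manifest(
    T_list: Iterable[float] = T_GRID, W_list: Iterable[float] = W_GRID
) -> list[PredictionWindow]:
    """Enumerate the full T×W experimental grid (15 × 9 = 135 windows)."""
    return [PredictionWindow(T=t, W=w) for w in W_list for t in T_list]
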