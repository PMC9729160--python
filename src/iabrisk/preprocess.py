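"""Level harmonisation, log transform and seroconversion detection.

Levels are expressed as multiples of the upper limit of normal (mULN);
``mULN > 1`` defines autoantibody positivity. Seroconversion for a given
autoantibody is the first appearance of positive results in two consecutive
recorded visits, regardless of the time between them; the first of the pair
is the *initial* visit and the second the *confirmatory* visit. A child's
seroconversion is anchored at the antibody whose confirmatory visit comes
earliest.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical antibody order (also the tie-break order)
ANTIBODIES = ("iaa", "gada", "ia2a")

#: mULN strictly above this value counts as positive
POSITIVITY_THRESHOLD = 1.0

#: default floor applied inside the log transform so that mULN = 0 stays finite
DEFAULT_LOG_FLOOR = 0.01


def to_mULN(raw_level: float, uln: float) -> float:
    """Convert a raw assay level to multiples of the upper limit of normal.

    Parameters
    ----------
    raw_level : float
        Raw assay readout (assay units), must be >= 0.
    uln : float
        Upper limit of normal for the assay, must be > 0.
    """
    if uln <= 0:
        raise ValueError(f"uln must be positive, got {uln!r}")
    if np.any(np.asarray(raw_level) < 0):
        raise ValueError("raw_level must be non-negative")
    return raw_level / uln


def log_level(mULN, floor: float = DEFAULT_LOG_FLOOR):
    """Natural log of an mULN level with a small positive floor.

    All levels enter the models on the log scale whether or not they exceed
    the positivity threshold; the floor keeps ln defined at zero.
    Accepts scalars or arrays.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    return np.log(np.maximum(np.asarray(mULN, dtype=float), floor))


def detect_seroconversion(levels: Sequence[float]) -> Optional[Tuple[int, int]]:
    """Find the first pair of consecutive positive visits for one antibody.

    ``levels`` is the age-ordered mULN series of a single antibody for one
    child. Returns ``(initial_index, confirmatory_index)`` for the first pair
    of adjacent visits both strictly above the positivity threshold, or
    ``None`` when no such pair exists. Missing values never count as positive.
    """
    arr = np.asarray(levels, dtype=float)
    pos = arr > POSITIVITY_THRESHOLD  # NaN compares False
    for i in range(len(arr) - 1):
        if pos[i] and pos[i + 1]:
            return i, i + 1
    return None


def build_seroconversion_record(child: pd.Series, visits: pd.DataFrame) -> Optional[dict]:
    """Assemble the child-level seroconversion record, or None if excluded.

    ``visits`` must be the child's visits sorted by age. A child is retained
    only when (i) some antibody shows two consecutive positive visits, (ii)
    the confirmatory visit precedes the diagnosis (when one exists), and
    (iii) all three antibody levels are recorded at both the initial and the
    confirmatory visit. Among antibodies with a confirmed pair, the one with
    the earliest confirmatory visit anchors the child-level record; ties go
    to the earliest initial visit, then to the fixed order IAA, GADA, IA-2A.
    """
    if visits.empty:
        return None
    ages = visits["age_years"].to_numpy(dtype=float)
    diagnosis = child.get("diagnosis_age_years")
    diagnosis = None if diagnosis is None or pd.isna(diagnosis) else float(diagnosis)

    candidates = []  # (confirm_age, initial_age, antibody_rank, ab, i, j)
    for rank, ab in enumerate(ANTIBODIES):
        hit = detect_seroconversion(visits[f"{ab}_mULN"].to_numpy(dtype=float))
        if hit is None:
            continue
        i, j = hit
        candidates.append((ages[j], ages[i], rank, ab, i, j))
    if not candidates:
        return None
    candidates.sort()
    confirm_age, initial_age, _, ab, i, j = candidates[0]

    # measurements must exist before diagnosis: a child diagnosed at or
    # before the confirmatory visit never enters the study cohort
    if diagnosis is not None and diagnosis <= confirm_age:
        return None

    rec = {
        "child_id": child["child_id"],
        "antibody": ab,
        "initial_age": float(initial_age),
        "confirm_age": float(confirm_age),
    }
    for other in ANTIBODIES:
        lv = visits[f"{other}_mULN"].to_numpy(dtype=float)
        rec[f"{other}_init_mULN"] = float(lv[i])
        rec[f"{other}_conf_mULN"] = float(lv[j])
    # completeness rule: all three levels at both visits
    if any(
        np.isnan(rec[f"{a}_{v}_mULN"]) for a in ANTIBODIES for v in ("init", "conf")
    ):
        return None
    for a in ANTIBODIES:
        rec[f"pos_init_{a}"] = int(rec[f"{a}_init_mULN"] > POSITIVITY_THRESHOLD)
        rec[f"pos_conf_{a}"] = int(rec[f"{a}_conf_mULN"] > POSITIVITY_THRESHOLD)
    return rec


def seroconversion_table(
    children: pd.DataFrame,
    visits: pd.DataFrame,
    log_floor: float = DEFAULT_LOG_FLOOR,
) -> pd.DataFrame:
    """Build the per-child seroconversion table for the retained study cohort.

    One row per child with a confirmed seroconversion and complete levels at
    both defining visits, carrying the static covariates, the initial and
    confirmatory ages, the three antibodies' mULN levels and positivity flags
    at both visits, and the log-transformed levels used by the models.
    Vectorised equivalent of applying :func:`build_seroconversion_record` to
    every child.
    """
    empty = pd.DataFrame(columns=_SEROCONVERSION_COLUMNS)
    if children.empty or visits.empty:
        return empty
    v = visits.sort_values(["child_id", "age_years"], kind="stable").reset_index(drop=True)
    cid = v["child_id"].to_numpy()
    ages = v["age_years"].to_numpy(dtype=float)
    same_next = np.zeros(len(v), dtype=bool)
    same_next[:-1] = cid[1:] == cid[:-1]

    # first consecutive positive pair per (child, antibody)
    cand = []
    for rank, ab in enumerate(ANTIBODIES):
        lv = v[f"{ab}_mULN"].to_numpy(dtype=float)
        pos = lv > POSITIVITY_THRESHOLD
        pair = pos & np.concatenate([pos[1:], [False]]) & same_next
        idx = np.flatnonzero(pair)
        if idx.size == 0:
            continue
        first = pd.Series(idx).groupby(pd.Series(cid[idx])).min()
        cand.append(
            pd.DataFrame(
                {
                    "child_id": first.index,
                    "i": first.to_numpy(),
                    "j": first.to_numpy() + 1,
                    "initial_age": ages[first.to_numpy()],
                    "confirm_age": ages[first.to_numpy() + 1],
                    "rank": rank,
                    "antibody": ab,
                }
            )
        )
    if not cand:
        return empty
    # earliest confirmatory visit wins; ties by initial age, then IAA<GADA<IA-2A
    best = (
        pd.concat(cand)
        .sort_values(["child_id", "confirm_age", "initial_age", "rank"], kind="stable")
        .drop_duplicates("child_id", keep="first")
    )
    sero = best.merge(children, on="child_id", how="inner")
    for ab in ANTIBODIES:
        lv = v[f"{ab}_mULN"].to_numpy(dtype=float)
        sero[f"{ab}_init_mULN"] = lv[sero["i"].to_numpy()]
        sero[f"{ab}_conf_mULN"] = lv[sero["j"].to_numpy()]

    # study-cohort selection: diagnosis after the confirmatory visit and
    # complete levels for all three antibodies at both defining visits
    diag = sero["diagnosis_age_years"]
    keep = diag.isna() | (diag > sero["confirm_age"])
    for ab in ANTIBODIES:
        keep &= sero[f"{ab}_init_mULN"].notna() & sero[f"{ab}_conf_mULN"].notna()
    sero = sero[keep].reset_index(drop=True)
    logger.info("seroconversion: retained %d of %d children", len(sero), len(children))
    if sero.empty:
        return empty
    for ab in ANTIBODIES:
        sero[f"pos_init_{ab}"] = (sero[f"{ab}_init_mULN"] > POSITIVITY_THRESHOLD).astype(int)
        sero[f"pos_conf_{ab}"] = (sero[f"{ab}_conf_mULN"] > POSITIVITY_THRESHOLD).astype(int)
        sero[f"lnlvl_init_{ab}"] = log_level(sero[f"{ab}_init_mULN"], log_floor)
        sero[f"lnlvl_conf_{ab}"] = log_level(sero[f"{ab}_conf_mULN"], log_floor)
    return sero[_SEROCONVERSION_COLUMNS]


_SEROCONVERSION_COLUMNS = (
    ["child_id", "antibody", "initial_age", "confirm_age"]
    + [f"{ab}_{v}_mULN" for ab in ANTIBODIES for v in ("init", "conf")]
    + [f"pos_{v}_{ab}" for v in ("init", "conf") for ab in ANTIBODIES]
    + [f"lnlvl_{v}_{ab}" for v in ("init", "conf") for ab in ANTIBODIES]
    + [
        "source",
        "sex",
        "family_history",
        "hla_group",
        "diagnosis_age_years",
        "last_followup_age_years",
    ]
)
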