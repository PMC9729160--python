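"""The three experiments: covariate battery, horizon sweep and T×W grid.

Every experiment shares one engine: 10-fold cross-validated IPCW logistic
regression, scored by the IPCW concordance index on the held-out fold and
averaged over folds (fold-level averaging, not pooled predictions). The
censoring model is fitted on the training folds by default and applied to
the test fold. Percentile bootstrap CIs resample children, never visits,
either re-running the whole cross-validation per resample (``refit``) or
resampling the ten fold-level C indices (``fold``, cheaper).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import glm, ipcw
from .glm import COVARIATE_SETS, THIRD_VISIT_SET, CovariateSet
from .windows import T_GRID, W_GRID, PredictionWindow, build_instances

logger = logging.getLogger(__name__)

DEFAULT_N_FOLDS = 10
DEFAULT_BOOTSTRAP_B = 1000


@dataclass
class EvalResult:
    covariate_set: str
    T: float
    W: float
    fold_c: List[float]
    mean_c: float
    ci: Optional[Tuple[float, float]]
    ci_method: Optional[str]
    n_instances: int
    n_events: int
    warnings: List[str] = field(default_factory=list)


def assign_folds(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random child-level partition into ``n_folds`` near-equal folds."""
    fold = np.arange(n) % n_folds
    rng.shuffle(fold)
    return fold


def cross_validate(
    instances: pd.DataFrame,
    covariate_set: CovariateSet,
    T: float,
    seed: int,
    n_folds: int = DEFAULT_N_FOLDS,
    w_max: float = ipcw.DEFAULT_WEIGHT_CAP,
    censor_fit: str = "train",
    W: float = 0.0,
) -> EvalResult:
    """10-fold cross-validated mean IPCW C index for one covariate set.

    Folds partition children at random (seeded). Per fold the censoring
    model and the weighted logistic model are fitted on the nine training
    folds; held-out children are scored by predicted event probability and
    concordance is computed with truncation at τ = T. Folds without both
    outcome classes, or without comparable pairs, are skipped and recorded.
    """
    n = len(instances)
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} instances, got {n}")
    design, names = glm.encode_design(instances, covariate_set)
    y = instances["label"].to_numpy(dtype=float)
    x_time = instances["followup_years"].to_numpy(dtype=float)
    delta = instances["event"].to_numpy(dtype=bool)

    rng = np.random.default_rng(seed)
    fold_id = assign_folds(n, n_folds, rng)
    if censor_fit == "full":
        G_full = ipcw.fit_censoring_km(x_time, delta)

    fold_c: List[float] = []
    warn: List[str] = []
    for k in range(n_folds):
        test = fold_id == k
        train = ~test
        G = (
            G_full
            if censor_fit == "full"
            else ipcw.fit_censoring_km(x_time[train], delta[train])
        )
        w_train = ipcw.ipcw_weights(x_time[train], y[train], G, tau=T, w_max=w_max)
        y_train = y[train]
        fit_rows = w_train > 0
        classes = np.unique(y_train[fit_rows])
        if len(classes) < 2:
            warn.append(f"fold {k}: single outcome class, skipped")
            continue
        fit = glm.fit_weighted_logistic(
            design[train][fit_rows], y_train[fit_rows], w_train[fit_rows], terms=names
        )
        warn.extend(f"fold {k}: {m}" for m in fit.messages)
        scores = fit.predict(design[test])
        try:
            c = ipcw.ipcw_c_index(scores, x_time[test], delta[test], G, tau=T, w_max=w_max)
        except ipcw.ConcordanceUndefinedError:
            warn.append(f"fold {k}: concordance undefined, skipped")
            continue
        fold_c.append(c)
    if not fold_c:
        raise ValueError("no fold produced a defined concordance index")
    return EvalResult(
        covariate_set=covariate_set.id,
        T=T,
        W=W,
        fold_c=fold_c,
        mean_c=float(np.mean(fold_c)),
        ci=None,
        ci_method=None,
        n_instances=n,
        n_events=int(np.nansum(y == 1.0)),
        warnings=warn,
    )


def bootstrap_ci(
    statistic: Callable[[pd.DataFrame], float],
    instances: pd.DataFrame,
    B: int,
    seed: int,
) -> Tuple[float, float]:
    """Percentile 95% bootstrap CI resampling children with replacement."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(instances)
    stats = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        stats[b] = statistic(instances.iloc[idx].reset_index(drop=True))
    return float(np.percentile(stats, 2.5)), float(np.percentile(stats, 97.5))


def _fold_level_ci(fold_c: Sequence[float], B: int, rng: np.random.Generator):
    fc = np.asarray(fold_c, dtype=float)
    means = fc[rng.integers(0, len(fc), size=(B, len(fc)))].mean(axis=1)
    return float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5))


def evaluate_window(
    instances: pd.DataFrame,
    covariate_set: CovariateSet,
    window: PredictionWindow,
    seed: int,
    bootstrap_B: int = 0,
    bootstrap_method: str = "fold",
    **cv_kwargs,
) -> EvalResult:
    """Cross-validate one (covariate set, T, W) cell, optionally with a CI."""
    res = cross_validate(
        instances, covariate_set, T=window.T, seed=seed, W=window.W, **cv_kwargs
    )
    if bootstrap_B > 0:
        rng = np.random.default_rng([seed, 977])
        if bootstrap_method == "fold":
            res.ci = _fold_level_ci(res.fold_c, bootstrap_B, rng)
        elif bootstrap_method == "refit":
            def stat(df: pd.DataFrame) -> float:
                sub_seed = int(rng.integers(0, 2**31 - 1))
                return cross_validate(
                    df, covariate_set, T=window.T, seed=sub_seed, W=window.W, **cv_kwargs
                ).mean_c

            res.ci = bootstrap_ci(stat, instances, bootstrap_B, int(rng.integers(0, 2**31 - 1)))
        else:
            raise ValueError(f"unknown bootstrap method {bootstrap_method!r}")
        res.ci_method = bootstrap_method
        if not (res.ci[0] <= res.mean_c <= res.ci[1]):
            res.warnings.append("mean C outside bootstrap CI")
            logger.warning("mean C %.3f outside bootstrap CI %s", res.mean_c, res.ci)
    return res


def covariate_battery(
    sero: pd.DataFrame,
    visits: pd.DataFrame,
    T: float = 10.0,
    seed: int = 0,
    bootstrap_B: int = 0,
    bootstrap_method: str = "fold",
    **cv_kwargs,
) -> List[EvalResult]:
    """The nine-covariate-set comparison at seroconversion (T = 10, W = 0)."""
    window = PredictionWindow(T=T, W=0.0)
    instances = build_instances(sero, visits, window)
    results = []
    for set_id in sorted(COVARIATE_SETS):
        cs = COVARIATE_SETS[set_id]
        results.append(
            evaluate_window(
                instances, cs, window, seed=seed, bootstrap_B=bootstrap_B,
                bootstrap_method=bootstrap_method, **cv_kwargs,
            )
        )
    return results


def t_sweep(
    sero: pd.DataFrame,
    visits: pd.DataFrame,
    T_list: Iterable[float] = T_GRID,
    covariate_sets: Sequence[CovariateSet] = (COVARIATE_SETS[6], COVARIATE_SETS[9]),
    seed: int = 0,
    bootstrap_B: int = 0,
    **cv_kwargs,
) -> List[EvalResult]:
    """Follow-up-period sweep: relabel the cohort per T and re-evaluate.

    By default compares the levels-at-confirmatory-visit model with the
    full baseline-plus-levels-from-both-visits model, as in the published
    horizon analysis.
    """
    results = []
    for T in T_list:
        window = PredictionWindow(T=T, W=0.0)
        instances = build_instances(sero, visits, window)
        for cs in covariate_sets:
            results.append(
                evaluate_window(
                    instances, cs, window, seed=seed, bootstrap_B=bootstrap_B, **cv_kwargs
                )
            )
    return results


def tw_grid(
    sero: pd.DataFrame,
    visits: pd.DataFrame,
    T_list: Iterable[float] = T_GRID,
    W_list: Iterable[float] = W_GRID,
    seed: int = 0,
    **cv_kwargs,
) -> List[EvalResult]:
    """Third-test grid: 15 horizons × 9 test intervals = 135 cohorts.

    Every cell's model uses only the three log antibody levels from the
    visit immediately prior to time 0 (confirmatory visit + W).
    """
    results = []
    for W in W_list:
        for T in T_list:
            window = PredictionWindow(T=T, W=W)
            instances = build_instances(sero, visits, window)
            results.append(
                evaluate_window(instances, THIRD_VISIT_SET, window, seed=seed, **cv_kwargs)
            )
    return results


def results_frame(results: Sequence[EvalResult], experiment: str = "") -> pd.DataFrame:
    """Tidy results table: one row per evaluated cell."""
    rows = []
    for r in results:
        rows.append(
            {
                "experiment": experiment,
                "covariate_set": r.covariate_set,
                "T": r.T,
                "W": r.W,
                "mean_C": r.mean_c,
                "CI_lo": r.ci[0] if r.ci else np.nan,
                "CI_hi": r.ci[1] if r.ci else np.nan,
                "n": r.n_instances,
                "events": r.n_events,
                "n_folds_used": len(r.fold_c),
            }
        )
    return pd.DataFrame(rows)


def grid_matrix(results: Sequence[EvalResult]) -> pd.DataFrame:
    """Pivot a T×W grid of results into a W-by-T matrix of mean C indices."""
    df = results_frame(results)
    return df.pivot(index="W", columns="T", values="mean_C").sort_index()
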