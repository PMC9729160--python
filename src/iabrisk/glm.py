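"""Weighted logistic regression with Wald inference and fold-change ORs.

The nine covariate sets of the seroconversion analysis are enumerated here:
baseline covariates (data source, sex, diabetes family history, HLA risk
group, ages at the initial and confirmatory visits), positivity indicators
and log levels at either or both seroconversion visits, and their unions
with the baseline set. A tenth set — the three log levels at the time-0
feature visit — serves the T×W third-test grid.

Fits maximise the IPCW-weighted Bernoulli log-likelihood by iteratively
reweighted least squares with step-halving, so the likelihood never
decreases across iterations. Because IPCW weights are estimated quantities
rather than frequency weights, Wald inference uses the robust (sandwich)
variance A⁻¹BA⁻¹ by default, with the model-based inverse-information
variance kept alongside (``se_info``); no regularisation is applied and
complete separation is flagged, not penalised away.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .preprocess import ANTIBODIES

logger = logging.getLogger(__name__)

SOURCES = ("BABYDIAB", "DAISY", "DEW-IT", "DiPiS", "DIPP")
SOURCE_REFERENCE = "DIPP"
HLA_LEVELS = ("A", "B", "C", "D", "missing")
HLA_REFERENCE = "B"

BASELINE_FEATURES = (
    "source",
    "sex",
    "family_history",
    "hla_group",
    "age_initial",
    "age_confirm",
)
POS_INITIAL = tuple(f"pos_init_{ab}" for ab in ANTIBODIES)
POS_CONFIRM = tuple(f"pos_conf_{ab}" for ab in ANTIBODIES)
LEVELS_INITIAL = tuple(f"lnlvl_init_{ab}" for ab in ANTIBODIES)
LEVELS_CONFIRM = tuple(f"lnlvl_conf_{ab}" for ab in ANTIBODIES)
LEVELS_THIRD = tuple(f"lnlvl_t0_{ab}" for ab in ANTIBODIES)


@dataclass(frozen=True)
class CovariateSet:
    id: str
    name: str
    features: Tuple[str, ...]


#: the nine covariate sets compared at seroconversion (T = 10, W = 0)
COVARIATE_SETS: Dict[int, CovariateSet] = {
    1: CovariateSet("1", "baseline", BASELINE_FEATURES),
    2: CovariateSet("2", "positivity (initial)", POS_INITIAL),
    3: CovariateSet("3", "positivity (confirmatory)", POS_CONFIRM),
    4: CovariateSet("4", "positivity (both)", POS_INITIAL + POS_CONFIRM),
    5: CovariateSet("5", "levels (initial)", LEVELS_INITIAL),
    6: CovariateSet("6", "levels (confirmatory)", LEVELS_CONFIRM),
    7: CovariateSet("7", "levels (both)", LEVELS_INITIAL + LEVELS_CONFIRM),
    8: CovariateSet(
        "8", "baseline + positivity (both)", BASELINE_FEATURES + POS_INITIAL + POS_CONFIRM
    ),
    9: CovariateSet(
        "9", "baseline + levels (both)", BASELINE_FEATURES + LEVELS_INITIAL + LEVELS_CONFIRM
    ),
}

#: three log levels from the time-0 feature visit (T×W grid models)
THIRD_VISIT_SET = CovariateSet("third", "levels (third visit)", LEVELS_THIRD)


def encode_design(
    instances: pd.DataFrame, covariate_set: CovariateSet
) -> Tuple[np.ndarray, List[str]]:
    """Expand a covariate set into a design matrix with an intercept.

    Treatment coding with fixed references: data source vs DIPP, HLA risk
    group vs B (with an explicit 'missing' level), sex as a male indicator,
    family history as 0/1; ages and log levels enter untouched. Columns that
    are constant in ``instances`` are dropped with a warning. Category values
    outside the known level lists raise, naming the offender.
    """
    if instances.empty:
        raise ValueError("cannot encode an empty instance table")
    cols: List[np.ndarray] = [np.ones(len(instances))]
    names: List[str] = ["intercept"]
    for feat in covariate_set.features:
        if feat == "source":
            _check_levels(instances["source"], SOURCES, "source")
            for lv in SOURCES:
                if lv == SOURCE_REFERENCE:
                    continue
                cols.append((instances["source"] == lv).to_numpy(float))
                names.append(f"source_{lv}")
        elif feat == "hla_group":
            _check_levels(instances["hla_group"], HLA_LEVELS, "hla_group")
            for lv in HLA_LEVELS:
                if lv == HLA_REFERENCE:
                    continue
                cols.append((instances["hla_group"] == lv).to_numpy(float))
                names.append(f"hla_{lv}")
        elif feat == "sex":
            _check_levels(instances["sex"], ("M", "F"), "sex")
            cols.append((instances["sex"] == "M").to_numpy(float))
            names.append("sex_male")
        else:
            cols.append(instances[feat].to_numpy(float))
            names.append(feat)
    X = np.column_stack(cols)
    keep = [0] + [
        j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0
    ]
    dropped = [names[j] for j in range(1, X.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"dropping constant design column(s): {', '.join(dropped)}")
    return X[:, keep], [names[j] for j in keep]


def _check_levels(series: pd.Series, allowed: Sequence[str], what: str) -> None:
    bad = set(series.dropna().unique()) - set(allowed)
    if bad:
        raise ValueError(f"unknown {what} level(s): {sorted(bad)}")


@dataclass
class ModelFit:
    """A fitted weighted logistic regression with Wald inference."""

    terms: List[str]
    beta: np.ndarray
    se: np.ndarray  # robust (sandwich) standard errors, used for Wald tests
    cov: np.ndarray  # robust covariance
    se_info: np.ndarray  # model-based (inverse weighted information) SEs
    cov_info: np.ndarray
    loglik: float
    n_obs: int
    weight_sum: float
    n_iter: int
    converged: bool
    messages: List[str] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted event probability for design rows ``X``."""
        return expit(np.asarray(X, dtype=float) @ self.beta)

    def odds_ratios(self) -> pd.DataFrame:
        """Forest-plot-style table: OR with 95% CI and two-sided Wald p."""
        z = np.divide(self.beta, self.se, out=np.zeros_like(self.beta), where=self.se > 0)
        p = 2 * norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.beta,
                "se": self.se,
                "OR": np.exp(self.beta),
                "OR_lo": np.exp(self.beta - 1.96 * self.se),
                "OR_hi": np.exp(self.beta + 1.96 * self.se),
                "z": z,
                "p": p,
            }
        )


def _weighted_loglik(beta, X, y, w):
    eta = X @ beta
    # log(1 + e^eta) computed stably
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def fit_weighted_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    terms: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ModelFit:
    """Maximise the weighted Bernoulli log-likelihood by IRLS.

    Zero-weight rows are removed up front (they contribute nothing to the
    likelihood). Convergence is declared when max |Δβ| < ``tol``; the
    likelihood is asserted nondecreasing at every accepted step (step-halving
    enforces ascent). Complete separation is flagged in ``messages``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    keep = w > 0
    X, y, w = X[keep], y[keep], w[keep]
    if X.shape[0] == 0:
        raise ValueError("no positively weighted observations")
    if w[y == 1].sum() == 0 or w[y == 0].sum() == 0:
        raise ValueError("need positive weight in both outcome classes")

    p_dim = X.shape[1]
    beta = np.zeros(p_dim)
    ll = _weighted_loglik(beta, X, y, w)
    messages: List[str] = []
    converged = False
    info = np.eye(p_dim)
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        wk = w * mu * (1 - mu)
        score = X.T @ (w * (y - mu))
        info = X.T @ (X * np.maximum(wk, 1e-12)[:, None])
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(info, score, rcond=None)[0]
            messages.append("singular information matrix; least-squares step used")
        # step-halving guarantees likelihood ascent
        step = 1.0
        for _ in range(50):
            ll_new = _weighted_loglik(beta + step * delta, X, y, w)
            if ll_new >= ll - 1e-10:
                break
            step /= 2.0
        beta = beta + step * delta
        assert ll_new >= ll - 1e-10, "weighted log-likelihood decreased"
        ll = ll_new
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break

    eta = X @ beta
    if np.max(np.abs(eta)) > 30:
        messages.append("possible complete separation: |linear predictor| > 30")
        logger.warning("possible complete separation detected")
    if not converged:
        messages.append(f"IRLS did not converge in {max_iter} iterations")
        logger.warning("IRLS did not converge in %d iterations", max_iter)

    mu = expit(eta)
    wk = w * mu * (1 - mu)
    info = X.T @ (X * wk[:, None])
    try:
        cov_info = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_info = np.linalg.pinv(info)
        messages.append("singular information matrix; pseudo-inverse covariance")
    cov_info = (cov_info + cov_info.T) / 2.0
    # sandwich: score contributions s_i = w_i (y_i - mu_i) x_i
    s = X * (w * (y - mu))[:, None]
    cov = cov_info @ (s.T @ s) @ cov_info
    cov = (cov + cov.T) / 2.0
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    se_info = np.sqrt(np.maximum(np.diag(cov_info), 0.0))
    if terms is None:
        terms = [f"x{j}" for j in range(p_dim)]
    return ModelFit(
        terms=list(terms),
        beta=beta,
        se=se,
        cov=cov,
        se_info=se_info,
        cov_info=cov_info,
        loglik=ll,
        n_obs=int(X.shape[0]),
        weight_sum=float(w.sum()),
        n_iter=it,
        converged=converged,
        messages=messages,
    )


def wald_test(fit: ModelFit, term: str) -> Tuple[float, float]:
    """Two-sided Wald test (z, p) for one term of a fit."""
    try:
        j = fit.terms.index(term)
    except ValueError:
        raise KeyError(f"term {term!r} not in fit") from None
    if fit.se[j] == 0:
        raise ZeroDivisionError(f"standard error of {term!r} is zero; z undefined")
    z = float(fit.beta[j] / fit.se[j])
    return z, float(2 * norm.sf(abs(z)))


def fold_change_or(beta_per_ln_unit: float, n: float) -> float:
    """Odds ratio for an n-fold increase in an antibody level.

    An n-fold increase in the level adds ln(n) to the log-level covariate, so
    the OR is exp(β · ln n) for a per-log-unit coefficient β.
    """
    if n <= 0:
        raise ValueError("fold change n must be positive")
    return float(np.exp(beta_per_ln_unit * np.log(n)))
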