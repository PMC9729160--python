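"""Inverse probability of censoring weighting (IPCW).

The censoring distribution G(t) = P(censoring time > t) is estimated by the
Kaplan–Meier product-limit estimator with the roles of event and censoring
swapped: dropout/end-of-follow-up is the "event" and a diabetes diagnosis
censors the censoring process. Weights for the horizon-restricted binary
outcome and the Uno-type concordance index both divide by Ĝ evaluated just
before the subject's own event time (the left limit), the convention that
avoids a subject's own jump.

At tied times, diagnoses are processed before censorings by default, i.e.
subjects diagnosed at t remain in the risk set of a censoring at t.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: default cap on any single IPCW weight (bounds variance when Ĝ is tiny)
DEFAULT_WEIGHT_CAP = 20.0


class ConcordanceUndefinedError(ValueError):
    """Raised when the IPCW C index has no comparable pairs."""


@dataclass(frozen=True)
class CensoringModel:
    """Right-continuous step-function estimate Ĝ(t) of censoring survival."""

    jump_times: np.ndarray
    survival_values: np.ndarray
    n_fitted: int = 0

    def __post_init__(self):
        t = np.asarray(self.jump_times, dtype=float)
        s = np.asarray(self.survival_values, dtype=float)
        if t.shape != s.shape:
            raise ValueError("jump_times and survival_values must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("jump_times must be strictly increasing")
        if np.any(np.diff(s) > 1e-12) or np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValueError("survival_values must be nonincreasing within [0, 1]")
        object.__setattr__(self, "jump_times", t)
        object.__setattr__(self, "survival_values", s)

    def evaluate(self, t):
        """Ĝ(t), right-continuous: the value at or just after t."""
        idx = np.searchsorted(self.jump_times, np.asarray(t, dtype=float), side="right")
        vals = np.concatenate(([1.0], self.survival_values))
        return vals[idx]

    def evaluate_left(self, t):
        """Ĝ(t⁻): the value just before t."""
        idx = np.searchsorted(self.jump_times, np.asarray(t, dtype=float), side="left")
        vals = np.concatenate(([1.0], self.survival_values))
        return vals[idx]

    def to_json(self) -> str:
        return json.dumps(
            {
                "jump_times": self.jump_times.tolist(),
                "survival_values": self.survival_values.tolist(),
                "n_fitted": self.n_fitted,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "CensoringModel":
        d = json.loads(payload)
        return cls(
            np.asarray(d["jump_times"], dtype=float),
            np.asarray(d["survival_values"], dtype=float),
            int(d["n_fitted"]),
        )


def fit_censoring_km(
    followup_years,
    event_observed,
    ties: str = "event_first",
) -> CensoringModel:
    """Kaplan–Meier estimate of the censoring survival function Ĝ.

    Parameters
    ----------
    followup_years : array-like
        X = time to diagnosis or last contact, per subject.
    event_observed : array-like of bool
        True when X is a diagnosis; False when X is a censoring time.
    ties : {"event_first", "censor_first"}
        Whether subjects diagnosed exactly at a censoring time still belong
        to that censoring's risk set (default) or have already left it.
    """
    x = np.asarray(followup_years, dtype=float)
    delta = np.asarray(event_observed, dtype=bool)
    if x.size == 0:
        raise ValueError("cannot fit a censoring model on an empty sample")
    if np.any(x < 0):
        raise ValueError("follow-up times must be non-negative")
    if ties not in ("event_first", "censor_first"):
        raise ValueError(f"unknown tie rule {ties!r}")

    cens_times = np.unique(x[~delta])
    surv = np.empty(cens_times.size)
    g = 1.0
    for k, tk in enumerate(cens_times):
        d_k = np.count_nonzero((x == tk) & ~delta)
        if ties == "event_first":
            at_risk = np.count_nonzero(x >= tk)
        else:
            at_risk = np.count_nonzero(x > tk) + d_k
        g *= 1.0 - d_k / at_risk
        surv[k] = g
    return CensoringModel(cens_times, surv, n_fitted=int(x.size))


def _inverse(g, w_max: float) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    out = np.full(g.shape, w_max)
    ok = g > 0
    out[ok] = np.minimum(1.0 / g[ok], w_max)
    n_capped = int(np.count_nonzero(out >= w_max))
    if n_capped:
        logger.warning("IPCW: %d weight(s) capped at %.1f", n_capped, w_max)
    return out


def ipcw_weights(
    followup_years,
    label,
    G: CensoringModel,
    tau: float,
    w_max: float = DEFAULT_WEIGHT_CAP,
) -> np.ndarray:
    """Per-instance IPCW weights for the T-horizon binary outcome.

    Events within the horizon get 1/Ĝ(X⁻); subjects known event-free through
    the horizon get 1/Ĝ(τ); censored subjects (label NaN) get weight 0 and
    drop out of the weighted likelihood. Weights are capped at ``w_max``.
    """
    x = np.asarray(followup_years, dtype=float)
    y = np.asarray(label, dtype=float)
    w = np.zeros(x.shape)
    ev = y == 1.0
    w[ev] = _inverse(G.evaluate_left(x[ev]), w_max)
    nf = y == 0.0
    if np.any(nf):
        w[nf] = _inverse(G.evaluate(tau), w_max)
    return w


def ipcw_c_index(
    risk_scores,
    followup_years,
    event_observed,
    G: CensoringModel,
    tau: float,
    w_max: float = DEFAULT_WEIGHT_CAP,
) -> float:
    """Uno-type IPCW concordance index truncated at τ.

    Comparable pairs (i, j) have subject i diagnosed strictly before τ and
    before X_j; each contributes weight 1/Ĝ(X_i⁻)², counted fully when i's
    risk score exceeds j's and half on score ties.

    Raises
    ------
    ConcordanceUndefinedError
        When no comparable pair exists.
    """
    s = np.asarray(risk_scores, dtype=float)
    x = np.asarray(followup_years, dtype=float)
    delta = np.asarray(event_observed, dtype=bool)
    if not np.all(np.isfinite(s)):
        raise ValueError("risk scores must be finite")
    if tau <= 0:
        raise ValueError("tau must be positive")

    i_mask = delta & (x < tau)
    if not np.any(i_mask):
        raise ConcordanceUndefinedError("no events before the truncation time")
    xi, si = x[i_mask], s[i_mask]
    wi = _inverse(G.evaluate_left(xi), w_max) ** 2

    later = xi[:, None] < x[None, :]
    conc = si[:, None] > s[None, :]
    tied = si[:, None] == s[None, :]
    den = float((wi[:, None] * later).sum())
    if den == 0.0:
        raise ConcordanceUndefinedError("no comparable pairs")
    num = float((wi[:, None] * later * (conc + 0.5 * tied)).sum())
    return num / den
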