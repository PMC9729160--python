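"""Synthetic visit-level cohorts of autoantibody-positive children.

The restricted multi-study cohort behind this analysis cannot be shipped, so
this module generates cohorts with the statistical structure the pipeline
assumes, in two modes:

``longitudinal``
    Children accrue scheduled visits with per-antibody log-mULN level
    trajectories (child-specific intercept + linear post-seroconversion
    drift + noise; pre-seroconversion levels stay below the positivity
    threshold). Diabetes onset follows a piecewise-constant hazard
    exp(η(t)) with η linear in the most recent visit's log levels and the
    HLA risk group; dropout/end-of-study censoring is independent of η.

``logistic_direct``
    An exactly well-specified world for parameter recovery: one feature row
    per child, event ~ Bernoulli(logistic(η)) at a fixed horizon, with
    independent right-censoring.

Defaults are calibrated once to the published cohort's marginals (≈1400
children, ≈37% progressors, seroconversion ages ≈0.3–23 y, initial→
confirmatory spacing ≈0.4–0.5 y, follow-up to 15 y); all tuned values live
in the config, not the code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .preprocess import ANTIBODIES, POSITIVITY_THRESHOLD

HLA_GROUPS = ("A", "B", "C", "D")
SOURCES = ("BABYDIAB", "DAISY", "DEW-IT", "DiPiS", "DIPP")


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class LevelParams:
    """Per-antibody log-mULN trajectory parameters."""

    baseline_mean: float  # mean ln mULN while below the positivity threshold
    baseline_sd: float
    post_mean: float  # mean ln mULN at seroconversion for converted antibodies
    post_sd: float
    drift_per_year: float  # mean linear post-seroconversion drift of ln mULN
    noise_sd: float  # visit-to-visit measurement noise
    #: sd of the child-specific drift slope around drift_per_year; a slope
    #: unknown at seroconversion is what makes late events harder to predict
    #: from time-0 levels and a third test informative
    drift_sd: float = 0.0


@dataclass(frozen=True)
class RiskBetas:
    """Linear predictor of the onset process, on the log-hazard scale in
    longitudinal mode and the log-odds scale in logistic_direct mode."""

    intercept: float
    iaa: float
    gada: float
    ia2a: float
    hla: Dict[str, float] = field(
        default_factory=lambda: {"A": 0.5, "B": 0.0, "C": -0.3, "D": -0.6, "missing": 0.0}
    )

    def level_vector(self) -> np.ndarray:
        return np.array([self.iaa, self.gada, self.ia2a])


def _default_level_params() -> Dict[str, LevelParams]:
    return {
        "iaa": LevelParams(-1.8, 0.7, 0.8, 1.3, 0.15, 0.30, drift_sd=0.25),
        "gada": LevelParams(-1.8, 0.7, 1.0, 1.5, 0.08, 0.30, drift_sd=0.15),
        "ia2a": LevelParams(-1.8, 0.7, 1.1, 1.7, 0.20, 0.30, drift_sd=0.30),
    }


@dataclass(frozen=True)
class CohortConfig:
    n_children: int = 1500
    seed: int = 0
    mode: str = "longitudinal"  # or "logistic_direct"
    source_probs: Tuple[float, ...] = (0.111, 0.127, 0.123, 0.049, 0.590)
    male_prob: float = 0.555
    hla_probs: Tuple[float, ...] = (0.2375, 0.4750, 0.1300, 0.1575)  # A, B, C, D
    hla_missing_prob: float = 0.002
    famhist_prob: float = 0.25
    serocon_age_dist: Tuple[float, float] = (1.50, 0.67)  # (log-mean, log-sd), years
    serocon_age_range: Tuple[float, float] = (0.3, 13.0)
    visit_interval_years: float = 0.45
    followup_end_years: float = 15.0
    #: administrative end of study is drawn per child between
    #: followup_end_years and followup_end_max_years of age, reflecting the
    #: constituent studies' protocols (oldest observed ages ≈ 24 y)
    followup_end_max_years: float = 24.0
    dropout_rate: float = 0.045  # per-year hazard of loss to follow-up
    convert_probs: Dict[str, float] = field(
        default_factory=lambda: {"iaa": 0.56, "gada": 0.62, "ia2a": 0.30}
    )
    level_params: Dict[str, LevelParams] = field(default_factory=_default_level_params)
    child_intercept_sd: float = 0.4
    risk_betas: RiskBetas = field(
        default_factory=lambda: RiskBetas(intercept=-3.3, iaa=0.30, gada=0.20, ia2a=0.35)
    )
    horizon_T: float = 10.0  # logistic_direct mode only
    log_floor: float = 0.01

    def validate(self) -> None:
        if self.n_children < 0:
            raise ConfigError("n_children must be >= 0")
        if self.mode not in ("longitudinal", "logistic_direct"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        for name, probs, k in (
            ("source_probs", self.source_probs, 5),
            ("hla_probs", self.hla_probs, 4),
        ):
            if len(probs) != k or any(p < 0 for p in probs):
                raise ConfigError(f"{name} must be a {k}-vector of probabilities")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {sum(probs)!r})")
        for p in (self.male_prob, self.famhist_prob, self.hla_missing_prob):
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.visit_interval_years <= 0:
            raise ConfigError("visit_interval_years must be > 0")
        if self.serocon_age_dist[1] < 0 or self.child_intercept_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        for lp in self.level_params.values():
            if min(lp.baseline_sd, lp.post_sd, lp.noise_sd, lp.drift_sd) < 0:
                raise ConfigError("level-parameter sds must be >= 0")
        if self.dropout_rate < 0:
            raise ConfigError("dropout_rate must be >= 0")
        if self.followup_end_max_years < self.followup_end_years:
            raise ConfigError("followup_end_max_years must be >= followup_end_years")


@dataclass(frozen=True)
class GeneratedCohort:
    children: pd.DataFrame
    visits: pd.DataFrame
    truth: dict


_CHILD_COLUMNS = [
    "child_id",
    "source",
    "sex",
    "family_history",
    "hla_group",
    "diagnosis_age_years",
    "last_followup_age_years",
]
_VISIT_COLUMNS = ["child_id", "age_years"] + [f"{ab}_mULN" for ab in ANTIBODIES]


def generate_cohort(config: CohortConfig) -> GeneratedCohort:
    """Generate a cohort; deterministic given (config, config.seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.mode == "longitudinal":
        return _generate_longitudinal(config, rng)
    return _generate_logistic_direct(config, rng)


def _draw_static(config: CohortConfig, rng: np.random.Generator, n: int):
    source = rng.choice(SOURCES, size=n, p=np.asarray(config.source_probs))
    sex = np.where(rng.random(n) < config.male_prob, "M", "F")
    famhist = (rng.random(n) < config.famhist_prob).astype(int)
    hla = rng.choice(HLA_GROUPS, size=n, p=np.asarray(config.hla_probs)).astype(object)
    hla[rng.random(n) < config.hla_missing_prob] = "missing"
    return source, sex, famhist, hla


def _draw_serocon_age(config: CohortConfig, rng: np.random.Generator) -> float:
    mu, sd = config.serocon_age_dist
    lo, hi = config.serocon_age_range
    for _ in range(1000):
        age = float(rng.lognormal(mu, sd))
        if lo <= age <= hi:
            return age
    return float(np.clip(age, lo, hi))


def _generate_longitudinal(config: CohortConfig, rng: np.random.Generator) -> GeneratedCohort:
    betas = config.risk_betas
    beta_lvl = betas.level_vector()
    ln_floor = np.log(config.log_floor)
    children, visits, latent = [], [], []
    for idx in range(config.n_children):
        cid = f"C{idx:05d}"
        source, sex, famhist, hla = (x[0] for x in _draw_static(config, rng, 1))
        s_age = _draw_serocon_age(config, rng)

        # per-child administrative end of study (protocols differ across
        # constituent studies; observed ages run to about 24 y)
        admin_end = float(
            rng.uniform(config.followup_end_years, config.followup_end_max_years)
        )

        # scheduled visits from about two intervals before seroconversion
        start = max(0.25, s_age - 2 * config.visit_interval_years)
        ages = [start]
        while ages[-1] < admin_end:
            ages.append(ages[-1] + config.visit_interval_years * rng.uniform(0.85, 1.15))
        ages = np.asarray(ages[:-1] or [start])

        # which antibodies this child converts for (at least one)
        conv = {ab: rng.random() < config.convert_probs[ab] for ab in ANTIBODIES}
        if not any(conv.values()):
            probs = np.array([config.convert_probs[ab] for ab in ANTIBODIES])
            conv[rng.choice(ANTIBODIES, p=probs / probs.sum())] = True

        b_child = rng.normal(0.0, config.child_intercept_sd)
        lnlvl = np.empty((len(ages), 3))
        for k, ab in enumerate(ANTIBODIES):
            lp = config.level_params[ab]
            base = rng.normal(lp.baseline_mean, lp.baseline_sd, size=len(ages))
            base = np.minimum(base, -0.05)  # pre-seroconversion stays below ln(1)
            lnlvl[:, k] = base
            if conv[ab]:
                post_mask = ages >= s_age
                t_since = ages[post_mask] - s_age
                level_at_serocon = rng.normal(lp.post_mean, lp.post_sd)
                drift = rng.normal(lp.drift_per_year, lp.drift_sd)
                lnlvl[post_mask, k] = (
                    level_at_serocon
                    + b_child
                    + drift * t_since
                    + rng.normal(0.0, lp.noise_sd, size=post_mask.sum())
                )
        lnlvl = np.maximum(lnlvl, ln_floor)

        # independent censoring: dropout from entry, or administrative end
        cens_age = min(
            float(ages[0] + rng.exponential(1.0 / config.dropout_rate))
            if config.dropout_rate > 0
            else np.inf,
            admin_end,
        )

        # piecewise-constant hazard between visits, levels from latest visit
        eta = betas.intercept + lnlvl @ beta_lvl + betas.hla.get(hla, 0.0)
        bounds = np.append(ages, max(cens_age, ages[-1]) + 50.0)
        target = rng.exponential(1.0)
        cum = 0.0
        onset_age = np.inf
        for k in range(len(ages)):
            lam = float(np.exp(eta[k]))
            width = bounds[k + 1] - bounds[k]
            if cum + lam * width >= target:
                onset_age = bounds[k] + (target - cum) / lam
                break
            cum += lam * width

        if onset_age < cens_age:
            diag, last_fu = onset_age, onset_age
        else:
            diag, last_fu = None, cens_age
        kept = ages <= last_fu
        if diag is not None:
            kept &= ages < diag
        if not kept.any():
            kept[0] = True  # entry visit always observed
            last_fu = max(last_fu, float(ages[0]))
        children.append(
            dict(
                child_id=cid,
                source=source,
                sex=sex,
                family_history=famhist,
                hla_group=hla,
                diagnosis_age_years=diag,
                last_followup_age_years=last_fu,
            )
        )
        for a, row in zip(ages[kept], np.exp(lnlvl[kept])):
            visits.append(
                dict(
                    child_id=cid,
                    age_years=float(a),
                    **{f"{ab}_mULN": float(row[k]) for k, ab in enumerate(ANTIBODIES)},
                )
            )
        latent.append(
            dict(
                child_id=cid,
                serocon_age=s_age,
                onset_age=onset_age,
                censor_age=cens_age,
                eta_at_serocon=float(eta[np.searchsorted(ages, s_age, side="right") - 1])
                if len(ages)
                else np.nan,
            )
        )
    return _package(config, children, visits, latent)


def _generate_logistic_direct(config: CohortConfig, rng: np.random.Generator) -> GeneratedCohort:
    from scipy.special import expit

    betas = config.risk_betas
    beta_lvl = betas.level_vector()
    ln_floor = np.log(config.log_floor)
    T = config.horizon_T
    n = config.n_children

    source, sex, famhist, hla = _draw_static(config, rng, n)
    s_age = np.array([_draw_serocon_age(config, rng) for _ in range(n)])
    confirm_age = s_age + config.visit_interval_years

    # one feature vector per child, identical at both defining visits;
    # redraw until at least one antibody is positive (selection on the
    # covariates only, so the conditional outcome model is untouched)
    means = np.array([config.level_params[ab].post_mean for ab in ANTIBODIES])
    sds = np.array([config.level_params[ab].post_sd for ab in ANTIBODIES])
    x = np.maximum(rng.normal(means, sds, size=(n, 3)), ln_floor)
    for _ in range(100):
        redo = ~np.any(np.exp(x) > POSITIVITY_THRESHOLD, axis=1)
        if not redo.any():
            break
        x[redo] = np.maximum(rng.normal(means, sds, size=(int(redo.sum()), 3)), ln_floor)

    hla_eff = np.array([betas.hla.get(h, 0.0) for h in hla])
    eta = betas.intercept + x @ beta_lvl + hla_eff
    p_event = expit(eta)
    event = rng.random(n) < p_event
    event_time = np.where(event, rng.uniform(0.0, T, size=n) + 1e-9, np.inf)

    cens = (
        rng.exponential(1.0 / config.dropout_rate, size=n)
        if config.dropout_rate > 0
        else np.full(n, np.inf)
    )
    cens = np.minimum(cens, T + 2.0)  # administrative end past the horizon

    observed = event & (event_time <= cens)
    diag = np.where(observed, confirm_age + event_time, np.nan)
    last_fu = np.where(observed, confirm_age + event_time, confirm_age + cens)

    cids = np.array([f"C{i:05d}" for i in range(n)])
    children = pd.DataFrame(
        {
            "child_id": cids,
            "source": source,
            "sex": sex,
            "family_history": famhist,
            "hla_group": hla,
            "diagnosis_age_years": diag,
            "last_followup_age_years": last_fu,
        }
    )
    mULN = np.exp(x)
    visits = pd.DataFrame(
        {
            "child_id": np.repeat(cids, 2),
            "age_years": np.column_stack([s_age, confirm_age]).ravel(),
            **{
                f"{ab}_mULN": np.repeat(mULN[:, k], 2)
                for k, ab in enumerate(ANTIBODIES)
            },
        }
    )
    latent = pd.DataFrame(
        {
            "child_id": cids,
            "eta": eta,
            "p_event": p_event,
            "event": event,
            "event_time": event_time,
            "censor_time": cens,
        }
    )
    return _package(config, children, visits, latent)


def _package(config, children, visits, latent) -> GeneratedCohort:
    children_df = (
        children
        if isinstance(children, pd.DataFrame)
        else pd.DataFrame(children, columns=_CHILD_COLUMNS)
    )
    visits_df = (
        visits if isinstance(visits, pd.DataFrame) else pd.DataFrame(visits, columns=_VISIT_COLUMNS)
    )
    truth = {
        "mode": config.mode,
        "seed": config.seed,
        "risk_betas": {
            "intercept": config.risk_betas.intercept,
            "iaa": config.risk_betas.iaa,
            "gada": config.risk_betas.gada,
            "ia2a": config.risk_betas.ia2a,
            "hla": dict(config.risk_betas.hla),
        },
        "horizon_T": config.horizon_T,
        "latent": pd.DataFrame(latent),
    }
    return GeneratedCohort(children=children_df, visits=visits_df, truth=truth)


def progressor_fraction(children: pd.DataFrame) -> float:
    """Fraction of children with an observed diabetes diagnosis."""
    if children.empty:
        return float("nan")
    return float(children["diagnosis_age_years"].notna().mean())


def summarise_cohort(
    children: pd.DataFrame, sero: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Key-characteristics table by progression status.

    Counts (with percentages) for sex, data source and HLA risk group, and
    mean ± SD seroconversion ages and antibody levels at the initial and
    confirmatory visits when a seroconversion table is supplied. Columns:
    all / progressors / non-progressors.
    """
    if sero is not None and not children.empty:
        children = children[children["child_id"].isin(sero["child_id"])]
    prog = children["diagnosis_age_years"].notna() if not children.empty else pd.Series(dtype=bool)
    groups = {
        "all": children,
        "progressors": children[prog] if not children.empty else children,
        "non_progressors": children[~prog] if not children.empty else children,
    }
    rows = []

    def count_row(variable, mask_fn):
        row = {"variable": variable}
        for g, df in groups.items():
            n = int(mask_fn(df).sum()) if not df.empty else 0
            total = len(df)
            pct = 100.0 * n / total if total else float("nan")
            row[g] = f"{n} ({pct:.1f}%)" if total else "0"
            row[f"{g}_n"] = n
        rows.append(row)

    def mean_row(variable, values_fn):
        row = {"variable": variable}
        for g, df in groups.items():
            vals = values_fn(df) if not df.empty else pd.Series(dtype=float)
            vals = pd.Series(vals).dropna()
            if len(vals):
                row[g] = f"{vals.mean():.1f} ± {vals.std(ddof=1) if len(vals) > 1 else 0.0:.1f}"
                row[f"{g}_mean"] = float(vals.mean())
            else:
                row[g] = "NA"
                row[f"{g}_mean"] = float("nan")
        rows.append(row)

    count_row("n", lambda df: pd.Series(True, index=df.index))
    count_row("male", lambda df: df["sex"] == "M")
    for src in SOURCES:
        count_row(f"source_{src}", lambda df, s=src: df["source"] == s)
    for g in HLA_GROUPS + ("missing",):
        count_row(f"hla_{g}", lambda df, h=g: df["hla_group"] == h)
    if sero is not None and not sero.empty:
        merged = sero.merge(children[["child_id"]], on="child_id")
        prog_s = merged["diagnosis_age_years"].notna()
        sgroups = {"all": merged, "progressors": merged[prog_s], "non_progressors": merged[~prog_s]}

        def sero_mean_row(variable, col):
            row = {"variable": variable}
            for g, df in sgroups.items():
                vals = df[col].dropna()
                if len(vals):
                    row[g] = f"{vals.mean():.1f} ± {vals.std(ddof=1) if len(vals) > 1 else 0.0:.1f}"
                    row[f"{g}_mean"] = float(vals.mean())
                else:
                    row[g] = "NA"
                    row[f"{g}_mean"] = float("nan")
            rows.append(row)

        sero_mean_row("age_at_initial_visit", "initial_age")
        sero_mean_row("age_at_confirmatory_visit", "confirm_age")
        for ab in ANTIBODIES:
            sero_mean_row(f"{ab}_mULN_initial", f"{ab}_init_mULN")
            sero_mean_row(f"{ab}_mULN_confirmatory", f"{ab}_conf_mULN")
    return pd.DataFrame(rows)


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
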