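"""Synthetic linked perinatal cohorts with a retained ground-truth ledger.

The real analysis runs on confidential registry data, so every pipeline
stage is exercised on simulated cohorts that reproduce the statistical
structure the analysis depends on:

* mothers with 1-3 study-window births (default split 80.8 / 18.5 / 0.7 %)
  plus optional pre-window births supplying obstetric history;
* within-mother outcome correlation via a mother-level random intercept on
  the logit scale;
* binary/categorical risk factors at configurable prevalences with
  configurable conditional log-odds effects;
* ~5.2% preterm births, and a baseline solved numerically so the marginal
  SGA prevalence hits its target (default 10%);
* birthweights drawn on the correct side of the growth standard's
  10th-percentile cutoff, so classification reproduces the generated labels;
* reported previous-pregnancy counts set truthfully, then corrupted for a
  configurable fraction of mothers to exercise the completeness check.

Everything the generator knows is retained in a :class:`TruthLedger` - the
per-birth linear predictors, outcome probabilities, counterfactual
probabilities with each modifiable factor's effect removed, stratum labels
and history bookkeeping - so parameter-recovery and coverage tests can
compare estimates with ground truth.  Planted log-odds are conditional on
the random intercept; marginal (GEE-target) effects are available through
:func:`marginal_logodds` by numeric integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from ._util import DataError
from .cohort import DAYS_PER_MONTH, DEFAULT_WINDOWS, StratumDataset, StudyWindows
from .growth import GrowthStandard, make_synthetic_standard

__all__ = [
    "FactorSpec",
    "CohortConfig",
    "TruthLedger",
    "generate_cohort",
    "true_marginal_paf",
    "marginal_logodds",
    "simulate_stratum",
]


@dataclass(frozen=True)
class FactorSpec:
    """One simulated risk factor.

    Binary factors take ``prevalence`` and a scalar ``log_odds``;
    categorical factors take ``level_probs`` (level -> probability, summing
    to 1) and ``log_odds`` as a level -> value map (reference level 0).
    ``per_mother`` factors are constant across a mother's births.
    """

    name: str
    kind: str = "binary"
    prevalence: float = 0.1
    level_probs: tuple[tuple[object, float], ...] = ()
    log_odds: object = 0.0
    modifiable: bool = False
    per_mother: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical"):
            raise ValueError(f"unknown factor kind {self.kind!r}")
        if self.kind == "binary":
            if not 0.0 <= self.prevalence <= 1.0:
                raise ValueError(f"{self.name}: prevalence outside [0, 1]")
            if not np.isfinite(self.log_odds):
                raise ValueError(f"{self.name}: non-finite log-odds")
        else:
            probs = [p for _, p in self.level_probs]
            if abs(sum(probs) - 1.0) > 1e-12:
                raise ValueError(f"{self.name}: level probabilities must sum to 1")


def _default_factors() -> tuple[FactorSpec, ...]:
    # prevalences and effects chosen to echo the magnitudes reported for the
    # NSW 2007-2010 cohort (smoking aOR ~2.3, overseas-born ~1.5, ...)
    return (
        FactorSpec("smoking", prevalence=0.12, log_odds=float(np.log(2.31)), modifiable=True),
        FactorSpec("illicit_drug_abuse", prevalence=0.015, log_odds=float(np.log(2.0)), modifiable=True),
        FactorSpec("pregnancy_hypertension", prevalence=0.07, log_odds=float(np.log(1.5)), modifiable=True),
        FactorSpec("country_of_birth_non_australian", prevalence=0.30,
                   log_odds=float(np.log(1.54)), per_mother=True),
        FactorSpec(
            "socioeconomic_quintile",
            kind="categorical",
            level_probs=((1, 0.2), (2, 0.2), (3, 0.2), (4, 0.2), (5, 0.2)),
            log_odds={1: 0.0, 2: 0.02, 3: 0.05, 4: 0.11, 5: 0.17},
            per_mother=True,
        ),
        FactorSpec("diabetes", prevalence=0.06, log_odds=float(np.log(0.85))),
        FactorSpec("aboriginality", prevalence=0.03, log_odds=float(np.log(1.29)), per_mother=True),
    )


_GA_PRETERM = np.arange(24, 37)
_GA_PRETERM_P = np.array([1, 1, 1, 1.5, 2, 2.5, 3, 4, 6, 9, 14, 22, 33], dtype=float)
_GA_PRETERM_P /= _GA_PRETERM_P.sum()
_GA_TERM = np.arange(37, 45)
_GA_TERM_P = np.array([8, 20, 30, 24, 11, 5, 1.5, 0.5], dtype=float)
_GA_TERM_P /= _GA_TERM_P.sum()


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the simulated registry extract."""

    n_mothers: int = 10_000
    births_per_mother_probs: tuple[float, float, float] = (0.808, 0.185, 0.007)
    prior_births_probs: tuple[float, ...] = (0.55, 0.30, 0.15)
    random_effect_sd: float = 0.5
    factor_specs: tuple[FactorSpec, ...] = field(default_factory=_default_factors)
    preterm_rate: float = 0.052
    baseline_sga_target: float = 0.10
    history_miscount_rate: float = 0.03
    twin_rate: float = 0.0
    stillbirth_rate: float = 0.0
    caesarean_rate: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("preterm_rate", "baseline_sga_target", "history_miscount_rate",
                     "twin_rate", "stillbirth_rate", "caesarean_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        for probs in (self.births_per_mother_probs, self.prior_births_probs):
            if abs(sum(probs) - 1.0) > 1e-12:
                raise ValueError("birth-count probabilities must sum to 1")

    @property
    def modifiable_factors(self) -> list[str]:
        return [f.name for f in self.factor_specs if f.modifiable]


@dataclass
class TruthLedger:
    """Ground truth for every generated birth, keyed like the cohort frame."""

    frame: pd.DataFrame
    config: CohortConfig
    baseline: float

    def true_marginal_paf(self, factor: str, stratum: str | None = None) -> float:
        return true_marginal_paf(self, factor, stratum)


def true_marginal_paf(ledger: TruthLedger, factor: str, stratum: str | None = None) -> float:
    """Ground-truth PAF (%) over the included study births of a stratum.

    Uses the generator's own outcome probabilities and their counterfactuals
    with the factor's effect removed, marginalised over the realised
    mother-level intercepts:  100 * (sum p - sum p_cf) / sum p.
    """
    col = f"p_cf_{factor}"
    if col not in ledger.frame.columns:
        raise DataError(f"factor {factor!r} is not a modifiable factor of this ledger")
    d = ledger.frame
    mask = d["is_study"] & d["included"]
    if stratum is not None:
        mask &= d["stratum"].eq(stratum)
    p = d.loc[mask, "p"].to_numpy()
    p_cf = d.loc[mask, col].to_numpy()
    return float(100.0 * (p.sum() - p_cf.sum()) / p.sum())


def _solve_baseline(lp: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(c + lp)) = target, by bisection."""
    lo, hi = -30.0, 10.0
    f = lambda c: float(np.mean(expit(np.clip(c + lp, -35, 35)))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise DataError(
            f"target prevalence {target} unreachable given the planted effects"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _group_cumsum(values: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Cumulative sum restarting at each mother's first birth."""
    cs = np.cumsum(values)
    starts = np.concatenate([[0], np.cumsum(K)[:-1]])
    offsets = np.concatenate([[0.0], cs[np.cumsum(K)[:-1] - 1]]) if K.size else np.empty(0)
    return cs - np.repeat(offsets, K)


def generate_cohort(
    config: CohortConfig,
    standard: GrowthStandard | None = None,
    windows: StudyWindows = DEFAULT_WINDOWS,
) -> tuple[pd.DataFrame, TruthLedger]:
    """Draw a linked cohort (one row per birth) plus its truth ledger.

    Output rows include both study-window births and earlier history births;
    feed the frame to the cohort-builder filters exactly as a registry
    extract would be.
    """
    rng = np.random.default_rng(config.seed)
    standard = standard or make_synthetic_standard()
    if standard.model is None:
        raise DataError("generation needs a standard with a generating model")

    n_m = config.n_mothers
    k_study = rng.choice([1, 2, 3], size=n_m, p=config.births_per_mother_probs)
    k_prior = rng.choice(
        np.arange(len(config.prior_births_probs)), size=n_m, p=config.prior_births_probs
    )
    K = (k_study + k_prior).astype(int)
    N = int(K.sum())
    mother_row = np.repeat(np.arange(n_m), K)
    starts = np.concatenate([[0], np.cumsum(K)[:-1]])
    order = np.arange(N) - np.repeat(starts, K)
    is_study = order >= np.repeat(k_prior, K)

    # --- gestational age, sex, structural flags -----------------------------
    preterm = rng.random(N) < config.preterm_rate
    ga = np.where(
        preterm,
        rng.choice(_GA_PRETERM, size=N, p=_GA_PRETERM_P),
        rng.choice(_GA_TERM, size=N, p=_GA_TERM_P),
    ).astype(int)
    sex = np.where(rng.random(N) < 0.5, "male", "female")
    twin = rng.random(N) < config.twin_rate
    stillborn = rng.random(N) < config.stillbirth_rate
    caesarean = rng.random(N) < config.caesarean_rate

    # --- birth dates --------------------------------------------------------
    # inter-pregnancy intervals (months), a mixture straddling the 6- and
    # 42-month category bounds
    comp = rng.choice(3, size=N, p=[0.25, 0.60, 0.15])
    interval_months = np.select(
        [comp == 0, comp == 1, comp == 2],
        [rng.uniform(1, 6, N), rng.uniform(6, 41, N), rng.uniform(42, 80, N)],
    )
    interval_days = interval_months * DAYS_PER_MONTH
    ga_days = ga * 7.0
    window_days = float((windows.study_end - windows.study_start).days)
    # shrink each mother's *inter-pregnancy intervals* (never the gestation
    # component of a gap) so her study births fit inside the study window
    study_gap_mask = is_study & (order > np.repeat(k_prior, K))
    tot_int = np.bincount(
        mother_row, weights=np.where(study_gap_mask, interval_days, 0.0), minlength=n_m
    )
    tot_ga = np.bincount(
        mother_row, weights=np.where(study_gap_mask, ga_days, 0.0), minlength=n_m
    )
    shrink = np.clip((window_days - 1.0 - tot_ga) / np.maximum(tot_int, 1e-9), 0.0, 1.0)
    interval_days = np.where(
        study_gap_mask, interval_days * np.repeat(shrink, K), interval_days
    )
    # the last history birth sits >=320 days before the study window (so the
    # first study pregnancy's conception always postdates it); earlier
    # history intervals are shrunk if needed to stay inside the lookback window
    last_prior_back = np.where(k_prior > 0, 320.0 + rng.uniform(0.0, 1500.0, n_m), 0.0)
    prior_gap_mask = ~is_study & (order > 0)
    tot_int_p = np.bincount(
        mother_row, weights=np.where(prior_gap_mask, interval_days, 0.0), minlength=n_m
    )
    tot_ga_p = np.bincount(
        mother_row, weights=np.where(prior_gap_mask, ga_days, 0.0), minlength=n_m
    )
    back_budget = (
        float((windows.study_start - windows.history_start).days)
        - 60.0
        - last_prior_back
        - tot_ga_p
    )
    shrink_p = np.clip(back_budget / np.maximum(tot_int_p, 1e-9), 0.0, 1.0)
    interval_days = np.where(
        prior_gap_mask, interval_days * np.repeat(shrink_p, K), interval_days
    )
    gap_days = interval_days + ga_days
    gap_days[order == 0] = 0.0
    tot_study = np.bincount(
        mother_row, weights=np.where(study_gap_mask, gap_days, 0.0), minlength=n_m
    )

    cum = _group_cumsum(gap_days, K)  # days since each mother's first birth
    first_study_cum = cum[order == np.repeat(k_prior, K)]  # one per mother
    last_prior_cum = _last_prior_cum(cum, order, k_prior, K)
    first_offset = rng.uniform(0.0, np.maximum(window_days - tot_study, 1.0))
    offset_days = np.where(
        is_study,
        np.repeat(first_offset, K) + cum - np.repeat(first_study_cum, K),
        cum - np.repeat(last_prior_cum, K) - np.repeat(last_prior_back, K),
    )
    birth_date = windows.study_start + pd.to_timedelta(np.round(offset_days), unit="D")
    prev_offset = np.empty(N)
    prev_offset[1:] = offset_days[:-1]
    prev_offset[order == 0] = np.nan
    realised_interval_months = (offset_days - ga_days - prev_offset) / DAYS_PER_MONTH

    # --- covariates ---------------------------------------------------------
    data: dict[str, np.ndarray] = {}
    lp = np.zeros(N)
    contrib: dict[str, np.ndarray] = {}
    for spec in config.factor_specs:
        size = n_m if spec.per_mother else N
        if spec.kind == "binary":
            vals = rng.random(size) < spec.prevalence
            if spec.per_mother:
                vals = vals[mother_row]
            c = np.where(vals, float(spec.log_odds), 0.0)
        else:
            levels = [lv for lv, _ in spec.level_probs]
            probs = [p for _, p in spec.level_probs]
            idx = rng.choice(len(levels), size=size, p=probs)
            if spec.per_mother:
                idx = idx[mother_row]
            vals = np.array(levels, dtype=object)[idx]
            lo_map = spec.log_odds or {}
            c = np.array([float(lo_map.get(v, 0.0)) for v in vals])
        data[spec.name] = vals
        contrib[spec.name] = c
        lp += c

    b = rng.normal(0.0, config.random_effect_sd, size=n_m)
    lp += b[mother_row]

    baseline = _solve_baseline(lp[is_study], config.baseline_sga_target)
    eta = baseline + lp
    p = expit(np.clip(eta, -35, 35))
    sga = rng.random(N) < p

    # --- birthweight consistent with the SGA label --------------------------
    mu_w, sd_w = _standard_curves(standard, ga, sex)
    u = rng.random(N)
    q = np.where(sga, 0.10 * u, 0.10 + 0.90 * u)
    w = mu_w + sd_w * norm.ppf(np.clip(q, 1e-7, 1.0 - 1e-9))
    w = np.round(w / 5.0) * 5.0
    cut = mu_w + sd_w * norm.ppf(0.10)
    below = np.floor(cut / 5.0) * 5.0
    below = np.where(below >= cut, below - 5.0, below)  # largest 5g multiple < cutoff
    above = np.ceil(cut / 5.0) * 5.0
    w = np.where(sga, np.minimum(w, below), np.maximum(w, above))
    w = np.maximum(w, 5.0)

    # --- reported previous pregnancies, with deliberate miscounts -----------
    reported = order.copy()
    miscount_mother = rng.random(n_m) < config.history_miscount_rate
    last_row = np.cumsum(K) - 1
    corrupt = np.zeros(N, dtype=bool)
    corrupt[last_row[miscount_mother]] = True
    reported = np.where(corrupt, reported + 1, reported)

    diabetes = np.asarray(data.get("diabetes", np.zeros(N, dtype=bool)), dtype=bool)
    stratum = np.where(
        ga < 37, "preterm", np.where(diabetes, "term_diabetic", "term_nondiabetic")
    )

    cohort = pd.DataFrame(
        {
            "mother_id": np.char.add("m", np.char.zfill(mother_row.astype(str), 7)),
            "birth_date": birth_date,
            "plurality": np.where(twin, "multiple", "singleton"),
            "vital_status": np.where(stillborn, "stillbirth", "livebirth"),
            "gestational_weeks": ga,
            "sex": sex,
            "birthweight_grams": w,
            "reported_previous_pregnancies": reported,
            "caesarean_section": caesarean,
            **data,
        }
    )
    if "diabetes" not in cohort.columns:
        cohort["diabetes"] = False

    included = (
        is_study
        & ~twin
        & ~stillborn
        & (ga >= 24)
        & (ga <= 44)
        & ~np.repeat(miscount_mother, K)
    )
    ledger = pd.DataFrame(
        {
            "mother_id": cohort["mother_id"],
            "is_study": is_study,
            "included": included,
            "stratum": stratum,
            "b_mother": b[mother_row],
            "eta": eta,
            "p": p,
            "sga": sga,
            "parity": order,
            "interval_months": realised_interval_months,
        }
    )
    # generator-side history bookkeeping (cumulative over earlier births)
    for name, flag in (
        ("prev_preterm", ga < 37),
        ("prev_stillbirths", stillborn),
        ("prev_caesareans", caesarean),
        ("prev_sga", sga & ~stillborn & (ga >= 24) & (ga <= 44)),
    ):
        ledger[name] = (_group_cumsum(flag.astype(float), K) - flag).astype(int)
    for fname in config.modifiable_factors:
        ledger[f"p_cf_{fname}"] = expit(np.clip(eta - contrib[fname], -35, 35))

    return cohort, TruthLedger(frame=ledger, config=config, baseline=baseline)


def _last_prior_cum(cum: np.ndarray, order: np.ndarray, k_prior: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Per-mother cum position of the last prior birth (0 when none)."""
    n_m = K.size
    out = np.zeros(n_m)
    mask = order == np.repeat(np.maximum(k_prior - 1, 0), K)
    has_prior = k_prior > 0
    vals = cum[mask]
    # one matched row per mother (order==k_prior-1, or order==0 when no prior)
    out[:] = vals
    out[~has_prior] = 0.0
    return out


def _standard_curves(standard: GrowthStandard, ga: np.ndarray, sex: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = np.empty(ga.size)
    sd = np.empty(ga.size)
    for s in ("male", "female"):
        cell = standard.model["by_sex"][s]
        weeks = np.asarray(cell["weeks"])
        mean = np.asarray(cell["mean"])
        sdv = np.asarray(cell["sd"])
        m = sex == s
        idx = np.searchsorted(weeks, ga[m])
        mu[m] = mean[idx]
        sd[m] = sdv[idx]
    return mu, sd


def marginal_logodds(baseline: float, log_or: float, random_effect_sd: float, n_nodes: int = 80) -> float:
    """Marginal (GEE-target) log-odds of a binary factor, by Gauss-Hermite.

    Planted effects are conditional on the mother intercept u ~ N(0, sd);
    the marginal effect logit(E[p(x=1)]) - logit(E[p(x=0)]) is attenuated
    towards zero, and is the large-sample target of the GEE fit.
    """
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    w = w / np.sqrt(np.pi)
    u = np.sqrt(2.0) * random_effect_sd * x
    p1 = float(w @ expit(baseline + log_or + u))
    p0 = float(w @ expit(baseline + u))
    return float(logit(p1) - logit(p0))


def marginal_baseline(baseline: float, random_effect_sd: float, n_nodes: int = 80) -> float:
    """logit of the marginal response probability at the reference profile."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    w = w / np.sqrt(np.pi)
    u = np.sqrt(2.0) * random_effect_sd * x
    return float(logit(w @ expit(baseline + u)))


def simulate_stratum(
    n_mothers: int,
    factors: list[tuple[str, float, float]],
    *,
    baseline: float = -2.3,
    random_effect_sd: float = 0.5,
    births_per_mother_probs: tuple[float, float, float] = (0.808, 0.185, 0.007),
    seed: int = 0,
) -> tuple[StratumDataset, dict]:
    """Minimal clustered stratum: binary factors only, with analytic truths.

    A fast generator for parameter-recovery and bootstrap-coverage studies:
    mothers with 1-3 births, a shared N(0, sd) intercept, and binary factors
    given as (name, prevalence, conditional log-odds).  Returns the
    stratum dataset plus a truth dict with the realised-sample marginal PAF
    per factor and each factor's marginal log-odds target.
    """
    rng = np.random.default_rng(seed)
    sizes = rng.choice([1, 2, 3], size=n_mothers, p=births_per_mother_probs)
    groups = np.repeat(np.arange(n_mothers), sizes)
    n = groups.size
    b = rng.normal(0.0, random_effect_sd, size=n_mothers)[groups]
    eta = baseline + b
    cols = [np.ones(n)]
    names = ["Intercept"]
    contrib = {}
    term_map: dict[str, list[int]] = {}
    for j, (name, prev, lo) in enumerate(factors, start=1):
        x = (rng.random(n) < prev).astype(float)
        cols.append(x)
        names.append(name)
        term_map[name] = [j]
        contrib[name] = lo * x
        eta += lo * x
    X = np.column_stack(cols)
    p = expit(eta)
    y = (rng.random(n) < p).astype(float)
    truth = {"baseline": baseline, "n_births": n}
    for name, _, lo in factors:
        p_cf = expit(eta - contrib[name])
        truth[f"paf_{name}"] = float(100.0 * (p.sum() - p_cf.sum()) / p.sum())
        truth[f"marginal_logodds_{name}"] = marginal_logodds(baseline, lo, random_effect_sd)
    data = StratumDataset(
        stratum="simulated",
        y=y,
        X=X,
        colnames=names,
        term_map=term_map,
        cluster_ids=groups,
        codings={},
        frame=None,
    )
    return data, truth
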