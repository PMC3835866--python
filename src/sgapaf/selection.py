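"""Model-building protocol: screening, collinearity, backward elimination, GEE.

The protocol mirrors standard epidemiological practice for registry studies:

1. crude chi-squared screen — factors enter the initial multivariable model
   only if the factor x outcome Pearson chi-squared has P < 0.10;
2. variance inflation factors as a multicollinearity diagnostic (reported,
   never auto-dropped);
3. backward elimination on independence logistic fits — the overall least
   significant factor (largest multi-df Wald P over its design columns) is
   removed while P >= 0.01, unless removing it shifts any remaining factor's
   adjusted odds ratio by 10% or more, in which case it is kept as a
   confounder and frozen in the model;
4. a re-entry pass (each eliminated factor added back independently and
   re-admitted if now significant) and a one-at-a-time two-way interaction
   pass at P < 0.01;
5. the final model is refit by GEE with a logit link, exchangeable working
   correlation over births to the same mother, and robust standard errors,
   from which adjusted odds ratios with 95% CIs are reported.

Selection-stage fits use independence logistic regression (the clustering
correction is applied only to the final model); both choices are
configurable via :class:`SelectionConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, norm

from ._util import DataError
from .cohort import StratumDataset
from .gee import GEEResult, SeparationError, check_separation, gee_logistic, wald_test

Z_95 = float(norm.ppf(0.975))  # 1.959964; reported CIs use the normal 1.96 convention


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the model-building protocol."""

    screen_alpha: float = 0.10
    retain_alpha: float = 0.01
    confounder_threshold: float = 0.10  # relative aOR change triggering retention
    interaction_alpha: float = 0.01
    vif_threshold: float = 10.0
    candidate_interactions: tuple[tuple[str, str], ...] = ()
    #: "independence" (default) or "gee" for the selection-stage fits
    selection_mode: str = "independence"

    def __post_init__(self) -> None:
        if not 0 < self.retain_alpha <= self.screen_alpha < 1:
            raise ValueError("need 0 < retain_alpha <= screen_alpha < 1")
        if self.confounder_threshold <= 0:
            raise ValueError("confounder_threshold must be positive")


@dataclass
class ScreenResult:
    factor: str
    statistic: float
    p_value: float
    df: int
    included: bool
    note: str = ""


def univariate_screen(
    df: pd.DataFrame,
    factor_columns: dict[str, str],
    config: SelectionConfig = SelectionConfig(),
    outcome: str = "sga",
) -> list[ScreenResult]:
    """Crude Pearson chi-squared screen of each factor against the outcome.

    ``factor_columns`` maps factor name -> cohort column (categorical or
    boolean; continuous covariates must be pre-binned).  A factor with a
    single observed level cannot be tested: it is excluded with a warning.
    """
    results = []
    y = df[outcome].astype(bool)
    for name, col in factor_columns.items():
        vals = df[col]
        if vals.nunique() < 2:
            warnings.warn(f"factor {name!r} has a single observed level; excluded from screen")
            results.append(ScreenResult(name, np.nan, np.nan, 0, False, "single level"))
            continue
        table = pd.crosstab(vals, y)
        stat, p, dof, _ = chi2_contingency(table.to_numpy(), correction=False)
        results.append(ScreenResult(name, float(stat), float(p), int(dof), bool(p < config.screen_alpha)))
    return results


def compute_vif(X: np.ndarray, colnames: list[str] | None = None) -> pd.Series:
    """Variance inflation factor 1/(1-R^2) per column, regressing on the rest.

    The intercept column (if present) is excluded from the report.  Perfectly
    collinear columns get VIF = inf with a warning; nothing is dropped — the
    diagnostic is for analyst review.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two columns")
    names = colnames or [f"x{j}" for j in range(p)]
    keep = [j for j, nm in enumerate(names) if nm != "Intercept"]
    out = {}
    ones = np.ones((n, 1))
    for j in keep:
        others = [k for k in range(p) if k != j]
        A = np.hstack([ones, X[:, others]])
        yj = X[:, j]
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        tss = float(((yj - yj.mean()) ** 2).sum())
        rss = float((resid**2).sum())
        if tss == 0:
            raise DataError(f"column {names[j]!r} is constant")
        r2 = 1.0 - rss / tss
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"column {names[j]!r} is perfectly collinear with the others")
            out[names[j]] = np.inf
        else:
            out[names[j]] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def _fit(data: StratumDataset, factors: list[str], mode: str, beta0=None) -> GEEResult:
    sub = data.subset_factors(factors)
    fixed = 0.0 if mode == "independence" else None
    return gee_logistic(sub.y, sub.X, sub.cluster_ids, fixed_alpha=fixed, beta0=beta0)


def _factor_pvalues(res: GEEResult, data: StratumDataset, factors: list[str], robust: bool) -> dict[str, float]:
    sub_map: dict[str, list[int]] = {}
    pos = 1
    for f in factors:
        k = len(data.term_map[f])
        sub_map[f] = list(range(pos, pos + k))
        pos += k
    return {f: wald_test(res, cols, robust=robust)[1] for f, cols in sub_map.items()}


@dataclass
class EliminationStep:
    action: str  # considered | removed | kept_confounder | reentered | interaction_kept | interaction_dropped | failed
    factor: str
    statistic: float = np.nan
    p_value: float = np.nan
    detail: str = ""


@dataclass
class EliminationResult:
    final_factors: list[str]
    confounders: list[str]
    interactions: list[tuple[str, str]]
    trace: list[EliminationStep] = field(default_factory=list)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.trace])


def backward_eliminate(
    data: StratumDataset,
    candidates: list[str],
    config: SelectionConfig = SelectionConfig(),
) -> EliminationResult:
    """Backward elimination with confounder retention, re-entry and interactions.

    Factors are removed one at a time (largest multi-df Wald P first, ties
    broken lexicographically) while the largest P is >= ``retain_alpha``;
    a factor whose tentative removal shifts any remaining factor's adjusted
    odds ratio by ``confounder_threshold`` (relative, on the OR scale) is
    retained as a confounder and becomes ineligible for removal.  After the
    main-effects model stabilises, each eliminated factor is added back
    independently (re-admitted if significant) and each configured two-way
    interaction is tested one at a time.
    """
    mode = config.selection_mode
    robust = mode == "gee"
    current = sorted(candidates)
    frozen: set[str] = set()  # confounders, ineligible for removal
    eliminated: list[str] = []
    trace: list[EliminationStep] = []

    while True:
        res = _fit(data, current, mode)
        if not res.converged:
            trace.append(EliminationStep("failed", ",".join(current), detail="non-convergent fit"))
            break
        pvals = _factor_pvalues(res, data, current, robust)
        removable = {f: p for f, p in pvals.items() if f not in frozen}
        if not removable:
            break
        # largest P first; ties -> lexicographically smaller name removed first
        worst = sorted(removable.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        if removable[worst] < config.retain_alpha:
            break
        remaining = [f for f in current if f != worst]
        if not remaining:
            trace.append(EliminationStep("removed", worst, p_value=removable[worst]))
            eliminated.append(worst)
            current = remaining
            break
        res_without = _fit(data, remaining, mode)
        if not res_without.converged:
            trace.append(EliminationStep("failed", worst, detail="refit without factor failed; retained"))
            frozen.add(worst)
            continue
        shift = _max_aor_shift(res, res_without, data, current, remaining)
        if shift >= config.confounder_threshold:
            frozen.add(worst)
            trace.append(
                EliminationStep(
                    "kept_confounder", worst, p_value=removable[worst],
                    detail=f"max aOR shift {shift:.3f}",
                )
            )
        else:
            trace.append(
                EliminationStep(
                    "removed", worst, p_value=removable[worst], detail=f"max aOR shift {shift:.3f}"
                )
            )
            eliminated.append(worst)
            current = remaining

    # re-entry pass: each eliminated factor added back independently
    readmitted: list[tuple[str, float]] = []
    for f in sorted(eliminated):
        res = _fit(data, sorted(current + [f]), mode)
        if not res.converged:
            trace.append(EliminationStep("failed", f, detail="re-entry fit failed"))
            continue
        p = _factor_pvalues(res, data, sorted(current + [f]), robust)[f]
        if p < config.retain_alpha:
            readmitted.append((f, p))
            trace.append(EliminationStep("reentered", f, p_value=p))
    for f, _ in sorted(readmitted, key=lambda t: (t[1], t[0])):
        if f not in current:
            current = sorted(current + [f])

    # interaction pass: candidate pairs, one at a time
    interactions: list[tuple[str, str]] = []
    for a, b in config.candidate_interactions:
        if a not in current or b not in current:
            continue
        stat, p = _interaction_test(data, current, (a, b), mode, robust)
        if np.isnan(p):
            trace.append(EliminationStep("failed", f"{a}x{b}", detail="interaction fit failed"))
        elif p < config.interaction_alpha:
            interactions.append((a, b))
            trace.append(EliminationStep("interaction_kept", f"{a}x{b}", statistic=stat, p_value=p))
        else:
            trace.append(EliminationStep("interaction_dropped", f"{a}x{b}", statistic=stat, p_value=p))

    return EliminationResult(
        final_factors=sorted(current),
        confounders=sorted(frozen),
        interactions=interactions,
        trace=trace,
    )


def _max_aor_shift(
    res_with: GEEResult,
    res_without: GEEResult,
    data: StratumDataset,
    factors_with: list[str],
    factors_without: list[str],
) -> float:
    """Largest relative adjusted-OR change across remaining factor levels."""

    def coef_map(res: GEEResult, factors: list[str]) -> dict[str, float]:
        out, pos = {}, 1
        for f in factors:
            for k in range(len(data.term_map[f])):
                out[f"{f}#{k}"] = res.params[pos]
                pos += 1
        return out

    a = coef_map(res_with, factors_with)
    b = coef_map(res_without, factors_without)
    shifts = [abs(np.exp(b[k] - a[k]) - 1.0) for k in b]
    return max(shifts) if shifts else 0.0


def _interaction_test(
    data: StratumDataset, current: list[str], pair: tuple[str, str], mode: str, robust: bool
) -> tuple[float, float]:
    sub = data.subset_factors(current)
    ca = [sub.term_map[pair[0]]][0]
    cb = [sub.term_map[pair[1]]][0]
    inter_cols = []
    for i in ca:
        for j in cb:
            inter_cols.append(sub.X[:, i] * sub.X[:, j])
    Xi = np.column_stack([sub.X] + inter_cols)
    fixed = 0.0 if mode == "independence" else None
    res = gee_logistic(sub.y, Xi, sub.cluster_ids, fixed_alpha=fixed)
    if not res.converged:
        return np.nan, np.nan
    cols = list(range(sub.X.shape[1], Xi.shape[1]))
    stat, p, _ = wald_test(res, cols, robust=robust)
    return stat, p


@dataclass
class GEEFit:
    """Final-model GEE fit with the stratum's term structure attached."""

    result: GEEResult
    dataset: StratumDataset  # subset to the final factors (intercept first)

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.result.params, index=self.dataset.colnames)

    @property
    def term_map(self) -> dict[str, list[int]]:
        return self.dataset.term_map

    @property
    def converged(self) -> bool:
        return self.result.converged


def fit_gee(data: StratumDataset, factors: list[str]) -> GEEFit:
    """Fit the final GEE model (exchangeable correlation, robust SEs).

    Raises :class:`SeparationError` if any factor level perfectly predicts
    the outcome; a non-convergent fit is returned with ``converged=False``
    rather than raising.
    """
    sub = data.subset_factors(factors)
    if np.unique(sub.cluster_ids).size < 2:
        raise DataError("need at least 2 clusters (mothers)")
    if sub.y.min() == sub.y.max():
        raise DataError("outcome constant within stratum")
    check_separation(sub.y, sub.X, sub.colnames)
    res = gee_logistic(sub.y, sub.X, sub.cluster_ids)
    return GEEFit(result=res, dataset=sub)


def adjusted_ors(fit: GEEFit) -> pd.DataFrame:
    """Adjusted odds ratios exp(beta) with 95% robust CIs, one row per level.

    Reference levels appear with aOR 1.00 and empty CI bounds, matching the
    reporting convention for stratified tables.
    """
    if not fit.converged:
        raise DataError("cannot report aORs from a non-convergent fit")
    res = fit.result
    rows = []
    for factor, cols in fit.term_map.items():
        coding = fit.dataset.codings.get(factor)
        ref = coding.reference if coding is not None else False
        rows.append(
            {
                "factor": factor,
                "level": str(ref),
                "aor": 1.00,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "reference": True,
            }
        )
        for j in cols:
            b = res.params[j]
            se = res.robust_se[j]
            rows.append(
                {
                    "factor": factor,
                    "level": fit.dataset.colnames[j],
                    "aor": float(np.exp(b)),
                    "ci_low": float(np.exp(b - Z_95 * se)),
                    "ci_high": float(np.exp(b + Z_95 * se)),
                    "reference": False,
                }
            )
    return pd.DataFrame(
        rows, columns=["factor", "level", "aor", "ci_low", "ci_high", "reference"]
    )
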