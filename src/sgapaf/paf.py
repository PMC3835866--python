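"""Model-based population attributable fractions with cluster-bootstrap CIs.

The PAF of a risk factor is computed from the final fitted model by a
coefficient-zeroing counterfactual: with fitted SGA probabilities p_i and
counterfactual probabilities p_i0 obtained by setting the factor's
regression coefficient(s) to zero (all other coefficients and every birth's
covariates unchanged),

    PAF = 100 * (sum_i p_i - sum_i p_i0) / sum_i p_i .

This is the expected percentage reduction in SGA births were the factor's
effect removed from the population.  Confidence intervals come from a
cluster bootstrap: mothers are resampled with replacement (all of a mother's
births enter together, preserving the within-mother correlation), the final
model is refit on each replicate with the factor set frozen (no
re-selection), and the 95% interval is the bias-corrected (BC) percentile
interval — percentile endpoints shifted by the median-bias correction
z0 = Phi^{-1}(fraction of replicate PAFs below the point estimate), with no
acceleration constant.

`closed_form_af` provides the classical Miettinen case-based attributable
fraction pc*(RR-1)/RR from a 2x2 table; on a saturated one-factor logistic
model the model-based PAF reproduces it exactly, which the test suite uses
as an independent oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from ._util import DataError
from .cohort import StratumDataset
from .gee import gee_logistic
from .selection import GEEFit

_ETA_CLIP = 30.0


def model_paf(fit: GEEFit, factor_levels: list[int] | str) -> float:
    """Point PAF (%) from zeroing the named coefficients of a converged fit.

    ``factor_levels`` is either a factor name (all its design columns are
    zeroed) or an explicit list of design-column indices.
    """
    if not fit.converged:
        raise DataError("PAF requires a converged fit")
    cols = _resolve_levels(fit, factor_levels)
    X = fit.dataset.X
    beta = fit.result.params
    return _paf_from(beta, X, cols)


def _resolve_levels(fit: GEEFit, factor_levels) -> list[int]:
    if isinstance(factor_levels, str):
        if factor_levels not in fit.term_map:
            raise DataError(f"factor {factor_levels!r} not in the fitted model")
        cols = list(fit.term_map[factor_levels])
    else:
        cols = list(factor_levels)
    if not cols:
        raise DataError("empty factor level set")
    p = fit.result.params.size
    if any(j <= 0 or j >= p for j in cols):
        raise DataError(f"design columns {cols} outside the model (p={p})")
    return cols


def _paf_from(beta: np.ndarray, X: np.ndarray, cols: list[int]) -> float:
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    beta0 = beta.copy()
    beta0[cols] = 0.0
    eta0 = np.clip(X @ beta0, -_ETA_CLIP, _ETA_CLIP)
    expected = expit(eta).sum()
    counterfactual = expit(eta0).sum()
    return float(100.0 * (expected - counterfactual) / expected)


def closed_form_af(exposed_cases: float, exposed_total: float,
                   unexposed_cases: float, unexposed_total: float) -> float:
    """Miettinen's case-based attributable fraction (%), from a 2x2 table.

    AF = pc * (RR - 1) / RR with pc the exposed fraction among cases and RR
    the risk ratio.  Independent of the regression pipeline; used as the
    validation oracle for `model_paf` on saturated one-factor fits.
    """
    if min(exposed_cases, exposed_total - exposed_cases,
           unexposed_cases, unexposed_total - unexposed_cases) <= 0:
        raise DataError("all four cells of the 2x2 table must be positive")
    r1 = exposed_cases / exposed_total
    r0 = unexposed_cases / unexposed_total
    rr = r1 / r0
    pc = exposed_cases / (exposed_cases + unexposed_cases)
    return float(100.0 * pc * (rr - 1.0) / rr)


@dataclass
class PafEstimate:
    """Point PAF with its bias-corrected cluster-bootstrap interval."""

    factor: str
    levels: list[int]
    point_paf: float
    ci_low: float
    ci_high: float
    bootstrap_reps: int
    successful_reps: int
    bias_correction_z0: float
    seed: int
    replicates: np.ndarray | None = None

    @property
    def valid(self) -> bool:
        return self.successful_reps >= 0.9 * self.bootstrap_reps


def bc_interval(replicates: np.ndarray, point: float, level: float = 0.95) -> tuple[float, float, float]:
    """Bias-corrected percentile interval; returns (low, high, z0).

    z0 corrects median bias of the bootstrap distribution relative to the
    point estimate; with a symmetric, median-unbiased distribution z0 = 0 and
    the interval reduces to the plain 2.5/97.5 percentile interval.
    """
    reps = np.asarray(replicates, dtype=float)
    reps = reps[np.isfinite(reps)]
    if reps.size < 2:
        raise DataError("too few bootstrap replicates for an interval")
    frac = np.mean(reps < point)
    # all replicates on one side of the point estimate: z0 unbounded
    frac = min(max(frac, 0.5 / reps.size), 1.0 - 0.5 / reps.size)
    z0 = float(norm.ppf(frac))
    zq = norm.ppf(1.0 - (1.0 - level) / 2.0)
    lo_q = float(norm.cdf(2.0 * z0 - zq))
    hi_q = float(norm.cdf(2.0 * z0 + zq))
    lo, hi = np.percentile(reps, [100.0 * lo_q, 100.0 * hi_q])
    return float(lo), float(hi), z0


def bootstrap_paf(
    data: StratumDataset,
    final_factors: list[str],
    factor_levels: list[int] | str,
    reps: int = 10_000,
    seed: int = 0,
    *,
    factor_name: str | None = None,
    estimation: str = "gee",
    max_failure_fraction: float = 0.10,
) -> PafEstimate:
    """PAF with a 95% BC interval from a mother-level cluster bootstrap.

    Mothers are resampled with replacement; every replicate refits the final
    model (same factor set — selection is NOT re-run) in the same estimation
    mode as the reported model (GEE by default) and recomputes the PAF.
    Replicates that fail to converge are dropped and counted; the estimate is
    invalid (raises) if more than ``max_failure_fraction`` of replicates
    fail.  A single integer ``seed`` fully determines the resampling.
    """
    if reps < 100:
        raise DataError("refusing to bootstrap with fewer than 100 replicates")
    sub = data.subset_factors(final_factors)
    fixed = 0.0 if estimation == "independence" else None
    point_res = gee_logistic(sub.y, sub.X, sub.cluster_ids, fixed_alpha=fixed)
    if not point_res.converged:
        raise DataError("point fit did not converge; no PAF")
    fit = GEEFit(result=point_res, dataset=sub)
    cols = _resolve_levels(fit, factor_levels)
    point = _paf_from(point_res.params, sub.X, cols)

    # pre-index rows by mother for fast replicate assembly
    clusters, codes = np.unique(sub.cluster_ids, return_inverse=True)
    order = np.argsort(codes, kind="stable")
    sizes = np.bincount(codes)
    starts = np.concatenate([[0], np.cumsum(sizes)])
    rows_sorted = order  # rows grouped by cluster
    G = clusters.size

    rng = np.random.default_rng(seed)
    values = np.full(reps, np.nan)
    y, X = sub.y, sub.X
    arangeG = np.arange(G)
    for r in range(reps):
        take = rng.integers(0, G, size=G)
        L = sizes[take]
        ends = np.cumsum(L)
        intra = np.arange(ends[-1]) - np.repeat(ends - L, L)
        idx = rows_sorted[np.repeat(starts[take], L) + intra]
        new_groups = np.repeat(arangeG, L)
        res = gee_logistic(
            y[idx], X[idx], new_groups,
            fixed_alpha=fixed, beta0=point_res.params, compute_cov=False,
        )
        if res.converged:
            values[r] = _paf_from(res.params, X[idx], cols)

    ok = np.isfinite(values)
    n_ok = int(ok.sum())
    if n_ok < (1.0 - max_failure_fraction) * reps:
        raise DataError(
            f"bootstrap invalid: only {n_ok}/{reps} replicates converged"
        )
    lo, hi, z0 = bc_interval(values[ok], point)
    if not (lo <= point <= hi):
        warnings.warn(
            f"BC interval [{lo:.3f}, {hi:.3f}] does not contain the point PAF "
            f"{point:.3f}; pathological bootstrap geometry"
        )
    name = factor_name or (factor_levels if isinstance(factor_levels, str) else "levels")
    return PafEstimate(
        factor=str(name),
        levels=cols,
        point_paf=point,
        ci_low=lo,
        ci_high=hi,
        bootstrap_reps=reps,
        successful_reps=n_ok,
        bias_correction_z0=z0,
        seed=seed,
        replicates=values,
    )
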