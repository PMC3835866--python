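"""Screening, VIF, backward elimination and adjusted-OR reporting."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from sgapaf.cohort import StratumDataset
from sgapaf.gee import GEEResult, gee_logistic
from sgapaf.selection import (
    GEEFit,
    SelectionConfig,
    adjusted_ors,
    backward_eliminate,
    compute_vif,
    fit_gee,
    univariate_screen,
)


def _frame_from_counts(n00, n01, n10, n11):
    """factor x outcome frame with given (factor, sga) cell counts."""
    rows = (
        [(False, False)] * n00 + [(False, True)] * n01
        + [(True, False)] * n10 + [(True, True)] * n11
    )
    return pd.DataFrame(rows, columns=["factor", "sga"])


def test_screen_chi_squared_on_2x2_table():
    """Pearson statistic on the (200,50 / 200,100) table is 12.222 (P=4.7e-4).

    Oracle: the textbook formula sum (O-E)^2/E computed by hand; the factor
    clears the P<0.10 entry bar.
    """
    df = _frame_from_counts(200, 50, 200, 100)
    res = univariate_screen(df, {"factor": "factor"})[0]
    assert res.statistic == pytest.approx(12.2222, abs=2e-4)
    assert res.p_value == pytest.approx(4.7224e-4, rel=1e-3)
    assert res.included


def test_screen_type_one_error_rate_near_ten_percent():
    """A null factor survives the P<0.10 screen in ~10% of replicates."""
    rng = np.random.default_rng(42)
    n, reps, kept = 10_000, 300, 0
    for _ in range(reps):
        df = pd.DataFrame({"factor": rng.random(n) < 0.3, "sga": rng.random(n) < 0.1})
        kept += univariate_screen(df, {"factor": "factor"})[0].included
    frac = kept / reps
    assert 0.10 - 4 * np.sqrt(0.09 / reps) < frac < 0.10 + 4 * np.sqrt(0.09 / reps)


def test_screen_zero_association_is_excluded():
    df = _frame_from_counts(300, 100, 300, 100)  # identical outcome distribution
    res = univariate_screen(df, {"factor": "factor"})[0]
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    assert not res.included


def test_screen_single_level_factor_warned_and_excluded():
    df = pd.DataFrame({"factor": [True] * 50, "sga": [False, True] * 25})
    with pytest.warns(UserWarning, match="single"):
        res = univariate_screen(df, {"factor": "factor"})[0]
    assert not res.included and res.note == "single level"


def test_vif_limits():
    rng = np.random.default_rng(0)
    n = 10_000
    a, b = rng.normal(0, 1, n), rng.normal(0, 1, n)
    v = compute_vif(np.column_stack([a, b]))
    assert np.allclose(v, 1.0, atol=0.05)  # orthogonal columns
    c = 0.9 * a + np.sqrt(1 - 0.81) * b  # corr(a, c) = 0.9
    v2 = compute_vif(np.column_stack([a, c]), ["a", "c"])
    assert v2["a"] == pytest.approx(1 / (1 - 0.81), rel=0.05)
    with pytest.warns(UserWarning, match="collinear"):
        v3 = compute_vif(np.column_stack([a, a]), ["a", "a_copy"])
    assert np.isinf(v3["a_copy"])


def _toy_dataset(seed, n_true=3, n_noise=5, n=20_000, log_or=0.7, prev=0.2):
    rng = np.random.default_rng(seed)
    cols, names, term_map = [np.ones(n)], ["Intercept"], {}
    eta = np.full(n, -2.4)
    for j in range(n_true + n_noise):
        x = (rng.random(n) < prev).astype(float)
        name = f"true{j}" if j < n_true else f"noise{j}"
        cols.append(x)
        names.append(name)
        term_map[name] = [j + 1]
        if j < n_true:
            eta += log_or * x
    y = (rng.random(n) < expit(eta)).astype(float)
    return StratumDataset("s", y, np.column_stack(cols), names, term_map,
                          np.arange(n), {}), [f"true{j}" for j in range(n_true)]


def test_backward_elimination_keeps_signal_drops_noise():
    data, true_names = _toy_dataset(seed=0)
    res = backward_eliminate(data, list(data.term_map), SelectionConfig())
    assert set(true_names) <= set(res.final_factors)
    noise_kept = [f for f in res.final_factors if f.startswith("noise")]
    assert len(noise_kept) <= 1


def test_single_significant_factor_terminates_immediately():
    data, _ = _toy_dataset(seed=1, n_true=1, n_noise=0)
    res = backward_eliminate(data, ["true0"], SelectionConfig())
    assert res.final_factors == ["true0"]
    assert all(s.action != "removed" for s in res.trace)


def test_final_set_insensitive_to_candidate_order():
    data, _ = _toy_dataset(seed=2)
    a = backward_eliminate(data, list(data.term_map), SelectionConfig())
    b = backward_eliminate(data, list(data.term_map)[::-1], SelectionConfig())
    assert a.final_factors == b.final_factors


def _confounder_dataset(seed=8, n=1500, bx=0.45, be=0.7):
    """Exposure driven by a confounder that also raises the outcome."""
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < 0.4).astype(float)
    e = (rng.random(n) < np.where(x == 1, 0.6, 0.15)).astype(float)
    y = (rng.random(n) < expit(-1.6 + bx * x + be * e)).astype(float)
    X = np.column_stack([np.ones(n), e, x])
    return StratumDataset("s", y, X, ["Intercept", "exposure", "confounder"],
                          {"exposure": [1], "confounder": [2]}, np.arange(n), {})


def test_confounder_retained_despite_nonsignificance():
    """The 10% change-in-aOR rule keeps a non-significant confounder.

    Oracle: two statsmodels fits (with/without the confounder) confirm the
    confounder's Wald P is above 0.01 while dropping it shifts the exposure
    aOR by more than 10%.
    """
    data = _confounder_dataset()
    full = sm.GLM(data.y, data.X, family=sm.families.Binomial()).fit()
    reduced = sm.GLM(data.y, data.X[:, :2], family=sm.families.Binomial()).fit()
    p_conf = full.pvalues[2]
    shift = abs(np.exp(reduced.params[1] - full.params[1]) - 1)
    assert p_conf >= 0.01 and shift >= 0.10  # scenario is as constructed
    res = backward_eliminate(data, ["exposure", "confounder"], SelectionConfig())
    assert "confounder" in res.final_factors
    assert res.confounders == ["confounder"]
    assert any(s.action == "kept_confounder" and s.factor == "confounder" for s in res.trace)


def test_interaction_pass_keeps_strong_product_term():
    rng = np.random.default_rng(3)
    n = 20_000
    a = (rng.random(n) < 0.4).astype(float)
    b = (rng.random(n) < 0.4).astype(float)
    y = (rng.random(n) < expit(-2.2 + 0.5 * a + 0.5 * b + 0.8 * a * b)).astype(float)
    X = np.column_stack([np.ones(n), a, b])
    data = StratumDataset("s", y, X, ["Intercept", "a", "b"],
                          {"a": [1], "b": [2]}, np.arange(n), {})
    cfg = SelectionConfig(candidate_interactions=(("a", "b"),))
    res = backward_eliminate(data, ["a", "b"], cfg)
    assert ("a", "b") in res.interactions


def test_adjusted_or_arithmetic_and_reference_rows():
    """aOR = exp(beta); 95% CI = exp(beta +/- 1.96 SE); references print 1.00."""
    n = 10
    ds = StratumDataset("s", np.zeros(n), np.column_stack([np.ones(n), np.zeros(n)]),
                        ["Intercept", "exposure"], {"exposure": [1]}, np.arange(n), {})
    res = GEEResult(
        params=np.array([-2.0, 0.8329]),
        cov_robust=np.diag([0.01, 0.08**2]),
        cov_naive=np.diag([0.01, 0.08**2]),
        alpha=0.0, scale=1.0, fitted=np.full(n, 0.1), converged=True,
        n_iter=3, n_clusters=n,
    )
    table = adjusted_ors(GEEFit(result=res, dataset=ds))
    ref = table[table["reference"]].iloc[0]
    lev = table[~table["reference"]].iloc[0]
    assert ref["aor"] == 1.00 and np.isnan(ref["ci_low"])
    assert lev["aor"] == pytest.approx(2.30, abs=0.005)
    assert lev["ci_low"] == pytest.approx(1.97, abs=0.005)
    assert lev["ci_high"] == pytest.approx(2.69, abs=0.005)


def test_null_coefficient_gives_unit_aor():
    n = 10
    ds = StratumDataset("s", np.zeros(n), np.column_stack([np.ones(n), np.zeros(n)]),
                        ["Intercept", "x"], {"x": [1]}, np.arange(n), {})
    res = GEEResult(np.array([-2.0, 0.0]), np.diag([0.01, 0.04]), np.diag([0.01, 0.04]),
                    0.0, 1.0, np.full(n, 0.1), True, 3, n)
    lev = adjusted_ors(GEEFit(res, ds)).iloc[1]
    assert lev["aor"] == pytest.approx(1.0)
    assert lev["ci_low"] == pytest.approx(np.exp(-1.959964 * 0.2), rel=1e-6)
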