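"""The cohort generator: calibration, reproducibility and truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from sgapaf._util import DataError
from sgapaf.cohort import apply_inclusion_filters
from sgapaf.growth import classify_sga
from sgapaf.simulate import (
    CohortConfig,
    FactorSpec,
    generate_cohort,
    marginal_logodds,
    simulate_stratum,
    true_marginal_paf,
)


def test_generation_is_bit_reproducible(standard):
    cfg = CohortConfig(n_mothers=500, seed=33)
    a, la = generate_cohort(cfg, standard)
    b, lb = generate_cohort(cfg, standard)
    pd.testing.assert_frame_equal(a, b)
    pd.testing.assert_frame_equal(la.frame, lb.frame)


def test_null_model_prevalence_matches_target(standard):
    specs = (FactorSpec("flat", prevalence=0.3, log_odds=0.0),)
    cfg = CohortConfig(
        n_mothers=20_000, factor_specs=specs, random_effect_sd=0.0,
        history_miscount_rate=0.0, seed=5,
    )
    _, ledger = generate_cohort(cfg, standard)
    study = ledger.frame[ledger.frame["is_study"]]
    prev = study["sga"].mean()
    se = np.sqrt(0.1 * 0.9 / len(study))
    assert abs(prev - 0.10) < 3 * se


def test_birth_multiplicity_matches_configured_split(standard):
    cfg = CohortConfig(n_mothers=20_000, seed=6, history_miscount_rate=0.0)
    df, ledger = generate_cohort(cfg, standard)
    study = df[ledger.frame["is_study"].to_numpy()]
    counts = study.groupby("mother_id").size().value_counts(normalize=True)
    se = np.sqrt(0.808 * 0.192 / 20_000)
    assert abs(counts[1] - 0.808) < 4 * se
    assert abs(counts[2] - 0.185) < 4 * np.sqrt(0.185 * 0.815 / 20_000)


def test_birthweights_on_grid_and_consistent_with_labels(small_cohort, standard):
    df, ledger, _ = small_cohort
    assert (np.mod(df["birthweight_grams"], 5) == 0).all()
    got = classify_sga(
        standard,
        df["birthweight_grams"].to_numpy(),
        df["gestational_weeks"].to_numpy(),
        df["sex"].to_numpy(),
    )
    assert (got == ledger.frame["sga"].to_numpy()).all()


def test_preterm_rate_near_configured_value(small_cohort):
    df, ledger, cfg = small_cohort
    frac = (df["gestational_weeks"] < 37).mean()
    assert abs(frac - cfg.preterm_rate) < 4 * np.sqrt(0.052 * 0.948 / len(df))


def test_records_pass_filters_except_deliberate_corruption(small_cohort):
    df, ledger, cfg = small_cohort
    _, tally = apply_inclusion_filters(df)
    assert tally.multiple_pregnancy == 0 and tally.stillbirth == 0
    assert tally.gestation_out_of_range == 0
    rate = tally.incomplete_history / tally.n_study_births
    assert abs(rate - cfg.history_miscount_rate) < 3 * np.sqrt(0.05 * 0.95 / 2000)


def test_within_mother_correlation_matches_latent_model(standard):
    """Observed within-mother outcome correlation matches the random-intercept
    model's implied value (oracle: Gauss-Hermite integration of the joint
    Bernoulli moments over the N(0, sd) intercept)."""
    sd = 0.8
    specs = (FactorSpec("flat", prevalence=0.3, log_odds=0.0),)
    cfg = CohortConfig(
        n_mothers=40_000, factor_specs=specs, random_effect_sd=sd,
        births_per_mother_probs=(0.0, 1.0, 0.0), history_miscount_rate=0.0,
        prior_births_probs=(1.0,), seed=7,
    )
    _, ledger = generate_cohort(cfg, standard)
    f = ledger.frame
    y = f["sga"].to_numpy().astype(float)
    pair = y.reshape(-1, 2)
    r_obs = np.corrcoef(pair[:, 0], pair[:, 1])[0, 1]
    # oracle: implied observable ICC from the latent model
    x, w = np.polynomial.hermite.hermgauss(80)
    w = w / np.sqrt(np.pi)
    u = np.sqrt(2.0) * sd * x
    c = ledger.baseline
    pbar = float(w @ expit(c + u))
    p11 = float(w @ expit(c + u) ** 2)
    icc = (p11 - pbar**2) / (pbar * (1 - pbar))
    assert r_obs == pytest.approx(icc, abs=0.02)


def test_true_paf_zero_for_null_factor_and_closed_form_identity(standard):
    specs = (FactorSpec("exposure", prevalence=0.3, log_odds=0.8, modifiable=True),
             FactorSpec("null", prevalence=0.2, log_odds=0.0, modifiable=True))
    cfg = CohortConfig(
        n_mothers=5_000, factor_specs=specs, random_effect_sd=0.0,
        history_miscount_rate=0.0, seed=8,
    )
    _, ledger = generate_cohort(cfg, standard)
    assert ledger.true_marginal_paf("null") == pytest.approx(0.0, abs=1e-12)
    # with no random effect and no other covariates, the truth is the
    # Miettinen closed form on the expected 2x2 table of the included births
    from sgapaf.paf import closed_form_af

    f = ledger.frame[ledger.frame["is_study"] & ledger.frame["included"]]
    exp_mask = f["p"] > f["p_cf_exposure"]
    n1, n0 = int(exp_mask.sum()), int((~exp_mask).sum())
    k1, k0 = float(f.loc[exp_mask, "p"].sum()), float(f.loc[~exp_mask, "p"].sum())
    assert ledger.true_marginal_paf("exposure") == pytest.approx(
        closed_form_af(k1, n1, k0, n0), abs=1e-9
    )


def test_true_paf_increases_with_prevalence(standard):
    pafs = []
    for prev in (0.1, 0.25):
        specs = (FactorSpec("exposure", prevalence=prev, log_odds=0.8, modifiable=True),)
        cfg = CohortConfig(n_mothers=8_000, factor_specs=specs, seed=9,
                           history_miscount_rate=0.0)
        _, ledger = generate_cohort(cfg, standard)
        pafs.append(ledger.true_marginal_paf("exposure"))
    assert pafs[0] < pafs[1]


def test_unknown_factor_raises(small_cohort):
    _, ledger, _ = small_cohort
    with pytest.raises(DataError):
        true_marginal_paf(ledger, "not_simulated")


def test_infeasible_prevalence_target_raises(standard):
    cfg = CohortConfig(n_mothers=200, baseline_sga_target=1.0, seed=1)
    with pytest.raises((DataError, ValueError)):
        generate_cohort(cfg, standard)


def test_marginal_logodds_attenuation():
    cond = 0.8
    assert marginal_logodds(-2.2, cond, 0.0) == pytest.approx(cond, abs=1e-9)
    att = marginal_logodds(-2.2, cond, 1.0)
    assert 0 < att < cond


def test_simulate_stratum_truths_are_internally_consistent():
    data, truth = simulate_stratum(2000, [("e", 0.3, 0.7)], seed=12)
    assert data.X.shape[1] == 2 and data.y.size == truth["n_births"]
    assert 0 < truth["paf_e"] < 100
    assert truth["marginal_logodds_e"] < 0.7
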