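"""Inclusion filters, history completeness and derived obstetric covariates."""

import numpy as np
import pandas as pd
import pytest

from sgapaf._util import DataError
from sgapaf.cohort import (
    DEFAULT_WINDOWS,
    apply_inclusion_filters,
    check_complete_history,
    derive_obstetric_history,
    add_sga_labels,
    stratify,
    stratum_of,
)


def _birth(mother="m1", date="2008-03-01", plurality="singleton", vital="livebirth",
           ga=39, sex="male", bw=3300.0, reported=0, cs=False, diabetes=False):
    return {
        "mother_id": mother,
        "birth_date": pd.Timestamp(date),
        "plurality": plurality,
        "vital_status": vital,
        "gestational_weeks": ga,
        "sex": sex,
        "birthweight_grams": bw,
        "reported_previous_pregnancies": reported,
        "caesarean_section": cs,
        "diabetes": diabetes,
    }


def test_complete_history_true_when_reported_matches_linked_births():
    df = pd.DataFrame([
        _birth(date="2000-05-01", reported=0),
        _birth(date="2004-02-01", reported=1),
        _birth(date="2008-03-01", reported=2),
    ])
    assert check_complete_history(df) is True


def test_complete_history_false_on_reported_miscount():
    df = pd.DataFrame([
        _birth(date="2004-02-01", reported=0),
        _birth(date="2008-03-01", reported=3),  # only 1 linked prior record
    ])
    assert check_complete_history(df) is False


def test_complete_history_rejects_unsorted_and_duplicate_dates():
    df = pd.DataFrame([_birth(date="2008-03-01"), _birth(date="2004-02-01")])
    with pytest.raises(DataError):
        check_complete_history(df)
    dup = pd.DataFrame([_birth(date="2008-03-01"), _birth(date="2008-03-01")])
    with pytest.raises(DataError):
        check_complete_history(dup)


def test_inclusion_filters_tally_by_rule_in_order():
    """10 records, 3 violating exactly one rule each -> 7 kept, tally 1/1/1/0."""
    records = [_birth(mother=f"m{i}", date=f"2008-0{1 + i % 9}-15") for i in range(7)]
    records.append(_birth(mother="t1", date="2008-05-01", plurality="multiple"))
    records.append(_birth(mother="t2", date="2008-06-01", vital="stillbirth"))
    records.append(_birth(mother="t3", date="2008-07-01", ga=23, bw=550.0))
    df = pd.DataFrame(records)
    kept, tally = apply_inclusion_filters(df)
    assert len(kept) == 7
    assert tally.n_study_births == 10
    assert (tally.multiple_pregnancy, tally.stillbirth,
            tally.gestation_out_of_range, tally.incomplete_history) == (1, 1, 1, 0)


def test_incomplete_history_drops_all_of_the_mothers_births():
    df = pd.DataFrame([
        _birth(mother="a", date="2007-03-01", reported=0),
        _birth(mother="a", date="2009-06-01", reported=2),  # miscount
        _birth(mother="b", date="2008-01-01", reported=0),
    ])
    kept, tally = apply_inclusion_filters(df)
    assert list(kept["mother_id"]) == ["b"]
    assert tally.incomplete_history == 2


def test_filters_are_idempotent(small_cohort):
    df, _, _ = small_cohort
    once, t1 = apply_inclusion_filters(df)
    twice, t2 = apply_inclusion_filters(once)
    assert once.equals(twice)
    assert t2.multiple_pregnancy == t2.stillbirth == t2.gestation_out_of_range == 0


def test_first_birth_has_empty_history(standard):
    df = pd.DataFrame([_birth(date="2008-03-01")])
    hist = derive_obstetric_history(df, standard)
    row = hist.iloc[0]
    assert row["parity"] == 0 and row["prev_sga"] == 0 and row["prev_preterm"] == 0
    assert np.isnan(row["interpregnancy_interval_months"])
    assert row["interval_category"] == "6-41_months_or_nulliparous"


def test_prior_preterm_sga_birth_counts_in_both_columns(standard):
    prior = _birth(date="2005-03-01", ga=35, bw=1500.0, reported=0)  # preterm and SGA
    current = _birth(date="2008-03-01", reported=1)
    hist = derive_obstetric_history(pd.DataFrame([prior, current]), standard)
    row = hist.loc[1]
    assert row["parity"] == 1
    assert row["prev_preterm"] == 1
    assert row["prev_sga"] == 1
    assert row["interval_category"] == "6-41_months_or_nulliparous"
    months = row["interpregnancy_interval_months"]
    assert months == pytest.approx((1096 - 273 - 0) / 30.4375, abs=1.0)


def test_negative_interval_raises(standard):
    df = pd.DataFrame([
        _birth(date="2008-01-01", reported=0),
        _birth(date="2008-06-01", ga=40, reported=1),  # conception before prior birth
    ])
    with pytest.raises(DataError, match="negative"):
        derive_obstetric_history(df, standard)


def test_derived_history_matches_generator_ledger(small_cohort, standard):
    df, ledger, _ = small_cohort
    hist = derive_obstetric_history(df, standard)
    truth = ledger.frame.loc[hist.index]
    for col in ["parity", "prev_preterm", "prev_stillbirths", "prev_caesareans", "prev_sga"]:
        assert (hist[col].to_numpy() == truth[col].to_numpy()).all(), col


def test_history_is_prefix_consistent(standard):
    """Appending a later birth never changes earlier births' history."""
    rows = [
        _birth(date="2000-05-01", reported=0),
        _birth(date="2004-02-01", ga=35, bw=1600.0, reported=1),
        _birth(date="2008-03-01", reported=2),
    ]
    base = derive_obstetric_history(pd.DataFrame(rows[:2] + rows[2:]), standard)
    extended_rows = rows + [_birth(date="2010-06-01", reported=3)]
    ext = derive_obstetric_history(pd.DataFrame(extended_rows), standard)
    shared = base.index.intersection(ext.index)
    pd.testing.assert_frame_equal(base.loc[shared], ext.loc[shared])


def test_completeness_pass_rate_tracks_miscount_rate(small_cohort):
    df, ledger, cfg = small_cohort
    _, tally = apply_inclusion_filters(df)
    observed = tally.n_included / tally.n_study_births
    expected = 1.0 - cfg.history_miscount_rate
    se = np.sqrt(cfg.history_miscount_rate * expected / tally.n_study_births) * 2.5
    assert abs(observed - expected) < 3 * np.sqrt(expected * (1 - expected) / 2000) + se


def test_stratification_rules_and_partition(small_cohort, standard):
    df, ledger, _ = small_cohort
    kept, _ = apply_inclusion_filters(df)
    labelled = add_sga_labels(kept, standard)
    strata = stratify(labelled)
    sizes = {k: len(v) for k, v in strata.items()}
    assert sum(sizes.values()) == len(labelled)
    idx = [set(v.index) for v in strata.values()]
    assert not (idx[0] & idx[1]) and not (idx[0] & idx[2]) and not (idx[1] & idx[2])
    # a preterm diabetic mother's birth goes to the preterm stratum
    lab = stratum_of(labelled)
    pre_diab = labelled[(labelled["gestational_weeks"] == 36) & labelled["diabetes"]]
    assert (lab.loc[pre_diab.index] == "preterm").all()
    term_nd = labelled[(labelled["gestational_weeks"] == 39) & ~labelled["diabetes"]]
    assert (lab.loc[term_nd.index] == "term_nondiabetic").all()
    # generator agrees
    truth = ledger.frame.loc[labelled.index, "stratum"]
    assert (lab.to_numpy() == truth.to_numpy()).all()
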