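"""From raw linked birth records to analysis-ready stratum datasets.

The input is one row per birth, keyed by ``mother_id``, spanning both the
study window (the births being analysed) and a longer lookback window whose
records exist only to supply each mother's obstetric history.  This module

* verifies complete obstetric histories (a mother's self-reported count of
  previous pregnancies must agree with her linked prior birth records at
  every study-window birth),
* applies the inclusion filters (singleton, livebirth, 24-44 completed
  weeks, complete history) with a reproducible exclusion tally,
* derives history covariates (parity, inter-pregnancy interval, previous
  caesarean / preterm / stillbirth / SGA counts) from strictly earlier
  births, and
* partitions included births into the three analysis strata: preterm,
  term with a diabetic mother, term with a non-diabetic mother.

Records travel as a pandas DataFrame with the column schema in
``STRUCTURAL_COLUMNS`` plus arbitrary covariate columns; `read_cohort` /
`write_cohort` round-trip the comma-separated text representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import DataError
from .growth import GrowthStandard, classify_sga

DAYS_PER_MONTH = 30.4375

#: columns every birth record must carry; anything else is a covariate
STRUCTURAL_COLUMNS = [
    "mother_id",
    "birth_date",
    "plurality",
    "vital_status",
    "gestational_weeks",
    "sex",
    "birthweight_grams",
    "reported_previous_pregnancies",
    "caesarean_section",
]

PRETERM_WEEKS = 37  # <37 completed weeks; the universal obstetric convention
GA_MIN, GA_MAX = 24, 44

STRATA = ("preterm", "term_diabetic", "term_nondiabetic")


@dataclass(frozen=True)
class StudyWindows:
    """Calendar windows: analysis births vs obstetric-history lookback."""

    study_start: pd.Timestamp = pd.Timestamp("2007-01-01")
    study_end: pd.Timestamp = pd.Timestamp("2010-12-31")
    history_start: pd.Timestamp = pd.Timestamp("1994-01-01")


DEFAULT_WINDOWS = StudyWindows()


@dataclass
class ExclusionTally:
    """Births removed per inclusion rule, in the order the rules are applied."""

    n_study_births: int = 0
    multiple_pregnancy: int = 0
    stillbirth: int = 0
    gestation_out_of_range: int = 0
    incomplete_history: int = 0
    n_included: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("study-window births", self.n_study_births),
            ("excluded: multiple pregnancy", self.multiple_pregnancy),
            ("excluded: stillbirth", self.stillbirth),
            ("excluded: gestation outside 24-44 weeks", self.gestation_out_of_range),
            ("excluded: incomplete obstetric history", self.incomplete_history),
            ("included births", self.n_included),
        ]
        return pd.DataFrame(rows, columns=["rule", "count"])


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["birth_date"])
    missing = [c for c in STRUCTURAL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"cohort file lacks required columns: {missing}")
    _validate_records(df)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["birth_date"] = pd.to_datetime(out["birth_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def _validate_records(df: pd.DataFrame) -> None:
    ga = df["gestational_weeks"]
    if (ga < 20).any():
        raise DataError("records with gestational age < 20 weeks are outside registry scope")
    bw = df["birthweight_grams"]
    if (bw <= 0).any():
        raise DataError("non-positive birthweight")
    off_grid = np.abs(np.mod(bw, 5)) > 1e-9
    if off_grid.any():
        bad = df.loc[off_grid, "birthweight_grams"].iloc[0]
        raise DataError(f"birthweight {bad} g not on the 5 g recording grid")


def _sorted_by_mother(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["mother_id", "birth_date"], kind="mergesort")


def check_complete_history(
    births_of_one_mother: pd.DataFrame, windows: StudyWindows = DEFAULT_WINDOWS
) -> bool:
    """True iff the reported previous-pregnancy count matches linked records.

    At every study-window birth, ``reported_previous_pregnancies`` must equal
    the number of this mother's linked births strictly earlier and within the
    lookback window.  Input must be date-sorted; duplicate birth dates are a
    data error.
    """
    df = births_of_one_mother
    dates = pd.to_datetime(df["birth_date"])
    if not dates.is_monotonic_increasing:
        raise DataError("births of one mother must be sorted by date")
    if dates.duplicated().any():
        raise DataError(
            f"duplicate birth dates for mother {df['mother_id'].iloc[0]!r}"
        )
    in_window = dates >= windows.history_start
    prior_count = in_window.cumsum() - in_window.astype(int)
    is_study = (dates >= windows.study_start) & (dates <= windows.study_end)
    reported = df["reported_previous_pregnancies"].to_numpy()
    return bool(np.all(reported[is_study.to_numpy()] == prior_count.to_numpy()[is_study.to_numpy()]))


def _complete_history_mask(df: pd.DataFrame, windows: StudyWindows) -> pd.Series:
    """Per-row mother-level completeness flag (vectorised over all mothers)."""
    d = _sorted_by_mother(df)
    dates = pd.to_datetime(d["birth_date"])
    if d.duplicated(["mother_id", "birth_date"]).any():
        bad = d.loc[d.duplicated(["mother_id", "birth_date"]), "mother_id"].iloc[0]
        raise DataError(f"duplicate birth dates for mother {bad!r}")
    in_window = (dates >= windows.history_start).astype(int)
    prior = in_window.groupby(d["mother_id"], sort=False).cumsum() - in_window
    is_study = (dates >= windows.study_start) & (dates <= windows.study_end)
    ok_row = ~is_study | (d["reported_previous_pregnancies"] == prior)
    mother_ok = ok_row.groupby(d["mother_id"], sort=False).transform("all")
    return mother_ok.reindex(df.index)


def apply_inclusion_filters(
    df: pd.DataFrame, windows: StudyWindows = DEFAULT_WINDOWS
) -> tuple[pd.DataFrame, ExclusionTally]:
    """Select the analysis births and tally exclusions rule by rule.

    Rules are applied in a fixed order so the tally is reproducible:
    plurality -> vital status -> gestational age -> complete history.  A
    mother failing the history check has *all* her study births removed.
    History-window rows are never part of the output; they only feed the
    completeness check and the derived history covariates.  The completeness
    verdict is stored on the output as ``history_complete`` (and trusted on
    re-application, since the lookback rows needed to recompute it are gone),
    which makes the filter idempotent.
    """
    _validate_records(df)
    if "history_complete" in df.columns:
        complete_mask = df["history_complete"].astype(bool)
    else:
        complete_mask = _complete_history_mask(df, windows)
    df = df.assign(history_complete=complete_mask)
    dates = pd.to_datetime(df["birth_date"])
    study = df[(dates >= windows.study_start) & (dates <= windows.study_end)]
    tally = ExclusionTally(n_study_births=len(study))

    keep = study["plurality"].eq("singleton")
    tally.multiple_pregnancy = int((~keep).sum())
    study = study[keep]

    keep = study["vital_status"].eq("livebirth")
    tally.stillbirth = int((~keep).sum())
    study = study[keep]

    keep = study["gestational_weeks"].between(GA_MIN, GA_MAX)
    tally.gestation_out_of_range = int((~keep).sum())
    study = study[keep]

    complete = study["history_complete"].astype(bool)
    tally.incomplete_history = int((~complete).sum())
    study = study[complete]

    tally.n_included = len(study)
    return study, tally


INTERVAL_REFERENCE = "6-41_months_or_nulliparous"
INTERVAL_EXTREME = "lt6_or_ge42_months"


def derive_obstetric_history(
    df: pd.DataFrame,
    standard: GrowthStandard,
    windows: StudyWindows = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """History covariates for every study-window birth, from earlier births.

    For each birth the counts run over that mother's strictly earlier linked
    births (study or lookback window): parity, previous caesareans, previous
    preterm (<37 weeks), previous stillbirths, and previous SGA infants
    (classified against ``standard``; unclassifiable prior births - those
    outside 24-44 weeks or stillborn - count as non-SGA).  The
    inter-pregnancy interval runs from the immediately preceding birth to the
    conception of the current pregnancy (birth date minus gestation), in
    months, and is binned as in the analysis: 6-41 months or nulliparous
    (reference) vs <6 or >=42 months.
    """
    d = _sorted_by_mother(df)
    dates = pd.to_datetime(d["birth_date"])
    mid = d["mother_id"]

    classifiable = (
        d["vital_status"].eq("livebirth")
        & d["gestational_weeks"].between(GA_MIN, GA_MAX)
    ).to_numpy()
    sga = np.zeros(len(d), dtype=bool)
    if classifiable.any():
        sga[classifiable] = classify_sga(
            standard,
            d.loc[classifiable, "birthweight_grams"].to_numpy(),
            d.loc[classifiable, "gestational_weeks"].to_numpy(),
            d.loc[classifiable, "sex"].to_numpy(),
        )

    def prior_counts(indicator: np.ndarray) -> np.ndarray:
        s = pd.Series(indicator.astype(int), index=d.index)
        return (s.groupby(mid, sort=False).cumsum() - s).to_numpy()

    ones = np.ones(len(d))
    hist = pd.DataFrame(index=d.index)
    hist["parity"] = prior_counts(ones).astype(int)
    hist["prev_caesareans"] = prior_counts(d["caesarean_section"].to_numpy(dtype=bool))
    hist["prev_preterm"] = prior_counts((d["gestational_weeks"] < PRETERM_WEEKS).to_numpy())
    hist["prev_stillbirths"] = prior_counts(d["vital_status"].eq("stillbirth").to_numpy())
    hist["prev_sga"] = prior_counts(sga)
    hist["nulliparous"] = hist["parity"].eq(0)

    prev_date = dates.groupby(mid, sort=False).shift(1)
    conception = dates - pd.to_timedelta(d["gestational_weeks"] * 7, unit="D")
    interval_days = (conception - prev_date).dt.days
    interval_months = interval_days / DAYS_PER_MONTH
    if (interval_months.dropna() < 0).any():
        bad = mid[interval_months < 0].iloc[0]
        raise DataError(
            f"negative inter-pregnancy interval for mother {bad!r}: inconsistent dates"
        )
    hist["interpregnancy_interval_months"] = interval_months
    in_ref = hist["nulliparous"] | interval_months.between(6, 42, inclusive="left")
    hist["interval_category"] = np.where(in_ref, INTERVAL_REFERENCE, INTERVAL_EXTREME)

    is_study = ((dates >= windows.study_start) & (dates <= windows.study_end)).to_numpy()
    hist = hist.loc[d.index[is_study]]
    return hist.loc[df.index[df.index.isin(hist.index)]]


def add_sga_labels(df: pd.DataFrame, standard: GrowthStandard) -> pd.DataFrame:
    """Return a copy with a boolean ``sga`` outcome column."""
    out = df.copy()
    out["sga"] = classify_sga(
        standard,
        df["birthweight_grams"].to_numpy(),
        df["gestational_weeks"].to_numpy(),
        df["sex"].to_numpy(),
    )
    return out


def stratum_of(df: pd.DataFrame) -> pd.Series:
    """Stratum label per included birth (requires a boolean diabetes column)."""
    preterm = df["gestational_weeks"] < PRETERM_WEEKS
    diab = df["diabetes"].astype(bool)
    return pd.Series(
        np.where(preterm, "preterm", np.where(diab, "term_diabetic", "term_nondiabetic")),
        index=df.index,
        name="stratum",
    )


def stratify(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition included, SGA-labelled births into the three analysis strata.

    Preterm births form one stratum regardless of maternal diabetes (diabetes
    is a covariate there); term births split by the diabetes flag.
    """
    labels = stratum_of(df)
    return {name: df[labels == name] for name in STRATA}


# ---------------------------------------------------------------------------
# design-matrix construction


@dataclass(frozen=True)
class FactorCoding:
    """Declarative coding of one model factor.

    ``column`` is the cohort column; ``levels`` the non-reference levels in
    display order (omit for boolean columns, which code True vs False); the
    ``reference`` level prints as aOR 1.00.  ``collapse`` optionally maps raw
    values onto analysis levels first (e.g. quintiles 1-4 -> "Q1-4").
    """

    name: str
    column: str
    reference: object = False
    levels: tuple = ()
    collapse: dict = field(default_factory=dict, hash=False)

    def encode(self, series: pd.Series) -> tuple[np.ndarray, list[str]]:
        vals = series.map(lambda v: self.collapse.get(v, v)) if self.collapse else series
        if not self.levels:  # boolean factor
            return vals.astype(bool).to_numpy(dtype=float)[:, None], [self.name]
        cols, names = [], []
        observed = set(vals.unique())
        for lev in self.levels:
            if lev == self.reference:
                continue
            if lev not in observed:
                continue  # absent level contributes no column
            cols.append(vals.eq(lev).to_numpy(dtype=float))
            names.append(f"{self.name}[{lev}]")
        if not cols:
            raise DataError(f"factor {self.name!r}: no non-reference level observed")
        return np.column_stack(cols), names


@dataclass
class StratumDataset:
    """Design matrix, outcome and cluster keys for one analysis stratum."""

    stratum: str
    y: np.ndarray
    X: np.ndarray
    colnames: list[str]
    term_map: dict[str, list[int]]
    cluster_ids: np.ndarray
    codings: dict[str, FactorCoding]
    frame: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return self.y.size

    def columns_for(self, factors: list[str]) -> list[int]:
        return [j for f in factors for j in self.term_map[f]]

    def subset_factors(self, factors: list[str]) -> "StratumDataset":
        """Dataset restricted to the intercept plus the named factors."""
        cols = [0] + self.columns_for(factors)
        term_map: dict[str, list[int]] = {}
        pos = 1
        for f in factors:
            k = len(self.term_map[f])
            term_map[f] = list(range(pos, pos + k))
            pos += k
        return StratumDataset(
            stratum=self.stratum,
            y=self.y,
            X=self.X[:, cols],
            colnames=[self.colnames[j] for j in cols],
            term_map=term_map,
            cluster_ids=self.cluster_ids,
            codings={f: self.codings[f] for f in factors if f in self.codings},
            frame=self.frame,
        )


def make_stratum_dataset(
    df: pd.DataFrame, stratum: str, factors: list[FactorCoding]
) -> StratumDataset:
    """Build the intercept-plus-dummies design for one stratum's births."""
    if "sga" not in df.columns:
        raise DataError("dataframe needs an 'sga' outcome column (run add_sga_labels)")
    n = len(df)
    blocks = [np.ones((n, 1))]
    colnames = ["Intercept"]
    term_map: dict[str, list[int]] = {}
    pos = 1
    for fc in factors:
        block, names = fc.encode(df[fc.column])
        blocks.append(block)
        colnames.extend(names)
        term_map[fc.name] = list(range(pos, pos + block.shape[1]))
        pos += block.shape[1]
    return StratumDataset(
        stratum=stratum,
        y=df["sga"].to_numpy(dtype=float),
        X=np.hstack(blocks),
        colnames=colnames,
        term_map=term_map,
        cluster_ids=df["mother_id"].to_numpy(),
        codings={fc.name: fc for fc in factors},
        frame=df,
    )
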