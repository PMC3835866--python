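"""End-to-end orchestration: cohort -> strata -> models -> PAF tables.

Stages are pure functions over files/frames so runs are resumable and
deterministic given the configured seeds: ``simulate`` (or ingest) ->
``build`` (filters, history covariates, SGA labels) -> ``select`` (screen +
backward elimination per stratum) -> ``fit`` (final GEE, adjusted ORs) ->
``paf`` (bootstrap intervals for modifiable factors) -> ``report`` (tables
in the conventional stratified layout plus a JSON manifest).
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import DataError, percentage
from .cohort import (
    DEFAULT_WINDOWS,
    STRATA,
    FactorCoding,
    StudyWindows,
    add_sga_labels,
    apply_inclusion_filters,
    derive_obstetric_history,
    make_stratum_dataset,
    read_cohort,
    stratify,
)
from .growth import GrowthStandard, load_standard, make_synthetic_standard, write_standard
from .paf import bootstrap_paf, model_paf
from .selection import (
    SelectionConfig,
    adjusted_ors,
    backward_eliminate,
    compute_vif,
    fit_gee,
    univariate_screen,
)
from .simulate import CohortConfig, generate_cohort

PREV_SGA_LEVELS = ("0", "1", "2+")


def default_factor_codings(stratum: str) -> list[FactorCoding]:
    """Per-stratum codings for the default synthetic risk-factor set.

    Socio-economic quintiles are collapsed differently by stratum (a coarser
    split where the stratum is small), mirroring how sparse strata are
    handled in practice; maternal diabetes is a covariate only in the
    preterm stratum (it is the stratifier for term births).
    """
    if stratum == "term_nondiabetic":
        ses = FactorCoding(
            "socioeconomic_group",
            "socioeconomic_quintile",
            reference="Q1-3",
            levels=("Q1-3", "Q4", "Q5"),
            collapse={1: "Q1-3", 2: "Q1-3", 3: "Q1-3", 4: "Q4", 5: "Q5"},
        )
    else:
        ses = FactorCoding(
            "socioeconomic_group",
            "socioeconomic_quintile",
            reference="Q1-4",
            levels=("Q1-4", "Q5"),
            collapse={1: "Q1-4", 2: "Q1-4", 3: "Q1-4", 4: "Q1-4", 5: "Q5"},
        )
    codings = [
        FactorCoding("smoking", "smoking"),
        FactorCoding("illicit_drug_abuse", "illicit_drug_abuse"),
        FactorCoding("pregnancy_hypertension", "pregnancy_hypertension"),
        FactorCoding("country_of_birth", "country_of_birth_non_australian"),
        ses,
        FactorCoding("nulliparous", "nulliparous"),
        # the sparse strata get a coarser previous-SGA split (the richest
        # stratum supports the full 0 / 1 / 2+ dose-response coding)
        FactorCoding(
            "previous_sga",
            "prev_sga_cat",
            reference="0",
            levels=PREV_SGA_LEVELS if stratum == "term_nondiabetic" else ("0", "1+"),
            collapse={} if stratum == "term_nondiabetic" else {"1": "1+", "2+": "1+"},
        ),
        FactorCoding(
            "interpregnancy_interval",
            "interval_category",
            reference="6-41_months_or_nulliparous",
            levels=("6-41_months_or_nulliparous", "lt6_or_ge42_months"),
        ),
        FactorCoding("aboriginality", "aboriginality"),
    ]
    if stratum == "preterm":
        codings.append(FactorCoding("diabetes", "diabetes"))
    return codings


DEFAULT_MODIFIABLE = ("smoking", "illicit_drug_abuse", "pregnancy_hypertension")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serialisable)."""

    mode: str = "synthetic"  # or "file"
    cohort_path: str | None = None
    standard_path: str | None = None
    outdir: str = "results/run"
    seed: int = 0
    bootstrap_reps: int = 10_000
    cohort: CohortConfig = field(default_factory=CohortConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    modifiable_factors: tuple[str, ...] = DEFAULT_MODIFIABLE

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "file"):
            raise ValueError("mode must be 'synthetic' or 'file'")
        if self.mode == "file" and not self.cohort_path:
            raise ValueError("file mode needs cohort_path")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort" in raw:
            raw["cohort"] = CohortConfig(**raw["cohort"])
        if "selection" in raw:
            raw["selection"] = SelectionConfig(**raw["selection"])
        if "modifiable_factors" in raw:
            raw["modifiable_factors"] = tuple(raw["modifiable_factors"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# cohort summaries


@dataclass
class CohortSummary:
    """The headline counts and one-decimal percentages of a built cohort."""

    n_births: int
    n_mothers: int
    n_preterm: int
    n_term: int
    pct_preterm: float
    pct_term: float
    n_sga: int
    sga_by_stratum: dict[str, int]
    pct_sga_by_stratum: dict[str, float]
    mothers_by_birth_count: dict[int, int]
    pct_mothers_by_birth_count: dict[int, float]

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("births", self.n_births, ""),
            ("mothers", self.n_mothers, ""),
            ("preterm births", self.n_preterm, self.pct_preterm),
            ("term births", self.n_term, self.pct_term),
            ("SGA births", self.n_sga, ""),
        ]
        for s in STRATA:
            rows.append(
                (f"SGA: {s}", self.sga_by_stratum.get(s, 0), self.pct_sga_by_stratum.get(s))
            )
        for k in sorted(self.mothers_by_birth_count):
            rows.append(
                (
                    f"mothers with {k} birth(s)",
                    self.mothers_by_birth_count[k],
                    self.pct_mothers_by_birth_count[k],
                )
            )
        return pd.DataFrame(rows, columns=["quantity", "count", "percent"])


def stratum_shares(sga_counts: dict[str, int]) -> dict[str, float]:
    """Each stratum's SGA count as a percentage of all SGA births."""
    total = sum(sga_counts.values())
    return {k: percentage(v, total) for k, v in sga_counts.items()}


def multiplicity_shares(mother_counts: dict[int, int]) -> dict[int, float]:
    """Share of mothers by number of study-window births."""
    total = sum(mother_counts.values())
    return {k: percentage(v, total) for k, v in mother_counts.items()}


def summarize_cohort(labelled: pd.DataFrame) -> CohortSummary:
    """Counts and percentages of an included, SGA-labelled cohort."""
    from .cohort import stratum_of

    preterm = labelled["gestational_weeks"] < 37
    sga = labelled["sga"].astype(bool)
    strata = stratum_of(labelled)
    sga_by = {s: int((sga & strata.eq(s)).sum()) for s in STRATA}
    per_mother = labelled.groupby("mother_id").size()
    # mothers with >=3 births reported as one class, as in registry summaries
    mult = per_mother.clip(upper=3).value_counts().to_dict()
    n = len(labelled)
    return CohortSummary(
        n_births=n,
        n_mothers=int(per_mother.size),
        n_preterm=int(preterm.sum()),
        n_term=int((~preterm).sum()),
        pct_preterm=percentage(int(preterm.sum()), n),
        pct_term=percentage(int((~preterm).sum()), n),
        n_sga=int(sga.sum()),
        sga_by_stratum=sga_by,
        pct_sga_by_stratum=stratum_shares(sga_by) if sga.sum() else {},
        mothers_by_birth_count={int(k): int(v) for k, v in sorted(mult.items())},
        pct_mothers_by_birth_count=multiplicity_shares(
            {int(k): int(v) for k, v in mult.items()}
        ),
    )


# ---------------------------------------------------------------------------
# stages


def build_cohort(
    df: pd.DataFrame,
    standard: GrowthStandard,
    windows: StudyWindows = DEFAULT_WINDOWS,
):
    """Filters + history covariates + SGA labels; returns (frame, tally).

    The returned frame has one row per included study birth, with derived
    history columns (``parity``, ``nulliparous``, ``prev_sga_cat``,
    ``interval_category``, ...) and the boolean ``sga`` outcome.
    """
    included, tally = apply_inclusion_filters(df, windows)
    hist = derive_obstetric_history(df, standard, windows).loc[included.index]
    merged = included.join(hist)
    merged["prev_sga_cat"] = np.where(
        merged["prev_sga"] >= 2, "2+", merged["prev_sga"].astype(str)
    )
    return add_sga_labels(merged, standard), tally


def analyse_stratum(
    labelled_stratum: pd.DataFrame,
    stratum: str,
    selection: SelectionConfig,
    modifiable: tuple[str, ...],
    bootstrap_reps: int,
    seed: int,
    codings: list[FactorCoding] | None = None,
):
    """Screen, select, fit and bootstrap one stratum; returns a result dict."""
    codings = codings or default_factor_codings(stratum)
    factor_cols = {fc.name: fc.column for fc in codings}
    screen = univariate_screen(labelled_stratum, factor_cols, selection)
    # a factor level with an empty outcome cell in this stratum cannot carry
    # a finite odds ratio; exclude it here (noted) rather than let the final
    # fit hit perfect separation
    sga = labelled_stratum["sga"].astype(bool)
    for s in screen:
        if not s.included:
            continue
        table = pd.crosstab(labelled_stratum[factor_cols[s.factor]], sga)
        if (table.to_numpy() == 0).any():
            s.included = False
            s.note = "zero outcome cell in stratum"
            warnings.warn(
                f"factor {s.factor!r} excluded in stratum {stratum}: empty outcome cell"
            )
    candidates = [s.factor for s in screen if s.included]
    usable = [fc for fc in codings if fc.name in candidates]
    data = make_stratum_dataset(labelled_stratum, stratum, usable)
    vif = compute_vif(data.X, data.colnames) if data.X.shape[1] > 2 else pd.Series(dtype=float)
    elim = backward_eliminate(data, [fc.name for fc in usable], selection)
    fit = fit_gee(data, elim.final_factors)
    aors = adjusted_ors(fit)
    pafs = []
    for name in modifiable:
        if name not in elim.final_factors:
            continue
        for j in fit.term_map[name]:  # per-level PAFs for multi-level factors
            est = bootstrap_paf(
                data,
                elim.final_factors,
                [j],
                reps=bootstrap_reps,
                seed=seed + 7919 * (j + 1),
                factor_name=fit.dataset.colnames[j],
            )
            pafs.append(est)
    return {
        "stratum": stratum,
        "n": data.n,
        "screen": screen,
        "vif": vif,
        "elimination": elim,
        "fit": fit,
        "aors": aors,
        "pafs": pafs,
    }


def stratum_table(result: dict) -> pd.DataFrame:
    """Adjusted-OR + PAF table for one stratum (reference rows print 1.00)."""
    aors = result["aors"].copy()
    paf_by_level = {p.factor: p for p in result["pafs"]}
    aors["paf"] = [
        paf_by_level[lv].point_paf if lv in paf_by_level else np.nan
        for lv in aors["level"]
    ]
    aors["paf_ci_low"] = [
        paf_by_level[lv].ci_low if lv in paf_by_level else np.nan for lv in aors["level"]
    ]
    aors["paf_ci_high"] = [
        paf_by_level[lv].ci_high if lv in paf_by_level else np.nan for lv in aors["level"]
    ]
    aors.insert(0, "stratum", result["stratum"])
    return aors


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write tables + manifest to ``outdir``.

    Returns the in-memory result bundle (summary, per-stratum results,
    manifest).  Raises on any invalid estimate; warnings (separation, high
    VIF, failed bootstrap replicates) are collected into the manifest.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []

    if config.mode == "synthetic":
        cohort_cfg = config.cohort
        if cohort_cfg.seed != config.seed:
            cohort_cfg = CohortConfig(**{**asdict(cohort_cfg), "seed": config.seed})
        standard = (
            load_standard(config.standard_path)
            if config.standard_path
            else make_synthetic_standard()
        )
        raw, ledger = generate_cohort(cohort_cfg, standard)
    else:
        standard = (
            load_standard(config.standard_path)
            if config.standard_path
            else make_synthetic_standard()
        )
        raw, ledger = read_cohort(config.cohort_path), None

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        labelled, tally = build_cohort(raw, standard)
        summary = summarize_cohort(labelled)
        strata = stratify(labelled)
        results = {}
        for name, frame in strata.items():
            results[name] = analyse_stratum(
                frame,
                name,
                config.selection,
                config.modifiable_factors,
                config.bootstrap_reps,
                config.seed,
            )
        caught.extend(str(w.message) for w in wlist)

    tally.as_frame().to_csv(outdir / "exclusions.csv", index=False)
    summary.as_frame().to_csv(outdir / "cohort_summary.csv", index=False)
    write_standard(standard, outdir / "growth_standard.csv")
    for name, res in results.items():
        stratum_table(res).to_csv(outdir / f"table_{name}.csv", index=False)
        res["elimination"].trace_frame().to_csv(
            outdir / f"elimination_trace_{name}.csv", index=False
        )

    manifest = {
        "seed": config.seed,
        "mode": config.mode,
        "bootstrap_reps": config.bootstrap_reps,
        "n_input_study_births": tally.n_study_births,
        "exclusions": {
            "multiple_pregnancy": tally.multiple_pregnancy,
            "stillbirth": tally.stillbirth,
            "gestation_out_of_range": tally.gestation_out_of_range,
            "incomplete_history": tally.incomplete_history,
        },
        "n_included": tally.n_included,
        "stratum_sizes": {k: int(len(v)) for k, v in strata.items()},
        "final_factors": {k: res["elimination"].final_factors for k, res in results.items()},
        "confounders": {k: res["elimination"].confounders for k, res in results.items()},
        "bootstrap_failures": {
            k: {p.factor: p.bootstrap_reps - p.successful_reps for p in res["pafs"]}
            for k, res in results.items()
        },
        "warnings": caught,
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if sum(manifest["stratum_sizes"].values()) != tally.n_included:
        raise DataError("stratum sizes do not reconcile with included births")
    return {
        "summary": summary,
        "tally": tally,
        "results": results,
        "manifest": manifest,
        "ledger": ledger,
        "standard": standard,
    }
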