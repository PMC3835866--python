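"""Gestational-age- and sex-specific birthweight percentile standards.

Small-for-gestational-age (SGA) is defined as birthweight strictly below the
10th percentile of a reference distribution indexed by completed weeks of
gestation (24-44) and infant sex.  This module holds the reference table
(:class:`GrowthStandard`), reads/writes it as delimited text, classifies
births against it, and can synthesise a self-consistent standard from a
normal location-scale model calibrated so the 10th percentile at 39 weeks is
2500 g for either sex.

Gestational age is treated as a discrete per-week lookup; no interpolation is
performed between weeks because the exposure is recorded in completed weeks.
Ties at a cutoff are classified as non-SGA (strict "less than").
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._util import DataError

WEEK_MIN = 24
WEEK_MAX = 44
SEXES = ("male", "female")
DEFAULT_PERCENTILES = (3, 5, 10, 25, 50, 75, 90, 95, 97)

#: birthweights are recorded on a 5 g grid, in (0, 7000] g
WEIGHT_GRID_G = 5
WEIGHT_MAX_G = 7000


class StandardError(DataError):
    """A growth-standard table violates a structural invariant."""


@dataclass(frozen=True)
class GrowthStandard:
    """Percentile cutoffs by (gestational week, sex).

    ``entries`` maps ``(week, sex)`` to a dict ``{percentile: cutoff_grams}``
    whose cutoffs are strictly increasing in percentile.  Every week in
    24..44 for both sexes must carry a 10th-percentile cutoff.
    """

    entries: Mapping[tuple[int, str], Mapping[int, float]]
    provenance: str = "unspecified"
    #: optional generating model, set by :func:`make_synthetic_standard`
    model: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        _validate_entries(self.entries)

    def cutoff(self, week: int, sex: str, percentile: int = 10) -> float:
        """Stored cutoff in grams; raises outside the 24-44 week range."""
        if not WEEK_MIN <= week <= WEEK_MAX:
            raise StandardError(
                f"gestational age {week} outside supported range "
                f"{WEEK_MIN}-{WEEK_MAX} completed weeks"
            )
        cell = self.entries.get((week, _norm_sex(sex)))
        if cell is None or percentile not in cell:
            raise StandardError(
                f"no cutoff stored for week={week}, sex={sex}, percentile={percentile}"
            )
        return cell[percentile]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (week, sex, pct, grams)
            for (week, sex), cell in sorted(self.entries.items())
            for pct, grams in sorted(cell.items())
        ]
        return pd.DataFrame(rows, columns=["week", "sex", "percentile", "grams"])


def _norm_sex(sex: str) -> str:
    s = str(sex).strip().lower()
    if s not in SEXES:
        raise StandardError(f"sex must be one of {SEXES}, got {sex!r}")
    return s


def _validate_entries(entries: Mapping[tuple[int, str], Mapping[int, float]]) -> None:
    for week in range(WEEK_MIN, WEEK_MAX + 1):
        for sex in SEXES:
            cell = entries.get((week, sex))
            if cell is None or 10 not in cell:
                raise StandardError(
                    f"standard lacks a 10th-percentile cutoff for week={week}, sex={sex}"
                )
    for (week, sex), cell in entries.items():
        pcts = sorted(cell)
        grams = [cell[p] for p in pcts]
        if any(g <= 0 for g in grams):
            raise StandardError(f"non-positive cutoff at week={week}, sex={sex}")
        if any(b <= a for a, b in zip(grams, grams[1:])):
            raise StandardError(
                f"cutoffs not strictly increasing in percentile at week={week}, sex={sex}"
            )
    # cutoffs must not decrease with gestational week at fixed (percentile, sex)
    for sex in SEXES:
        for week in range(WEEK_MIN, WEEK_MAX):
            a, b = entries[(week, sex)], entries[(week + 1, sex)]
            for pct in set(a) & set(b):
                if b[pct] < a[pct]:
                    raise StandardError(
                        f"cutoff decreases from week {week} to {week + 1} "
                        f"(sex={sex}, percentile={pct})"
                    )


def load_standard(source, provenance: str = "file") -> GrowthStandard:
    """Read a standard from comma-separated text with header week,sex,percentile,grams.

    ``source`` may be a path or a file-like object.  Malformed rows, missing
    (week, sex) coverage and monotonicity violations raise
    :class:`StandardError` naming the offence.
    """
    try:
        df = pd.read_csv(source)
    except Exception as exc:  # noqa: BLE001 - surface as structured error
        raise StandardError(f"unparseable standard table: {exc}") from exc
    required = {"week", "sex", "percentile", "grams"}
    if not required.issubset(df.columns):
        raise StandardError(
            f"standard table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    entries: dict[tuple[int, str], dict[int, float]] = {}
    for i, row in df.iterrows():
        try:
            week = int(row["week"])
            pct = int(row["percentile"])
            grams = float(row["grams"])
            sex = _norm_sex(row["sex"])
        except (TypeError, ValueError, StandardError) as exc:
            raise StandardError(f"unparseable standard row {i}: {dict(row)}") from exc
        if grams <= 0:
            raise StandardError(f"non-positive cutoff in row {i}: {grams}")
        cell = entries.setdefault((week, sex), {})
        if pct in cell:
            raise StandardError(f"duplicate cell (week={week}, sex={sex}, percentile={pct})")
        cell[pct] = grams
    return GrowthStandard(entries=entries, provenance=provenance)


def write_standard(standard: GrowthStandard, path) -> None:
    """Write the standard back out in the same comma-separated layout."""
    standard.to_frame().to_csv(path, index=False)


def percentile_cutoff(standard: GrowthStandard, week: int, sex: str, percentile: int = 10) -> float:
    """Stored cutoff in grams for (week, sex, percentile); no interpolation."""
    return standard.cutoff(week, sex, percentile)


def classify_sga(standard: GrowthStandard, birthweight_grams, week, sex):
    """True iff birthweight is strictly below the 10th-percentile cutoff.

    Accepts scalars or aligned array-likes (vectorised over births).  A
    weight exactly at the cutoff is NOT SGA.
    """
    scalar = np.isscalar(birthweight_grams) or isinstance(birthweight_grams, (int, float))
    bw = np.atleast_1d(np.asarray(birthweight_grams, dtype=float))
    wk = np.atleast_1d(np.asarray(week, dtype=int))
    sx = np.atleast_1d(np.asarray(sex, dtype=object))
    wk, sx = np.broadcast_to(wk, bw.shape).ravel(), np.broadcast_to(sx, bw.shape).ravel()
    if np.any(bw <= 0) or np.any(bw > WEIGHT_MAX_G):
        bad = bw[(bw <= 0) | (bw > WEIGHT_MAX_G)][0]
        raise DataError(f"birthweight {bad} g outside (0, {WEIGHT_MAX_G}] g")
    cut = np.array(
        [standard.cutoff(int(w), str(s), 10) for w, s in zip(wk, sx)], dtype=float
    )
    out = bw.ravel() < cut
    return bool(out[0]) if scalar else out.reshape(bw.shape)


# ---------------------------------------------------------------------------
# synthetic default standard


def _gompertz_shape(weeks: np.ndarray, k: float, w0: float) -> np.ndarray:
    return np.exp(-np.exp(-k * (weeks - w0)))


def make_synthetic_standard(
    mean_39_g: Mapping[str, float] | None = None,
    anchor_10th_39w_g: float = 2500.0,
    percentiles: Iterable[int] = DEFAULT_PERCENTILES,
    growth_rate: float = 0.13,
    inflection_week: float = 28.0,
) -> GrowthStandard:
    """Build a normal location-scale standard anchored at 2500 g (P10, 39 weeks).

    Per (week, sex) the weight reference is Normal(mean(w), sd(w)).  The mean
    curve is a Gompertz growth curve scaled so mean(39) hits ``mean_39_g`` for
    each sex (defaults 3300 g male / 3230 g female), and the coefficient of
    variation is constant in week, chosen per sex so that
    ``mean(39) + z_{0.10} * sd(39)`` equals the anchor exactly.  Cutoffs at
    the requested percentiles follow in closed form as mean + z_p * sd.
    """
    means = dict(mean_39_g or {"male": 3300.0, "female": 3230.0})
    weeks = np.arange(WEEK_MIN, WEEK_MAX + 1)
    shape = _gompertz_shape(weeks, growth_rate, inflection_week)
    shape = shape / _gompertz_shape(np.array([39.0]), growth_rate, inflection_week)[0]
    if np.any(np.diff(shape) <= 0):
        raise StandardError("mean curve is not strictly increasing in gestational week")
    z10 = norm.ppf(0.10)
    entries: dict[tuple[int, str], dict[int, float]] = {}
    model: dict = {"family": "normal", "by_sex": {}}
    for sex in SEXES:
        m39 = float(means[sex])
        cv = (m39 - anchor_10th_39w_g) / (-z10 * m39)
        if cv <= 0:
            raise StandardError("anchor above the 39-week mean implies negative SD")
        mean_curve = m39 * shape
        sd_curve = cv * mean_curve
        model["by_sex"][sex] = {
            "weeks": weeks.tolist(),
            "mean": mean_curve.tolist(),
            "sd": sd_curve.tolist(),
        }
        for w, mu, sd in zip(weeks, mean_curve, sd_curve):
            entries[(int(w), sex)] = {
                int(p): float(mu + norm.ppf(p / 100.0) * sd) for p in percentiles
            }
    return GrowthStandard(entries=entries, provenance="synthetic normal location-scale", model=model)


def standard_mean_sd(standard: GrowthStandard, week: int, sex: str) -> tuple[float, float]:
    """Generating mean/SD of a synthetic standard's reference distribution."""
    if standard.model is None:
        raise StandardError("standard has no generating model (loaded from table?)")
    cell = standard.model["by_sex"][_norm_sex(sex)]
    idx = cell["weeks"].index(week)
    return cell["mean"][idx], cell["sd"][idx]


def snap_to_grid(grams: np.ndarray) -> np.ndarray:
    """Round weights to the 5 g recording grid."""
    return np.round(np.asarray(grams, dtype=float) / WEIGHT_GRID_G) * WEIGHT_GRID_G
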