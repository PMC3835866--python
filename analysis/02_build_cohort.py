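"""Build the analysis cohort: filters, history covariates, SGA labels.

Reads the simulated extract from step 01, applies the inclusion rules
(singleton, livebirth, 24-44 weeks, complete obstetric history), derives
parity / inter-pregnancy interval / previous-outcome counts, classifies SGA
against the growth standard and reports the exclusion tally and headline
cohort summary.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"

from sgapaf import load_standard, read_cohort, summarize_cohort, write_cohort
from sgapaf.pipeline import build_cohort


def main() -> None:
    std = load_standard(OUT / "growth_standard.csv")
    raw = read_cohort(OUT / "cohort.csv")
    labelled, tally = build_cohort(raw, std)
    write_cohort(labelled, OUT / "included.csv")
    tally.as_frame().to_csv(OUT / "exclusions.csv", index=False)
    summary = summarize_cohort(labelled)
    summary.as_frame().to_csv(OUT / "cohort_summary.csv", index=False)
    print(tally.as_frame().to_string(index=False))
    print()
    print(summary.as_frame().to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
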