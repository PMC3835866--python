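"""Compare estimates with the generator's ground truth.

Reads the truth ledger from step 01 and the fitted tables from steps 03-04
and reports, per stratum and modifiable factor, the estimated PAF next to
the ledger's true marginal PAF, and the smoking aOR next to the planted
(conditional) and marginal targets.  This is the closing consistency check
of the analysis: it quantifies how well the pipeline recovers known truths
under the simulated study conditions.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"

from sgapaf import CohortConfig
from sgapaf.cohort import STRATA

SEED = 20260922


def main() -> None:
    ledger = pd.read_csv(OUT / "truth_ledger.csv")
    rows = []
    for stratum in STRATA:
        table_path = OUT / f"table_{stratum}.csv"
        if not table_path.exists():
            continue
        table = pd.read_csv(table_path)
        mask = ledger["is_study"] & ledger["included"] & ledger["stratum"].eq(stratum)
        for factor in CohortConfig().modifiable_factors:
            col = f"p_cf_{factor}"
            sub = ledger[mask]
            truth = 100.0 * (sub["p"].sum() - sub[col].sum()) / sub["p"].sum()
            est = table.loc[table["level"].eq(factor), "paf"]
            rows.append(
                {
                    "stratum": stratum,
                    "factor": factor,
                    "true_paf": round(truth, 2),
                    "estimated_paf": round(float(est.iloc[0]), 2) if len(est) and np.isfinite(est.iloc[0]) else None,
                }
            )
    out = pd.DataFrame(rows)
    out.to_csv(OUT / "paf_vs_truth.csv", index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
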