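"""Per-stratum model selection and final GEE fits.

For each stratum (preterm, term diabetic, term non-diabetic): chi-squared
screen at P<0.10, VIF diagnostics, backward elimination at P<0.01 with the
10% change-in-aOR confounder rule and re-entry pass, then the final GEE fit
(exchangeable working correlation, robust SEs) and adjusted odds ratios.
Writes the elimination traces and aOR tables under results/.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"

import json

from sgapaf import SelectionConfig, read_cohort, stratify
from sgapaf.pipeline import analyse_stratum

SEED = 20260922


def main() -> None:
    labelled = read_cohort(OUT / "included.csv")
    sel = SelectionConfig()
    finals = {}
    for name, frame in stratify(labelled).items():
        res = analyse_stratum(frame, name, sel, (), bootstrap_reps=100, seed=SEED)
        res["elimination"].trace_frame().to_csv(OUT / f"elimination_trace_{name}.csv", index=False)
        res["aors"].to_csv(OUT / f"aor_{name}.csv", index=False)
        if len(res["vif"]):
            res["vif"].to_csv(OUT / f"vif_{name}.csv", header=["vif"])
        finals[name] = res["elimination"].final_factors
        print(f"{name}: n={res['n']}, working alpha={res['fit'].result.alpha:.4f}")
        print(f"  final factors: {res['elimination'].final_factors}")
        print(f"  confounder-retained: {res['elimination'].confounders}")
    (OUT / "final_factors.json").write_text(json.dumps(finals, indent=2))


if __name__ == "__main__":
    sys.exit(main())
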