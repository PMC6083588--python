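#!/usr/bin/env python
"""Step 5 — association bias: the OR/ROR panel.

Fits the four multivariable logistic models (resection, > 4 weeks in
hospital, > 2 ED attendances, one-year survival) separately among
participants and in the source population, and reports relative odds
ratios with nested-sample confidence limits, per cancer cohort.
"""

from pathlib import Path

import pandas as pd

from cohortbias.association_bias import bias_panel

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rows = pd.read_csv(ROOT / "scratch" / "analysis_rows.csv")
    frames = []
    for cancer, grp in rows.groupby("cohort"):
        panel = bias_panel(grp)
        panel.insert(0, "cohort", cancer)
        frames.append(panel)
    panel = pd.concat(frames, ignore_index=True)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    panel.to_csv(out / "ror_panel.csv", index=False)

    ok = panel[(panel["status"] == "ok") & (panel["model"] == "multivariable")]
    refused = panel[panel["status"] != "ok"]
    print(f"panel: {len(ok)} estimated factor levels, "
          f"{refused[['cohort', 'outcome']].drop_duplicates().shape[0]} "
          "model(s) refused for sparse events")
    sig = ok[(ok["cl_upper"] < 1) | (ok["cl_lower"] > 1)]
    print(f"{len(sig)} of {len(ok)} RORs significantly different from 1:")
    if len(sig):
        cols = ["cohort", "outcome", "factor", "level", "or_sub", "or_pop",
                "ror", "cl_lower", "cl_upper"]
        print(sig[cols].round(2).to_string(index=False))


if __name__ == "__main__":
    main()
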