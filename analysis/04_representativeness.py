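#!/usr/bin/env python
"""Step 4 — representativeness: RRF tables with nested-sample limits.

Builds the three publication-style tables (case characteristics, hospital
and ED use, survival) and the SES-by-remoteness stratified table, then
reports which categories the self-selected subsample over- and
under-represents.
"""

from pathlib import Path

import pandas as pd

from cohortbias.report import make_tables, ses_by_remoteness_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rows = pd.read_csv(ROOT / "scratch" / "analysis_rows.csv")
    tables = make_tables(rows)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    strat = ses_by_remoteness_table(rows)
    strat.to_csv(out / "rrf_ses_by_remoteness.csv", index=False)

    t1 = tables["table1"]
    ok = t1[(t1["status"] == "ok") & (t1["x_sub"] >= 30)].copy()
    ok["dev"] = (ok["rrf"] - 1).abs()
    print("strongest representativeness deviations (table1, x_sub >= 30):")
    cols = ["cohort", "variable", "category", "pct_sub", "pct_pop",
            "rrf", "cl_lower", "cl_upper"]
    print(ok.nlargest(8, "dev")[cols].to_string(index=False))
    sig = ok[(ok["cl_upper"] < 1) | (ok["cl_lower"] > 1)]
    print(f"{len(sig)} of {len(ok)} categories differ significantly from "
          "the population (95% limits exclude 1)")


if __name__ == "__main__":
    main()
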