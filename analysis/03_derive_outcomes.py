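#!/usr/bin/env python
"""Step 3 — derive per-person health-service-use and survival outcomes.

Turns the record-level admission/ED/death tables into one analysis row
per eligible person: admission and bed-day bands in the year before and
after diagnosis, ED attendance bands, Charlson comorbidity band (5-year
lookback), major resection and its urgency, and 1-/3-year post-diagnosis
and 1-year post-operative survival.
"""

from pathlib import Path

import pandas as pd

from cohortbias import outcomes
from cohortbias.synthetic_data import LinkedDataset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ds = LinkedDataset.read(ROOT / "scratch" / "sim")
    cohort = pd.read_csv(ROOT / "scratch" / "cohort.csv",
                         parse_dates=["diagnosis_date", "recruitment_date"])
    rows = outcomes.derive_analysis_rows(cohort, ds.admissions, ds.ed,
                                         ds.deaths, ds.censor_date)
    rows.to_csv(ROOT / "scratch" / "analysis_rows.csv", index=False)
    print(f"derived {len(rows)} analysis rows")
    for cancer, grp in rows.groupby("cohort"):
        print(f"  {cancer}: resection {100 * grp['resection'].mean():.1f}%, "
              f"1y survival {100 * grp['survival_1y'].mean():.1f}%, "
              f"3y survival {100 * grp['survival_3y'].mean():.1f}%, "
              f"Charlson 2+ {100 * grp['charlson_band'].eq('2+').mean():.1f}%")


if __name__ == "__main__":
    main()
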