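#!/usr/bin/env python
"""Step 2 — apply the eligibility cascade and the participant split.

Reads the simulated registry and roster, applies the inclusion/exclusion
cascade (study window, age >= 45, site/histology scope, prior cancers,
multiple primaries, DCO, unknown date/residence), flags cohort-study
participants (recruited before diagnosis), and writes the cohort plus the
recruitment-flow table.
"""

from pathlib import Path

import pandas as pd

from cohortbias import eligibility
from cohortbias.synthetic_data import LinkedDataset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ds = LinkedDataset.read(ROOT / "scratch" / "sim")
    cohort, ledger = eligibility.select_index_cases(ds.registry)
    flow = eligibility.flow_table(ds.registry, cohort, ledger)
    cohort = eligibility.split_by_membership(cohort, ds.roster)

    (ROOT / "scratch").mkdir(exist_ok=True)
    cohort.to_csv(ROOT / "scratch" / "cohort.csv", index=False)
    (ROOT / "results").mkdir(exist_ok=True)
    flow.to_csv(ROOT / "results" / "flow_table.csv", index=False)

    n = len(cohort)
    n_part = int(cohort["participant"].sum())
    print(flow.to_string(index=False))
    by = cohort.groupby("cohort")["participant"].agg(["count", "sum"])
    for cancer, row in by.iterrows():
        print(f"  {cancer}: {int(row['count'])} eligible, "
              f"{int(row['sum'])} participants "
              f"({100 * row['sum'] / row['count']:.1f}%)")
    print(f"total {n} eligible, {n_part} participants")


if __name__ == "__main__":
    main()
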