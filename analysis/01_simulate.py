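#!/usr/bin/env python
"""Step 1 — generate the linked synthetic study data.

Simulates a source population of bowel and lung cancer patients with the
self-selection scenario (non-English-speaking and younger patients
under-enrol, healthier people over-enrol, rural/oldest-age oversampling
by design) and writes the five linked record-level CSVs plus the
generating truth under scratch/sim/.
"""

from pathlib import Path

from cohortbias.scenarios import selection_scenario
from cohortbias.synthetic_data import simulate

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "sim"
N_PERSONS = 60_000
SEED = 2026


def main() -> None:
    pop, part, osp = selection_scenario(N_PERSONS, seed=SEED)
    ds = simulate(pop, part, osp, seed=SEED)
    ds.write(OUT)
    n_roster = len(ds.roster)
    print(f"wrote {OUT}")
    print(f"  registry   {len(ds.registry):>7} cancer patients")
    print(f"  admissions {len(ds.admissions):>7} records")
    print(f"  ed         {len(ds.ed):>7} attendances")
    print(f"  deaths     {len(ds.deaths):>7} records")
    print(f"  roster     {n_roster:>7} cohort-study members "
          f"({100 * n_roster / len(ds.registry):.1f}% of patients)")
    print(f"  censor date {ds.censor_date}")


if __name__ == "__main__":
    main()
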