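"""Publication-style outputs and the one-command end-to-end run.

Produces the three replica tables (case characteristics, hospital/ED use,
survival), the recruitment-flow table, SES-by-remoteness stratified RRFs,
the OR/ROR bias panel, and a machine-readable summary JSON.  Small cells
in the urgency-of-resection block are suppressed below a configurable
threshold (default 5), mirroring linked-data reporting practice.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import eligibility, outcomes, representativeness as rep
from .association_bias import bias_panel, default_model_specs
from .synthetic_data import LinkedDataset, simulate
from .scenarios import SCENARIOS
from ._util import round_half_up, spawn_seeds

logger = logging.getLogger(__name__)

TABLE1_VARIABLES = ("sex", "age_group", "charlson_band", "extent",
                    "remoteness", "ses_quintile", "cob_group")
TABLE2_VARIABLES = ("adm_prior_band", "weeks_prior_band", "ed_prior_band",
                    "adm_post_band", "weeks_post_band", "ed_post_band",
                    "resection", "resection_urgency")
TABLE3_VARIABLES = ("survival_1y_postop", "survival_1y", "survival_3y")

SUPPRESSED = "<suppressed>"


def _rrf_block(rows: pd.DataFrame, variable: str, cohort: str) -> pd.DataFrame:
    sub = rows[rows["cohort"] == cohort].copy()
    if variable in ("resection", "survival_1y", "survival_3y"):
        sub[variable] = sub[variable].map({True: "yes", False: "no"})
    if variable == "survival_1y_postop":
        sub = sub[sub["resection"]]
        sub[variable] = sub[variable].map({True: "yes", False: "no"})
    if variable == "resection_urgency":
        sub = sub[sub["resection"]]
    results = rep.rrf_table(sub, variable)
    df = rep.results_frame(results)
    if len(df) == 0:
        return df.assign(cohort=cohort)
    df.insert(0, "cohort", cohort)
    for col in ("pct_sub", "pct_pop"):
        df[col] = df[col].map(lambda v: round_half_up(v, 1))
    for col in ("rrf", "cl_lower", "cl_upper"):
        df[col] = df[col].map(round_half_up)
    return df


def _suppress_small_cells(df: pd.DataFrame, variable: str,
                          threshold: int) -> pd.DataFrame:
    """Suppress an urgency block when any of its subsample cells is small."""
    out = df.copy()
    mask = out["variable"] == variable
    for cohort in out.loc[mask, "cohort"].unique():
        block = mask & (out["cohort"] == cohort)
        if (out.loc[block, "x_sub"] < threshold).any():
            cols = ["x_sub", "pct_sub", "x_pop", "pct_pop",
                    "rrf", "cl_lower", "cl_upper"]
            out.loc[block, cols] = None
            out.loc[block, "status"] = SUPPRESSED
    return out


def make_tables(rows: pd.DataFrame, suppress_threshold: int = 5
                ) -> dict[str, pd.DataFrame]:
    """Build the three replica tables (both cohorts side by side, long
    format: one row per cohort x variable x category)."""
    tables = {}
    for name, variables in (("table1", TABLE1_VARIABLES),
                            ("table2", TABLE2_VARIABLES),
                            ("table3", TABLE3_VARIABLES)):
        blocks = []
        for cohort in ("bowel", "lung"):
            for variable in variables:
                blk = _rrf_block(rows, variable, cohort)
                if len(blk):
                    blocks.append(blk)
        if blocks:
            df = pd.concat(blocks, ignore_index=True)
        else:
            df = pd.DataFrame(columns=["cohort", "variable", "stratum",
                                       "category", "x_sub", "n_sub", "pct_sub",
                                       "x_pop", "n_pop", "pct_pop", "rrf",
                                       "cl_lower", "cl_upper", "status"])
        if name == "table2":
            df = _suppress_small_cells(df, "resection_urgency", suppress_threshold)
        tables[name] = df
    return tables


def hospital_type_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Admission-level private/public shares per cohort and window.

    The published tables report hospital type over admissions, not
    persons; the per-person private/public admission counts derived in
    the outcomes stage are summed here.
    """
    recs = []
    for cohort, grp in rows.groupby("cohort"):
        for window in ("prior", "post"):
            for group_name, g in (("subsample", grp[grp["participant"]]),
                                  ("population", grp)):
                priv = int(g[f"n_adm_private_{window}"].sum())
                pub = int(g[f"n_adm_public_{window}"].sum())
                total = priv + pub
                recs.append({
                    "cohort": cohort, "window": window, "group": group_name,
                    "n_private": priv, "n_public": pub,
                    "pct_private": round_half_up(100 * priv / total, 1) if total else None,
                })
    return pd.DataFrame(recs)


def ses_by_remoteness_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Stratified SES RRFs (the urban/rural stratification that reveals
    socioeconomic self-selection masked in the marginal distribution)."""
    blocks = []
    for cohort, grp in rows.groupby("cohort"):
        res = rep.rrf_table(grp, "ses_quintile", by="remoteness")
        df = rep.results_frame(res)
        df.insert(0, "cohort", cohort)
        blocks.append(df)
    return pd.concat(blocks, ignore_index=True)


# --------------------------------------------------------------------------
# end-to-end run
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Either a scenario simulation or paths to the five raw CSV files."""

    out_dir: str = "cohortbias_out"
    seed: int = 0
    scenario: str | None = None
    n_persons: int = 30_000
    data_dir: str | None = None  # directory with the five CSVs + truth.json
    suppress_threshold: int = 5
    min_events_per_param: float = 10.0
    rrf_variables: tuple[str, ...] = TABLE1_VARIABLES
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.scenario is None and self.data_dir is None:
            raise ValueError("config must name either a scenario or a data_dir")
        if self.scenario is not None and self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"one of {sorted(SCENARIOS)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**cfg)


SUMMARY_SCHEMA = {
    "seed": int, "scenario": (str, type(None)), "n_registry": int,
    "n_eligible": int, "n_participants": int, "exclusions": dict,
    "max_abs_rrf_minus_1": float, "rrf": list, "ror": list,
    "stage_seeds": dict,
}


def validate_summary(summary: dict) -> None:
    """Schema check for the machine-readable summary (run on every run)."""
    for key, typ in SUMMARY_SCHEMA.items():
        if key not in summary:
            raise ValueError(f"summary missing key {key!r}")
        if not isinstance(summary[key], typ):
            raise ValueError(f"summary key {key!r} has type "
                             f"{type(summary[key]).__name__}")


def run_all(config: RunConfig) -> dict:
    """simulate (optional) -> build cohort -> derive -> RRF -> ROR -> tables.

    Writes every artefact under ``config.out_dir`` and returns the summary
    dict (also written as summary.json).  Deterministic given the seed:
    one root seed is split into per-stage seeds, which are logged.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = dict(zip(("simulate",), spawn_seeds(config.seed, 1)))

    if config.scenario is not None:
        pop_spec, part_spec, out_spec = SCENARIOS[config.scenario](
            config.n_persons, seed=stage_seeds["simulate"])
        ds = simulate(pop_spec, part_spec, out_spec, seed=stage_seeds["simulate"])
        logger.info("simulated %d registry records (scenario %s)",
                    len(ds.registry), config.scenario)
    else:
        ds = LinkedDataset.read(config.data_dir)
        logger.info("loaded %d registry records from %s",
                    len(ds.registry), config.data_dir)

    cohort, ledger = eligibility.select_index_cases(ds.registry)
    flow = eligibility.flow_table(ds.registry, cohort, ledger)
    logger.info("eligibility: %d eligible of %d persons",
                len(cohort), ds.registry["person_id"].nunique())
    cohort = eligibility.split_by_membership(cohort, ds.roster)

    rows = outcomes.derive_analysis_rows(cohort, ds.admissions, ds.ed,
                                         ds.deaths, ds.censor_date)

    tables = make_tables(rows, config.suppress_threshold)
    strat = ses_by_remoteness_table(rows)
    hosp = hospital_type_table(rows)
    panel = bias_panel(rows, default_model_specs(),
                       min_events_per_param=config.min_events_per_param)

    rows.to_csv(out / "analysis_rows.csv", index=False)
    ledger.to_csv(out / "exclusion_ledger.csv", index=False)
    flow.to_csv(out / "flow_table.csv", index=False)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    strat.to_csv(out / "rrf_ses_by_remoteness.csv", index=False)
    hosp.to_csv(out / "hospital_type.csv", index=False)
    panel.to_csv(out / "ror_panel.csv", index=False)

    t1 = tables["table1"]
    ok = t1["status"].eq("ok")
    summary = {
        "seed": int(config.seed),
        "scenario": config.scenario,
        "n_registry": int(ds.registry["person_id"].nunique()),
        "n_eligible": int(len(cohort)),
        "n_participants": int(cohort["participant"].sum()),
        "exclusions": {r.stage: int(r.n) for r in flow.itertuples(index=False)},
        "max_abs_rrf_minus_1": float((t1.loc[ok, "rrf"] - 1.0).abs().max()),
        "rrf": json.loads(t1.to_json(orient="records")),
        "ror": json.loads(panel.to_json(orient="records")),
        "stage_seeds": {k: int(v) for k, v in stage_seeds.items()},
    }
    validate_summary(summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
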