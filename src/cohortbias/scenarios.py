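"""Named simulation scenarios.

``null_scenario``   — participation completely at random: no covariate
                      offsets, no design multipliers, no latent
                      dependence.  Every downstream RRF/ROR is 1 up to
                      sampling noise; used for calibration checks.
``design_scenario`` — selection at random *given the design*: the
                      documented oversampling multipliers only.
``selection_scenario`` — self-selection with the qualitative pattern a
                      volunteer cohort shows: people born in non-English-
                      speaking countries strongly under-enrol, younger
                      patients under-enrol, healthier people (higher
                      latent propensity) over-enrol, on top of the
                      design's rural/oldest-age oversampling.
"""

from __future__ import annotations

from .synthetic_data import (OutcomeSpec, ParticipationSpec, PopulationSpec,
                             default_design_multipliers)
from ._util import logit


def population_spec(n_persons: int, seed: int = 0) -> PopulationSpec:
    return PopulationSpec(n_persons=n_persons, seed=seed)


def null_scenario(n_persons: int, seed: int = 0
                  ) -> tuple[PopulationSpec, ParticipationSpec, OutcomeSpec]:
    part = ParticipationSpec(baseline_logodds=logit(0.07),
                             covariate_logodds={},
                             design_multipliers={},
                             outcome_dependence=0.0)
    return population_spec(n_persons, seed), part, OutcomeSpec()


def design_scenario(n_persons: int, seed: int = 0
                    ) -> tuple[PopulationSpec, ParticipationSpec, OutcomeSpec]:
    part = ParticipationSpec(baseline_logodds=logit(0.06),
                             design_multipliers=default_design_multipliers())
    return population_spec(n_persons, seed), part, OutcomeSpec()


def selection_scenario(n_persons: int, seed: int = 0
                       ) -> tuple[PopulationSpec, ParticipationSpec, OutcomeSpec]:
    pop = population_spec(n_persons, seed)
    # lung cancer loads negatively on latent health, so health-driven
    # enrolment under-represents lung cancer among participants
    pop.cancer_mix.latent_loading = -0.25
    part = ParticipationSpec(
        baseline_logodds=logit(0.055),
        covariate_logodds={
            "cob_group": {"non_english": -0.85, "other_english": 0.20},
            "age_group": {"45-54": -0.40, "55-64": -0.15},
            "ses_quintile": {"1": 0.22, "2": 0.10, "4": -0.08, "5": -0.18},
        },
        design_multipliers=default_design_multipliers(),
        outcome_dependence=0.45,
    )
    return pop, part, OutcomeSpec()


SCENARIOS = {
    "null": null_scenario,
    "design": design_scenario,
    "selection": selection_scenario,
}
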