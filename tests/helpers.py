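"""Shared scenario factories for the test suite."""

from __future__ import annotations

import numpy as np

from gxescreen import ModelSpec, fit_logistic, generate_cohort, prepare_cohort
from gxescreen.phenotypes import build_catalog
from gxescreen.simulate import InteractionSpec, OutcomeSpec, SimulationScenario

#: one single-symptom domain, the smallest catalog the cascade accepts
FLAT_SOLO = build_catalog({"solo": 1}, continuous_domains=())

INTERACTION_TERM = "prs_scz_high:any_ace"

NOCOV_INTERACTION = ModelSpec(
    outcome="solo",
    exposures=("prs_scz_high", "any_ace"),
    interactions=(("prs_scz_high", "any_ace"),),
    covariates=(),
)


def solo_scenario(
    n: int,
    seed: int,
    prevalence: float = 0.3,
    beta_prs: float = float(np.log(1.5)),
    beta_ace: float = float(np.log(2.0)),
    interaction: InteractionSpec | None = None,
    covariate_betas: dict | None = None,
) -> SimulationScenario:
    spec = OutcomeSpec(
        baseline_prevalence=prevalence,
        beta_prs_scz=beta_prs,
        beta_ace=beta_ace,
        interaction_scz=interaction,
        covariate_betas=covariate_betas or {},
    )
    return SimulationScenario(
        n_participants=n, seed=seed, catalog=FLAT_SOLO, outcome_spec={"solo": spec}
    )


def solo_interaction_fit(n: int, seed: int, **kwargs):
    """Generate a single-symptom cohort and fit the unadjusted interaction model."""
    scenario = solo_scenario(n, seed, **kwargs)
    derived, _ = prepare_cohort(generate_cohort(scenario), FLAT_SOLO)
    return fit_logistic(derived, NOCOV_INTERACTION)
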