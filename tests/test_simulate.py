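"""Synthetic cohort generator: structure, determinism, planted effects."""

import numpy as np
import pytest

from gxescreen.phenotypes import CTS5_COLUMNS, build_catalog
from gxescreen.prs import prs_pca
from gxescreen.simulate import (
    AceSpec,
    InfeasibleInteractionError,
    InteractionSpec,
    OutcomeSpec,
    PrsSpec,
    SimulationScenario,
    cohort_hash,
    data_dictionary,
    demo_scenario,
    generate_cohort,
    plant_additive_interaction,
    scenario_from_yaml,
    write_cohort,
)

from helpers import FLAT_SOLO, solo_scenario


class TestPlantAdditiveInteraction:
    def test_multiplicative_null_reri(self):
        # RERI 0.5 = 3 - 2 - 1.5 + 1 happens to need no product term
        b3 = plant_additive_interaction(np.log(2.0), np.log(1.5), 0.5)
        assert b3 == pytest.approx(0.0, abs=1e-12)

    def test_full_null(self):
        assert plant_additive_interaction(0.0, 0.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_zero_reri_needs_negative_product_term(self):
        b3 = plant_additive_interaction(np.log(2.0), np.log(1.5), 0.0)
        assert b3 == pytest.approx(np.log(2.5 / 3.0), abs=1e-12)

    def test_infeasible_target_rejected(self):
        with pytest.raises(InfeasibleInteractionError):
            plant_additive_interaction(0.0, 0.0, -1.5)


class TestGenerateCohort:
    def test_null_model_prevalence(self):
        scenario = solo_scenario(10_000, seed=41, prevalence=0.3, beta_prs=0.0, beta_ace=0.0)
        cohort = generate_cohort(scenario)
        se = np.sqrt(0.3 * 0.7 / 10_000)
        assert abs(cohort["item_solo"].mean() - 0.3) < 3 * se

    def test_degenerate_correlation_gives_proportional_columns(self):
        scenario = SimulationScenario(
            n_participants=500,
            seed=42,
            catalog=FLAT_SOLO,
            prs_spec={"scz": PrsSpec(inter_threshold_correlation=1.0), "bip": PrsSpec()},
        )
        cohort = generate_cohort(scenario)
        cols = [cohort[f"scz_score_t{t}"] for t in (1, 5, 10)]
        for col in cols[1:]:
            assert abs(np.corrcoef(cols[0], col)[0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_pc1_variance_target_honoured(self):
        scenario = SimulationScenario(
            n_participants=20_000,
            seed=43,
            catalog=FLAT_SOLO,
            prs_spec={"scz": PrsSpec(pc1_variance_target=0.8), "bip": PrsSpec()},
        )
        cohort = generate_cohort(scenario)
        mat = cohort[[f"scz_score_t{t}" for t in range(1, 11)]]
        assert prs_pca(mat).pc1_variance_fraction == pytest.approx(0.8, abs=0.02)

    def test_identical_seed_reproduces_identical_table(self):
        a = generate_cohort(solo_scenario(800, seed=44))
        b = generate_cohort(solo_scenario(800, seed=44))
        c = generate_cohort(solo_scenario(800, seed=45))
        assert cohort_hash(a) == cohort_hash(b)
        assert cohort_hash(a) != cohort_hash(c)

    def test_invalid_probability_names_field(self):
        scenario = SimulationScenario(
            n_participants=100,
            seed=0,
            catalog=FLAT_SOLO,
            ace_spec=AceSpec(endorsement_probs=(0.1, 0.1, 1.2, 0.1, 0.1)),
        )
        with pytest.raises(ValueError, match="endorsement_probs"):
            generate_cohort(scenario)

    def test_invalid_prevalence_names_field(self):
        scenario = solo_scenario(100, seed=0, prevalence=0.3)
        bad = SimulationScenario(
            n_participants=100,
            seed=0,
            catalog=FLAT_SOLO,
            outcome_spec={"solo": OutcomeSpec(baseline_prevalence=1.5)},
        )
        generate_cohort(scenario)  # sanity: the valid twin passes
        with pytest.raises(ValueError, match="baseline_prevalence"):
            generate_cohort(bad)

    def test_unknown_outcome_symptom_rejected(self):
        scenario = SimulationScenario(
            n_participants=100,
            seed=0,
            catalog=FLAT_SOLO,
            outcome_spec={"ghost": OutcomeSpec()},
        )
        with pytest.raises(ValueError, match="ghost"):
            generate_cohort(scenario)

    def test_missingness_respects_inclusion_rule(self):
        scenario = SimulationScenario(
            n_participants=3000,
            seed=46,
            catalog=FLAT_SOLO,
            ace_spec=AceSpec(missing_rate=0.5),
        )
        cohort = generate_cohort(scenario)
        items = cohort[list(CTS5_COLUMNS)]
        assert items.isna().any().any()
        assert (items.isna().all(axis=1)).sum() == 0

    def test_planted_multiplicative_effect_recovered(self):
        from gxescreen import fit_logistic
        from gxescreen.pipeline import prepare_cohort
        from helpers import INTERACTION_TERM, NOCOV_INTERACTION

        scenario = solo_scenario(
            40_000, seed=47, interaction=InteractionSpec("multiplicative", 0.5)
        )
        derived, _ = prepare_cohort(generate_cohort(scenario), FLAT_SOLO)
        fit = fit_logistic(derived, NOCOV_INTERACTION)
        b3, se = fit.get(INTERACTION_TERM)
        assert abs(b3 - 0.5) < 3 * se

    def test_cognition_items_are_continuous(self):
        catalog = build_catalog({"cognition": 2}, continuous_domains=("cognition",))
        scenario = SimulationScenario(n_participants=500, seed=48, catalog=catalog)
        cohort = generate_cohort(scenario)
        values = cohort["item_cognition_01"]
        assert values.nunique() > 100  # continuous test score, not 0/1


class TestScenarioIO:
    def test_write_cohort_and_dictionary(self, tmp_path):
        scenario = demo_scenario(300, seed=1)
        cohort = generate_cohort(scenario)
        path = tmp_path / "cohort.tsv"
        write_cohort(cohort, str(path), scenario)
        assert path.exists()
        assert (tmp_path / "cohort.dictionary.json").exists()
        dictionary = data_dictionary(scenario)
        assert dictionary["cts5_item_1"]["ace_type"] == "physical_abuse"
        assert dictionary["scz_score_t1"]["role"] == "threshold_score"

    def test_scenario_yaml_round_trip(self, tmp_path):
        config = """
n_participants: 250
seed: 9
ace_spec:
  endorsement_probs: [0.05, 0.1, 0.05, 0.15, 0.05]
  item_correlation: 0.3
outcome_spec:
  solo:
    baseline_prevalence: 0.2
    beta_prs_scz: 0.4
    interaction_scz: {scale: multiplicative, value: -0.2}
"""
        path = tmp_path / "scenario.yaml"
        path.write_text(config)
        scenario = scenario_from_yaml(str(path), catalog=FLAT_SOLO)
        assert scenario.n_participants == 250
        assert scenario.outcome_spec["solo"].interaction_scz.value == -0.2
        cohort = generate_cohort(scenario)
        assert len(cohort) == 250
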