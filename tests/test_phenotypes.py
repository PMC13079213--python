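"""Adversity classification and phenotype catalog behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gxescreen.phenotypes import (
    AllItemsMissingError,
    PhenotypeCatalog,
    PhenotypeEntry,
    build_catalog,
    catalog_from_yaml,
    catalog_to_yaml,
    default_catalog,
    derive_ace,
    derive_ace_table,
    derive_domain,
    derive_phenotypes,
    derive_symptom,
)

# item order: physical abuse, emotional abuse, sexual abuse (forward-keyed),
# emotional neglect, physical neglect (reverse-keyed)
NONE_ENDORSED = [0, 0, 0, 4, 4]


class TestDeriveAce:
    @pytest.mark.parametrize(
        "items, any_ace, count, flag_name",
        [
            # "Sometimes true" on an abuse item is endorsement
            ([2, 0, 0, 4, 4], 1, 1, "physical_abuse"),
            # "Never true" on the reverse-keyed felt-loved item is neglect
            ([0, 0, 0, 0, 4], 1, 1, "emotional_neglect"),
            # "Often"/"Very often" on abuse
            ([0, 3, 0, 4, 4], 1, 1, "emotional_abuse"),
            ([0, 0, 4, 4, 4], 1, 1, "sexual_abuse"),
            # "Rarely true" on reverse-keyed doctor item is neglect
            ([0, 0, 0, 4, 1], 1, 1, "physical_neglect"),
        ],
    )
    def test_single_endorsement(self, items, any_ace, count, flag_name):
        status = derive_ace(items)
        assert status.any_ace == any_ace
        assert status.ace_count == count
        assert getattr(status, flag_name) == 1

    def test_fully_non_endorsed_profile(self):
        # abuse never true, neglect items "Very often true" (loved / cared for)
        status = derive_ace(NONE_ENDORSED)
        assert status.any_ace == 0
        assert status.ace_count == 0

    def test_rarely_true_abuse_is_not_endorsed(self):
        status = derive_ace([1, 1, 1, 4, 4])
        assert status.any_ace == 0

    def test_partial_missingness_classified_from_observed(self):
        status = derive_ace([None, 0, None, 4, 4])
        assert status.any_ace == 0
        assert status.physical_abuse is None
        assert status.ace_count == 0

    def test_all_missing_raises(self):
        with pytest.raises(AllItemsMissingError):
            derive_ace([None] * 5)

    def test_out_of_range_code_rejected(self):
        with pytest.raises(ValueError, match="outside levels"):
            derive_ace([5, 0, 0, 4, 4])

    @given(
        base=st.lists(st.integers(0, 4), min_size=5, max_size=5),
        item=st.integers(0, 4),
    )
    def test_monotonicity_extra_endorsement(self, base, item):
        """Endorsing one more item never lowers the count or clears any_ace."""
        before = derive_ace(base)
        endorsed = list(base)
        endorsed[item] = 4 if item < 3 else 0  # force endorsement on that item
        after = derive_ace(endorsed)
        assert after.ace_count >= before.ace_count
        if before.any_ace == 1:
            assert after.any_ace == 1

    def test_table_derivation_and_exclusions(self):
        cohort = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c"],
                "cts5_item_1": [2.0, np.nan, 0.0],
                "cts5_item_2": [0.0, np.nan, 0.0],
                "cts5_item_3": [0.0, np.nan, 0.0],
                "cts5_item_4": [4.0, np.nan, 4.0],
                "cts5_item_5": [4.0, np.nan, 4.0],
            }
        )
        derived, exclusions = derive_ace_table(cohort)
        assert list(derived.index) == [0, 2]
        assert derived.loc[0, "any_ace"] == 1 and derived.loc[2, "any_ace"] == 0
        assert list(exclusions["participant_id"]) == ["b"]


class TestSymptomsAndDomains:
    def test_direct_identity_and_validation(self):
        entry = PhenotypeEntry("s", "s", "d", "symptom", ("item_s",))
        frame = pd.DataFrame({"item_s": [0.0, 1.0, np.nan]})
        out = derive_symptom(frame, entry)
        assert out.tolist()[:2] == [0.0, 1.0] and np.isnan(out.iloc[2])
        with pytest.raises(ValueError, match="non-binary"):
            derive_symptom(pd.DataFrame({"item_s": [2.0]}), entry)

    def test_ordinal_threshold_rule(self):
        entry = PhenotypeEntry(
            "s", "s", "d", "symptom", ("item_s",), rule="ordinal_threshold",
            rule_params={"threshold": 2},
        )
        out = derive_symptom(pd.DataFrame({"item_s": [0, 1, 2, 3]}), entry)
        assert out.tolist() == [0.0, 0.0, 1.0, 1.0]

    def test_quantile_impairment_rule(self):
        entry = PhenotypeEntry(
            "cog", "cog", "cognition", "symptom", ("item_cog",),
            rule="quantile_impairment", rule_params={"quantile": 0.25},
        )
        frame = pd.DataFrame({"item_cog": np.arange(100.0)})
        out = derive_symptom(frame, entry)
        assert out.sum() == pytest.approx(25, abs=1)
        assert out.iloc[0] == 1.0 and out.iloc[-1] == 0.0

    def test_unregistered_rule_rejected(self):
        with pytest.raises(ValueError, match="unregistered"):
            PhenotypeEntry("s", "s", "d", "symptom", ("item_s",), rule="mystery")

    @pytest.mark.parametrize(
        "members, expected",
        [
            ([(0, 0, 1)], 1.0),
            ([(0, 0, 0)], 0.0),
        ],
    )
    def test_domain_any_endorsement(self, members, expected):
        frame = pd.DataFrame(np.array(members, dtype=float))
        assert derive_domain(frame).iloc[0] == expected

    def test_domain_missing_handling(self):
        frame = pd.DataFrame([[np.nan, 1.0], [np.nan, np.nan], [np.nan, 0.0]])
        out = derive_domain(frame)
        assert out.iloc[0] == 1.0
        assert np.isnan(out.iloc[1])
        assert out.iloc[2] == 0.0

    @given(values=st.lists(st.sampled_from([0.0, 1.0, np.nan]), min_size=2, max_size=6))
    def test_domain_invariant_to_member_order(self, values):
        frame = pd.DataFrame([values])
        shuffled = pd.DataFrame([values[::-1]])
        a, b = derive_domain(frame).iloc[0], derive_domain(shuffled).iloc[0]
        assert (np.isnan(a) and np.isnan(b)) or a == b


class TestCatalog:
    def test_default_catalog_counts(self):
        cat = default_catalog()
        cat.validate_standard()
        assert cat.n_symptoms == 55
        assert cat.n_domains == 7
        assert cat.n_phenotypes == 61
        # the single-symptom domain is one shared entry
        help_seeking = cat.get("help_seeking")
        assert help_seeking.level == "both"

    def test_duplicate_ids_rejected(self):
        e = PhenotypeEntry("x", "x", "d", "symptom", ("item_x",))
        with pytest.raises(ValueError, match="duplicate"):
            PhenotypeCatalog(entries=(e, e))

    def test_domain_member_reference_checked(self):
        s = PhenotypeEntry("x", "x", "d", "symptom", ("item_x",))
        d = PhenotypeEntry("dom_d", "d", "d", "domain", ("x", "ghost"), rule="any_member")
        with pytest.raises(ValueError, match="unknown symptoms"):
            PhenotypeCatalog(entries=(s, d))

    def test_yaml_round_trip(self, tmp_path):
        cat = build_catalog({"a": 2, "b": 1}, continuous_domains=())
        path = tmp_path / "catalog.yaml"
        catalog_to_yaml(cat, str(path))
        loaded = catalog_from_yaml(str(path))
        assert loaded == cat

    def test_derive_phenotypes_columns(self):
        cat = build_catalog({"a": 2, "b": 1}, continuous_domains=())
        rng = np.random.default_rng(0)
        cohort = pd.DataFrame(
            {f"item_{pid}": rng.integers(0, 2, 50).astype(float)
             for pid in ("a_01", "a_02", "b")}
        )
        out = derive_phenotypes(cohort, cat)
        assert set(out.columns) == {"a_01", "a_02", "b", "dom_a"}
        expected_dom = ((out["a_01"] == 1) | (out["a_02"] == 1)).astype(float)
        assert (out["dom_a"] == expected_dom).all()
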