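"""Synthetic cohort generator with planted gene-environment effects.

Produces participant-level tables with the structure the interaction
models assume: correlated per-threshold polygenic-score columns for two
disorders, five ordinal adversity items with realistic endorsement rates,
recruitment covariates (sex, birth year, ordinal socioeconomic variables,
deprivation index, 10 genetic principal components) and binary symptom
items drawn from logistic models whose linear predictor uses exactly the
dichotomised exposures the downstream pipeline reconstructs (high/low
aggregated PRS, any/no adversity).  Every planted coefficient is therefore
on the same scale as its downstream estimate, giving exact ground truth
for parameter-recovery, CI-coverage and screening tests.

Interaction effects can be planted on either scale: a multiplicative
interaction is the product-term log-OR itself, while an additive
interaction is specified as a target RERI and converted to the product
coefficient that realises it exactly via
:func:`plant_additive_interaction`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit as logit_fn

from .phenotypes import (
    ACE_TYPES,
    CTS5_COLUMNS,
    PhenotypeCatalog,
    default_catalog,
    derive_ace_table,
)
from .prs import PrsPca

__all__ = [
    "PrsSpec",
    "AceSpec",
    "CovariateSpec",
    "InteractionSpec",
    "OutcomeSpec",
    "SimulationScenario",
    "plant_additive_interaction",
    "generate_cohort",
    "cohort_hash",
    "data_dictionary",
    "write_cohort",
    "demo_scenario",
    "scenario_from_yaml",
]


class InfeasibleInteractionError(ValueError):
    """The requested RERI cannot be realised by any product-term coefficient."""


def plant_additive_interaction(
    beta_prs: float, beta_ace: float, target_reri: float
) -> float:
    """Product-term log-OR that realises an exact target RERI.

    Inverts RERI = exp(b1+b2+b3) - exp(b1) - exp(b2) + 1:
    b3 = log(target + exp(b1) + exp(b2) - 1) - b1 - b2.
    Feasible only while the implied joint OR stays positive.
    """
    arg = target_reri + np.exp(beta_prs) + np.exp(beta_ace) - 1.0
    if arg <= 0:
        raise InfeasibleInteractionError(
            f"target RERI {target_reri} infeasible for beta_prs={beta_prs}, "
            f"beta_ace={beta_ace}: implied joint OR {arg} is not positive"
        )
    return float(np.log(arg) - beta_prs - beta_ace)


# ---------------------------------------------------------------------------
# Scenario specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrsSpec:
    """Per-disorder threshold-score structure.

    Columns are drawn from an equicorrelated multivariate normal and then
    rescaled by a geometric decay (10**0 ... 10**-3) to mimic the orders-of-
    magnitude scale differences between p-value thresholds.  If
    ``pc1_variance_target`` is given, the implied equicorrelation
    rho = (k*t - 1)/(k - 1) is used instead of ``inter_threshold_correlation``.
    """

    n_thresholds: int = 10
    inter_threshold_correlation: float = 0.8
    pc1_variance_target: Optional[float] = None

    def correlation(self) -> float:
        k = self.n_thresholds
        if self.pc1_variance_target is not None:
            t = self.pc1_variance_target
            if not (1.0 / k < t <= 1.0):
                raise ValueError(
                    f"pc1_variance_target must lie in (1/{k}, 1], got {t}"
                )
            return (k * t - 1.0) / (k - 1.0)
        rho = self.inter_threshold_correlation
        if not (0.0 < rho <= 1.0):
            raise ValueError(
                f"inter_threshold_correlation must lie in (0, 1], got {rho}"
            )
        return rho


@dataclass(frozen=True)
class AceSpec:
    """Ordinal adversity items via a latent Gaussian copula.

    ``endorsement_probs`` are the marginal probabilities of an adverse
    response per item (abuse items: "Sometimes true" or worse; neglect
    items: "Never/Rarely true" on the reverse-keyed questions).
    """

    endorsement_probs: tuple[float, ...] = (0.06, 0.10, 0.05, 0.15, 0.04)
    item_correlation: float = 0.35
    missing_rate: float = 0.0


@dataclass(frozen=True)
class CovariateSpec:
    p_male: float = 0.437
    birth_year_mean: float = 1953.0
    birth_year_sd: float = 8.0
    employment_probs: tuple[float, ...] = (0.55, 0.25, 0.15, 0.05)
    income_probs: tuple[float, ...] = (0.15, 0.25, 0.25, 0.20, 0.15)
    smoking_probs: tuple[float, ...] = (0.55, 0.35, 0.10)
    education_probs: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25, 0.30)
    imd_shape: float = 2.0
    imd_scale: float = 8.0
    n_genetic_pcs: int = 10


@dataclass(frozen=True)
class InteractionSpec:
    """Planted interaction: ``scale`` is "multiplicative" (value = product-term
    log-OR) or "additive" (value = target RERI)."""

    scale: str
    value: float

    def __post_init__(self) -> None:
        if self.scale not in ("multiplicative", "additive"):
            raise ValueError(f"interaction scale must be multiplicative|additive, got {self.scale!r}")


@dataclass(frozen=True)
class OutcomeSpec:
    """Planted generative model for one symptom.

    Binary symptoms: Bernoulli with logit = logit(baseline_prevalence)
    + beta_prs_scz*G_scz + beta_prs_bip*G_bip + beta_ace*E + interactions
    + covariate terms, where G and E are the dichotomised exposures and
    covariate effects apply to internally standardised covariate values.
    Continuous symptoms (cognition tests): standard normal shifted
    downward by the same linear predictor (impairment = low score), in SD
    units, then dichotomised downstream at the catalog quantile.
    ``ace_variable`` selects which derived adversity variable drives the
    effect: ``any_ace``, ``ace_count`` or one of the five type flags.
    """

    baseline_prevalence: float = 0.15
    beta_prs_scz: float = 0.0
    beta_prs_bip: float = 0.0
    beta_ace: float = 0.0
    ace_variable: str = "any_ace"
    interaction_scz: Optional[InteractionSpec] = None
    interaction_bip: Optional[InteractionSpec] = None
    covariate_betas: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimulationScenario:
    n_participants: int
    seed: int
    catalog: PhenotypeCatalog
    prs_spec: Mapping[str, PrsSpec] = field(
        default_factory=lambda: {"scz": PrsSpec(), "bip": PrsSpec()}
    )
    ace_spec: AceSpec = field(default_factory=AceSpec)
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    outcome_spec: Mapping[str, OutcomeSpec] = field(default_factory=dict)
    symptom_missing_rate: float = 0.0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError(f"n_participants must be >= 1, got {self.n_participants}")
        for disorder, spec in self.prs_spec.items():
            spec.correlation()  # raises with the field name
            if spec.n_thresholds < 2:
                raise ValueError(f"prs_spec[{disorder}].n_thresholds must be >= 2")
        if len(self.ace_spec.endorsement_probs) != 5:
            raise ValueError("ace_spec.endorsement_probs must have 5 entries")
        for i, p in enumerate(self.ace_spec.endorsement_probs):
            if not (0.0 < p < 1.0):
                raise ValueError(
                    f"ace_spec.endorsement_probs[{i}] must lie in (0, 1), got {p}"
                )
        if not (0.0 < self.ace_spec.item_correlation < 1.0):
            raise ValueError(
                f"ace_spec.item_correlation must lie in (0, 1), got "
                f"{self.ace_spec.item_correlation}"
            )
        if not (0.0 <= self.ace_spec.missing_rate < 1.0):
            raise ValueError("ace_spec.missing_rate must lie in [0, 1)")
        if not (0.0 < self.covariate_spec.p_male < 1.0):
            raise ValueError("covariate_spec.p_male must lie in (0, 1)")
        symptom_ids = {e.phenotype_id for e in self.catalog.symptoms}
        valid_ace_vars = {"any_ace", "ace_count", *ACE_TYPES}
        for pid, spec in self.outcome_spec.items():
            if pid not in symptom_ids:
                raise ValueError(f"outcome_spec names unknown symptom {pid!r}")
            if not (0.0 < spec.baseline_prevalence < 1.0):
                raise ValueError(
                    f"outcome_spec[{pid}].baseline_prevalence must lie in (0, 1), "
                    f"got {spec.baseline_prevalence}"
                )
            if spec.ace_variable not in valid_ace_vars:
                raise ValueError(
                    f"outcome_spec[{pid}].ace_variable {spec.ace_variable!r} unknown"
                )
            for inter, beta_prs in (
                (spec.interaction_scz, spec.beta_prs_scz),
                (spec.interaction_bip, spec.beta_prs_bip),
            ):
                if inter is not None and inter.scale == "additive":
                    if spec.ace_variable not in {"any_ace", *ACE_TYPES}:
                        raise ValueError(
                            f"outcome_spec[{pid}]: additive interaction requires a "
                            "binary adversity variable"
                        )
                    plant_additive_interaction(beta_prs, spec.beta_ace, inter.value)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _equicorrelated_normal(
    rng: np.random.Generator, n: int, k: int, rho: float
) -> np.ndarray:
    if rho == 1.0:
        z = rng.standard_normal((n, 1))
        return np.repeat(z, k, axis=1)
    shared = rng.standard_normal((n, 1))
    unique = rng.standard_normal((n, k))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * unique


def _threshold_scores(rng: np.random.Generator, n: int, spec: PrsSpec) -> np.ndarray:
    k = spec.n_thresholds
    z = _equicorrelated_normal(rng, n, k, spec.correlation())
    scales = 10.0 ** np.linspace(0.0, -3.0, k)
    return z * scales


# within-group ordinal code probabilities given endorsement status
_ABUSE_ENDORSED = ((2, 3, 4), (0.5, 0.3, 0.2))
_ABUSE_NOT = ((0, 1), (0.85, 0.15))
_NEGLECT_ENDORSED = ((0, 1), (0.55, 0.45))
_NEGLECT_NOT = ((2, 3, 4), (0.15, 0.35, 0.5))


def _ordinal_items(rng: np.random.Generator, n: int, spec: AceSpec) -> np.ndarray:
    from scipy.stats import norm as _norm

    z = _equicorrelated_normal(rng, n, 5, spec.item_correlation)
    cuts = _norm.ppf(np.asarray(spec.endorsement_probs))
    endorsed = z < cuts  # lower tail -> adverse response
    codes = np.empty((n, 5), dtype=float)
    for j in range(5):
        if j < 3:
            yes_levels, yes_p = _ABUSE_ENDORSED
            no_levels, no_p = _ABUSE_NOT
        else:
            yes_levels, yes_p = _NEGLECT_ENDORSED
            no_levels, no_p = _NEGLECT_NOT
        codes[:, j] = np.where(
            endorsed[:, j],
            rng.choice(yes_levels, size=n, p=yes_p),
            rng.choice(no_levels, size=n, p=no_p),
        )
    if spec.missing_rate > 0:
        mask = rng.random((n, 5)) < spec.missing_rate
        # inclusion rule: keep at least one observed item per row
        all_masked = mask.all(axis=1)
        if all_masked.any():
            keep = rng.integers(0, 5, size=int(all_masked.sum()))
            mask[np.flatnonzero(all_masked), keep] = False
        codes = np.where(mask, np.nan, codes)
    return codes


def _covariates(rng: np.random.Generator, n: int, spec: CovariateSpec) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "sex": rng.binomial(1, spec.p_male, size=n),
            "birth_year": np.round(
                rng.normal(spec.birth_year_mean, spec.birth_year_sd, size=n)
            ).astype(int),
            "employment": rng.choice(
                len(spec.employment_probs), size=n, p=spec.employment_probs
            ),
            "income": rng.choice(len(spec.income_probs), size=n, p=spec.income_probs),
            "smoking": rng.choice(len(spec.smoking_probs), size=n, p=spec.smoking_probs),
            "education": rng.choice(
                len(spec.education_probs), size=n, p=spec.education_probs
            ),
            "imd": rng.gamma(spec.imd_shape, spec.imd_scale, size=n),
        }
    )
    for i in range(1, spec.n_genetic_pcs + 1):
        out[f"gpc{i}"] = rng.standard_normal(n)
    return out


def _resolve_interaction(
    inter: Optional[InteractionSpec], beta_prs: float, beta_ace: float
) -> float:
    if inter is None:
        return 0.0
    if inter.scale == "multiplicative":
        return inter.value
    return plant_additive_interaction(beta_prs, beta_ace, inter.value)


def generate_cohort(scenario: SimulationScenario) -> pd.DataFrame:
    """Generate a participant-level cohort table for the scenario.

    Identical (scenario, seed) pairs reproduce the identical table
    bit-for-bit; all randomness flows from one generator seeded with
    ``scenario.seed``.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_participants

    cohort = pd.DataFrame({"participant_id": [f"P{i:07d}" for i in range(n)]})
    cohort = pd.concat([cohort, _covariates(rng, n, scenario.covariate_spec)], axis=1)

    items = _ordinal_items(rng, n, scenario.ace_spec)
    for j, col in enumerate(CTS5_COLUMNS):
        cohort[col] = items[:, j]

    score_blocks: dict[str, np.ndarray] = {}
    for disorder in ("scz", "bip"):
        spec = scenario.prs_spec.get(disorder, PrsSpec())
        scores = _threshold_scores(rng, n, spec)
        score_blocks[disorder] = scores
        for t in range(spec.n_thresholds):
            cohort[f"{disorder}_score_t{t + 1}"] = scores[:, t]

    # exposures exactly as the downstream pipeline reconstructs them
    ace, _ = derive_ace_table(cohort)
    prs_high = {
        d: PrsPca().fit_result(score_blocks[d]).high.astype(float)
        for d in ("scz", "bip")
    }

    cov_z: dict[str, np.ndarray] = {}

    def _standardised(col: str) -> np.ndarray:
        if col not in cov_z:
            x = cohort[col].to_numpy(dtype=float)
            sd = x.std(ddof=1)
            cov_z[col] = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        return cov_z[col]

    for entry in scenario.catalog.symptoms:
        spec = scenario.outcome_spec.get(entry.phenotype_id, OutcomeSpec())
        e = ace[spec.ace_variable].to_numpy(dtype=float)
        g_scz = prs_high["scz"]
        g_bip = prs_high["bip"]
        b3_scz = _resolve_interaction(spec.interaction_scz, spec.beta_prs_scz, spec.beta_ace)
        b3_bip = _resolve_interaction(spec.interaction_bip, spec.beta_prs_bip, spec.beta_ace)
        eta = (
            spec.beta_prs_scz * g_scz
            + spec.beta_prs_bip * g_bip
            + spec.beta_ace * e
            + b3_scz * g_scz * e
            + b3_bip * g_bip * e
        )
        for col, beta in spec.covariate_betas.items():
            eta = eta + beta * _standardised(col)
        col = entry.members[0]
        if entry.rule == "quantile_impairment":
            # continuous test score; impairment = low values
            cohort[col] = rng.standard_normal(n) - eta
        else:
            p = expit(logit_fn(spec.baseline_prevalence) + eta)
            cohort[col] = rng.binomial(1, p).astype(float)
        if scenario.symptom_missing_rate > 0:
            mask = rng.random(n) < scenario.symptom_missing_rate
            cohort.loc[mask, col] = np.nan

    return cohort


def cohort_hash(cohort: pd.DataFrame) -> str:
    """SHA-256 of the cohort serialised as CSV (determinism checks)."""
    return hashlib.sha256(cohort.to_csv(index=False).encode()).hexdigest()


def data_dictionary(scenario: SimulationScenario) -> dict[str, dict]:
    """Machine-readable column roles and levels for a generated cohort."""
    d: dict[str, dict] = {"participant_id": {"role": "identifier"}}
    for col in ("sex", "birth_year", "employment", "income", "smoking", "education", "imd"):
        role = "covariate"
        levels = {
            "sex": [0, 1],
            "employment": list(range(len(scenario.covariate_spec.employment_probs))),
            "income": list(range(len(scenario.covariate_spec.income_probs))),
            "smoking": list(range(len(scenario.covariate_spec.smoking_probs))),
            "education": list(range(len(scenario.covariate_spec.education_probs))),
        }.get(col)
        d[col] = {"role": role, **({"levels": levels} if levels else {})}
    for i in range(1, scenario.covariate_spec.n_genetic_pcs + 1):
        d[f"gpc{i}"] = {"role": "covariate"}
    for col, ace_type in zip(CTS5_COLUMNS, ACE_TYPES):
        d[col] = {
            "role": "adversity_item",
            "ace_type": ace_type,
            "levels": list(range(5)),
        }
    for disorder in ("scz", "bip"):
        spec = scenario.prs_spec.get(disorder, PrsSpec())
        for t in range(spec.n_thresholds):
            d[f"{disorder}_score_t{t + 1}"] = {
                "role": "threshold_score",
                "disorder": disorder,
            }
    for entry in scenario.catalog.symptoms:
        d[entry.members[0]] = {
            "role": "symptom_item",
            "phenotype_id": entry.phenotype_id,
            "domain": entry.domain,
            "kind": "continuous" if entry.rule == "quantile_impairment" else "binary",
        }
    return d


def write_cohort(
    cohort: pd.DataFrame, path: str, scenario: Optional[SimulationScenario] = None
) -> None:
    """Write the cohort as TSV; with a scenario, also a data dictionary JSON."""
    cohort.to_csv(path, sep="\t", index=False)
    if scenario is not None:
        dict_path = str(path).rsplit(".", 1)[0] + ".dictionary.json"
        with open(dict_path, "w") as fh:
            json.dump(data_dictionary(scenario), fh, indent=1)


# ---------------------------------------------------------------------------
# Ready-made scenarios and config I/O
# ---------------------------------------------------------------------------


def demo_scenario(n_participants: int = 20_000, seed: int = 7) -> SimulationScenario:
    """A small demonstration scenario on a reduced catalog.

    Two multi-symptom domains plus a single-symptom help-seeking analogue;
    one symptom carries joint PRS and adversity effects with an
    antagonistic multiplicative interaction, one carries main effects only,
    and the rest are null.
    """
    from .phenotypes import build_catalog

    catalog = build_catalog({"alpha": 3, "beta": 3, "solo": 1}, continuous_domains=())
    outcome_spec = {
        "alpha_01": OutcomeSpec(
            baseline_prevalence=0.25,
            beta_prs_scz=np.log(1.5),
            beta_ace=np.log(2.0),
            interaction_scz=InteractionSpec("multiplicative", -0.3),
            covariate_betas={"imd": 0.1, "gpc1": 0.05},
        ),
        "alpha_02": OutcomeSpec(
            baseline_prevalence=0.2,
            beta_prs_scz=np.log(1.4),
            beta_ace=np.log(1.8),
        ),
        "beta_01": OutcomeSpec(baseline_prevalence=0.3, beta_ace=np.log(1.5)),
        "solo": OutcomeSpec(
            baseline_prevalence=0.15,
            beta_prs_bip=np.log(1.3),
            beta_ace=np.log(1.6),
        ),
    }
    return SimulationScenario(
        n_participants=n_participants,
        seed=seed,
        catalog=catalog,
        outcome_spec=outcome_spec,
    )


def scenario_from_yaml(path: str, catalog: Optional[PhenotypeCatalog] = None) -> SimulationScenario:
    """Load a scenario from a structured YAML config.

    The config mirrors the dataclass tree; ``catalog`` may be given inline
    as ``catalog: default`` or as a path to a catalog YAML, or passed in.
    """
    from .phenotypes import catalog_from_yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if catalog is None:
        cat_ref = cfg.get("catalog", "default")
        catalog = default_catalog() if cat_ref == "default" else catalog_from_yaml(cat_ref)

    def _interaction(d):
        return InteractionSpec(scale=d["scale"], value=float(d["value"])) if d else None

    outcome_spec = {
        pid: OutcomeSpec(
            baseline_prevalence=float(d.get("baseline_prevalence", 0.15)),
            beta_prs_scz=float(d.get("beta_prs_scz", 0.0)),
            beta_prs_bip=float(d.get("beta_prs_bip", 0.0)),
            beta_ace=float(d.get("beta_ace", 0.0)),
            ace_variable=d.get("ace_variable", "any_ace"),
            interaction_scz=_interaction(d.get("interaction_scz")),
            interaction_bip=_interaction(d.get("interaction_bip")),
            covariate_betas=d.get("covariate_betas", {}) or {},
        )
        for pid, d in (cfg.get("outcome_spec") or {}).items()
    }
    prs_spec = {
        k: PrsSpec(**v) for k, v in (cfg.get("prs_spec") or {"scz": {}, "bip": {}}).items()
    }
    ace_cfg = cfg.get("ace_spec") or {}
    if "endorsement_probs" in ace_cfg:
        ace_cfg["endorsement_probs"] = tuple(ace_cfg["endorsement_probs"])
    cov_cfg = cfg.get("covariate_spec") or {}
    for key in ("employment_probs", "income_probs", "smoking_probs", "education_probs"):
        if key in cov_cfg:
            cov_cfg[key] = tuple(cov_cfg[key])
    return SimulationScenario(
        n_participants=int(cfg["n_participants"]),
        seed=int(cfg.get("seed", 0)),
        catalog=catalog,
        prs_spec=prs_spec,
        ace_spec=AceSpec(**ace_cfg),
        covariate_spec=CovariateSpec(**cov_cfg),
        outcome_spec=outcome_spec,
        symptom_missing_rate=float(cfg.get("symptom_missing_rate", 0.0)),
    )


def with_seed(scenario: SimulationScenario, seed: int) -> SimulationScenario:
    """Copy of the scenario with a different seed."""
    return replace(scenario, seed=seed)
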