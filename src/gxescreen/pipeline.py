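"""Screening cascade: univariate screen, overlap selection, joint models,
interaction models, Bonferroni tiers and sensitivity analyses.

The cascade mirrors a phenome-wide gene-environment screen:

1. every catalog phenotype is regressed on each of the three binary
   exposures (high PRS for each disorder, any adversity) with covariate
   adjustment, at a Bonferroni level of alpha / (n_phenotypes x 3);
2. a phenotype is selected for a PRS only when both that PRS and the
   adversity exposure pass the univariate screen;
3. selected pairs get a joint main-effect model and an interaction model
   whose product term feeds the additive (RERI) and multiplicative
   statistics, with per-PRS Bonferroni tiers of alpha / n_selected;
4. optional sensitivity analyses: covariate x exposure product terms
   (Keller adjustment), adversity-count dose-response models, per-type
   adversity models, and a generic ancestry-style row filter.

Every attempted model lands exactly once in a result table or in the
exclusion log; flagged fits (separation, non-convergence) are never
silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .glm import DEFAULT_CATEGORICAL, DEFAULT_COVARIATES, FitResult, ModelSpec, fit_logistic
from .interaction import (
    classify_additive,
    classify_multiplicative,
    multiplicative_from_fit,
    reri_from_fit,
)
from .phenotypes import ACE_TYPES, PhenotypeCatalog, derive_ace_table, derive_phenotypes
from .prs import prs_pca

__all__ = [
    "PRS_EXPOSURES",
    "ACE_COLUMN",
    "bonferroni_alpha",
    "prepare_cohort",
    "ScreeningResult",
    "run_univariate_screen",
    "run_joint_models",
    "run_interaction_models",
    "run_sensitivity",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "write_outputs",
]

PRS_EXPOSURES: Mapping[str, str] = {"prs_scz": "prs_scz_high", "prs_bip": "prs_bip_high"}
ACE_COLUMN = "any_ace"
NOMINAL_ALPHA = 0.05


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test significance level alpha / n_tests."""
    if not isinstance(n_tests, (int, np.integer)) or n_tests < 1:
        raise ValueError(f"n_tests must be a positive integer, got {n_tests!r}")
    if not (0.0 < family_alpha < 1.0):
        raise ValueError(f"family alpha must lie in (0, 1), got {family_alpha}")
    return family_alpha / n_tests


def prepare_cohort(
    cohort: pd.DataFrame, catalog: PhenotypeCatalog, high_quantile: float = 0.75
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach derived exposure and phenotype columns to a raw cohort table.

    Adds ``any_ace``/``ace_count`` and the five adversity-type flags (rows
    with all five items missing are dropped and returned as exclusions),
    the aggregated standardized PRS and its high/low split per disorder,
    and one binary column per catalog phenotype.
    """
    ace, exclusions = derive_ace_table(cohort)
    df = cohort.loc[ace.index].copy()
    df = pd.concat([df, ace], axis=1)
    for disorder in ("scz", "bip"):
        pattern = re.compile(rf"^{disorder}_score_t(\d+)$")
        cols = sorted(
            (c for c in df.columns if pattern.match(c)),
            key=lambda c: int(pattern.match(c).group(1)),
        )
        if cols:
            result = prs_pca(df[cols], high_quantile=high_quantile)
            df[f"prs_{disorder}"] = result.score
            df[f"prs_{disorder}_high"] = result.high
    phen = derive_phenotypes(df, catalog)
    return pd.concat([df, phen], axis=1), exclusions


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    catalog: PhenotypeCatalog
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    categorical: tuple[str, ...] = DEFAULT_CATEGORICAL
    alpha: float = 0.05
    run_keller: bool = False
    run_dose: bool = False
    run_types: bool = False
    dose_coding: str = "linear"  # or "categorical"
    ancestry_column: Optional[str] = None
    ancestry_keep: Optional[tuple] = None
    outdir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.dose_coding not in ("linear", "categorical"):
            raise ValueError(f"dose_coding must be linear|categorical, got {self.dose_coding!r}")

    def hash(self) -> str:
        payload = {
            "alpha": self.alpha,
            "covariates": list(self.covariates),
            "categorical": list(self.categorical),
            "phenotypes": [e.phenotype_id for e in self.catalog.entries],
            "run_keller": self.run_keller,
            "run_dose": self.run_dose,
            "run_types": self.run_types,
            "dose_coding": self.dose_coding,
            "ancestry_column": self.ancestry_column,
            "ancestry_keep": list(self.ancestry_keep) if self.ancestry_keep else None,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


_EXCLUSION_COLUMNS = ["stage", "phenotype", "exposure", "reason"]


def _fit_or_exclude(
    df: pd.DataFrame,
    spec: ModelSpec,
    stage: str,
    phenotype: str,
    exposure: str,
    exclusions: list[dict],
) -> Optional[FitResult]:
    try:
        fit = fit_logistic(df, spec)
    except ValueError as err:  # e.g. single-level outcome among complete cases
        exclusions.append(
            {"stage": stage, "phenotype": phenotype, "exposure": exposure, "reason": str(err)}
        )
        return None
    if not fit.ok:
        reason = "quasi-complete separation" if fit.separation_flag else "non-convergence"
        exclusions.append(
            {"stage": stage, "phenotype": phenotype, "exposure": exposure, "reason": reason}
        )
        return None
    return fit


# ---------------------------------------------------------------------------
# Univariate screen
# ---------------------------------------------------------------------------


@dataclass
class ScreeningResult:
    """Per (phenotype x exposure) univariate estimates with pass/selection flags."""

    table: pd.DataFrame
    alpha_univariate: float
    exclusions: pd.DataFrame

    def passes(self, alpha: Optional[float] = None) -> pd.DataFrame:
        """Phenotype x exposure matrix of univariate pass flags."""
        alpha = self.alpha_univariate if alpha is None else alpha
        t = self.table
        flags = t.assign(ok=(t["p"] < alpha) & ~t["flagged"])
        return flags.pivot(index="phenotype", columns="exposure", values="ok").fillna(False)

    def selection(self, prs: str, alpha: Optional[float] = None) -> list[str]:
        """Phenotypes selected for one PRS: both the PRS and adversity pass."""
        wide = self.passes(alpha)
        if prs not in wide.columns or "ace" not in wide.columns:
            return []
        chosen = wide.index[wide[prs] & wide["ace"]]
        order = [p for p in self.table["phenotype"].unique() if p in set(chosen)]
        return order


def run_univariate_screen(
    df: pd.DataFrame, catalog: PhenotypeCatalog, config: PipelineConfig
) -> ScreeningResult:
    """Regress every catalog phenotype on each exposure separately.

    The Bonferroni family is the realized catalog size times the number of
    exposures (three: adversity plus one PRS per disorder), recomputed per
    run so reduced catalogs stay consistent.
    """
    exposures = {"ace": ACE_COLUMN, **PRS_EXPOSURES}
    n_tests = catalog.n_phenotypes * len(exposures)
    alpha_uni = bonferroni_alpha(config.alpha, n_tests)
    rows: list[dict] = []
    exclusions: list[dict] = []
    for entry in catalog.entries:
        for exposure, column in exposures.items():
            spec = ModelSpec(
                outcome=entry.phenotype_id,
                exposures=(column,),
                covariates=config.covariates,
                categorical=config.categorical,
            )
            fit = _fit_or_exclude(df, spec, "univariate", entry.phenotype_id, exposure, exclusions)
            if fit is None:
                rows.append(
                    {
                        "phenotype": entry.phenotype_id,
                        "domain": entry.domain,
                        "exposure": exposure,
                        "beta": np.nan,
                        "se": np.nan,
                        "or": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p": np.nan,
                        "n": np.nan,
                        "flagged": True,
                        "pass_univariate": False,
                    }
                )
                continue
            beta, se = fit.get(column)
            p = float(fit.pvalues()[fit.index(column)])
            rows.append(
                {
                    "phenotype": entry.phenotype_id,
                    "domain": entry.domain,
                    "exposure": exposure,
                    "beta": beta,
                    "se": se,
                    "or": float(np.exp(beta)),
                    "ci_low": float(np.exp(beta - 1.96 * se)),
                    "ci_high": float(np.exp(beta + 1.96 * se)),
                    "p": p,
                    "n": fit.n_used,
                    "flagged": False,
                    "pass_univariate": bool(p < alpha_uni),
                }
            )
    return ScreeningResult(
        table=pd.DataFrame(rows),
        alpha_univariate=alpha_uni,
        exclusions=pd.DataFrame(exclusions, columns=_EXCLUSION_COLUMNS),
    )


# ---------------------------------------------------------------------------
# Joint main-effect models
# ---------------------------------------------------------------------------


def run_joint_models(
    df: pd.DataFrame, screening: ScreeningResult, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Joint models (PRS + adversity, covariate-adjusted) per selected pair."""
    rows: list[dict] = []
    exclusions: list[dict] = []
    for prs, prs_col in PRS_EXPOSURES.items():
        for phenotype in screening.selection(prs):
            spec = ModelSpec(
                outcome=phenotype,
                exposures=(prs_col, ACE_COLUMN),
                covariates=config.covariates,
                categorical=config.categorical,
            )
            fit = _fit_or_exclude(df, spec, "joint", phenotype, prs, exclusions)
            if fit is None:
                continue
            for term, label in ((prs_col, prs), (ACE_COLUMN, "ace")):
                beta, se = fit.get(term)
                rows.append(
                    {
                        "phenotype": phenotype,
                        "prs": prs,
                        "term": label,
                        "beta": beta,
                        "se": se,
                        "or": float(np.exp(beta)),
                        "ci_low": float(np.exp(beta - 1.96 * se)),
                        "ci_high": float(np.exp(beta + 1.96 * se)),
                        "p": float(fit.pvalues()[fit.index(term)]),
                        "n": fit.n_used,
                    }
                )
    columns = ["phenotype", "prs", "term", "beta", "se", "or", "ci_low", "ci_high", "p", "n"]
    return (
        pd.DataFrame(rows, columns=columns),
        pd.DataFrame(exclusions, columns=_EXCLUSION_COLUMNS),
    )


# ---------------------------------------------------------------------------
# Interaction models
# ---------------------------------------------------------------------------


def _tier(p: float, alpha_bonferroni: float) -> str:
    if p < alpha_bonferroni:
        return "bonferroni"
    if p < NOMINAL_ALPHA:
        return "nominal"
    return "ns"


def _interaction_spec(
    phenotype: str, prs_col: str, config: PipelineConfig, extra_products=()
) -> ModelSpec:
    return ModelSpec(
        outcome=phenotype,
        exposures=(prs_col, ACE_COLUMN),
        interactions=((prs_col, ACE_COLUMN),),
        covariates=config.covariates,
        categorical=config.categorical,
        extra_products=tuple(extra_products),
    )


def run_interaction_models(
    df: pd.DataFrame, screening: ScreeningResult, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Additive (RERI) and multiplicative interaction per selected pair.

    Returns (additive, multiplicative, decomposition, exclusions); the
    per-PRS Bonferroni tier divides the family alpha by the realized count
    of phenotypes selected for that PRS.
    """
    additive_rows: list[dict] = []
    mult_rows: list[dict] = []
    decomp_rows: list[dict] = []
    exclusions: list[dict] = []
    for prs, prs_col in PRS_EXPOSURES.items():
        selected = screening.selection(prs)
        if not selected:
            continue
        alpha_b = bonferroni_alpha(config.alpha, len(selected))
        term = f"{prs_col}:{ACE_COLUMN}"
        for phenotype in selected:
            spec = _interaction_spec(phenotype, prs_col, config)
            fit = _fit_or_exclude(df, spec, "interaction", phenotype, prs, exclusions)
            if fit is None:
                continue
            add = reri_from_fit(fit, prs_col, ACE_COLUMN, term)
            mult = multiplicative_from_fit(fit, term)
            additive_rows.append(
                {
                    "phenotype": phenotype,
                    "prs": prs,
                    "reri": add.reri,
                    "se": add.se,
                    "ci_low": add.ci95[0],
                    "ci_high": add.ci95[1],
                    "p": add.p,
                    "or_11": add.or_11,
                    "or_10": add.or_10,
                    "or_01": add.or_01,
                    "excess_prs": add.excess_prs,
                    "excess_ace": add.excess_ace,
                    "n": fit.n_used,
                    "alpha_bonferroni": alpha_b,
                    "tier": _tier(add.p, alpha_b),
                    "classification": classify_additive(add),
                }
            )
            mult_rows.append(
                {
                    "phenotype": phenotype,
                    "prs": prs,
                    "coefficient": mult.coefficient,
                    "se": mult.se,
                    "ci_low": mult.ci95[0],
                    "ci_high": mult.ci95[1],
                    "p": mult.p,
                    "n": fit.n_used,
                    "alpha_bonferroni": alpha_b,
                    "tier": _tier(mult.p, alpha_b),
                    "classification": classify_multiplicative(mult.coefficient),
                }
            )
            decomp_rows.append(
                {
                    "phenotype": phenotype,
                    "prs": prs,
                    "excess_prs": add.excess_prs,
                    "excess_ace": add.excess_ace,
                    "reri": add.reri,
                    "reri_ci_low": add.ci95[0],
                    "reri_ci_high": add.ci95[1],
                    "log_or_prs": float(np.log(add.or_10)),
                    "log_or_ace": float(np.log(add.or_01)),
                    "interaction_coefficient": mult.coefficient,
                }
            )
    add_cols = [
        "phenotype", "prs", "reri", "se", "ci_low", "ci_high", "p", "or_11", "or_10",
        "or_01", "excess_prs", "excess_ace", "n", "alpha_bonferroni", "tier",
        "classification",
    ]
    mult_cols = [
        "phenotype", "prs", "coefficient", "se", "ci_low", "ci_high", "p", "n",
        "alpha_bonferroni", "tier", "classification",
    ]
    decomp_cols = [
        "phenotype", "prs", "excess_prs", "excess_ace", "reri", "reri_ci_low",
        "reri_ci_high", "log_or_prs", "log_or_ace", "interaction_coefficient",
    ]
    return (
        pd.DataFrame(additive_rows, columns=add_cols),
        pd.DataFrame(mult_rows, columns=mult_cols),
        pd.DataFrame(decomp_rows, columns=decomp_cols),
        pd.DataFrame(exclusions, columns=_EXCLUSION_COLUMNS),
    )


# ---------------------------------------------------------------------------
# Sensitivity analyses
# ---------------------------------------------------------------------------


def run_sensitivity(
    df: pd.DataFrame, screening: ScreeningResult, config: PipelineConfig
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Toggled sensitivity analyses.

    * ``keller``: interaction models re-fitted with every covariate x PRS
      and covariate x adversity product term added, so covariate
      confounding of the product term is controlled.
    * ``dose``: adversity-count dose-response models per domain phenotype,
      univariate and jointly with each PRS (linear count by default,
      per-level categorical optionally).
    * ``types``: per adversity-type models per domain phenotype,
      univariate and jointly with each PRS.
    """
    tables: dict[str, pd.DataFrame] = {}
    exclusions: list[dict] = []

    if config.run_keller:
        rows: list[dict] = []
        for prs, prs_col in PRS_EXPOSURES.items():
            selected = screening.selection(prs)
            if not selected:
                continue
            alpha_b = bonferroni_alpha(config.alpha, len(selected))
            term = f"{prs_col}:{ACE_COLUMN}"
            products = [(c, prs_col) for c in config.covariates]
            products += [(c, ACE_COLUMN) for c in config.covariates]
            for phenotype in selected:
                spec = _interaction_spec(phenotype, prs_col, config, products)
                fit = _fit_or_exclude(df, spec, "keller", phenotype, prs, exclusions)
                if fit is None:
                    continue
                add = reri_from_fit(fit, prs_col, ACE_COLUMN, term)
                mult = multiplicative_from_fit(fit, term)
                rows.append(
                    {
                        "phenotype": phenotype,
                        "prs": prs,
                        "coefficient": mult.coefficient,
                        "se": mult.se,
                        "p": mult.p,
                        "reri": add.reri,
                        "reri_se": add.se,
                        "reri_p": add.p,
                        "n": fit.n_used,
                        "tier": _tier(mult.p, alpha_b),
                    }
                )
        tables["keller"] = pd.DataFrame(
            rows,
            columns=[
                "phenotype", "prs", "coefficient", "se", "p", "reri", "reri_se",
                "reri_p", "n", "tier",
            ],
        )

    domain_ids = [e.phenotype_id for e in config.catalog.domains]

    if config.run_dose:
        rows = []
        exposure_term = "ace_count" if config.dose_coding == "linear" else "C(ace_count)"
        for phenotype in domain_ids:
            for model, extra in (
                ("univariate", ()),
                ("joint_prs_scz", ("prs_scz_high",)),
                ("joint_prs_bip", ("prs_bip_high",)),
            ):
                spec = ModelSpec(
                    outcome=phenotype,
                    exposures=(exposure_term, *extra),
                    covariates=config.covariates,
                    categorical=config.categorical,
                )
                fit = _fit_or_exclude(df, spec, f"dose_{model}", phenotype, "ace_count", exclusions)
                if fit is None:
                    continue
                for t in fit.terms:
                    if "ace_count" not in t:
                        continue
                    beta, se = fit.get(t)
                    level = t
                    m = re.search(r"\[T\.(.+)\]", t)
                    if m:
                        level = m.group(1)
                    elif t == "ace_count":
                        level = "per_count"
                    rows.append(
                        {
                            "phenotype": phenotype,
                            "model": model,
                            "level": level,
                            "beta": beta,
                            "se": se,
                            "or": float(np.exp(beta)),
                            "p": float(fit.pvalues()[fit.index(t)]),
                            "n": fit.n_used,
                        }
                    )
        tables["dose"] = pd.DataFrame(
            rows, columns=["phenotype", "model", "level", "beta", "se", "or", "p", "n"]
        )

    if config.run_types:
        rows = []
        for phenotype in domain_ids:
            for ace_type in ACE_TYPES:
                for model, extra in (
                    ("univariate", ()),
                    ("joint_prs_scz", ("prs_scz_high",)),
                    ("joint_prs_bip", ("prs_bip_high",)),
                ):
                    spec = ModelSpec(
                        outcome=phenotype,
                        exposures=(ace_type, *extra),
                        covariates=config.covariates,
                        categorical=config.categorical,
                    )
                    fit = _fit_or_exclude(
                        df, spec, f"types_{model}", phenotype, ace_type, exclusions
                    )
                    if fit is None:
                        continue
                    beta, se = fit.get(ace_type)
                    rows.append(
                        {
                            "phenotype": phenotype,
                            "ace_type": ace_type,
                            "model": model,
                            "beta": beta,
                            "se": se,
                            "or": float(np.exp(beta)),
                            "p": float(fit.pvalues()[fit.index(ace_type)]),
                            "n": fit.n_used,
                        }
                    )
        tables["types"] = pd.DataFrame(
            rows, columns=["phenotype", "ace_type", "model", "beta", "se", "or", "p", "n"]
        )

    return tables, pd.DataFrame(exclusions, columns=_EXCLUSION_COLUMNS)


# ---------------------------------------------------------------------------
# End-to-end driver
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    derived: pd.DataFrame
    screening: ScreeningResult
    joint: pd.DataFrame
    additive: pd.DataFrame
    multiplicative: pd.DataFrame
    decomposition: pd.DataFrame
    sensitivity: dict[str, pd.DataFrame]
    exclusions: pd.DataFrame


def run_pipeline(cohort: pd.DataFrame, config: PipelineConfig) -> PipelineResult:
    """Run the whole cascade on a raw cohort table."""
    if config.ancestry_column is not None and config.ancestry_keep is not None:
        cohort = cohort[cohort[config.ancestry_column].isin(config.ancestry_keep)]
    df, row_exclusions = prepare_cohort(cohort, config.catalog)
    screening = run_univariate_screen(df, config.catalog, config)
    joint, joint_excl = run_joint_models(df, screening, config)
    additive, multiplicative, decomposition, inter_excl = run_interaction_models(
        df, screening, config
    )
    sensitivity, sens_excl = run_sensitivity(df, screening, config)
    row_excl = row_exclusions.assign(
        stage="inclusion", phenotype="", exposure="",
    ).rename(columns={"participant_id": "unit"}) if len(row_exclusions) else pd.DataFrame(
        columns=["unit", "reason", "stage", "phenotype", "exposure"]
    )
    model_excl = pd.concat(
        [screening.exclusions, joint_excl, inter_excl, sens_excl], ignore_index=True
    )
    exclusions = pd.concat([row_excl, model_excl], ignore_index=True)
    return PipelineResult(
        derived=df,
        screening=screening,
        joint=joint,
        additive=additive,
        multiplicative=multiplicative,
        decomposition=decomposition,
        sensitivity=sensitivity,
        exclusions=exclusions,
    )


_TABLE_FILES = {
    "s3_univariate": lambda r: r.screening.table,
    "s4_joint_prs_scz": lambda r: r.joint[r.joint["prs"] == "prs_scz"],
    "s5_joint_prs_bip": lambda r: r.joint[r.joint["prs"] == "prs_bip"],
    "s6_additive_prs_scz": lambda r: r.additive[r.additive["prs"] == "prs_scz"],
    "s7_additive_prs_bip": lambda r: r.additive[r.additive["prs"] == "prs_bip"],
    "s8_multiplicative_prs_scz": lambda r: r.multiplicative[
        r.multiplicative["prs"] == "prs_scz"
    ],
    "s9_multiplicative_prs_bip": lambda r: r.multiplicative[
        r.multiplicative["prs"] == "prs_bip"
    ],
    "decomposition": lambda r: r.decomposition,
    "exclusions": lambda r: r.exclusions,
}

_SENSITIVITY_FILES = {"keller": "s10_keller", "dose": "s11_dose", "types": "s14_ace_types"}


def write_outputs(result: PipelineResult, config: PipelineConfig) -> Path:
    """Write tidy TSVs plus a JSON run manifest to ``config.outdir``."""
    if config.outdir is None:
        raise ValueError("config.outdir is not set")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, getter in _TABLE_FILES.items():
        getter(result).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    for key, fname in _SENSITIVITY_FILES.items():
        if key in result.sensitivity:
            result.sensitivity[key].to_csv(outdir / f"{fname}.tsv", sep="\t", index=False)
    manifest = {
        "package": "gxescreen",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.hash(),
        "n_rows_analysed": int(len(result.derived)),
        "alpha_univariate": result.screening.alpha_univariate,
        "selected_prs_scz": result.screening.selection("prs_scz"),
        "selected_prs_bip": result.screening.selection("prs_bip"),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir


def plot_decomposition(decomposition: pd.DataFrame, path: str) -> None:
    """Simple horizontal bar export of the excess-risk decomposition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if decomposition.empty:
        fig, ax = plt.subplots(figsize=(4, 2))
        ax.set_title("no selected phenotypes")
        fig.savefig(path)
        plt.close(fig)
        return
    groups = list(decomposition.groupby("prs"))
    fig, axes = plt.subplots(1, len(groups), figsize=(5 * len(groups), 0.5 * len(decomposition) + 2))
    axes = np.atleast_1d(axes)
    for ax, (prs, block) in zip(axes, groups):
        y = np.arange(len(block))
        ax.barh(y + 0.25, block["excess_prs"], height=0.25, label="excess risk, PRS alone")
        ax.barh(y, block["excess_ace"], height=0.25, label="excess risk, adversity alone")
        ax.barh(
            y - 0.25,
            block["reri"],
            height=0.25,
            xerr=np.vstack(
                [block["reri"] - block["reri_ci_low"], block["reri_ci_high"] - block["reri"]]
            ),
            label="RERI",
        )
        ax.set_yticks(y, block["phenotype"])
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel("excess risk (OR - 1 scale)")
        ax.set_title(prs)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
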