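"""Logistic-regression engine for the screening and interaction models.

All models are binary logistic regressions fitted by maximum likelihood on
complete cases for that model's columns.  A :class:`ModelSpec` names the
outcome, the binary exposures, optional exposure-pair interaction terms,
adjustment covariates (ordinal covariates enter as unordered categorical
indicators by default) and optional covariate x exposure product terms
(Keller-style sensitivity adjustment).  :class:`FitResult` carries the
coefficient vector with its variance-covariance matrix so downstream
interaction statistics can propagate uncertainty with the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    HessianInversionWarning,
    PerfectSeparationWarning,
)

try:  # raised by Logit on perfectly predicted outcomes
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
except ImportError:  # pragma: no cover
    class PerfectSeparationError(Exception):
        pass

__all__ = [
    "DEFAULT_COVARIATES",
    "DEFAULT_CATEGORICAL",
    "ModelSpec",
    "FitResult",
    "fit_logistic",
]

Z95 = 1.96

DEFAULT_COVARIATES: tuple[str, ...] = (
    "sex",
    "birth_year",
    "employment",
    "income",
    "smoking",
    "education",
    "imd",
) + tuple(f"gpc{i}" for i in range(1, 11))

#: ordinal covariates entered as unordered categorical indicators
DEFAULT_CATEGORICAL: tuple[str, ...] = ("employment", "income", "smoking", "education")

#: |beta| beyond which a fit is treated as quasi-complete separation
SEPARATION_BETA = 15.0


@dataclass(frozen=True)
class ModelSpec:
    """One logistic model: outcome ~ exposures (+ interactions) + covariates."""

    outcome: str
    exposures: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    categorical: tuple[str, ...] = DEFAULT_CATEGORICAL
    extra_products: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for a, b in self.interactions:
            if a not in self.exposures or b not in self.exposures:
                raise ValueError(
                    f"interaction ({a}, {b}) involves a term not listed in exposures"
                )

    def columns(self) -> list[str]:
        # exposures may carry a categorical wrapper, e.g. "C(ace_count)"
        def _raw(name: str) -> str:
            return name[2:-1] if name.startswith("C(") and name.endswith(")") else name

        cols = [self.outcome, *(_raw(e) for e in self.exposures), *self.covariates]
        cols += [c for c, _ in self.extra_products]
        seen: list[str] = []
        for c in cols:
            if c not in seen:
                seen.append(c)
        return seen

    def _cov_term(self, c: str) -> str:
        return f"C({c})" if c in self.categorical else c

    def formula(self) -> str:
        rhs = list(self.exposures)
        rhs += [f"{a}:{b}" for a, b in self.interactions]
        rhs += [self._cov_term(c) for c in self.covariates]
        rhs += [f"{self._cov_term(c)}:{e}" for c, e in self.extra_products]
        if not rhs:
            rhs = ["1"]
        return f"{self.outcome} ~ " + " + ".join(rhs)

    def interaction_term(self, a: str, b: str) -> str:
        return f"{a}:{b}"


@dataclass
class FitResult:
    """Coefficients, vcov and convergence metadata from one logistic fit."""

    terms: tuple[str, ...]
    beta: np.ndarray | None
    vcov: np.ndarray | None
    n_used: int
    converged: bool
    separation_flag: bool
    spec: ModelSpec | None = field(default=None, repr=False)

    @property
    def ok(self) -> bool:
        return self.converged and not self.separation_flag and self.beta is not None

    def index(self, term: str) -> int:
        try:
            return self.terms.index(term)
        except ValueError:
            raise KeyError(f"term {term!r} not in fitted model {list(self.terms)}")

    def get(self, term: str) -> tuple[float, float]:
        """(beta, se) for one term."""
        i = self.index(term)
        return float(self.beta[i]), float(np.sqrt(self.vcov[i, i]))

    def vcov_block(self, terms: Sequence[str]) -> np.ndarray:
        idx = [self.index(t) for t in terms]
        return self.vcov[np.ix_(idx, idx)]

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def pvalues(self) -> np.ndarray:
        z = self.beta / self.se()
        return 2.0 * norm.sf(np.abs(z))

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-term table: beta, SE, OR, 95% CI, Wald p, n."""
        if not self.ok:
            return pd.DataFrame(
                columns=["term", "beta", "se", "or", "ci_low", "ci_high", "p", "n"]
            )
        se = self.se()
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "beta": self.beta,
                "se": se,
                "or": np.exp(self.beta),
                "ci_low": np.exp(self.beta - Z95 * se),
                "ci_high": np.exp(self.beta + Z95 * se),
                "p": self.pvalues(),
                "n": self.n_used,
            }
        )


def fit_logistic(cohort: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Maximum-likelihood logistic fit on complete cases for the model columns.

    Non-convergence or quasi-complete separation (diverging coefficients or
    a perfectly predictive split) is flagged rather than raised; flagged
    fits carry no estimates and downstream consumers must skip them.
    """
    missing_cols = [c for c in spec.columns() if c not in cohort.columns]
    if missing_cols:
        raise KeyError(f"cohort is missing model columns {missing_cols}")
    data = cohort[spec.columns()].dropna()
    n_used = len(data)
    y = data[spec.outcome]
    levels = set(pd.unique(y.astype(float)))
    if not levels <= {0.0, 1.0}:
        raise ValueError(f"outcome {spec.outcome} is not binary: levels {sorted(levels)}")
    if len(levels) < 2:
        raise ValueError(
            f"outcome {spec.outcome} has a single level among complete cases"
        )

    def _flagged(converged: bool = False) -> FitResult:
        return FitResult(
            terms=(),
            beta=None,
            vcov=None,
            n_used=n_used,
            converged=converged,
            separation_flag=True,
            spec=spec,
        )

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", HessianInversionWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            model = smf.logit(spec.formula(), data=data)
            res = model.fit(
                method="newton", maxiter=100, tol=1e-10, disp=0, warn_convergence=False
            )
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return _flagged()

    beta = res.params.to_numpy(dtype=float)
    vcov = np.asarray(res.cov_params(), dtype=float)
    converged = bool(res.mle_retvals.get("converged", False))
    # diverging slopes signal quasi-separation; the intercept is exempt since
    # uncentred covariates (e.g. birth year) shift it arbitrarily
    slopes = np.array(
        [b for t, b in zip(res.params.index, beta) if t != "Intercept"]
    )
    if (
        not np.isfinite(beta).all()
        or not np.isfinite(vcov).all()
        or (slopes.size and np.abs(slopes).max() > SEPARATION_BETA)
    ):
        return _flagged(converged)
    # numerical symmetrisation only; Newton vcov is symmetric to rounding
    vcov = (vcov + vcov.T) / 2.0
    return FitResult(
        terms=tuple(res.params.index),
        beta=beta,
        vcov=vcov,
        n_used=n_used,
        converged=converged,
        separation_flag=False,
        spec=spec,
    )
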