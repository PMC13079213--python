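"""Additive and multiplicative interaction statistics for binary exposures.

From a logistic fit with binary exposures G (high vs low polygenic risk)
and E (any vs no adversity) and their product term, with coefficients
beta1 (G), beta2 (E), beta3 (G x E):

* joint odds ratios relative to the doubly unexposed group are
  ``OR10 = exp(beta1)``, ``OR01 = exp(beta2)``,
  ``OR11 = exp(beta1 + beta2 + beta3)``;
* the additive interaction is the relative excess risk due to interaction,
  ``RERI = OR11 - OR10 - OR01 + 1``, i.e. the joint excess risk minus the
  sum of the single-exposure excess risks; its standard error comes from a
  first-order delta method over the 3x3 coefficient covariance block;
* the multiplicative interaction is beta3 itself,
  ``log[OR11 / (OR10 * OR01)]``: zero means odds ratios multiply.

Sign conventions: a RERI whose sign agrees with the joint excess risk
(OR11 - 1) is synergistic, a discordant sign is antagonistic; beta3 > 0 is
multiplicative synergy (adversity effects amplified at high genetic risk),
beta3 < 0 antagonism (a ceiling effect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .glm import Z95, FitResult

__all__ = [
    "AdditiveInteractionResult",
    "MultiplicativeInteractionResult",
    "reri_from_fit",
    "multiplicative_from_fit",
    "reri_parametric_bootstrap",
    "classify_additive",
    "classify_multiplicative",
]


@dataclass(frozen=True)
class AdditiveInteractionResult:
    """RERI with delta-method CI and the excess-risk decomposition.

    ``excess_prs + excess_ace + reri`` equals the joint excess risk
    ``or_11 - 1`` by construction.
    """

    reri: float
    se: float
    ci95: tuple[float, float]
    p: float
    or_11: float
    or_10: float
    or_01: float

    @property
    def excess_prs(self) -> float:
        return self.or_10 - 1.0

    @property
    def excess_ace(self) -> float:
        return self.or_01 - 1.0


@dataclass(frozen=True)
class MultiplicativeInteractionResult:
    coefficient: float
    se: float
    p: float
    ci95: tuple[float, float]


def _require_ok(fit: FitResult) -> None:
    if fit.beta is None or fit.separation_flag:
        raise ValueError(
            "fit flagged for separation/non-convergence; interaction estimates unavailable"
        )
    if not fit.converged:
        raise ValueError("fit did not converge; interaction estimates unavailable")


def reri_from_fit(
    fit: FitResult, prs_term: str, ace_term: str, interaction_term: str
) -> AdditiveInteractionResult:
    """Relative excess risk due to interaction, with a delta-method CI.

    The gradient of RERI over (beta1, beta2, beta3) is
    (OR11 - OR10, OR11 - OR01, OR11); the variance is h' Sigma h on the
    corresponding 3x3 covariance block, and the p-value is the Wald test
    of RERI / SE against the standard normal.
    """
    _require_ok(fit)
    for term in (prs_term, ace_term, interaction_term):
        if term not in fit.terms:
            raise ValueError(f"term {term!r} missing from fit {list(fit.terms)}")
    b1 = fit.beta[fit.index(prs_term)]
    b2 = fit.beta[fit.index(ace_term)]
    b3 = fit.beta[fit.index(interaction_term)]
    or_10 = float(np.exp(b1))
    or_01 = float(np.exp(b2))
    or_11 = float(np.exp(b1 + b2 + b3))
    reri = or_11 - or_01 - or_10 + 1.0
    h = np.array([or_11 - or_10, or_11 - or_01, or_11])
    sigma = fit.vcov_block([prs_term, ace_term, interaction_term])
    var = float(h @ sigma @ h)
    se = float(np.sqrt(max(var, 0.0)))
    p = float(2.0 * norm.sf(abs(reri / se))) if se > 0 else float("nan")
    return AdditiveInteractionResult(
        reri=reri,
        se=se,
        ci95=(reri - Z95 * se, reri + Z95 * se),
        p=p,
        or_11=or_11,
        or_10=or_10,
        or_01=or_01,
    )


def multiplicative_from_fit(
    fit: FitResult, interaction_term: str
) -> MultiplicativeInteractionResult:
    """The product-term coefficient (log-OR scale) with its Wald test."""
    _require_ok(fit)
    if interaction_term not in fit.terms:
        raise ValueError(f"term {interaction_term!r} missing from fit {list(fit.terms)}")
    b3, se = fit.get(interaction_term)
    p = float(2.0 * norm.sf(abs(b3 / se))) if se > 0 else float("nan")
    return MultiplicativeInteractionResult(
        coefficient=b3, se=se, p=p, ci95=(b3 - Z95 * se, b3 + Z95 * se)
    )


def reri_parametric_bootstrap(
    fit: FitResult,
    prs_term: str,
    ace_term: str,
    interaction_term: str,
    n_draws: int = 2000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """RERI draws from the asymptotic coefficient distribution of the fit.

    Samples (beta1, beta2, beta3) from a multivariate normal centred at the
    estimates with the fitted 3x3 covariance block and evaluates the RERI
    formula on each draw; the SD of the draws is a simulation-based SE that
    a delta-method SE can be checked against.
    """
    _require_ok(fit)
    rng = rng or np.random.default_rng()
    terms = [prs_term, ace_term, interaction_term]
    mean = np.array([fit.beta[fit.index(t)] for t in terms])
    sigma = fit.vcov_block(terms)
    draws = rng.multivariate_normal(mean, sigma, size=n_draws)
    b1, b2, b3 = draws[:, 0], draws[:, 1], draws[:, 2]
    return np.exp(b1 + b2 + b3) - np.exp(b1) - np.exp(b2) + 1.0


def classify_additive(result: AdditiveInteractionResult) -> str:
    """"synergistic" / "antagonistic" / "none" for an additive interaction.

    "none" when the 95% CI spans zero; otherwise synergy when the RERI sign
    agrees with the joint excess risk (OR11 - 1), antagonism when it is
    discordant.
    """
    low, high = result.ci95
    if low <= 0.0 <= high:
        return "none"
    reference = result.or_11 - 1.0
    if reference == 0.0 or result.reri == 0.0:
        return "none"
    return "synergistic" if np.sign(result.reri) == np.sign(reference) else "antagonistic"


def classify_multiplicative(coefficient: float) -> str:
    """Sign of the product term: positive = synergistic, negative = antagonistic."""
    if coefficient > 0:
        return "synergistic"
    if coefficient < 0:
        return "antagonistic"
    return "none"
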