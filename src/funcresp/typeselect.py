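"""Functional-response type selection by polynomial logistic regression.

The kill proportion killed/N0 is regressed on polynomial terms of initial
density N0 with a logit link.  For a type II response the proportion killed
declines monotonically with density, giving a significant negative linear
coefficient; a type III (sigmoidal) response makes the proportion rise first,
giving a significant positive linear coefficient together with a negative
higher-order term.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from ._glm import fit_binomial_glm
from .errors import InvalidDesignError
from .tables import ExperimentTable

__all__ = ["TypeSelectionResult", "fit_proportion_logistic", "classify_response"]

TYPE_II = "type_II"
TYPE_III = "type_III"
INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class TypeSelectionResult:
    """Wald summary of the polynomial logistic fit plus the assigned type."""

    terms: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    classified_type: str
    degree: int
    deviance: float
    converged: bool

    def report(self) -> list[dict]:
        """One row per term: estimate, SE, z, p — plus the classification."""
        rows = [
            {
                "term": t,
                "estimate": float(b),
                "se": float(s),
                "z": float(z),
                "p": float(p),
            }
            for t, b, s, z, p in zip(
                self.terms, self.coefficients, self.standard_errors, self.z_values, self.p_values
            )
        ]
        rows.append({"term": "classified_type", "estimate": self.classified_type})
        return rows


def fit_proportion_logistic(table: ExperimentTable, degree: int = 2, alpha: float = 0.05) -> TypeSelectionResult:
    """Fit killed-out-of-N0 on polynomial density terms, logit link, by IRLS.

    Raw-density polynomials are badly scaled (N0^3 reaches 1.7e7 at density
    256), so columns are rescaled internally and the coefficients mapped back
    to the raw-density scale, which is the scale on which linear-term
    estimates in this literature are reported.

    Non-convergence (e.g. complete separation) yields a result flagged
    ``inconclusive`` rather than an exception.
    """
    if degree not in (1, 2, 3):
        raise InvalidDesignError(f"degree must be 1, 2 or 3, got {degree}")
    n0 = table.densities.astype(float)
    killed = table.killed.astype(float)

    names = ("intercept", "density", "density^2", "density^3")[: degree + 1]
    x = np.column_stack([n0**d for d in range(degree + 1)])
    scale = np.abs(x).max(axis=0)
    res = fit_binomial_glm(x / scale, killed, n0)
    beta = res.coefficients / scale
    vcov = res.vcov / np.outer(scale, scale)
    se = np.sqrt(np.diag(vcov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    result = TypeSelectionResult(
        terms=names,
        coefficients=beta,
        standard_errors=se,
        z_values=z,
        p_values=p,
        classified_type=INCONCLUSIVE,
        degree=degree,
        deviance=res.deviance,
        converged=res.converged,
    )
    return replace(result, classified_type=classify_response(result, alpha))


def classify_response(result: TypeSelectionResult, alpha: float = 0.05) -> str:
    """Deterministic label from the linear (and higher-order) Wald tests.

    Significant negative linear coefficient -> type II.  Significant positive
    linear coefficient -> type III, where at degree >= 2 the next-order term
    must also be significantly negative (the proportion must come back down);
    anything else, including a non-converged fit, is inconclusive.
    """
    if not 0 < alpha < 1:
        raise InvalidDesignError(f"alpha must be in (0, 1), got {alpha}")
    if not result.converged or len(result.coefficients) < 2:
        return INCONCLUSIVE
    linear, p_linear = result.coefficients[1], result.p_values[1]
    if not np.isfinite(p_linear):
        return INCONCLUSIVE
    if p_linear < alpha and linear < 0:
        return TYPE_II
    if p_linear < alpha and linear > 0:
        if result.degree == 1:
            return TYPE_III
        higher, p_higher = result.coefficients[2], result.p_values[2]
        if np.isfinite(p_higher) and p_higher < alpha and higher < 0:
            return TYPE_III
    return INCONCLUSIVE
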