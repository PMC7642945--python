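"""Prior elicitation for the coefficient variance.

The coefficient variance sigma_beta^2 gets a scaled-inverse-chi-squared prior
with degrees of freedom ``v_beta`` and scale ``S_beta``; its mean is
``S_beta / (v_beta - 2)`` and its coefficient of variation is
``sqrt(2 / (v_beta - 4))``, a function of the degrees of freedom alone.

The scale is elicited so that, a priori, a proportion ``1 - R2`` of the total
latent variance is attributed to the linear predictor.  Writing
``msq = tr(X X') / n`` for the average squared row norm of the design, the
average latent variance is ``Vl = msq * sigma_beta^2 + 1``.  Requiring the
prior-mean linear-predictor share to be ``1 - R2`` fixes
``E(sigma_beta^2) = (1 - R2) * Vl / msq`` and hence
``S_beta = E(sigma_beta^2) * (v_beta - 2)``.  The definition of ``Vl`` is
self-referential (it involves sigma_beta^2); the self-consistent solution of
``Vl = (1 - R2) * Vl + 1`` is ``Vl = 1 / R2``, which is what we use unless the
caller overrides ``Vl`` explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PriorSpec",
    "dof_to_cv",
    "cv_to_dof",
    "latent_total_variance",
    "elicit_scale",
]

DEFAULT_R2 = 0.5
DEFAULT_V_BETA = 1000.0


@dataclass(frozen=True)
class PriorSpec:
    """Elicited prior for the common coefficient variance.

    ``flat=True`` selects the improper-uniform variant: no shrinkage, no
    variance update.  Otherwise sigma_beta^2 ~ Scaled-Inv-chi2(v_beta, S_beta).
    """

    R2: float = DEFAULT_R2
    v_beta: float = DEFAULT_V_BETA
    S_beta: float = float("nan")
    cv: float = float("nan")
    flat: bool = False

    @property
    def prior_mean(self) -> float:
        """Prior mean of sigma_beta^2, S_beta / (v_beta - 2)."""
        return self.S_beta / (self.v_beta - 2.0)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draws from the scaled-inverse-chi-squared prior (for checking)."""
        # sigma^2 = S_beta / chi2(v_beta)
        return self.S_beta / rng.chisquare(self.v_beta, size=size)


def dof_to_cv(v_beta: float) -> float:
    """Coefficient of variation of the prior, ``sqrt(2 / (v_beta - 4))``."""
    if v_beta <= 4:
        raise ValueError("CV undefined: degrees of freedom must exceed 4")
    return math.sqrt(2.0 / (v_beta - 4.0))


def cv_to_dof(cv: float) -> float:
    """Degrees of freedom giving a target prior CV: ``2 / cv**2 + 4``."""
    if cv <= 0:
        raise ValueError("coefficient of variation must be positive")
    return 2.0 / cv**2 + 4.0


def latent_total_variance(sigma_beta2: float, mean_sq_design: float) -> float:
    """Average latent variance ``Vl = msq * sigma_beta2 + 1``.

    ``mean_sq_design`` is ``tr(X X') / n``, the mean squared row norm of the
    design matrix; the residual contributes unit variance.
    """
    if sigma_beta2 < 0 or mean_sq_design < 0:
        raise ValueError("variance inputs must be non-negative")
    return mean_sq_design * sigma_beta2 + 1.0


def mean_sq_design(X: np.ndarray) -> float:
    """``tr(X X') / n`` computed without forming the n x n product."""
    X = np.asarray(X, dtype=float)
    return float(np.sum(X * X) / X.shape[0])


def elicit_scale(R2: float = DEFAULT_R2,
                 v_beta: float | None = None,
                 mean_sq_design: float = 1.0,
                 cv: float | None = None,
                 vl_override: float | None = None) -> PriorSpec:
    """Elicit (S_beta, v_beta) from the target heritability-like split.

    Exactly one of ``v_beta`` and ``cv`` may be given; neither defaults to
    v_beta = 1000 (prior CV about 4.48%).
    """
    if not 0.0 < R2 < 1.0:
        raise ValueError("R2 must lie strictly between 0 and 1")
    if mean_sq_design <= 0:
        raise ValueError("mean_sq_design must be positive")
    if v_beta is not None and cv is not None:
        raise ValueError("give either v_beta or cv, not both")
    if v_beta is None:
        v_beta = cv_to_dof(cv) if cv is not None else DEFAULT_V_BETA
    if v_beta <= 4:
        raise ValueError("v_beta must exceed 4 for a finite prior CV")

    Vl = 1.0 / R2 if vl_override is None else float(vl_override)
    prior_mean = (1.0 - R2) * Vl / mean_sq_design
    S_beta = prior_mean * (v_beta - 2.0)
    return PriorSpec(R2=R2, v_beta=float(v_beta), S_beta=S_beta,
                     cv=dof_to_cv(v_beta), flat=False)
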