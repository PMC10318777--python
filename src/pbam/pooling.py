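"""Inverse-variance random-effects pooling of validation studies.

Sensitivity and specificity estimates from exposure-validation studies are
combined with a DerSimonian-Laird random-effects model.  Study standard
errors are recovered from 95% confidence intervals as half-width / 1.96.
Pooling is done on the raw proportion scale by default (pooled values are
then directly interpretable as percentages); a logit-scale alternative is
available for proportions near the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit, logit

__all__ = ["ValidationStudy", "PooledEstimate", "pool"]

_Z = 1.96


@dataclass(frozen=True)
class ValidationStudy:
    """One study's estimate of sensitivity or specificity with its 95% CI."""

    estimate: float
    ci_low: float
    ci_high: float
    population_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.estimate <= self.ci_high <= 1.0:
            raise ValueError(
                f"need 0 <= ci_low <= estimate <= ci_high <= 1, got "
                f"({self.ci_low}, {self.estimate}, {self.ci_high}) "
                f"[{self.population_label or 'unlabelled study'}]"
            )

    @property
    def se(self) -> float:
        return (self.ci_high - self.ci_low) / (2.0 * _Z)


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    tau2: float
    k: int


def pool(studies: Sequence[ValidationStudy],
         scale: Literal["proportion", "logit"] = "proportion") -> PooledEstimate:
    """DerSimonian-Laird pooled estimate across validation studies.

    Weights are 1/(se_i^2 + tau^2) with tau^2 estimated from Cochran's Q and
    truncated at zero; the pooled 95% CI is estimate +/- 1.96*se, truncated
    to [0, 1].  With a single study the inputs pass through unchanged
    (tau^2 = 0).  ``scale="logit"`` pools logit-transformed proportions with
    delta-method standard errors and back-transforms the result.
    """
    if len(studies) == 0:
        raise ValueError("cannot pool an empty list of studies")
    for s in studies:
        if s.se == 0.0:
            raise ValueError(
                f"zero-width CI in study {s.population_label or s!r}: "
                "standard error cannot be recovered"
            )
    eff = np.array([s.estimate for s in studies], dtype=float)
    var = np.array([s.se**2 for s in studies], dtype=float)
    if scale == "logit":
        # delta method: se(logit p) = se(p) / (p (1 - p))
        d = eff * (1.0 - eff)
        if np.any(d == 0.0):
            raise ValueError("logit scale undefined for an estimate of exactly 0 or 1")
        var = var / d**2
        eff = logit(eff)
    elif scale != "proportion":
        raise ValueError(f"unknown pooling scale {scale!r}")

    if len(studies) == 1:
        est, tau2 = float(eff[0]), 0.0
        se = float(np.sqrt(var[0]))
    else:
        # DerSimonian-Laird moment estimator, truncated at zero
        w = 1.0 / var
        est_fe = float(np.sum(w * eff) / np.sum(w))
        q = float(np.sum(w * (eff - est_fe) ** 2))
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (len(studies) - 1)) / c)
        w_re = 1.0 / (var + tau2)
        est = float(np.sum(w_re * eff) / np.sum(w_re))
        se = float(1.0 / np.sqrt(np.sum(w_re)))
    lo, hi = est - _Z * se, est + _Z * se

    if scale == "logit":
        est, lo, hi = float(expit(est)), float(expit(lo)), float(expit(hi))
    return PooledEstimate(
        estimate=est,
        ci_low=max(0.0, lo),
        ci_high=min(1.0, hi),
        tau2=tau2,
        k=len(studies),
    )
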