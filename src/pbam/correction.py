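"""Record-level misclassification correction for a 2x2 exposure table.

Given observed exposed/unexposed counts in one outcome group and a sampled
(sensitivity, specificity) pair, this module inverts the classification
matrix

    [ Sen    1-Spe ] [ A ]   [ A* ]
    [ 1-Sen  Spe   ] [ B ] = [ B* ]

to obtain the expected truly-exposed count A and truly-unexposed count B,
derives positive and negative predictive values, and imputes a record-level
"expected exposure" by Bernoulli draws with probability PPV for observed
exposed and NPV for observed unexposed subjects.  Draws whose predictive
values fall outside [0, 1] are flagged invalid and discarded by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .bias_params import BiasDraw

__all__ = [
    "ObservedCounts",
    "ExpectedCounts",
    "PredictiveValues",
    "ScreenResult",
    "SingularBiasDraw",
    "expected_counts",
    "predictive_values",
    "impute_exposure",
    "screen_draw",
]


class SingularBiasDraw(ValueError):
    """sens + spec = 1: the classification matrix is singular."""


@dataclass(frozen=True)
class ObservedCounts:
    """Observed exposed (a_star) and unexposed (b_star) counts in one group."""

    a_star: int
    b_star: int
    group: Literal["case", "control"] = "case"

    def __post_init__(self) -> None:
        if self.a_star < 0 or self.b_star < 0:
            raise ValueError("counts must be non-negative")
        if self.a_star + self.b_star < 1:
            raise ValueError("group must contain at least one subject")

    @property
    def total(self) -> int:
        return self.a_star + self.b_star


@dataclass(frozen=True)
class ExpectedCounts:
    """Expected truly exposed (a) and unexposed (b) counts; kept as reals."""

    a: float
    b: float


@dataclass(frozen=True)
class PredictiveValues:
    ppv: float
    npv: float

    @property
    def valid(self) -> bool:
        return (0.0 <= self.ppv <= 1.0) and (0.0 <= self.npv <= 1.0)


def expected_counts(sens: float, spec: float, counts: ObservedCounts) -> ExpectedCounts:
    """Invert the classification matrix; conserves the group total exactly.

    a = (spec*a* - (1-spec)*b*) / (sens+spec-1)
    b = (sens*b* - (1-sens)*a*) / (sens+spec-1)
    """
    det = sens + spec - 1.0
    if det == 0.0:
        raise SingularBiasDraw(f"sens + spec = 1 (sens={sens}, spec={spec})")
    a = (spec * counts.a_star - (1.0 - spec) * counts.b_star) / det
    b = (sens * counts.b_star - (1.0 - sens) * counts.a_star) / det
    return ExpectedCounts(a, b)


def predictive_values(sens: float, spec: float, expected: ExpectedCounts) -> PredictiveValues:
    """PPV and NPV from expected counts.

    PPV = Sen*A / (Sen*A + (1-Spe)*B), NPV = Spe*B / (Spe*B + (1-Sen)*A).
    By construction the PPV denominator equals the observed a* and the NPV
    denominator equals b*; invalid draws surface as values outside [0, 1].
    """
    ppv_den = sens * expected.a + (1.0 - spec) * expected.b
    npv_den = spec * expected.b + (1.0 - sens) * expected.a
    if ppv_den == 0.0 or npv_den == 0.0:
        return PredictiveValues(np.nan, np.nan)
    return PredictiveValues(sens * expected.a / ppv_den, spec * expected.b / npv_den)


def impute_exposure(observed: np.ndarray, pv: PredictiveValues, seed=None) -> np.ndarray:
    """Bernoulli imputation of expected exposure at the record level.

    Observed exposed stay exposed with probability PPV; observed unexposed
    stay unexposed with probability NPV.  One uniform per record,
    deterministic given the seed / generator.
    """
    if not pv.valid:
        raise ValueError(f"invalid predictive values ppv={pv.ppv}, npv={pv.npv}")
    observed = np.asarray(observed)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(observed.shape[0])
    return np.where(observed == 1, (u < pv.ppv).astype(np.int8),
                    (1 - (u < pv.npv)).astype(np.int8))


@dataclass(frozen=True)
class ScreenResult:
    valid: bool
    pv_case: PredictiveValues | None = None
    pv_control: PredictiveValues | None = None


def screen_draw(draw: BiasDraw, counts_case: ObservedCounts,
                counts_control: ObservedCounts) -> ScreenResult:
    """Validate one bias draw against both groups' observed tables.

    A draw is usable only if sens+spec > 1 in both groups and every PPV/NPV
    lies in [0, 1] — equivalently, the expected exposed count falls in
    [0, group total] for both groups.  Invalid draws are reported, not raised:
    the engine discards and redraws.
    """
    pvs = []
    for sens, spec, counts in (
        (draw.sens_case, draw.spec_case, counts_case),
        (draw.sens_control, draw.spec_control, counts_control),
    ):
        if sens + spec - 1.0 <= 0.0:
            return ScreenResult(False)
        pv = predictive_values(sens, spec, expected_counts(sens, spec, counts))
        if not pv.valid:
            return ScreenResult(False)
        pvs.append(pv)
    return ScreenResult(True, pvs[0], pvs[1])
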