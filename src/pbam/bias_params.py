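"""Bias-parameter distributions for sensitivity and specificity.

Pooled validation estimates (point estimate + 95% CI) are turned into one of
three prior families — triangular, beta, or logit-logistic — and sampled,
optionally with a Gaussian copula coupling case-group and control-group draws
in differential-misclassification scenarios.

Family parameterizations
------------------------
triangular      (min, max, mode): min = ci_low, max = ci_high, mode = estimate.
beta            (alpha, beta): moment-matched so the mean equals the estimate
                and the sd equals the CI half-width / 1.96.
logit_logistic  (location, scale): a logistic distribution on the probability
                scale with median = location (the estimate) and
                sd = scale * pi / sqrt(3); the scale is derived from the
                moment-matched beta sd so the dispersion of all three
                families is CI-consistent.  Draws are truncated to (0, 1) by
                inverting the truncated CDF.  An alternative logit-link form
                (``link="logit"``: expit(logit(loc) + scale*logit(U))) is
                available and never needs truncation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, logit, ndtr

__all__ = [
    "BiasParamSpec",
    "BiasDraw",
    "BiasDraws",
    "BiasModel",
    "fit_triangular",
    "fit_beta_moments",
    "fit_logit_logistic",
    "sample_draws",
]

Family = Literal["triangular", "beta", "logit_logistic"]
Role = Literal["sensitivity", "specificity"]
Group = Literal["case", "control", "both"]

#: sd of the standard logistic distribution, pi/sqrt(3)
_LOGISTIC_SD = math.pi / math.sqrt(3.0)


@dataclass(frozen=True)
class BiasParamSpec:
    """One classification parameter's prior distribution.

    ``params`` is family-specific: triangular ``(min, max, mode)``, beta
    ``(alpha, beta)``, logit_logistic ``(location, scale)``.
    """

    family: Family
    params: tuple[float, ...]
    role: Role = "sensitivity"
    group: Group = "both"
    link: Literal["identity", "logit"] = "identity"

    def __post_init__(self) -> None:
        p = self.params
        if self.family == "triangular":
            lo, hi, mode = p
            if not (0.0 <= lo <= mode <= hi <= 1.0):
                raise ValueError(
                    f"triangular requires 0 <= min <= mode <= max <= 1, got {p}"
                )
        elif self.family == "beta":
            a, b = p
            if a <= 0 or b <= 0:
                raise ValueError(f"beta requires alpha, beta > 0, got {p}")
        elif self.family == "logit_logistic":
            loc, scale = p
            if not (0.0 < loc < 1.0):
                raise ValueError(f"logit-logistic location must lie in (0,1), got {loc}")
            if scale < 0:
                raise ValueError(f"logit-logistic scale must be >= 0, got {scale}")
        else:
            raise ValueError(f"unknown family {self.family!r}")

    @classmethod
    def point_mass(cls, value: float, role: Role = "sensitivity",
                   group: Group = "both") -> "BiasParamSpec":
        """Degenerate prior concentrated at ``value`` (a zero-width triangular)."""
        return cls("triangular", (value, value, value), role=role, group=group)

    @property
    def is_degenerate(self) -> bool:
        if self.family == "triangular":
            lo, hi, _ = self.params
            return hi == lo
        if self.family == "logit_logistic":
            return self.params[1] == 0.0
        return False

    def ppf(self, u: np.ndarray | float) -> np.ndarray:
        """Quantile function on the probability scale; maps U(0,1) to draws."""
        u = np.asarray(u, dtype=float)
        if self.family == "triangular":
            lo, hi, mode = self.params
            if hi == lo:
                return np.full_like(u, lo)
            c = (mode - lo) / (hi - lo)
            return stats.triang.ppf(u, c, loc=lo, scale=hi - lo)
        if self.family == "beta":
            a, b = self.params
            return stats.beta.ppf(u, a, b)
        loc, scale = self.params
        if scale == 0.0:
            return np.full_like(u, loc)
        if self.link == "logit":
            return expit(logit(loc) + scale * logit(u))
        # identity link: logistic(loc, scale) truncated to (0, 1) by mapping
        # u onto the CDF mass inside the unit interval before inverting
        f0 = expit((0.0 - loc) / scale)
        f1 = expit((1.0 - loc) / scale)
        uu = f0 + u * (f1 - f0)
        return loc + scale * logit(uu)

    def mean(self, n_grid: int = 200_001) -> float:
        """Distribution mean (analytic where closed-form, quadrature otherwise)."""
        if self.family == "triangular":
            return sum(self.params) / 3.0
        if self.family == "beta":
            a, b = self.params
            return a / (a + b)
        u = (np.arange(n_grid) + 0.5) / n_grid
        return float(self.ppf(u).mean())


@dataclass(frozen=True)
class BiasDraw:
    """One sampled (sensitivity, specificity) pair per group."""

    sens_case: float
    spec_case: float
    sens_control: float
    spec_control: float


@dataclass
class BiasDraws:
    """Vectorized container of ``n`` bias draws (column arrays)."""

    sens_case: np.ndarray
    spec_case: np.ndarray
    sens_control: np.ndarray
    spec_control: np.ndarray

    def __len__(self) -> int:
        return len(self.sens_case)

    def __getitem__(self, i: int) -> BiasDraw:
        return BiasDraw(
            float(self.sens_case[i]),
            float(self.spec_case[i]),
            float(self.sens_control[i]),
            float(self.spec_control[i]),
        )


def _se_from_ci(ci_low: float, ci_high: float) -> float:
    return (ci_high - ci_low) / (2.0 * 1.96)


def fit_triangular(estimate: float, ci_low: float, ci_high: float,
                   role: Role = "sensitivity", group: Group = "both") -> BiasParamSpec:
    """Triangular prior: support equals the 95% CI, mode at the estimate."""
    if not (ci_low <= estimate <= ci_high):
        raise ValueError(
            f"need ci_low <= estimate <= ci_high, got ({ci_low}, {estimate}, {ci_high})"
        )
    return BiasParamSpec("triangular", (ci_low, ci_high, estimate), role=role, group=group)


def fit_beta_moments(estimate: float, ci_low: float, ci_high: float,
                     role: Role = "sensitivity", group: Group = "both") -> BiasParamSpec:
    """Beta prior moment-matched to the estimate and CI-implied sd.

    With sd = (ci_high - ci_low)/3.92 and nu = m(1-m)/sd^2 - 1, the fit is
    alpha = m*nu, beta = (1-m)*nu, which has mean exactly m and sd exactly sd.
    Fails when the CI is too wide for any beta with that mean (nu <= 0).
    """
    if not (0.0 < estimate < 1.0):
        raise ValueError(f"estimate must lie strictly in (0,1), got {estimate}")
    if ci_high <= ci_low:
        raise ValueError(f"ci_high must exceed ci_low, got ({ci_low}, {ci_high})")
    sd = _se_from_ci(ci_low, ci_high)
    nu = estimate * (1.0 - estimate) / sd**2 - 1.0
    if nu <= 0.0:
        raise ValueError(
            f"CI-implied sd {sd:.4f} too large for a beta with mean {estimate}: "
            f"need sd^2 < m(1-m) = {estimate * (1 - estimate):.4f}"
        )
    return BiasParamSpec("beta", (estimate * nu, (1.0 - estimate) * nu),
                         role=role, group=group)


def fit_logit_logistic(estimate: float, ci_low: float, ci_high: float,
                       role: Role = "sensitivity", group: Group = "both",
                       link: Literal["identity", "logit"] = "identity") -> BiasParamSpec:
    """Logit-logistic prior: location = estimate, scale = beta-fit sd * sqrt(3)/pi.

    The scale makes the logistic sd equal the moment-matched beta's sd, so the
    three families share a common dispersion derived from the 95% CI.
    """
    beta_spec = fit_beta_moments(estimate, ci_low, ci_high)
    a, b = beta_spec.params
    sd_beta = math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))
    return BiasParamSpec("logit_logistic", (estimate, sd_beta / _LOGISTIC_SD),
                         role=role, group=group, link=link)


FIT_BY_FAMILY = {
    "triangular": fit_triangular,
    "beta": fit_beta_moments,
    "logit_logistic": fit_logit_logistic,
}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _copula_uniforms(n: int, correlation: float, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Two U(0,1) streams with Gaussian-copula dependence ``correlation``."""
    z1 = rng.standard_normal(n)
    z2 = correlation * z1 + math.sqrt(1.0 - correlation**2) * rng.standard_normal(n)
    return ndtr(z1), ndtr(z2)


def sample_draws(
    sens_case: BiasParamSpec,
    spec_case: BiasParamSpec,
    sens_control: BiasParamSpec | None = None,
    spec_control: BiasParamSpec | None = None,
    *,
    n: int,
    correlation: float = 0.0,
    differential: bool = False,
    correlate: Literal["across_groups", "within_group"] = "across_groups",
    seed=None,
) -> BiasDraws:
    """Sample ``n`` bias draws.

    Non-differential mode draws one sensitivity and one specificity per
    replicate, shared by both groups.  Differential mode couples the draws
    through a Gaussian copula with the given correlation; by default the
    coupling is between the case-group and control-group values of the *same*
    parameter (``correlate="across_groups"``), the usual construction in
    differential-misclassification bias analysis.  ``correlate="within_group"``
    instead couples sensitivity with specificity inside each group.
    Marginals are preserved exactly in either mode.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not -1.0 <= correlation <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {correlation}")
    rng = _as_rng(seed)

    if not differential:
        u_sens = rng.random(n)
        u_spec = rng.random(n)
        sens = sens_case.ppf(u_sens)
        spec = spec_case.ppf(u_spec)
        return BiasDraws(sens, spec, sens.copy(), spec.copy())

    if sens_control is None or spec_control is None:
        raise ValueError("differential mode requires control-group specs")

    if correlate == "across_groups":
        u_sc, u_sn = _copula_uniforms(n, correlation, rng)
        u_pc, u_pn = _copula_uniforms(n, correlation, rng)
    elif correlate == "within_group":
        u_sc, u_pc = _copula_uniforms(n, correlation, rng)
        u_sn, u_pn = _copula_uniforms(n, correlation, rng)
    else:
        raise ValueError(f"unknown correlate mode {correlate!r}")
    return BiasDraws(
        sens_case.ppf(u_sc),
        spec_case.ppf(u_pc),
        sens_control.ppf(u_sn),
        spec_control.ppf(u_pn),
    )


@dataclass
class BiasModel:
    """Complete bias-parameter specification for a PBAM run."""

    sens_case: BiasParamSpec
    spec_case: BiasParamSpec
    sens_control: BiasParamSpec
    spec_control: BiasParamSpec
    differential: bool = False
    correlation: float = 0.0
    correlate: Literal["across_groups", "within_group"] = "across_groups"

    @classmethod
    def from_pooled(
        cls,
        family: Family,
        *,
        case: dict | None = None,
        control: dict | None = None,
        total: dict | None = None,
        differential: bool = False,
        correlation: float = 0.0,
        correlate: Literal["across_groups", "within_group"] = "across_groups",
        link: Literal["identity", "logit"] = "identity",
    ) -> "BiasModel":
        """Build a model from pooled (estimate, ci) blocks.

        Each block is ``{"sensitivity": {"estimate": e, "ci": [lo, hi]},
        "specificity": {...}}``.  Non-differential analyses supply ``total``;
        differential analyses supply ``case`` and ``control``.
        """
        fit = FIT_BY_FAMILY[family]

        def _spec(block: dict, role: Role, group: Group) -> BiasParamSpec:
            e = block[role]["estimate"]
            lo, hi = block[role]["ci"]
            kwargs = {"link": link} if family == "logit_logistic" else {}
            return fit(e, lo, hi, role=role, group=group, **kwargs)

        if differential:
            if case is None or control is None:
                raise ValueError("differential model needs case and control blocks")
            return cls(
                _spec(case, "sensitivity", "case"),
                _spec(case, "specificity", "case"),
                _spec(control, "sensitivity", "control"),
                _spec(control, "specificity", "control"),
                differential=True,
                correlation=correlation,
                correlate=correlate,
            )
        if total is None:
            raise ValueError("non-differential model needs a total block")
        s = _spec(total, "sensitivity", "both")
        p = _spec(total, "specificity", "both")
        return cls(s, p, s, p, differential=False)

    @classmethod
    def point_mass(cls, sens: float, spec: float,
                   sens_control: float | None = None,
                   spec_control: float | None = None) -> "BiasModel":
        """Degenerate model; differential iff control values are given."""
        sc = sens_control if sens_control is not None else sens
        pc = spec_control if spec_control is not None else spec
        differential = sens_control is not None or spec_control is not None
        return cls(
            BiasParamSpec.point_mass(sens, "sensitivity", "case"),
            BiasParamSpec.point_mass(spec, "specificity", "case"),
            BiasParamSpec.point_mass(sc, "sensitivity", "control"),
            BiasParamSpec.point_mass(pc, "specificity", "control"),
            differential=differential,
        )

    @property
    def is_degenerate(self) -> bool:
        return all(s.is_degenerate for s in
                   (self.sens_case, self.spec_case, self.sens_control, self.spec_control))

    def sample(self, n: int, seed=None) -> BiasDraws:
        return sample_draws(
            self.sens_case, self.spec_case, self.sens_control, self.spec_control,
            n=n, correlation=self.correlation, differential=self.differential,
            correlate=self.correlate, seed=seed,
        )
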