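"""Synthetic case-control data with known effect and controllable error.

The generator draws a source population from a logistic structural model:
confounders (age, smoking, education, physical activity, SES) have fixed
marginals; true exposure depends on the confounders through a logistic model;
the outcome depends on true exposure (log-odds = ln(true odds ratio)) and the
confounders.  Case-control sampling keeps the first ``n_cases`` cases and
``n_controls`` controls generated, oversampling the population in batches up
to a hard cap.  Self-report error is then overlaid per outcome group with
configurable sensitivity and specificity.

Confounder marginals default to values resembling an urban female
population: age normal, smoking and physical activity Bernoulli, education
(6 ordinal levels) and SES (5 ordinal levels) multinomial.  Confounder
effects are illustrative defaults, not estimates from any study; all are
exposed in :class:`SimulationConfig`.  Confounder terms are centered at
their marginal means so that ``exposure_prevalence`` and
``baseline_outcome_prob`` act as (approximate) marginal calibrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "PopulationCapExceeded",
    "generate_population",
    "apply_misclassification",
]

# marginal category probabilities for the ordinal confounders (levels 1..k)
EDUCATION_PROBS = (0.048, 0.108, 0.158, 0.342, 0.284, 0.060)
SES_PROBS = (0.011, 0.068, 0.273, 0.638, 0.010)
SMOKING_PREV = 0.03
PHYSICAL_ACTIVITY_PREV = 0.109

#: illustrative (log-odds on exposure, log-odds on outcome) per confounder
DEFAULT_CONFOUNDER_EFFECTS: Mapping[str, tuple[float, float]] = {
    "age": (0.01, 0.08),
    "smoking": (1.2, 0.4),
    "education": (0.15, -0.05),
    "physical_activity": (0.10, -0.10),
    "ses": (0.35, -0.20),
}


class PopulationCapExceeded(RuntimeError):
    """Raised when case/control quotas are not met within the draw cap."""


@dataclass
class SimulationConfig:
    """All knobs of the generative model.

    ``confounder_effects`` maps confounder name to a pair of log-odds
    coefficients ``(on_exposure, on_outcome)``; pass ``{}`` for a
    confounder-free model.
    """

    n_cases: int = 1000
    n_controls: int = 1000
    true_or: float = 1.0
    exposure_prevalence: float = 0.04
    sens_case: float = 1.0
    spec_case: float = 1.0
    sens_control: float = 1.0
    spec_control: float = 1.0
    baseline_outcome_prob: float = 0.05
    age_mean: float = 42.0
    age_sd: float = 9.5
    confounder_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDER_EFFECTS))
    seed: int = 0
    max_population_draws: int = 10_000_000

    def __post_init__(self) -> None:
        for name in ("exposure_prevalence", "baseline_outcome_prob"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        for name in ("sens_case", "spec_case", "sens_control", "spec_control"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0,1], got {v}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if self.true_or <= 0:
            raise ValueError(f"true_or must be positive, got {self.true_or}")
        unknown = set(self.confounder_effects) - set(DEFAULT_CONFOUNDER_EFFECTS)
        if unknown:
            raise ValueError(f"unknown confounders in effects map: {sorted(unknown)}")


@dataclass
class SyntheticDataset:
    """Generated records plus the config and bookkeeping that produced them."""

    data: pd.DataFrame
    config: SimulationConfig
    n_population_drawn: int

    def __len__(self) -> int:
        return len(self.data)


def _confounder_means(config: SimulationConfig) -> dict[str, float]:
    levels_edu = np.arange(1, len(EDUCATION_PROBS) + 1)
    levels_ses = np.arange(1, len(SES_PROBS) + 1)
    return {
        "age": config.age_mean,
        "smoking": SMOKING_PREV,
        "education": float(levels_edu @ np.asarray(EDUCATION_PROBS)),
        "physical_activity": PHYSICAL_ACTIVITY_PREV,
        "ses": float(levels_ses @ np.asarray(SES_PROBS)),
    }


def _draw_batch(config: SimulationConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    conf = pd.DataFrame({
        "age": rng.normal(config.age_mean, config.age_sd, n),
        "smoking": (rng.random(n) < SMOKING_PREV).astype(np.int8),
        "education": rng.choice(np.arange(1, 7), size=n, p=EDUCATION_PROBS).astype(np.int8),
        "physical_activity": (rng.random(n) < PHYSICAL_ACTIVITY_PREV).astype(np.int8),
        "ses": rng.choice(np.arange(1, 6), size=n, p=SES_PROBS).astype(np.int8),
    })
    means = _confounder_means(config)
    lp_exposure = np.full(n, logit(config.exposure_prevalence))
    lp_outcome = np.full(n, logit(config.baseline_outcome_prob))
    for name, (b_exp, b_out) in config.confounder_effects.items():
        centered = conf[name].to_numpy(float) - means[name]
        lp_exposure += b_exp * centered
        lp_outcome += b_out * centered
    exposure = (rng.random(n) < expit(lp_exposure)).astype(np.int8)
    lp_outcome += np.log(config.true_or) * exposure
    outcome = (rng.random(n) < expit(lp_outcome)).astype(np.int8)
    conf.insert(0, "exposure_true", exposure)
    conf.insert(0, "outcome", outcome)
    return conf


def generate_population(config: SimulationConfig) -> SyntheticDataset:
    """Generate a case-control sample from the structural model.

    Population members are drawn in batches; the first ``n_cases`` cases and
    ``n_controls`` controls encountered are retained.  Raises
    :class:`PopulationCapExceeded` naming ``max_population_draws`` if the
    quotas cannot be met within the cap.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    cases: list[pd.DataFrame] = []
    controls: list[pd.DataFrame] = []
    got_cases = got_controls = 0
    drawn = 0
    # size batches from the expected yield, bounded to keep memory flat
    expected_rate = max(config.baseline_outcome_prob, 1e-4)
    batch = int(np.clip(config.n_cases / expected_rate * 1.2, 10_000, 1_000_000))
    while got_cases < config.n_cases or got_controls < config.n_controls:
        if drawn >= config.max_population_draws:
            raise PopulationCapExceeded(
                f"drew {drawn} population members (cap max_population_draws="
                f"{config.max_population_draws}) but found only {got_cases}/"
                f"{config.n_cases} cases and {got_controls}/{config.n_controls} controls"
            )
        n = min(batch, config.max_population_draws - drawn)
        df = _draw_batch(config, n, rng)
        drawn += n
        if got_cases < config.n_cases:
            new = df[df["outcome"] == 1].iloc[: config.n_cases - got_cases]
            cases.append(new)
            got_cases += len(new)
        if got_controls < config.n_controls:
            new = df[df["outcome"] == 0].iloc[: config.n_controls - got_controls]
            controls.append(new)
            got_controls += len(new)
    data = pd.concat(cases + controls, ignore_index=True)
    observed = apply_misclassification(
        data["exposure_true"].to_numpy(), data["outcome"].to_numpy(),
        config.sens_case, config.spec_case, config.sens_control, config.spec_control,
        seed=rng,
    )
    data.insert(2, "exposure_observed", observed)
    return SyntheticDataset(data, config, drawn)


def apply_misclassification(
    exposure_true: np.ndarray,
    outcome: np.ndarray,
    sens_case: float,
    spec_case: float,
    sens_control: float,
    spec_control: float,
    seed=None,
) -> np.ndarray:
    """Overlay self-report error on the true exposure, per outcome group.

    A truly exposed subject reports exposure with probability sens; a truly
    unexposed subject reports non-exposure with probability spec, using the
    subject's group (case/control) parameters.  The expected observed
    prevalence per group is sens*p + (1-spec)*(1-p).
    """
    exposure_true = np.asarray(exposure_true)
    outcome = np.asarray(outcome)
    if exposure_true.shape != outcome.shape:
        raise ValueError("exposure_true and outcome must have the same length")
    for name, v in (("sens_case", sens_case), ("spec_case", spec_case),
                    ("sens_control", sens_control), ("spec_control", spec_control)):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"{name} must lie in (0,1], got {v}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sens = np.where(outcome == 1, sens_case, sens_control)
    spec = np.where(outcome == 1, spec_case, spec_control)
    u = rng.random(exposure_true.shape[0])
    # P(observed=1) is sens for the truly exposed, 1-spec for the truly unexposed
    p_report = np.where(exposure_true == 1, sens, 1.0 - spec)
    return (u < p_report).astype(np.int8)
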