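"""Bootstrap x Monte-Carlo engine for probabilistic bias analysis.

Each Monte-Carlo replicate draws a (sensitivity, specificity) pair per group
from the bias model, screens it against the observed 2x2 margins (redrawing
on invalid predictive values), imputes a record-level expected exposure, and
refits the confounder-adjusted logistic regression on the imputed exposure.
With random error included, the whole Monte-Carlo loop runs inside each of
``n_bootstrap`` stratified bootstrap resamples (cases and controls resampled
separately, preserving the design margins); the pooled replicate
distribution of adjusted odds ratios is summarized by its 50th percentile
(point estimate) and 2.5th/97.5th percentiles (the Monte-Carlo sensitivity
analysis, MCSA, interval).

The public surface is the scikit-learn style estimator
:class:`ProbabilisticBiasAnalysis`; :func:`run_pbam` and :func:`summarize`
are thin functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .bias_params import BiasModel
from .correction import ObservedCounts, impute_exposure, screen_draw

__all__ = [
    "EngineConfig",
    "ORDraws",
    "PbamSummary",
    "NonConvergence",
    "AcceptanceExhausted",
    "ProbabilisticBiasAnalysis",
    "fit_adjusted_or",
    "run_pbam",
    "summarize",
]


class NonConvergence(RuntimeError):
    """Logistic fit failed (separation, degenerate exposure, no convergence)."""


class AcceptanceExhausted(RuntimeError):
    """No valid bias draw found within the redraw cap."""


@dataclass
class EngineConfig:
    """Replication design and model declaration for a PBAM run."""

    n_bootstrap: int = 500
    n_monte_carlo: int = 1000
    confounders: Mapping[str, str] = field(default_factory=dict)  # name -> numeric|categorical
    include_random_error: bool = True
    seed: int = 0
    max_redraws: int = 100_000

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1 or self.n_monte_carlo < 1:
            raise ValueError("replication counts must be >= 1")
        bad = {t for t in self.confounders.values()} - {"numeric", "categorical"}
        if bad:
            raise ValueError(f"confounder types must be numeric/categorical, got {bad}")

    @property
    def n_slots(self) -> int:
        n_boot = self.n_bootstrap if self.include_random_error else 1
        return n_boot * self.n_monte_carlo


@dataclass
class ORDraws:
    """Replicate-level output: adjusted ORs plus diagnostics.

    ``pe_case`` holds, per surviving replicate, the imputed (bias-corrected)
    exposure prevalence in the case group — the input to attributable-fraction
    estimation.  ``skipped`` counts replicates lost to non-convergent fits;
    ``acceptance_rate`` is the fraction of bias draws passing the screen.
    """

    values: np.ndarray
    pe_case: np.ndarray
    skipped: int
    acceptance_rate: float
    n_slots: int


@dataclass(frozen=True)
class PbamSummary:
    """Percentile summary: median point estimate and 95% MCSA interval."""

    point: float
    mcsa_low: float
    mcsa_high: float
    n_replicates: int
    skipped: int


def _design_matrix(data: pd.DataFrame, exposure: np.ndarray,
                   confounders: Mapping[str, str]) -> pd.DataFrame:
    cols = {"exposure": exposure.astype(float)}
    for name, kind in confounders.items():
        if kind == "numeric":
            cols[name] = data[name].to_numpy(float)
        else:
            dummies = pd.get_dummies(data[name], prefix=name, drop_first=True)
            for c in dummies.columns:
                cols[str(c)] = dummies[c].to_numpy(float)
    X = pd.DataFrame(cols, index=data.index)
    return sm.add_constant(X, has_constant="add")


def fit_adjusted_or(
    data: pd.DataFrame,
    exposure: np.ndarray | str,
    confounders: Mapping[str, str] | None = None,
    outcome_col: str = "outcome",
) -> tuple[float, float]:
    """Adjusted odds ratio of exposure from multivariable logistic regression.

    ``exposure`` may be a column name or an array aligned with ``data`` (the
    engine passes the imputed expected-exposure column).  Categorical
    confounders expand to indicator contrasts; numeric ones enter linearly.
    Returns ``(odds_ratio, case-group exposure prevalence)``.  Degenerate
    exposure, perfect separation or non-convergence raise
    :class:`NonConvergence` — a signalled skip, never a crash.
    """
    if isinstance(exposure, str):
        exposure = data[exposure].to_numpy()
    exposure = np.asarray(exposure)
    y = data[outcome_col].to_numpy(np.int8)
    for grp in (0, 1):
        e = exposure[y == grp]
        if e.min(initial=1) == 1 or e.max(initial=0) == 0:
            raise NonConvergence(
                f"exposure constant within outcome group {grp}; model not identifiable"
            )
    X = _design_matrix(data, exposure, confounders or {})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except (np.linalg.LinAlgError, PerfectSeparationError, ValueError) as exc:
        raise NonConvergence(str(exc)) from exc
    beta = fit.params["exposure"]
    if not fit.mle_retvals.get("converged", False) or not np.isfinite(beta) or abs(beta) > 30:
        raise NonConvergence("logistic fit did not converge")
    pe_case = float(exposure[y == 1].mean())
    return float(np.exp(beta)), pe_case


def summarize(draws: ORDraws | np.ndarray) -> PbamSummary:
    """50th / 2.5th / 97.5th percentiles with linear interpolation."""
    if isinstance(draws, ORDraws):
        values, skipped = draws.values, draws.skipped
    else:
        values, skipped = np.asarray(draws, dtype=float), 0
    if len(values) == 0:
        raise ValueError("no surviving replicates to summarize")
    lo, point, hi = np.percentile(values, [2.5, 50.0, 97.5], method="linear")
    return PbamSummary(float(point), float(lo), float(hi), len(values), skipped)


class ProbabilisticBiasAnalysis(BaseEstimator):
    """Misclassification-corrected effect estimation for case-control data.

    Parameters
    ----------
    bias_model : BiasModel
        Prior distributions for per-group sensitivity and specificity.
    n_bootstrap, n_monte_carlo : int
        Replication design; with ``include_random_error`` the total number of
        adjusted-OR slots is their product (500 x 1000 = 500,000 by default).
    confounders : mapping of column name -> {"numeric", "categorical"}
        Adjustment set for the logistic outcome model.
    include_random_error : bool
        If False, bootstrapping is skipped and a single Monte-Carlo pass
        propagates bias-parameter uncertainty only.
    seed : int
        Master seed; each bootstrap sample gets an independent substream, so
        results are reproducible regardless of execution order.
    max_redraws : int
        Cap on consecutive invalid bias draws before failing loudly.

    Attributes (after ``fit``)
    --------------------------
    or_draws_ : ORDraws
        Replicate-level adjusted ORs and diagnostics.
    summary_ : PbamSummary
        Median and 95% MCSA interval.
    conventional_or_ : float
        Adjusted OR from the uncorrected (observed-exposure) regression.
    counts_case_, counts_control_ : ObservedCounts
        Observed exposure margins per group.
    """

    def __init__(
        self,
        bias_model: BiasModel | None = None,
        n_bootstrap: int = 500,
        n_monte_carlo: int = 1000,
        confounders: Mapping[str, str] | None = None,
        include_random_error: bool = True,
        seed: int = 0,
        max_redraws: int = 100_000,
        exposure_col: str = "exposure_observed",
        outcome_col: str = "outcome",
    ) -> None:
        self.bias_model = bias_model
        self.n_bootstrap = n_bootstrap
        self.n_monte_carlo = n_monte_carlo
        self.confounders = confounders
        self.include_random_error = include_random_error
        self.seed = seed
        self.max_redraws = max_redraws
        self.exposure_col = exposure_col
        self.outcome_col = outcome_col

    # -- internals -------------------------------------------------------

    def _counts(self, data: pd.DataFrame) -> tuple[ObservedCounts, ObservedCounts]:
        y = data[self.outcome_col].to_numpy()
        e = data[self.exposure_col].to_numpy()
        case = ObservedCounts(int(e[y == 1].sum()), int((1 - e[y == 1]).sum()), "case")
        control = ObservedCounts(int(e[y == 0].sum()), int((1 - e[y == 0]).sum()), "control")
        return case, control

    def _mc_pass(self, data: pd.DataFrame, rng: np.random.Generator,
                 or_out: list, pe_out: list) -> tuple[int, int, int]:
        """One Monte-Carlo pass over ``data``; returns (accepted, attempted, skipped)."""
        counts_case, counts_control = self._counts(data)
        y = data[self.outcome_col].to_numpy()
        e_obs = data[self.exposure_col].to_numpy()
        is_case = y == 1
        confounders = dict(self.confounders or {})
        accepted = attempted = skipped = 0
        for _ in range(self.n_monte_carlo):
            consecutive = 0
            while True:
                draw = self.bias_model.sample(1, seed=rng)[0]
                attempted += 1
                screen = screen_draw(draw, counts_case, counts_control)
                if screen.valid:
                    break
                consecutive += 1
                if consecutive >= self.max_redraws:
                    thr_case = counts_case.b_star / counts_case.total
                    thr_control = counts_control.b_star / counts_control.total
                    raise AcceptanceExhausted(
                        f"no valid bias draw in {self.max_redraws} attempts; "
                        f"with these margins specificity must be >= "
                        f"{thr_case:.4f} (cases) and >= {thr_control:.4f} (controls)"
                    )
            accepted += 1
            imputed = np.empty(len(data), dtype=np.int8)
            imputed[is_case] = impute_exposure(e_obs[is_case], screen.pv_case, seed=rng)
            imputed[~is_case] = impute_exposure(e_obs[~is_case], screen.pv_control, seed=rng)
            try:
                or_hat, pe = fit_adjusted_or(data, imputed, confounders, self.outcome_col)
            except NonConvergence:
                skipped += 1
                continue
            or_out.append(or_hat)
            pe_out.append(pe)
        return accepted, attempted, skipped

    # -- sklearn surface -------------------------------------------------

    def fit(self, data: pd.DataFrame, y=None) -> "ProbabilisticBiasAnalysis":
        """Run the full bias analysis on a subject-level case-control table."""
        if self.bias_model is None:
            raise ValueError("bias_model must be provided")
        for col in (self.outcome_col, self.exposure_col):
            if col not in data.columns:
                raise ValueError(f"column {col!r} missing from data")
            vals = set(pd.unique(data[col]))
            if not vals <= {0, 1}:
                raise ValueError(f"column {col!r} must be coded 0/1, found {sorted(vals)}")
        data = data.reset_index(drop=True)
        self.counts_case_, self.counts_control_ = self._counts(data)
        self.conventional_or_, self.conventional_pe_ = fit_adjusted_or(
            data, self.exposure_col, dict(self.confounders or {}), self.outcome_col)

        ss = np.random.SeedSequence(self.seed)
        ors: list[float] = []
        pes: list[float] = []
        accepted = attempted = skipped = 0
        if self.include_random_error:
            case_idx = np.flatnonzero(data[self.outcome_col].to_numpy() == 1)
            control_idx = np.flatnonzero(data[self.outcome_col].to_numpy() == 0)
            for child in ss.spawn(self.n_bootstrap):
                rng = np.random.default_rng(child)
                idx = np.concatenate([
                    rng.choice(case_idx, size=len(case_idx), replace=True),
                    rng.choice(control_idx, size=len(control_idx), replace=True),
                ])
                sample = data.iloc[idx].reset_index(drop=True)
                a, t, s = self._mc_pass(sample, rng, ors, pes)
                accepted += a
                attempted += t
                skipped += s
        else:
            rng = np.random.default_rng(ss)
            accepted, attempted, skipped = self._mc_pass(data, rng, ors, pes)

        n_slots = (self.n_bootstrap if self.include_random_error else 1) * self.n_monte_carlo
        self.or_draws_ = ORDraws(
            values=np.asarray(ors, dtype=float),
            pe_case=np.asarray(pes, dtype=float),
            skipped=skipped,
            acceptance_rate=accepted / attempted if attempted else 0.0,
            n_slots=n_slots,
        )
        self.summary_ = summarize(self.or_draws_)
        return self


def run_pbam(data: pd.DataFrame, bias_model: BiasModel,
             config: EngineConfig | None = None, **kwargs) -> tuple[ORDraws, PbamSummary]:
    """Functional wrapper around :class:`ProbabilisticBiasAnalysis`."""
    config = config or EngineConfig()
    est = ProbabilisticBiasAnalysis(
        bias_model=bias_model,
        n_bootstrap=config.n_bootstrap,
        n_monte_carlo=config.n_monte_carlo,
        confounders=dict(config.confounders),
        include_random_error=config.include_random_error,
        seed=config.seed,
        max_redraws=config.max_redraws,
        **kwargs,
    ).fit(data)
    return est.or_draws_, est.summary_
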