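"""Population attributable fraction and E-values for adjusted odds ratios.

PAF uses Miettinen's case-load form, PAF = p_e (RR - 1) / RR, where p_e is
the exposure prevalence among cases and the adjusted OR stands in for the RR
under the rare-outcome assumption.  In the bias-analysis pipeline PAF is
computed per replicate from that replicate's *imputed* case-group exposure
prevalence and adjusted OR, then summarized by percentiles like the ORs.

The E-value is the minimum strength of association, on the risk-ratio
scale, that an unmeasured confounder would need with both exposure and
outcome to fully explain away an observed association:
E = RR + sqrt(RR (RR - 1)) for RR >= 1, applied to 1/RR for protective
estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import ORDraws

__all__ = ["PafInput", "EffectSummary", "paf_miettinen", "evalue", "paf_pipeline"]


@dataclass(frozen=True)
class PafInput:
    """Exposure prevalence among cases and the risk-ratio stand-in."""

    p_e: float
    rr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_e <= 1.0:
            raise ValueError(f"p_e must lie in [0,1], got {self.p_e}")
        if self.rr <= 0.0:
            raise ValueError(f"rr must be positive, got {self.rr}")


@dataclass(frozen=True)
class EffectSummary:
    """PAF percentiles (in percent) and E-values for point and interval."""

    paf_point: float
    paf_low: float
    paf_high: float
    evalue_point: float
    evalue_low: float
    or_point: float
    or_low: float
    or_high: float


def paf_miettinen(input: PafInput | None = None, *, p_e: float | None = None,
                  rr: float | None = None) -> float:
    """Miettinen's population attributable fraction, p_e (RR - 1) / RR.

    Returns a fraction (multiply by 100 for percent); negative when RR < 1.
    """
    if input is not None:
        p_e, rr = input.p_e, input.rr
    if rr is None or p_e is None:
        raise ValueError("provide a PafInput or both p_e and rr")
    if rr <= 0.0:
        raise ValueError(f"rr must be positive, got {rr}")
    return p_e * (rr - 1.0) / rr


def evalue(or_estimate: float) -> float:
    """E-value for an odds ratio treated as a risk ratio.

    E = RR + sqrt(RR (RR - 1)); protective estimates are inverted first, so
    evalue(x) == evalue(1/x) and evalue(1) == 1.
    """
    if or_estimate <= 0.0:
        raise ValueError(f"odds ratio must be positive, got {or_estimate}")
    rr = or_estimate if or_estimate >= 1.0 else 1.0 / or_estimate
    return rr + math.sqrt(rr * (rr - 1.0))


def _interval_evalue(or_low: float, or_high: float, or_point: float) -> float:
    """E-value of the MCSA limit closer to the null; 1 if the interval spans 1."""
    if or_low <= 1.0 <= or_high:
        return 1.0
    return evalue(or_low if or_point >= 1.0 else or_high)


def paf_pipeline(replicates: ORDraws | tuple[np.ndarray, np.ndarray]) -> EffectSummary:
    """Per-replicate PAF and E-value summary of a bias-analysis run.

    Accepts the engine's :class:`~pbam.engine.ORDraws` (or a bare
    ``(or_values, pe_values)`` pair).  PAF is evaluated replicate by
    replicate from the replicate's own corrected case-group prevalence and
    adjusted OR, then summarized by 50/2.5/97.5 linear-interpolation
    percentiles and reported in percent.  E-values are computed for the OR
    point estimate and for the interval limit closer to the null.
    """
    if isinstance(replicates, ORDraws):
        ors, pes = replicates.values, replicates.pe_case
    else:
        ors, pes = (np.asarray(a, dtype=float) for a in replicates)
    if len(ors) == 0:
        raise ValueError("no replicates supplied")
    if len(ors) != len(pes):
        raise ValueError("odds-ratio and prevalence arrays must be aligned")
    paf = 100.0 * pes * (ors - 1.0) / ors
    paf_lo, paf_pt, paf_hi = np.percentile(paf, [2.5, 50.0, 97.5], method="linear")
    or_lo, or_pt, or_hi = np.percentile(ors, [2.5, 50.0, 97.5], method="linear")
    return EffectSummary(
        paf_point=float(paf_pt),
        paf_low=float(paf_lo),
        paf_high=float(paf_hi),
        evalue_point=evalue(float(or_pt)),
        evalue_low=_interval_evalue(float(or_lo), float(or_hi), float(or_pt)),
        or_point=float(or_pt),
        or_low=float(or_lo),
        or_high=float(or_hi),
    )
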