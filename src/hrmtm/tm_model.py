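"""Piecewise empirical melting-temperature formula for HRM amplicons.

The model predicts the melting temperature observed in high-resolution
melting of a 50-200 bp PCR product from four sequence-derived quantities:
total enthalpy dH (kcal/mol), total entropy dS (cal/(K*mol)), GC content
(percentage points) and stack count n (length - 1):

    Tm(degC) = 1000*dH/dS - g(GC%) - (150 + 2n)/n - 273.15

with a GC correction g that depends on the composition regime:

    40% <= GC% <= 60%  (mid_gc):  g = 0.27 * GC%
            GC% < 40%  (low_gc):  g = GC% / 3

The ratio term 1000*dH/dS is in Kelvin (dH is converted kcal->cal before
dividing), the GC and length terms are in degrees, and 273.15 converts to
Celsius.  The two branches do not join continuously at GC% = 40; the branch
assignment (mid_gc at exactly 40) is part of the model.  Above 60% GC the
model has no stated branch: prediction refuses by default and extrapolates
with the mid-GC branch only under an explicit flag (with a warning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .nn_thermo import NNParameterSet, SymmetryPolicy, ThermoResult, duplex_thermo
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

KELVIN_OFFSET = 273.15


class BranchError(ValueError):
    """GC content outside the model's stated domain."""


@dataclass(frozen=True)
class TmCoefficients:
    """Constants of the empirical formula; defaults are the published values.

    gc_coeff_mid : degC per GC percentage point on the 40-60% branch (0.27)
    gc_divisor_low : divisor of GC% on the <40% branch (3)
    length_const, length_slope : the (150 + 2n)/n length term
    branch_low_edge, branch_high_edge : GC% branch boundaries (40, 60)
    """

    gc_coeff_mid: float = 0.27
    gc_divisor_low: float = 3.0
    length_const: float = 150.0
    length_slope: float = 2.0
    kelvin_offset: float = KELVIN_OFFSET
    branch_low_edge: float = 40.0
    branch_high_edge: float = 60.0

    def __post_init__(self) -> None:
        if not self.branch_low_edge < self.branch_high_edge:
            raise ValueError("branch_low_edge must be below branch_high_edge")


@dataclass(frozen=True)
class TmPrediction:
    """A Tm prediction and its additive breakdown.

    tm_celsius == ratio_term - gc_term - length_term - kelvin offset, so the
    result is reconstructable from the components.
    """

    tm_celsius: float
    branch: str  # "mid_gc" or "low_gc"
    ratio_term: float  # Kelvin, 1000*dH/dS
    gc_term: float  # degC
    length_term: float  # degC
    sequence_id: str = ""


def select_branch(
    gc_percent: float,
    coefficients: TmCoefficients | None = None,
    *,
    extrapolate: bool = False,
) -> str:
    """Pick the GC-regime branch: ``mid_gc`` for 40 <= GC% <= 60, ``low_gc`` below.

    Boundaries are inclusive on the mid branch.  GC% above 60 raises
    :class:`BranchError` unless ``extrapolate`` is set, in which case the
    mid-GC branch is used with a warning.
    """
    c = coefficients or TmCoefficients()
    if not 0.0 <= gc_percent <= 100.0:
        raise BranchError(f"GC content {gc_percent} outside [0, 100]")
    if gc_percent > c.branch_high_edge:
        if not extrapolate:
            raise BranchError(
                f"GC content {gc_percent:.2f}% exceeds the model domain "
                f"(<= {c.branch_high_edge:g}%); pass extrapolate=True to force the mid-GC branch"
            )
        logger.warning(
            "GC content %.2f%% above %g%%: extrapolating with the mid-GC branch",
            gc_percent,
            c.branch_high_edge,
        )
        return "mid_gc"
    if gc_percent >= c.branch_low_edge:
        return "mid_gc"
    return "low_gc"


def predict_tm(
    thermo: ThermoResult,
    coefficients: TmCoefficients | None = None,
    *,
    extrapolate: bool = False,
) -> TmPrediction:
    """Evaluate the empirical formula on a :class:`ThermoResult`.

    Full precision is retained in the returned components; round to 2
    decimals only for display.
    """
    c = coefficients or TmCoefficients()
    if thermo.dS_total == 0:
        raise ValueError("dS_total is zero; the ratio term is undefined")
    if thermo.n < 1:
        raise ValueError("need at least one stack (n >= 1)")
    branch = select_branch(thermo.gc_percent, c, extrapolate=extrapolate)
    ratio_term = 1000.0 * thermo.dH_total / thermo.dS_total  # kcal->cal puts this in K
    if branch == "mid_gc":
        gc_term = c.gc_coeff_mid * thermo.gc_percent
    else:
        gc_term = thermo.gc_percent / c.gc_divisor_low
    length_term = (c.length_const + c.length_slope * thermo.n) / thermo.n
    tm = ratio_term - gc_term - length_term - c.kelvin_offset
    return TmPrediction(
        tm_celsius=tm,
        branch=branch,
        ratio_term=ratio_term,
        gc_term=gc_term,
        length_term=length_term,
        sequence_id=thermo.sequence_id,
    )


def predict_from_sequence(
    record: SequenceRecord | str,
    params: NNParameterSet | None = None,
    coefficients: TmCoefficients | None = None,
    symmetry_policy: SymmetryPolicy = "auto",
    *,
    extrapolate: bool = False,
) -> TmPrediction:
    """Compose duplex_thermo and predict_tm on one sequence."""
    thermo = duplex_thermo(record, params, symmetry_policy)
    return predict_tm(thermo, coefficients, extrapolate=extrapolate)
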