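"""Assay arithmetic: extraction yield, radical scavenging, NO inhibition,
and standard-curve quantification (gallic-acid / quercetin / Trolox
equivalents).

These are the deterministic formulas that turn raw masses and plate
absorbances into the percent and content values the downstream models
consume.  Scavenging percentages can legitimately be negative (a
pro-oxidant reading raises absorbance above the control); such values
are returned unclamped but flagged so callers can exclude them from
dose-response fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "YieldWeights",
    "AbsorbanceReading",
    "StandardCurve",
    "FlaggedValue",
    "percent_yield",
    "scavenging_percent",
    "no_inhibition_percent",
    "fit_standard_curve",
    "content_from_curve",
]

ANALYTES = ("gallic_acid", "quercetin", "trolox")


@dataclass(frozen=True)
class YieldWeights:
    """Gravimetric yield measurement: w0 dried sample mass, w1 empty
    receptacle mass, w2 receptacle-plus-extract mass (all grams)."""

    w0: float
    w1: float
    w2: float

    def __post_init__(self) -> None:
        if self.w0 <= 0:
            raise ValueError(f"dried-sample mass w0 must be positive, got {self.w0}")
        if self.w2 < self.w1:
            raise ValueError("receptacle+extract mass w2 cannot be below receptacle mass w1")


@dataclass(frozen=True)
class AbsorbanceReading:
    """Control / sample / blank absorbances for one inhibition assay well."""

    control: float
    sample: float
    blank: float = 0.0

    def __post_init__(self) -> None:
        if self.control <= 0:
            raise ValueError(f"control absorbance must be positive, got {self.control}")
        if self.sample < 0 or self.blank < 0:
            raise ValueError("absorbances must be non-negative")


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration: absorbance = slope * concentration + intercept."""

    analyte: str
    slope: float
    intercept: float
    r2: float

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValueError(f"analyte must be one of {ANALYTES}, got {self.analyte!r}")
        if self.slope == 0:
            raise ValueError("standard-curve slope must be nonzero")


@dataclass(frozen=True)
class FlaggedValue:
    """A numeric result plus a flag marking physically suspect readings."""

    value: float
    suspect: bool = False

    def __float__(self) -> float:
        return self.value


def percent_yield(w: YieldWeights) -> float:
    """Percent extraction yield, 100 * (w2 - w1) / w0."""
    return 100.0 * (w.w2 - w.w1) / w.w0


def scavenging_percent(r: AbsorbanceReading) -> FlaggedValue:
    """DPPH/ABTS radical-scavenging activity as percent of control.

    100 * (control - sample - blank) / control.  Negative results
    (pro-oxidant readings) are returned unclamped with ``suspect=True``.
    """
    pct = 100.0 * (r.control - r.sample - r.blank) / r.control
    return FlaggedValue(pct, suspect=pct < 0)


def no_inhibition_percent(r: AbsorbanceReading) -> FlaggedValue:
    """Percent inhibition of NO production, 100 * (control - sample) / control.

    The blank field of the reading is ignored (the Griess readout
    subtracts no separate blank).
    """
    pct = 100.0 * (r.control - r.sample) / r.control
    return FlaggedValue(pct, suspect=pct < 0)


def fit_standard_curve(concentrations, absorbances, analyte: str) -> StandardCurve:
    """Ordinary least-squares calibration line for a reference analyte.

    Requires at least three concentration levels with nonzero spread;
    fitted unweighted on the raw concentration scale.
    """
    conc = np.asarray(concentrations, dtype=float)
    absb = np.asarray(absorbances, dtype=float)
    if conc.shape != absb.shape or conc.ndim != 1:
        raise ValueError("concentrations and absorbances must be equal-length 1-D sequences")
    if conc.size < 3:
        raise ValueError(f"need >= 3 calibration points, got {conc.size}")
    if np.any(conc <= 0):
        raise ValueError("calibration concentrations must be strictly positive")
    if np.ptp(conc) == 0:
        raise ValueError("calibration concentrations are all equal; slope undefined")
    fit = stats.linregress(conc, absb)
    return StandardCurve(analyte=analyte, slope=fit.slope, intercept=fit.intercept, r2=fit.rvalue**2)


def content_from_curve(sample_abs: float, curve: StandardCurve, extract_conc: float) -> FlaggedValue:
    """Analyte-equivalent content, mg per g of dried extract.

    Inverts the calibration line to a concentration in ug/mL and
    divides by the extract concentration in mg/mL; the ug/mg ratio is
    numerically mg equivalents per g extract.  A negative computed
    concentration (absorbance below the intercept) is returned with
    ``suspect=True``.
    """
    if extract_conc <= 0:
        raise ValueError(f"extract concentration must be positive, got {extract_conc}")
    conc = (sample_abs - curve.intercept) / curve.slope
    value = conc / extract_conc
    return FlaggedValue(value, suspect=value < 0)
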