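"""Combination-effect analysis for constant-ratio herb mixtures.

Two complementary statistics are implemented:

* **FPI** (fractional percentage inhibitory index): the combination's
  percent inhibition divided by the sum of the single-component percent
  inhibitions at the same concentration.  FPI >= 2.0 indicates
  synergism, 0.5 <= FPI < 2.0 additivity, FPI < 0.5 antagonism.

* **CI** (Chou-Talalay combination index) under Loewe additivity for a
  constant-ratio mixture.  At effect level fa, the mixture's own
  median-effect fit gives the total dose Dx_mix reaching fa; component
  i then contributes D_i = w_i * Dx_mix (w_i its mass fraction), and

      CI(fa) = sum_i D_i / Dx_i

  where Dx_i is the dose of component i *alone* reaching fa.  CI < 1
  synergism, CI = 1 additivity, CI > 1 antagonism.  The dose-reduction
  index DRI_i = Dx_i / D_i is the fold by which component i's dose is
  reduced in combination at equal effect; CI = sum_i 1/DRI_i.

Classification by CI uses the strict rule; a configurable band around
1 (default +/-0.05) marks values as "nearly additive" so floating-point
output remains readable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io import FormulationPoint
from .median_effect import MedianEffectResults

__all__ = [
    "MixtureSpec",
    "FPIResult",
    "SynergyProfile",
    "fpi",
    "classify_ci",
    "combination_index",
    "dose_reduction_index",
    "ci_curve",
    "isobologram_points",
    "round_half_up",
]


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties going away from zero (the convention used for
    comparing against published one/two-decimal values)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MixtureSpec:
    """Mass-fraction composition of a fixed-ratio mixture."""

    labels: tuple[str, ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.fractions):
            raise ValueError("labels and fractions must have equal length")
        if any(w < 0 for w in self.fractions):
            raise ValueError("mass fractions must be non-negative")
        if abs(sum(self.fractions) - 1.0) > 1e-8:
            raise ValueError(f"mass fractions must sum to 1, got {sum(self.fractions)}")

    @classmethod
    def from_masses(cls, masses, labels=("GM", "CC", "AE")) -> "MixtureSpec":
        total = float(sum(masses))
        if total <= 0:
            raise ValueError("total mass must be positive")
        return cls(labels=tuple(labels), fractions=tuple(m / total for m in masses))

    @classmethod
    def from_point(cls, point: FormulationPoint) -> "MixtureSpec":
        return cls.from_masses(point.as_tuple())


@dataclass(frozen=True)
class FPIResult:
    """FPI value with its interaction classification.

    Classification is decided on the unrounded value; ``rounded_1dp``
    matches the one-decimal convention of published tables.
    """

    fpi: float
    classification: str
    rounded_1dp: float


def fpi(combo_inhibition: float, single_inhibitions) -> FPIResult:
    """Fractional percentage inhibitory index of a combination.

    ``combo_inhibition`` and the component ``single_inhibitions`` are
    percent inhibitions measured at one matched concentration.
    """
    singles = [float(s) for s in single_inhibitions]
    denom = sum(singles)
    if not all(math.isfinite(s) for s in singles) or not math.isfinite(combo_inhibition):
        raise ValueError("inhibition values must be finite")
    if denom <= 0:
        raise ValueError(f"sum of single-component inhibitions must be positive, got {denom}")
    value = float(combo_inhibition) / denom
    if value >= 2.0:
        cls = "synergism"
    elif value >= 0.5:
        cls = "additivity"
    else:
        cls = "antagonism"
    return FPIResult(fpi=value, classification=cls, rounded_1dp=round_half_up(value, 1))


def classify_ci(ci: float, additive_band: float = 0.05) -> str:
    """Interaction class from a combination index.

    Strict rule (CI < 1 synergism, CI > 1 antagonism) with an optional
    band around 1 reported as "nearly additive"; ``additive_band=0``
    recovers the strict rule with only CI = 1 (to numerical precision)
    additive.
    """
    if abs(ci - 1.0) <= 1e-9:
        return "additive"
    if abs(ci - 1.0) <= additive_band:
        return "nearly additive"
    return "synergism" if ci < 1.0 else "antagonism"


def _component_doses(fa, mixture, component_fits, mixture_fit):
    dx_mix = mixture_fit.dose_for_effect(fa)
    d_in_mix = [w * dx_mix for w in mixture.fractions]
    dx_alone = [fit.dose_for_effect(fa) for fit in component_fits]
    return d_in_mix, dx_alone


def combination_index(
    fa: float,
    mixture: MixtureSpec,
    component_fits,
    mixture_fit: MedianEffectResults,
) -> float:
    """Combination index at effect level ``fa`` for a constant-ratio mixture."""
    if len(component_fits) != len(mixture.fractions):
        raise ValueError("one median-effect fit per mixture component is required")
    d_in_mix, dx_alone = _component_doses(fa, mixture, component_fits, mixture_fit)
    return float(sum(d / dx for d, dx in zip(d_in_mix, dx_alone)))


def dose_reduction_index(
    fa: float,
    mixture: MixtureSpec,
    component_fits,
    mixture_fit: MedianEffectResults,
) -> tuple[float | None, ...]:
    """Per-component dose-reduction index at effect level ``fa``.

    Components with zero mass fraction have no dose in the mixture, so
    their DRI is undefined and reported as ``None`` (not infinity).
    """
    d_in_mix, dx_alone = _component_doses(fa, mixture, component_fits, mixture_fit)
    return tuple(
        (dx / d) if d > 0 else None for d, dx in zip(d_in_mix, dx_alone)
    )


@dataclass(frozen=True)
class SynergyProfile:
    """CI and DRI over a grid of effect levels (an Fa-CI curve)."""

    mixture: MixtureSpec
    table: pd.DataFrame  # columns: fa, ci, dri_<label>..., classification

    def ci_at(self, fa: float) -> float:
        idx = (self.table["fa"] - fa).abs().idxmin()
        return float(self.table.loc[idx, "ci"])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def ci_curve(
    mixture: MixtureSpec,
    component_fits,
    mixture_fit: MedianEffectResults,
    fa_grid=None,
    additive_band: float = 0.05,
) -> SynergyProfile:
    """Fa-CI curve: CI, per-component DRI and classification per effect level.

    Default grid is fa = 0.05 ... 0.95 in steps of 0.05.
    """
    if fa_grid is None:
        fa_grid = np.round(np.arange(0.05, 0.951, 0.05), 10)
    fa_grid = np.asarray(fa_grid, dtype=float)
    if np.any((fa_grid <= 0) | (fa_grid >= 1)):
        raise ValueError("fa grid must lie strictly inside (0, 1)")
    rows = []
    for fa in fa_grid:
        ci = combination_index(fa, mixture, component_fits, mixture_fit)
        dris = dose_reduction_index(fa, mixture, component_fits, mixture_fit)
        row = {"fa": fa, "ci": ci, "classification": classify_ci(ci, additive_band)}
        for label, dri in zip(mixture.labels, dris):
            row[f"dri_{label}"] = np.nan if dri is None else dri
        rows.append(row)
    cols = ["fa", "ci", *[f"dri_{l}" for l in mixture.labels], "classification"]
    return SynergyProfile(mixture=mixture, table=pd.DataFrame(rows, columns=cols))


def isobologram_points(
    fa: float,
    pair: tuple[int, int],
    component_fits,
    mixture: MixtureSpec,
    mixture_fit: MedianEffectResults,
) -> tuple[float, float]:
    """Normalized isobologram coordinates for a component pair at ``fa``.

    Returns (D_i/Dx_i, D_j/Dx_j): each component's dose in the mixture
    divided by its equally-effective single-agent dose.  The additivity
    line is x + y = 1; points below it indicate synergy.
    """
    i, j = pair
    d_in_mix, dx_alone = _component_doses(fa, mixture, component_fits, mixture_fit)
    return (d_in_mix[i] / dx_alone[i], d_in_mix[j] / dx_alone[j])
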