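"""Safety scoring: cytotoxic IC20, the selectivity index, and the
efficacy/viability safety window.

Cytotoxicity is read on L929 fibroblasts as cell viability versus
dose; the IC20 is the dose reducing viability to 80% (fraction
affected 0.2).  The selectivity index contrasts that cytotoxic
threshold with anti-inflammatory potency on RAW 264.7 macrophages::

    SI = IC20(cytotoxicity, fibroblast) / IC50(anti-inflammatory, macrophage)

SI > 1 means the formulation suppresses inflammation at doses below
those harming fibroblasts — a favorable therapeutic window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .median_effect import (
    DoseResponseCurve,
    MedianEffectModel,
    MedianEffectResults,
    icxx_interpolated,
)
from .synergy import round_half_up

__all__ = [
    "SafetyProfile",
    "ic20_from_viability",
    "selectivity_index",
    "safety_window",
]

#: Median-effect plot correlation below which the model fit is
#: distrusted and the model-free interpolation fallback is used.
MIN_FIT_CORRELATION = 0.9


@dataclass(frozen=True)
class SafetyProfile:
    """Paired cytotoxic IC20 and activity IC50 with the derived SI."""

    label: str
    ic20_cytotox: float
    ic50_activity: float
    si: float
    favorable: bool
    viability_threshold_pct: float = 80.0

    @property
    def si_2dp(self) -> float:
        """SI rounded half-up to two decimals (reporting convention)."""
        return round_half_up(self.si, 2)


def ic20_from_viability(doses, viability_pct, label: str = "") -> tuple[float, str]:
    """Cytotoxic IC20 (ug/mL) from a (dose, % viability) curve.

    Converts viability to fraction affected fa = (100 - viability)/100,
    fits the median-effect model, and inverts it at fa = 0.2.  When the
    median-effect plot correlates poorly (r < 0.9) the model-free
    log-dose interpolation is used instead.  Returns (dose, method).
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability_pct, dtype=float)
    fa = (100.0 - viability) / 100.0
    if fa.max() < 0.2:
        raise ValueError(
            "viability never falls below 80% in the tested dose range; "
            f"the extract is safe up to {doses.max():g} ug/mL and no IC20 is defined"
        )
    curve = DoseResponseCurve(doses=tuple(doses), fa=tuple(fa), label=label, assay="cytotoxicity")
    fit = MedianEffectModel(curve).fit()
    if fit.r >= MIN_FIT_CORRELATION:
        return fit.dose_for_effect(0.2), "median_effect"
    return icxx_interpolated(curve, 0.2), "interpolated"


def selectivity_index(ic20: float, ic50: float, label: str = "") -> SafetyProfile:
    """Selectivity index SI = IC20(cytotoxicity) / IC50(activity)."""
    if ic20 <= 0 or ic50 <= 0:
        raise ValueError(f"IC20 and IC50 must both be positive, got {ic20}, {ic50}")
    si = ic20 / ic50
    return SafetyProfile(
        label=label, ic20_cytotox=ic20, ic50_activity=ic50, si=si, favorable=si > 1
    )


def safety_window(
    activity_fit: MedianEffectResults,
    toxicity_fit: MedianEffectResults,
    dose_range: tuple[float, float],
    efficacy_threshold_pct: float = 50.0,
    viability_threshold_pct: float = 80.0,
) -> tuple[float, float] | None:
    """Dose interval that is both effective and safe.

    Within ``dose_range``, returns the interval where predicted
    activity inhibition >= ``efficacy_threshold_pct`` and predicted
    viability >= ``viability_threshold_pct``; ``None`` when the two
    requirements cannot be met together.  ``toxicity_fit`` models the
    fraction of cells affected (killed), so viability >= v maps to
    fa <= (100 - v)/100.
    """
    lo, hi = dose_range
    if not 0 < lo < hi:
        raise ValueError(f"dose_range must satisfy 0 < lo < hi, got {dose_range}")

    eff_lo = lo
    if efficacy_threshold_pct > 0:
        fa_eff = efficacy_threshold_pct / 100.0
        if fa_eff >= 1:
            return None
        eff_lo = max(lo, activity_fit.dose_for_effect(fa_eff))

    tox_hi = hi
    if viability_threshold_pct > 0:
        fa_tox = (100.0 - viability_threshold_pct) / 100.0
        if fa_tox <= 0:
            return None
        if fa_tox < 1:
            tox_hi = min(hi, toxicity_fit.dose_for_effect(fa_tox))

    if eff_lo > tox_hi:
        return None
    return (eff_lo, tox_hi)
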