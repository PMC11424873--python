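"""Median-effect (mass-action) dose-response modelling.

The median-effect equation relates the fraction affected fa (e.g. the
fraction of NO production inhibited, or of cells killed) to dose D::

    fa / (1 - fa) = (D / Dm)^m

Dm is the median-effect dose — the dose giving fa = 0.5, i.e. the IC50
— and m is the sigmoidicity of the curve (m = 1 hyperbolic, m > 1
sigmoidal).  Taking base-10 logarithms gives the median-effect plot,

    log10(fa / fu) = m * log10(D) - m * log10(Dm),

a straight line fitted here by unweighted least squares; r is the
Pearson correlation of the plot and measures conformity to the
mass-action model.  The same fit supplies any inverse dose query:
ICxx = Dm * (x / (100 - x))^(1/m).

Percent-inhibition data are converted as fa = pct / 100.  Because the
logit transform diverges at fa = 0 or 1, observations are clipped into
[0.005, 0.995] (with per-point flags); negative inhibition readings are
excluded from the fit by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DoseResponseCurve",
    "MedianEffectModel",
    "MedianEffectResults",
    "icxx_interpolated",
    "FA_CLIP",
]

#: Clipping bounds applied to the fraction affected before the logit
#: transform; values at exactly 0 or 1 are clipped, not dropped.
FA_CLIP = (0.005, 0.995)


@dataclass(frozen=True)
class DoseResponseCurve:
    """Dose (ug/mL) versus fraction-affected observations for one agent."""

    doses: tuple[float, ...]
    fa: tuple[float, ...]
    label: str = ""
    assay: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        f = np.asarray(self.fa, dtype=float)
        if d.shape != f.shape or d.ndim != 1:
            raise ValueError("doses and fa must be equal-length 1-D sequences")
        if np.any(d <= 0):
            raise ValueError("doses must be strictly positive")
        if np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise ValueError("fa values must be finite")

    @classmethod
    def from_percent_inhibition(cls, doses, pct, label: str = "", assay: str = "") -> "DoseResponseCurve":
        fa = tuple(float(p) / 100.0 for p in pct)
        return cls(doses=tuple(float(d) for d in doses), fa=fa, label=label, assay=assay)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dose": self.doses, "fa": self.fa})


class MedianEffectModel:
    """Median-effect model for a single dose-response curve.

    ``fit()`` performs the median-effect-plot regression and returns a
    :class:`MedianEffectResults`.

    Examples
    --------
    >>> curve = DoseResponseCurve.from_percent_inhibition(
    ...     (10, 20, 50), (44.84, 66.10, 98.86), label="5:10:15")
    >>> fit = MedianEffectModel(curve).fit()
    >>> round(fit.dm, 1)
    12.4
    """

    def __init__(self, curve: DoseResponseCurve, drop_negative: bool = True):
        self.curve = curve
        self.drop_negative = drop_negative

    def fit(self) -> "MedianEffectResults":
        doses = np.asarray(self.curve.doses, dtype=float)
        fa = np.asarray(self.curve.fa, dtype=float)

        keep = np.ones(len(fa), dtype=bool)
        if self.drop_negative:
            keep &= fa >= 0
        lo, hi = FA_CLIP
        fa_used = np.clip(fa[keep], lo, hi)
        clipped = (fa[keep] < lo) | (fa[keep] > hi)
        d_used = doses[keep]

        if len(d_used) < 2:
            raise ValueError(
                f"median-effect fit needs >= 2 usable points, got {len(d_used)}"
            )

        x = np.log10(d_used)
        y = np.log10(fa_used / (1.0 - fa_used))
        reg = stats.linregress(x, y)
        if reg.slope <= 0:
            raise ValueError(
                f"median-effect slope m = {reg.slope:.4g} <= 0: effect does not "
                "increase with dose; the mass-action model does not apply"
            )
        m = float(reg.slope)
        dm = float(10.0 ** (-reg.intercept / reg.slope))
        return MedianEffectResults(
            model=self,
            m=m,
            dm=dm,
            r=float(reg.rvalue),
            n_used=int(len(d_used)),
            clipped=tuple(bool(c) for c in clipped),
        )


@dataclass(frozen=True)
class MedianEffectResults:
    """Fitted median-effect parameters and inverse dose queries.

    Attributes
    ----------
    m : slope (sigmoidicity) of the median-effect plot.
    dm : median-effect dose in ug/mL; equals the IC50.
    r : Pearson correlation of the median-effect plot (1 for a perfect
        mass-action curve).
    """

    model: MedianEffectModel | None
    m: float
    dm: float
    r: float
    n_used: int
    clipped: tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.dm <= 0:
            raise ValueError("median-effect dose dm must be positive")
        if self.m <= 0:
            raise ValueError("median-effect slope m must be positive")

    @classmethod
    def from_parameters(cls, m: float, dm: float, label: str = "") -> "MedianEffectResults":
        """A results object from known (m, Dm) — e.g. for simulation."""
        return cls(model=None, m=m, dm=dm, r=1.0, n_used=0)

    @property
    def ic50(self) -> float:
        return self.dm

    def dose_for_effect(self, fa: float) -> float:
        """Dose producing fraction affected ``fa``: Dm * (fa/(1-fa))^(1/m)."""
        if not 0 < fa < 1:
            raise ValueError(f"fa must be strictly inside (0, 1), got {fa}")
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)

    def fa_at_dose(self, dose: float) -> float:
        """Fraction affected at ``dose``: (D/Dm)^m / (1 + (D/Dm)^m)."""
        if dose <= 0:
            raise ValueError(f"dose must be positive, got {dose}")
        ratio = (dose / self.dm) ** self.m
        return ratio / (1.0 + ratio)

    def ic(self, pct: float) -> float:
        """ICxx as a dose: e.g. ``ic(20)`` is the dose with 20% effect."""
        return self.dose_for_effect(pct / 100.0)

    def summary(self) -> str:
        label = self.model.curve.label if self.model is not None else "(parametric)"
        return (
            f"Median-effect fit: {label}\n"
            f"m = {self.m:.4f}, Dm (IC50) = {self.dm:.4f} ug/mL, "
            f"r = {self.r:.4f}, n = {self.n_used}"
        )


def icxx_interpolated(curve: DoseResponseCurve, target_fa: float) -> float:
    """Model-free ICxx by linear interpolation of fa against log10(dose).

    A clearly-labelled fallback for curves that fit the mass-action
    model poorly; the target must be bracketed by observed fa values.
    """
    if not 0 < target_fa < 1:
        raise ValueError(f"target fa must be inside (0, 1), got {target_fa}")
    doses = np.asarray(curve.doses, dtype=float)
    fa = np.asarray(curve.fa, dtype=float)
    for i in range(len(fa) - 1):
        f0, f1 = fa[i], fa[i + 1]
        if min(f0, f1) <= target_fa <= max(f0, f1):
            if f0 == f1:
                return float(doses[i])
            t = (target_fa - f0) / (f1 - f0)
            return float(10.0 ** (np.log10(doses[i]) + t * (np.log10(doses[i + 1]) - np.log10(doses[i]))))
    raise ValueError(
        f"target fa = {target_fa} is not bracketed by observed fa range "
        f"[{fa.min():.4f}, {fa.max():.4f}]"
    )
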