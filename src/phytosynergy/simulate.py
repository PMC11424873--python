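"""Synthetic-data generators mirroring the statistical structure each
analysis stage assumes.

Three generators are provided:

* a Box-Behnken extraction dataset — responses from a known quadratic
  surface plus independent Gaussian noise;
* a median-effect dose-response curve — fa from known (m, Dm), with
  optional Gaussian noise applied on the logit-log scale (the scale on
  which the model is linear), so perturbed fa stays inside (0, 1)
  without ad-hoc clipping;
* a Loewe-additive constant-ratio mixture curve — at each total dose D
  the fraction affected solves

      sum_i (w_i * D) / D_i(fa) = 1,

  with D_i(fa) the single-component dose reaching fa, by bracketed
  root-finding.  By construction such a mixture has combination index
  exactly 1 at every effect level, giving a sharp null against which
  the synergy pipeline is validated.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .io import FormulationPoint, FormulationRun, ResponseTable
from .median_effect import DoseResponseCurve, MedianEffectResults
from .rsm import ResponseSurfaceResults, bbd_design, quadratic_design_matrix
from .synergy import MixtureSpec

__all__ = [
    "gen_bbd_dataset",
    "gen_dose_response",
    "gen_loewe_mixture",
    "loewe_fa_at_dose",
]


def _coeff_vector(surface) -> np.ndarray:
    if isinstance(surface, ResponseSurfaceResults):
        return surface.params.to_numpy()
    arr = np.asarray(surface, dtype=float)
    if arr.shape != (10,):
        raise ValueError("surface must be ResponseSurfaceResults or 10 coefficients")
    return arr


def gen_bbd_dataset(
    surface,
    levels: tuple[float, float, float] = (5.0, 10.0, 15.0),
    noise_sd: float = 0.0,
    seed: int | None = None,
    response_name: str = "yield",
    solvent: str = "ethanol",
) -> ResponseTable:
    """15-run Box-Behnken dataset from a known quadratic surface.

    ``surface`` is either fitted results or a length-10 coefficient
    vector in the standard term order; responses get independent
    N(0, noise_sd) errors.  Deterministic given ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required for noisy generation")
    beta = _coeff_vector(surface)
    points = bbd_design(levels)
    X = quadratic_design_matrix(points).to_numpy()
    y = X @ beta
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(y))
    attr = {"yield": "yield_pct", "phenolic": "phenolic_gae", "flavonoid": "flavonoid_qe"}
    runs = tuple(
        FormulationRun(point=p, solvent=solvent, validate=False,
                       **{attr[response_name]: float(v)})
        for p, v in zip(points, y)
    )
    return ResponseTable(runs=runs, response_name=response_name, solvent=solvent)


def gen_dose_response(
    m: float,
    dm: float,
    doses,
    noise_sd: float = 0.0,
    seed: int | None = None,
    label: str = "synthetic",
) -> DoseResponseCurve:
    """Median-effect dose-response curve from known (m, Dm).

    ``noise_sd`` is the Gaussian standard deviation on the logit-log
    scale log10(fa/(1-fa)); zero noise gives the exact model curve.
    """
    if m <= 0 or dm <= 0:
        raise ValueError("m and dm must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required for noisy generation")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    logit = m * (np.log10(doses) - np.log10(dm))
    if noise_sd > 0:
        logit = logit + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(doses))
    ratio = 10.0**logit
    fa = ratio / (1.0 + ratio)
    return DoseResponseCurve(doses=tuple(doses), fa=tuple(fa), label=label)


def loewe_fa_at_dose(
    total_dose: float,
    component_fits,
    mixture: MixtureSpec,
    tol: float = 1e-12,
) -> float:
    """Fraction affected of a Loewe-additive mixture at a total dose.

    Solves sum_i (w_i * D) / dose_for_effect(fit_i, fa) = 1 for fa by
    bracketed root-finding on (1e-9, 1 - 1e-9).
    """
    if total_dose <= 0:
        raise ValueError("total dose must be positive")
    active = [(w, f) for w, f in zip(mixture.fractions, component_fits) if w > 0]
    if not active:
        raise ValueError("mixture has no active components")

    def g(fa: float) -> float:
        return sum(w * total_dose / f.dose_for_effect(fa) for w, f in active) - 1.0

    lo, hi = 1e-9, 1.0 - 1e-9
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        raise ArithmeticError(
            f"Loewe additivity equation has no root in ({lo}, {hi}) at dose {total_dose}"
        )
    return float(brentq(g, lo, hi, xtol=tol, rtol=8.9e-16))


def gen_loewe_mixture(
    component_fits,
    mixture: MixtureSpec,
    total_doses,
    noise_sd: float = 0.0,
    seed: int | None = None,
    label: str = "loewe-mixture",
) -> DoseResponseCurve:
    """Dose-response curve of an exactly Loewe-additive mixture.

    Feeding this curve's median-effect fit through the combination
    index recovers CI = 1 across effect levels (up to the root-finding
    and refit tolerance).
    """
    total_doses = np.asarray(total_doses, dtype=float)
    fa = np.array([loewe_fa_at_dose(d, component_fits, mixture) for d in total_doses])
    if noise_sd > 0:
        if seed is None:
            raise ValueError("a seed is required for noisy generation")
        logit = np.log10(fa / (1.0 - fa))
        logit = logit + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(fa))
        ratio = 10.0**logit
        fa = ratio / (1.0 + ratio)
    return DoseResponseCurve(doses=tuple(total_doses), fa=tuple(fa), label=label)
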