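"""Box-Behnken design construction and full-quadratic response-surface
modelling.

The model is the standard second-order response surface for three
factors x = (GM, CC, AE), fitted by ordinary least squares in actual
(uncoded) gram units::

    y = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 + sum_{i<j} b_ij x_i x_j + e

With the 15-run Box-Behnken design (12 edge midpoints + 3 center
replicates) the full quadratic leaves 5 residual degrees of freedom, so
the two-sided 5% critical value for standardized effects |b|/SE(b) is
t(0.975, 5) = 2.571 — the reference line of a Pareto chart.

Fitting in uncoded units reproduces published polynomial coefficients
directly; a coded (-1/0/+1) view is available from the results object
for effect comparison across factors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import FormulationPoint, ResponseTable

__all__ = [
    "TERM_NAMES",
    "bbd_design",
    "quadratic_design_matrix",
    "observed_optimum",
    "ResponseSurfaceModel",
    "ResponseSurfaceResults",
    "EffectRanking",
]


def observed_optimum(table: ResponseTable, minimize: bool = False) -> tuple[FormulationPoint, float]:
    """The design run with the best *observed* response.

    Complements :meth:`ResponseSurfaceResults.grid_optimum`: when design
    runs at a fixed total mass are compared directly, the recommended
    formulation is simply the best-performing run.  Ties break
    lexicographically on (GM, CC, AE).
    """
    values = table.values()
    pairs = sorted(
        zip(values, table.points()),
        key=lambda vp: ((vp[0] if minimize else -vp[0]), vp[1].as_tuple()),
    )
    best_value, best_point = pairs[0]
    return best_point, float(best_value)

#: Column order of the full-quadratic design matrix.
TERM_NAMES = (
    "Intercept",
    "GM",
    "CC",
    "AE",
    "GM^2",
    "CC^2",
    "AE^2",
    "GM*CC",
    "GM*AE",
    "CC*AE",
)


def bbd_design(
    levels: tuple[float, float, float] = (5.0, 10.0, 15.0), n_center: int = 3
) -> list[FormulationPoint]:
    """Three-factor Box-Behnken design points in run-standard order.

    Twelve edge-midpoint runs (each pair of factors at low/high, the
    third at mid) plus ``n_center`` replicated center runs; no cube
    corners.  ``levels`` are the common (low, mid, high) factor levels
    in grams.
    """
    low, mid, high = levels
    if len({low, mid, high}) != 3:
        raise ValueError(f"levels must be three distinct values, got {levels}")
    points: list[FormulationPoint] = []
    for i, j in itertools.combinations(range(3), 2):
        for a, b in itertools.product((low, high), repeat=2):
            coords = [mid, mid, mid]
            coords[i], coords[j] = a, b
            points.append(FormulationPoint(*coords))
    points.extend(FormulationPoint(mid, mid, mid) for _ in range(n_center))
    return points


def quadratic_design_matrix(points: list[FormulationPoint] | np.ndarray) -> pd.DataFrame:
    """Full-quadratic model matrix [1, x, x^2, pairwise x_i x_j] for 3 factors."""
    if isinstance(points, np.ndarray):
        arr = np.asarray(points, dtype=float)
    else:
        arr = np.array([p.as_tuple() for p in points], dtype=float)
    gm, cc, ae = arr[:, 0], arr[:, 1], arr[:, 2]
    cols = np.column_stack(
        [np.ones(len(arr)), gm, cc, ae, gm**2, cc**2, ae**2, gm * cc, gm * ae, cc * ae]
    )
    return pd.DataFrame(cols, columns=list(TERM_NAMES))


@dataclass(frozen=True)
class EffectRanking:
    """Standardized effects |b|/SE(b) sorted descending, with the
    two-sided t critical value they are compared against."""

    effects: tuple[tuple[str, float], ...]
    threshold: float
    alpha: float
    residual_df: int

    def significant_terms(self) -> list[str]:
        return [name for name, eff in self.effects if eff > self.threshold]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.effects, columns=["term", "standardized_effect"])
        df["significant"] = df["standardized_effect"] > self.threshold
        return df


class ResponseSurfaceModel:
    """Full-quadratic response-surface model for a three-herb formulation.

    Parameters
    ----------
    endog : array-like
        Response values, one per run.
    points : sequence of FormulationPoint or (n, 3) array
        Herb masses (GM, CC, AE) in grams for each run.
    response_name : str
        Label used in summaries.

    Examples
    --------
    >>> from phytosynergy.datasets import load_response_table
    >>> table = load_response_table("ethanol", "yield")
    >>> res = ResponseSurfaceModel.from_response_table(table).fit()
    >>> round(res.params["Intercept"], 2)
    10.38
    """

    def __init__(self, endog, points, response_name: str = "response"):
        self.exog = quadratic_design_matrix(
            points if isinstance(points, np.ndarray) else list(points)
        )
        self.endog = np.asarray(endog, dtype=float)
        if self.endog.ndim != 1 or len(self.endog) != len(self.exog):
            raise ValueError("endog must be 1-D with one value per design point")
        if len(self.endog) < len(TERM_NAMES):
            raise ValueError(
                f"need >= {len(TERM_NAMES)} runs to fit the full quadratic, got {len(self.endog)}"
            )
        self.response_name = response_name

    @classmethod
    def from_response_table(cls, table: ResponseTable) -> "ResponseSurfaceModel":
        return cls(table.values(), table.points(), response_name=table.response_name)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        response: str,
        factors: tuple[str, str, str] = ("gm_g", "cc_g", "ae_g"),
    ) -> "ResponseSurfaceModel":
        pts = df.loc[:, list(factors)].to_numpy(dtype=float)
        return cls(df[response].to_numpy(dtype=float), pts, response_name=response)

    def fit(self) -> "ResponseSurfaceResults":
        rank = np.linalg.matrix_rank(self.exog.to_numpy())
        if rank < self.exog.shape[1]:
            raise ValueError(
                f"design matrix is rank-deficient (rank {rank} < {self.exog.shape[1]}); "
                "the design does not support a full quadratic"
            )
        res = sm.OLS(self.endog, self.exog).fit()
        return ResponseSurfaceResults(self, res)


class ResponseSurfaceResults:
    """Fitted full-quadratic surface: coefficients, diagnostics, prediction,
    standardized-effect ranking and constrained grid optimization."""

    def __init__(self, model: ResponseSurfaceModel, _sm_results):
        self.model = model
        self._res = _sm_results
        #: Coefficients in actual gram units, indexed by term name.
        self.params: pd.Series = _sm_results.params
        #: Coefficient standard errors.
        self.bse: pd.Series = _sm_results.bse
        self.residual_df: int = int(_sm_results.df_resid)
        # R^2 is undefined when the response has no variance
        if _sm_results.centered_tss == 0:
            self.rsquared = self.rsquared_adj = float("nan")
        else:
            self.rsquared = float(_sm_results.rsquared)
            self.rsquared_adj = float(_sm_results.rsquared_adj)
        self.resid: np.ndarray = np.asarray(_sm_results.resid)

    @property
    def rsquared_pct(self) -> float:
        """Coefficient of determination as a percentage, 100 * (1 - SSE/SST)."""
        return 100.0 * self.rsquared

    def predict(self, point) -> float:
        """Evaluate the fitted polynomial at one formulation (gram units)."""
        if isinstance(point, FormulationPoint):
            pts = [point]
        else:
            pts = [FormulationPoint(*point)]
        X = quadratic_design_matrix(pts)
        return float((X.to_numpy() @ self.params.to_numpy())[0])

    def predict_many(self, points) -> np.ndarray:
        X = quadratic_design_matrix(list(points))
        return X.to_numpy() @ self.params.to_numpy()

    def standardized_effects(self, alpha: float = 0.05) -> EffectRanking:
        """Pareto-chart ranking: |coefficient| / SE per non-intercept term.

        Effects are taken from the coded-unit (-1/0/+1) refit of the same
        model — the Pareto-chart convention, which puts all factors on a
        common scale so their t statistics are comparable.  The fitted
        values, residuals and R^2 are identical to the actual-unit fit;
        only the coefficient parameterization differs.  The significance
        reference is the two-sided t critical value at the residual
        degrees of freedom (2.571 for the 15-run design).
        """
        factors = self.model.exog[["GM", "CC", "AE"]].to_numpy()
        center = (factors.max(axis=0) + factors.min(axis=0)) / 2.0
        half_range = (factors.max(axis=0) - factors.min(axis=0)) / 2.0
        coded = (factors - center) / half_range
        X = quadratic_design_matrix(coded)
        res = sm.OLS(self.model.endog, X).fit()
        se = res.bse.drop("Intercept")
        if self.residual_df <= 0 or not np.isfinite(se).all() or (se == 0).any():
            raise ValueError(
                "standardized effects undefined: zero residual variance or no residual "
                "degrees of freedom; add replicate runs"
            )
        effects = (res.params.drop("Intercept").abs() / se).sort_values(ascending=False)
        threshold = float(stats.t.ppf(1 - alpha / 2, self.residual_df))
        return EffectRanking(
            effects=tuple(effects.items()),
            threshold=threshold,
            alpha=alpha,
            residual_df=self.residual_df,
        )

    def grid_optimum(
        self,
        levels=None,
        step: float = 0.5,
        total_mass: float | None = None,
        minimize: bool = False,
    ) -> tuple[FormulationPoint, float]:
        """Exhaustive grid search for the best predicted response.

        ``levels`` gives the candidate values per factor; by default a
        regular grid of spacing ``step`` grams across the fitted factor
        range is used.  ``total_mass`` restricts the grid to
        formulations of that exact total (e.g. 30 g).  Ties break
        lexicographically on (GM, CC, AE), so the result is
        deterministic.
        """
        if levels is None:
            arr = self.model.exog[["GM", "CC", "AE"]].to_numpy()
            lo, hi = arr.min(axis=0), arr.max(axis=0)
            axes = [np.arange(lo[i], hi[i] + step / 2, step) for i in range(3)]
        else:
            axes = [np.asarray(levels, dtype=float)] * 3
        candidates = [
            (gm, cc, ae)
            for gm in axes[0]
            for cc in axes[1]
            for ae in axes[2]
            if total_mass is None or abs(gm + cc + ae - total_mass) < 1e-9
        ]
        if not candidates:
            raise ValueError("constraint leaves no candidate grid points")
        preds = self.predict_many([FormulationPoint(*c) for c in candidates])
        sign = 1.0 if minimize else -1.0
        order = sorted(range(len(candidates)), key=lambda i: (sign * preds[i], candidates[i]))
        best = order[0]
        return FormulationPoint(*candidates[best]), float(preds[best])

    def surface_slice(
        self, fixed_factor: str, fixed_value: float, step: float = 0.5
    ) -> pd.DataFrame:
        """Rectangular prediction grid over the two free factors with one
        factor held fixed — plot-ready data for contour/surface rendering."""
        factors = ["GM", "CC", "AE"]
        if fixed_factor not in factors:
            raise ValueError(f"fixed_factor must be one of {factors}")
        free = [f for f in factors if f != fixed_factor]
        arr = self.model.exog[factors].to_numpy()
        rows = []
        for x in np.arange(arr[:, factors.index(free[0])].min(),
                           arr[:, factors.index(free[0])].max() + step / 2, step):
            for y in np.arange(arr[:, factors.index(free[1])].min(),
                               arr[:, factors.index(free[1])].max() + step / 2, step):
                coords = {fixed_factor: fixed_value, free[0]: x, free[1]: y}
                pred = self.predict((coords["GM"], coords["CC"], coords["AE"]))
                rows.append({free[0]: x, free[1]: y, "prediction": pred})
        return pd.DataFrame(rows, columns=[free[0], free[1], "prediction"])

    def coefficients_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coefficient": self.params, "se": self.bse, "t": self.params / self.bse}
        )

    def summary(self) -> str:
        lines = [
            f"Full-quadratic response surface: {self.model.response_name}",
            f"n runs = {len(self.model.endog)}, residual df = {self.residual_df}",
            f"R^2 = {self.rsquared_pct:.2f}%   adj R^2 = {100 * self.rsquared_adj:.2f}%",
            "",
            f"{'term':<10}{'coef':>12}{'se':>12}{'t':>10}",
        ]
        for name in TERM_NAMES:
            b, se = self.params[name], self.bse[name]
            lines.append(f"{name:<10}{b:>12.4f}{se:>12.4f}{b / se:>10.2f}")
        return "\n".join(lines)
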