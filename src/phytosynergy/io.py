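"""Domain types and CSV readers/writers shared by all analysis stages.

The package works on small tabular inputs: formulation design runs
(herb masses in grams plus measured extraction responses), assay
inhibition records, and dose-response observations.  All files are
plain comma-separated UTF-8 with a header row and ``.`` decimals;
blank optional cells are read as missing, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "FormulationPoint",
    "FormulationRun",
    "ResponseTable",
    "InhibitionRecord",
    "SchemaError",
    "read_response_table",
    "write_response_table",
    "SOLVENTS",
    "RESPONSES",
    "HERBS",
]

#: Solvents used in the extraction experiment.
SOLVENTS = ("ethanol", "water")

#: Measured extraction responses: percent yield, total phenolic content
#: (mg gallic-acid equivalents per g extract), total flavonoid content
#: (mg quercetin equivalents per g extract).
RESPONSES = ("yield", "phenolic", "flavonoid")

#: Factor order used throughout: Garcinia mangostana (GM),
#: Curcuma comosa (CC), Acanthus ebracteatus (AE).
HERBS = ("GM", "CC", "AE")

#: Mass columns expected in every formulation CSV.
MASS_COLUMNS = ("gm_g", "cc_g", "ae_g")


class SchemaError(ValueError):
    """A CSV file does not match the documented column schema."""


@dataclass(frozen=True)
class FormulationPoint:
    """Herb masses (grams) of one three-herb formulation.

    Single-herb preparations are encoded with the other two masses at
    zero, so a 30 g Garcinia-only sample is ``FormulationPoint(30, 0, 0)``.
    """

    gm_g: float
    cc_g: float
    ae_g: float

    def __post_init__(self) -> None:
        for name in ("gm_g", "cc_g", "ae_g"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative mass, got {v!r}")

    @property
    def total_g(self) -> float:
        return self.gm_g + self.cc_g + self.ae_g

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.gm_g, self.cc_g, self.ae_g)

    def mass_fractions(self) -> tuple[float, float, float]:
        t = self.total_g
        if t <= 0:
            raise ValueError("cannot take mass fractions of an all-zero formulation")
        return (self.gm_g / t, self.cc_g / t, self.ae_g / t)

    def __str__(self) -> str:
        def fmt(v: float) -> str:
            return f"{v:g}"

        return f"{fmt(self.gm_g)}:{fmt(self.cc_g)}:{fmt(self.ae_g)}"


@dataclass(frozen=True)
class FormulationRun:
    """One design run: a formulation plus its measured responses.

    Responses not measured in a given table are ``None``.  Physical
    range checks can be switched off with ``validate=False`` for
    synthetic data, whose unbounded noise may stray outside them.
    """

    point: FormulationPoint
    solvent: str
    yield_pct: float | None = None
    phenolic_gae: float | None = None
    flavonoid_qe: float | None = None
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.solvent not in SOLVENTS:
            raise ValueError(f"solvent must be one of {SOLVENTS}, got {self.solvent!r}")
        if not self.validate:
            return
        if self.yield_pct is not None and not 0 <= self.yield_pct <= 100:
            raise ValueError(f"yield_pct outside [0, 100]: {self.yield_pct}")
        for name in ("phenolic_gae", "flavonoid_qe"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    def response(self, name: str) -> float | None:
        attr = {"yield": "yield_pct", "phenolic": "phenolic_gae", "flavonoid": "flavonoid_qe"}
        if name not in attr:
            raise ValueError(f"unknown response {name!r}; expected one of {RESPONSES}")
        return getattr(self, attr[name])


@dataclass(frozen=True)
class ResponseTable:
    """An ordered collection of runs carrying one response of interest.

    This is the unit the response-surface fitter consumes: the herb
    masses are the predictors and ``values()`` is the regression target.
    """

    runs: tuple[FormulationRun, ...]
    response_name: str
    solvent: str

    def __post_init__(self) -> None:
        if self.response_name not in RESPONSES:
            raise ValueError(f"response_name must be one of {RESPONSES}")
        if self.solvent not in SOLVENTS:
            raise ValueError(f"solvent must be one of {SOLVENTS}")

    def __len__(self) -> int:
        return len(self.runs)

    def points(self) -> list[FormulationPoint]:
        return [r.point for r in self.runs]

    def values(self) -> list[float]:
        out = []
        for i, r in enumerate(self.runs):
            v = r.response(self.response_name)
            if v is None:
                raise ValueError(f"run {i} is missing response {self.response_name!r}")
            out.append(v)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gm_g": r.point.gm_g,
                "cc_g": r.point.cc_g,
                "ae_g": r.point.ae_g,
                self.response_name: r.response(self.response_name),
            }
            for r in self.runs
        ]
        return pd.DataFrame(rows, columns=["gm_g", "cc_g", "ae_g", self.response_name])


@dataclass(frozen=True)
class InhibitionRecord:
    """One inhibition measurement: formulation, assay, concentration, percent."""

    point: FormulationPoint
    assay: str
    concentration: float
    inhibition_pct: float
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.assay not in ("DPPH", "ABTS", "NO"):
            raise ValueError(f"assay must be DPPH, ABTS or NO, got {self.assay!r}")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not -5 < self.inhibition_pct <= 100:
            raise ValueError(f"inhibition_pct outside (-5, 100]: {self.inhibition_pct}")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def _cell(df: pd.DataFrame, row: int, col: str, path: Path) -> float:
    raw = df.at[row, col]
    try:
        v = float(raw)
    except (TypeError, ValueError):
        raise ValueError(f"{path}: non-numeric value {raw!r} in column {col!r}, row {row + 2}") from None
    if math.isnan(v):
        raise ValueError(f"{path}: blank value in required column {col!r}, row {row + 2}")
    return v


def read_response_table(path: str | Path, solvent: str, response: str) -> ResponseTable:
    """Read a formulation-design CSV and select one (solvent, response) column.

    The file must carry the mass columns ``gm_g, cc_g, ae_g`` and, for
    the requested selection, a column named ``<response>_<solvent>``
    (e.g. ``yield_ethanol``).  Rows are returned in file order.
    """
    path = Path(path)
    if solvent not in SOLVENTS:
        raise ValueError(f"solvent must be one of {SOLVENTS}, got {solvent!r}")
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {RESPONSES}, got {response!r}")
    df = pd.read_csv(path)
    col = f"{response}_{solvent}"
    _require_columns(df, (*MASS_COLUMNS, col), path)

    attr = {"yield": "yield_pct", "phenolic": "phenolic_gae", "flavonoid": "flavonoid_qe"}
    runs = []
    for i in range(len(df)):
        point = FormulationPoint(
            _cell(df, i, "gm_g", path), _cell(df, i, "cc_g", path), _cell(df, i, "ae_g", path)
        )
        runs.append(
            FormulationRun(point=point, solvent=solvent, **{attr[response]: _cell(df, i, col, path)})
        )
    return ResponseTable(runs=tuple(runs), response_name=response, solvent=solvent)


def write_response_table(table: ResponseTable, path: str | Path) -> None:
    """Write a response table as a CSV readable by :func:`read_response_table`.

    Missing values are written as empty cells, never as the text "nan".
    """
    path = Path(path)
    col = f"{table.response_name}_{table.solvent}"
    rows = [
        {
            "gm_g": r.point.gm_g,
            "cc_g": r.point.cc_g,
            "ae_g": r.point.ae_g,
            col: r.response(table.response_name),
        }
        for r in table.runs
    ]
    df = pd.DataFrame(rows, columns=["gm_g", "cc_g", "ae_g", col])
    df.to_csv(path, index=False, na_rep="")
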