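"""Packaged study datasets for the three-herb formulation experiment.

The bundled tables transcribe the published measurements for a
formulation of *Garcinia mangostana* (GM), *Curcuma comosa* (CC) and
*Acanthus ebracteatus* (AE), dosed at a fixed total mass of 30 g:

* ``table1`` — 15-run Box-Behnken extraction design (levels 5/10/15 g
  with three replicated 10:10:10 center runs) with percent yield,
  phenolic (mg GAE/g) and flavonoid (mg QE/g) responses for ethanol
  and water extraction.
* ``table2`` — DPPH and ABTS radical-scavenging percent inhibition at
  250 ug/mL for seven combinations and the three single herbs, with
  the published fractional percentage inhibitory index (FPI).
* ``table3`` — percent inhibition of nitric-oxide production (Griess
  assay, LPS-stimulated RAW 264.7 macrophages) at 100 ug/mL.
* ``table4`` — NO-inhibition at 10/20/50 ug/mL (ethanol extracts) with
  the published anti-inflammatory IC50 per formulation.
* ``cytotoxicity IC20`` — published IC20 values on L929 fibroblasts
  (dose at which cell viability falls to 80%); the underlying
  viability curves were not published, so these are stored as
  constants rather than re-derived.

Every file is integrity-checked against a SHA-256 digest at load time;
single-herb rows encode the unused herbs as zero mass, and blank
standard-deviation or FPI cells load as missing values, not zeros.
One transcription quirk is preserved verbatim: the ABTS inhibition of
the 5:15:10 combination is printed with three decimals (90.511) where
every other entry has two; it may be a typo for 90.51 but is not
corrected here.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .io import FormulationPoint, ResponseTable, read_response_table

__all__ = [
    "FixtureBundle",
    "load_fixtures",
    "load_response_table",
    "FixtureIntegrityError",
    "VIABILITY_THRESHOLD_PCT",
    "ANTIOXIDANT_IC50_10_15_5",
]

#: Cell-viability level (percent) below which an extract is considered
#: cytotoxic; the dose where viability crosses it is the IC20.
VIABILITY_THRESHOLD_PCT = 80.0

#: Published antioxidant IC50s (ug/mL) of the 10:15:5 combination for
#: the DPPH and ABTS assays.  The dose-response data behind them were
#: not published, so they are reference constants only.
ANTIOXIDANT_IC50_10_15_5 = {"DPPH": 82.97, "ABTS": 23.94}

_FILES = {
    "table1": "table1_bbd_extraction.csv",
    "table2": "table2_antioxidant.csv",
    "table3": "table3_no_inhibition.csv",
    "table4": "table4_anti_inflammatory_doses.csv",
    "ic20": "cytotoxicity_ic20.csv",
}

_DIGESTS = {
    "table1": "1a1d7992a2d34701574a8127f1cafa57e8c28eb81375d9d7b38a83c79583a208",
    "table2": "76e131ba133151caa3ab7d62b9aebce519226384095073363bdba4fdbb91265f",
    "table3": "5f8fea4d1a06198eadb0a432c8cc6a1a0fba216dc94a99deb5a5dd6c5bf8b2a8",
    "table4": "51c2adca5c267b0b8b7f93000093020c39541ac6f2b2a7d7c847e9046ad3d02f",
    "ic20": "5ba7e82dcab1ffc487eacec0ab14f43e55717168e2b3c9dc57a7907f2297da0e",
}


class FixtureIntegrityError(RuntimeError):
    """A packaged data file does not match its recorded digest."""


def _data_path(key: str) -> Path:
    return Path(str(resources.files("phytosynergy").joinpath("data", _FILES[key])))


def _verify(key: str, path: Path) -> None:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _DIGESTS[key]:
        raise FixtureIntegrityError(
            f"packaged dataset {path.name} is corrupted: sha256 {digest} != {_DIGESTS[key]}"
        )


@dataclass(frozen=True)
class FixtureBundle:
    """The packaged study tables as pandas DataFrames."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    ic20: pd.DataFrame
    viability_threshold_pct: float = VIABILITY_THRESHOLD_PCT

    def ic20_for(self, point: FormulationPoint) -> float:
        """Cytotoxic IC20 (ug/mL) on L929 fibroblasts for a formulation."""
        df = self.ic20
        hit = df[
            (df["gm_g"] == point.gm_g) & (df["cc_g"] == point.cc_g) & (df["ae_g"] == point.ae_g)
        ]
        if hit.empty:
            raise KeyError(f"no published IC20 for formulation {point}")
        return float(hit["ic20_ug_ml"].iloc[0])

    def ic50_for(self, point: FormulationPoint) -> float:
        """Published anti-inflammatory IC50 (ug/mL, RAW 264.7) for a formulation."""
        df = self.table4
        hit = df[
            (df["gm_g"] == point.gm_g) & (df["cc_g"] == point.cc_g) & (df["ae_g"] == point.ae_g)
        ]
        if hit.empty:
            raise KeyError(f"no published IC50 for formulation {point}")
        return float(hit["ic50"].iloc[0])


def load_fixtures() -> FixtureBundle:
    """Load all packaged tables, verifying each file's SHA-256 digest."""
    frames = {}
    for key in _FILES:
        path = _data_path(key)
        _verify(key, path)
        frames[key] = pd.read_csv(path)
    return FixtureBundle(
        table1=frames["table1"],
        table2=frames["table2"],
        table3=frames["table3"],
        table4=frames["table4"],
        ic20=frames["ic20"],
    )


def load_response_table(solvent: str, response: str) -> ResponseTable:
    """Load one (solvent, response) column of the Box-Behnken design table."""
    path = _data_path("table1")
    _verify("table1", path)
    return read_response_table(path, solvent=solvent, response=response)
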