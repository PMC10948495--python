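"""Downstream arithmetic of the HPLC organic-acid analysis.

Chromatographic peak areas are taken as given (no signal processing);
this module implements what is computed from them: percent peak area over
a record set, single-point calibration quantification against the
1.25 mg/ml standards, and mg/ml → mM conversion with a bundled
molecular-weight table for the TCA-cycle acids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

#: Concentration of the single-point calibration standards, mg/ml.
CALIBRATION_CONC_MGML = 1.25


@dataclass(frozen=True)
class CompoundInfo:
    """A compound and its molecular weight (g/mol)."""

    name: str
    molecular_weight: float
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.molecular_weight > 0:
            raise InvalidParameterError("molecular weight must be > 0")


#: Molecular weights of the assayed TCA-cycle acids, g/mol.  Supernatant
#: conversions use the anhydrous acids; the monohydrate entry is the form
#: used to prepare the citric-acid gradient solution.
COMPOUNDS: dict[str, CompoundInfo] = {
    c.name: c
    for c in (
        CompoundInfo("oxaloacetic acid", 132.07),
        CompoundInfo("citric acid", 192.12, "anhydrous"),
        CompoundInfo("citric acid monohydrate", 210.14),
        CompoundInfo("malic acid", 134.09),
        CompoundInfo("succinic acid", 118.09),
        CompoundInfo("fumaric acid", 116.07),
    )
}


@dataclass(frozen=True)
class PeakRecord:
    """One integrated chromatogram peak."""

    compound: str
    retention_min: float
    area: float
    conc_mgml: float | None = None  # known concentration, if a standard

    def __post_init__(self) -> None:
        if self.area < 0:
            raise InvalidParameterError("peak area must be >= 0")
        if not self.retention_min > 0:
            raise InvalidParameterError("retention time must be > 0")


def percent_area(records: list[PeakRecord]) -> list[float]:
    """Percent of total area per record, over the supplied record set.

    Values are reported to 2 decimals and computed over exactly the
    records given (the denominator is the caller's responsibility).
    """
    if not records:
        raise InvalidParameterError("need at least one peak record")
    areas = np.array([r.area for r in records], dtype=float)
    total = areas.sum()
    if total <= 0:
        raise InvalidParameterError("total peak area must be positive")
    return [round(float(v), 2) for v in 100.0 * areas / total]


def single_point_concentration(
    sample_area: float,
    calibration_area: float,
    calibration_conc: float = CALIBRATION_CONC_MGML,
) -> float:
    """Linear-through-origin single-point quantification, mg/ml.

    c_sample = c_standard · area_sample / area_standard.
    """
    if not calibration_area > 0:
        raise InvalidParameterError("calibration area must be > 0")
    if sample_area < 0:
        raise InvalidParameterError("sample area must be >= 0")
    return calibration_conc * sample_area / calibration_area


def mgml_to_millimolar(conc_mgml: float, compound: CompoundInfo | str) -> float:
    """Convert mg/ml to mM: 1000·c/MW.  Full precision; round for reports."""
    if conc_mgml < 0:
        raise InvalidParameterError("concentration must be >= 0")
    if isinstance(compound, str):
        try:
            compound = COMPOUNDS[compound]
        except KeyError:
            raise InvalidParameterError(
                f"unknown compound {compound!r}; known: {sorted(COMPOUNDS)}"
            ) from None
    return 1000.0 * conc_mgml / compound.molecular_weight


def report_millimolar(conc_mgml: float, compound: CompoundInfo | str) -> float:
    """mg/ml → mM rounded to 1 decimal, as printed in reports."""
    return round(mgml_to_millimolar(conc_mgml, compound), 1)


def read_peak_table(path: str | Path) -> list[PeakRecord]:
    """Read a CSV peak table (compound, retention_min, area[, conc_mgml])."""
    df = pd.read_csv(path)
    required = {"compound", "retention_min", "area"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"peak table missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        conc = getattr(row, "conc_mgml", None)
        if conc is not None and pd.isna(conc):
            conc = None
        records.append(
            PeakRecord(
                compound=str(row.compound),
                retention_min=float(row.retention_min),
                area=float(row.area),
                conc_mgml=None if conc is None else float(conc),
            )
        )
    return records


def augment_peak_table(
    records: list[PeakRecord],
    calibration_areas: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Tabulate records with % area and, where possible, mg/ml and mM.

    ``calibration_areas`` maps compound name → standard peak area; when
    given, sample concentrations are quantified by single-point
    calibration and converted to mM via the bundled molecular weights.
    """
    pct = percent_area(records)
    rows = []
    for rec, p in zip(records, pct):
        mgml = rec.conc_mgml
        if mgml is None and calibration_areas and rec.compound in calibration_areas:
            mgml = single_point_concentration(
                rec.area, calibration_areas[rec.compound]
            )
        mm = None
        if mgml is not None and rec.compound in COMPOUNDS:
            mm = report_millimolar(mgml, rec.compound)
        rows.append(
            {
                "compound": rec.compound,
                "retention_min": rec.retention_min,
                "area": rec.area,
                "pct_area": p,
                "conc_mgml": mgml,
                "conc_mM": mm,
            }
        )
    return pd.DataFrame(rows)
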