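"""Colorimetric assay conversions: raw readings to digested-percent values.

Starch digestion is quantified by DNS reducing-sugar colorimetry (maltose
equivalents, 540 nm); multiplying maltose by 0.95 converts disaccharide mass
to anhydroglucose starch mass.  Protein digestion is quantified by OPA
colorimetry of free alpha-amino groups (L-serine equivalents, 340 nm) on
three fractions: the TCA-soluble supernatant (readily bioaccessible), the
fully acid-hydrolysed supernatant (digested soluble) and the undigested
sample (total), all relative to the pre-intestinal baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "CalibrationCurve",
    "CalibrationError",
    "ProteinAssayReadings",
    "StarchAssayReading",
    "fit_linear_calibration",
    "digested_starch_percent",
    "digested_soluble_protein_percent",
    "readily_bioaccessible_protein_percent",
    "quantify_plate",
]

#: disaccharide -> anhydroglucose (starch) mass conversion for maltose
MALTOSE_TO_STARCH = 0.95


class CalibrationError(ValueError):
    """Raised for degenerate or under-determined standard curves."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear absorbance -> concentration map fitted to standards.

    ``concentration = slope * absorbance + intercept``; ``valid_range`` is the
    concentration span of the standards.  Absorbances mapping outside it are
    extrapolated with a warning (single-reactor sampling leaves no re-dilution
    path).
    """

    analyte: Literal["maltose", "L-serine"]
    slope: float
    intercept: float
    valid_range: tuple[float, float]
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and self.slope > 0):
            raise CalibrationError(f"slope must be finite and > 0, got {self.slope!r}")
        lo, hi = self.valid_range
        if not lo < hi:
            raise CalibrationError(f"valid_range must satisfy low < high, got {self.valid_range!r}")

    def concentration(self, absorbance):
        """Map absorbance(s) to concentration, warning on extrapolation."""
        conc = self.slope * np.asarray(absorbance, dtype=float) + self.intercept
        lo, hi = self.valid_range
        if np.any((conc < lo) | (conc > hi)):
            warnings.warn(
                f"{self.analyte} reading outside calibration range "
                f"[{lo}, {hi}]; extrapolating",
                stacklevel=2,
            )
        return conc if np.ndim(absorbance) else float(conc)


@dataclass(frozen=True)
class ProteinAssayReadings:
    """Free alpha-amino group contents (L-serine equivalents, common basis)."""

    nh2_initial: float
    nh2_total: float
    nh2_hydrolyzed: float = float("nan")
    nh2_tca: float = float("nan")

    def __post_init__(self) -> None:
        # Ordering violations are measurement noise, not fatal: flag only.
        expected = (
            self.nh2_initial >= 0
            and self.nh2_total >= self.nh2_initial
            and (np.isnan(self.nh2_hydrolyzed) or self.nh2_hydrolyzed >= self.nh2_initial)
            and (np.isnan(self.nh2_tca) or self.nh2_tca >= self.nh2_initial)
        )
        if not expected:
            warnings.warn(
                "NH2 readings violate expected ordering "
                "(total >= hydrolyzed/TCA >= initial >= 0)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class StarchAssayReading:
    """Maltose equivalents and total starch on the same mass basis."""

    maltose_equivalents: float
    total_starch: float

    def __post_init__(self) -> None:
        if self.maltose_equivalents < 0:
            raise ValueError("maltose_equivalents must be >= 0")
        if not self.total_starch > 0:
            raise ZeroDivisionError("total_starch must be > 0")


def fit_linear_calibration(
    standards: Sequence[tuple[float, float]],
    analyte: Literal["maltose", "L-serine"] = "maltose",
) -> CalibrationCurve:
    """Ordinary least-squares standard curve from (concentration, absorbance) pairs.

    The fitted line maps absorbance to concentration with a free intercept
    (blanks are subtracted upstream but a zero intercept is not imposed).
    Requires at least 3 standards with non-degenerate absorbances.
    """
    if len(standards) < 3:
        raise CalibrationError(f"need >= 3 standards, got {len(standards)}")
    conc = np.asarray([s[0] for s in standards], dtype=float)
    absb = np.asarray([s[1] for s in standards], dtype=float)
    if np.ptp(absb) == 0:
        raise CalibrationError("standards have zero absorbance variance")
    slope, intercept = np.polyfit(absb, conc, 1)
    pred = slope * absb + intercept
    ss_res = float(np.sum((conc - pred) ** 2))
    ss_tot = float(np.sum((conc - conc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return CalibrationCurve(
        analyte=analyte,
        slope=float(slope),
        intercept=float(intercept),
        valid_range=(float(conc.min()), float(conc.max())),
        r_squared=r2,
    )


def digested_starch_percent(r: StarchAssayReading) -> float:
    """Digested starch (%): maltose equivalents x 0.95 over total starch x 100."""
    return r.maltose_equivalents * MALTOSE_TO_STARCH / r.total_starch * 100.0


def _protein_percent(numerator_reading: float, r: ProteinAssayReadings) -> float:
    if r.nh2_total <= 0:
        raise ZeroDivisionError("nh2_total must be > 0")
    value = (numerator_reading - r.nh2_initial) / r.nh2_total * 100.0
    if value < 0:
        warnings.warn(
            "negative digested-protein percentage (reading below the "
            "pre-digestion baseline); returning as-is",
            stacklevel=3,
        )
    return value


def digested_soluble_protein_percent(r: ProteinAssayReadings) -> float:
    """Digested soluble protein (%): (NH2 hydrolysed - NH2 initial) / NH2 total x 100."""
    return _protein_percent(r.nh2_hydrolyzed, r)


def readily_bioaccessible_protein_percent(r: ProteinAssayReadings) -> float:
    """Readily bioaccessible protein (%): (NH2 TCA - NH2 initial) / NH2 total x 100."""
    return _protein_percent(r.nh2_tca, r)


_ANALYTE_BY_ASSAY = {
    "DNS": "starch",
    "OPA_TCA": "bioaccessible_protein",
    "OPA_HYD": "soluble_protein",
}


def quantify_plate(plate, calibration: CalibrationCurve, totals: dict[str, float]):
    """Convert plate absorbance rows into a digested-% time course.

    ``plate`` is a DataFrame with columns ``sample_id, time_min, assay,
    absorbance, dilution_factor`` (optionally ``replicate``) holding a single
    assay type.  ``totals`` supplies ``total_starch`` for DNS plates, or
    ``nh2_total`` and ``nh2_initial`` for OPA plates, on the plate's common
    basis.  Returns a :class:`~pulsedigest.kinetics.DigestionTimeCourse`.
    """
    import pandas as pd

    from .kinetics import DigestionTimeCourse

    plate = pd.DataFrame(plate)
    assays = plate["assay"].unique()
    if len(assays) != 1:
        raise ValueError(f"plate must hold a single assay type, got {list(assays)}")
    assay_name = assays[0]
    if assay_name not in _ANALYTE_BY_ASSAY:
        raise ValueError(f"unknown assay {assay_name!r}; expected {sorted(_ANALYTE_BY_ASSAY)}")
    analyte = _ANALYTE_BY_ASSAY[assay_name]

    conc = (
        np.asarray(calibration.concentration(plate["absorbance"].to_numpy()))
        * plate["dilution_factor"].to_numpy(dtype=float)
    )
    values = []
    for c in conc:
        if analyte == "starch":
            values.append(
                digested_starch_percent(
                    StarchAssayReading(maltose_equivalents=float(c),
                                       total_starch=totals["total_starch"])
                )
            )
        else:
            readings = ProteinAssayReadings(
                nh2_initial=totals["nh2_initial"],
                nh2_total=totals["nh2_total"],
                nh2_hydrolyzed=float(c),
                nh2_tca=float(c),
            )
            fn = (
                readily_bioaccessible_protein_percent
                if analyte == "bioaccessible_protein"
                else digested_soluble_protein_percent
            )
            values.append(fn(readings))

    obs = pd.DataFrame(
        {
            "time_min": plate["time_min"].to_numpy(dtype=float),
            "value": values,
            "replicate": plate.get("replicate", pd.Series(0, index=plate.index)),
        }
    )
    label = str(plate["sample_id"].iloc[0]) if len(plate) else ""
    return DigestionTimeCourse(analyte=analyte, observations=obs, label=label)
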