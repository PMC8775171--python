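"""Proximate-composition bookkeeping and derived structural ratios.

Pulse (dry legume seed) samples are characterised by their macronutrient
contents per 100 g: starch, protein, lipid, ash and moisture.  The remainder
after subtracting these five components is the fiber-rich residue (FRR), a
proxy for cell-wall material.  Two derived ratios summarise how densely the
intracellular starch is packed in protein (starch/protein) and how much
cell-wall material accompanies it (starch/FRR); the seed-coat/cotyledon mass
ratio characterises the whole seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import pandas as pd

__all__ = [
    "ProximateComposition",
    "InvalidCompositionError",
    "compute_frr",
    "macronutrient_ratios",
    "seedcoat_cotyledon_ratio",
    "read_composition_csv",
]


class InvalidCompositionError(ValueError):
    """Raised when macronutrient components are negative or sum above 100 g/100 g."""


@dataclass(frozen=True)
class ProximateComposition:
    """Macronutrient contents of one sample, in g per 100 g.

    Parameters
    ----------
    starch, protein, lipid, ash, moisture : float
        Component contents, g/100 g, each >= 0.
    basis : {"as-is", "dry-matter"}
        Reporting basis.  Carried as metadata only; no automatic conversion
        between bases is performed.
    label : str
        Free-text sample label.
    """

    starch: float
    protein: float
    lipid: float
    ash: float
    moisture: float
    basis: Literal["as-is", "dry-matter"] = "as-is"
    label: str = ""

    def __post_init__(self) -> None:
        comps = {
            "starch": self.starch,
            "protein": self.protein,
            "lipid": self.lipid,
            "ash": self.ash,
            "moisture": self.moisture,
        }
        for name, value in comps.items():
            if not value >= 0:
                raise InvalidCompositionError(
                    f"{name} must be >= 0 g/100 g, got {value!r}"
                )
        total = sum(comps.values())
        if total > 100 + 1e-9:
            raise InvalidCompositionError(
                f"components sum to {total:.4f} g/100 g > 100 (label={self.label!r})"
            )
        if self.basis not in ("as-is", "dry-matter"):
            raise InvalidCompositionError(f"unknown basis {self.basis!r}")


def compute_frr(c: ProximateComposition) -> float:
    """Fiber-rich residue, g/100 g: the composition remainder.

    FRR = 100 - (moisture + protein + starch + lipid + ash).  Non-negative by
    the composition invariant; FRR plus the five components is exactly 100.
    """
    return 100.0 - (c.moisture + c.protein + c.starch + c.lipid + c.ash)


def macronutrient_ratios(
    c: ProximateComposition, frr: float | None = None
) -> dict[str, float]:
    """Starch/protein and starch/FRR ratios for one sample.

    ``frr`` defaults to :func:`compute_frr`; pass an externally tabulated
    value to override.  Full precision is returned; round to 2 decimals for
    reporting.
    """
    if c.protein <= 0:
        raise ZeroDivisionError("protein content is zero; starch/protein undefined")
    if frr is None:
        frr = compute_frr(c)
    if frr <= 0:
        raise ZeroDivisionError("fiber-rich residue is zero; starch/FRR undefined")
    return {"starch_protein": c.starch / c.protein, "starch_frr": c.starch / frr}


def seedcoat_cotyledon_ratio(seedcoat_fraction: float) -> float:
    """Seed-coat to cotyledon mass ratio w/(1-w) from the seed-coat fraction w.

    ``seedcoat_fraction`` is the seed coat's share of whole-seed dry mass,
    strictly inside (0, 1).
    """
    if not 0.0 < seedcoat_fraction < 1.0:
        raise ValueError(
            f"seedcoat_fraction must lie in (0, 1), got {seedcoat_fraction!r}"
        )
    return seedcoat_fraction / (1.0 - seedcoat_fraction)


_COLUMNS = ["label", "starch", "protein", "lipid", "ash", "moisture", "basis"]


def read_composition_csv(path) -> list[ProximateComposition]:
    """Read one composition per row from CSV with columns
    label, starch, protein, lipid, ash, moisture, basis."""
    df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidCompositionError(f"composition CSV missing columns: {sorted(missing)}")
    return [
        ProximateComposition(
            starch=float(row.starch),
            protein=float(row.protein),
            lipid=float(row.lipid),
            ash=float(row.ash),
            moisture=float(row.moisture),
            basis=str(row.basis),
            label=str(row.label),
        )
        for row in df.itertuples(index=False)
    ]
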