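"""Texture softening kinetics and hardness-based process alignment.

Whole pulse seeds soften during hydrothermal cooking following fractional
conversion kinetics: compression hardness decays from its raw value ``Ci``
(N) towards a residual plateau ``Cf`` (N) at rate ``k`` (min^-1).  Cooking
different pulses to the common hardness plateau ("hardness alignment")
standardises their microstructure before digestion experiments; the
alignment time is the earliest cook time whose predicted hardness is within
a tolerance of the plateau.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import DigestionTimeCourse, KineticFit, fit_kinetic_model

__all__ = [
    "HardnessProfile",
    "PLATEAU_TOLERANCE_N",
    "fit_hardness_profile",
    "hardness_reduction_percent",
    "plateau_alignment_time",
    "read_hardness_csv",
]

#: default plateau tolerance (N), the spread of the residual-hardness band
PLATEAU_TOLERANCE_N = 3.0


@dataclass
class HardnessProfile:
    """Per-seed maximum compression forces across cook times.

    ``measurements`` has columns ``cook_time_min``, ``seed_index``,
    ``force_N`` — nominally 25 seeds per cook time.  Individual seeds (not
    per-time means) enter the kinetic fit so plateau scatter propagates
    honestly into the parameter uncertainties.
    """

    measurements: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.measurements)
        required = {"cook_time_min", "seed_index", "force_N"}
        if not required <= set(df.columns):
            raise ValueError(f"hardness table needs columns {sorted(required)}")
        if not (df["force_N"] > 0).all():
            raise ValueError("forces must be > 0 N")
        if df["cook_time_min"].nunique() < 4:
            raise ValueError("need >= 4 distinct cook times")
        self.measurements = df.reset_index(drop=True)

    @property
    def sampling_interval(self) -> float:
        """Smallest positive spacing between distinct cook times (min)."""
        times = np.sort(self.measurements["cook_time_min"].unique())
        return float(np.diff(times).min())

    def as_timecourse(self) -> DigestionTimeCourse:
        df = self.measurements.rename(
            columns={"cook_time_min": "time_min", "force_N": "value",
                     "seed_index": "replicate"}
        )
        return DigestionTimeCourse(analyte="hardness", observations=df, label=self.label)


def fit_hardness_profile(
    h: HardnessProfile, n_starts: int = 10, random_state: int | None = 0
) -> KineticFit:
    """Fractional conversion fit to per-seed hardness observations.

    ``Ci`` is the raw-seed hardness, ``Cf`` the residual (plateau) hardness
    and ``k`` the softening rate; all three are estimated.
    """
    return fit_kinetic_model(
        h.as_timecourse(), model="fractional_conversion",
        n_starts=n_starts, random_state=random_state,
    )


def hardness_reduction_percent(fit: KineticFit) -> float:
    """Total softening (Ci - Cf)/Ci x 100 achieved at extended cooking."""
    ci, cf = fit.params["Ci"], fit.params["Cf"]
    if ci <= 0:
        raise ValueError("initial hardness Ci must be > 0")
    return (ci - cf) / ci * 100.0


def plateau_alignment_time(
    fit: KineticFit,
    tolerance: float = PLATEAU_TOLERANCE_N,
    sampling_interval: float | None = None,
) -> float:
    """Earliest cook time whose predicted hardness is within ``tolerance`` of
    the plateau: t = ln((Ci - Cf)/tolerance) / k.

    With ``sampling_interval`` set, the time is rounded up to the next
    multiple of it (cook times are chosen on a discrete schedule).  Returns 0
    with a warning when the tolerance already covers the whole decay.
    """
    ci, cf, k = fit.params["Ci"], fit.params["Cf"], fit.params["k"]
    if not tolerance > 0:
        raise ValueError("tolerance must be > 0 N")
    if cf >= ci:
        raise ValueError("fit does not describe softening (Cf >= Ci)")
    if tolerance >= ci - cf:
        warnings.warn("tolerance covers the full hardness decay; already at plateau")
        return 0.0
    t = math.log((ci - cf) / tolerance) / k
    if sampling_interval is not None:
        t = math.ceil(t / sampling_interval - 1e-12) * sampling_interval
    return t


def read_hardness_csv(path) -> list[HardnessProfile]:
    """Read per-seed hardness profiles from CSV with columns
    pulse, cook_time_min, seed_index, force_N (one profile per pulse)."""
    df = pd.read_csv(path)
    required = {"pulse", "cook_time_min", "seed_index", "force_N"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hardness CSV missing columns: {sorted(missing)}")
    return [
        HardnessProfile(measurements=group.drop(columns="pulse"), label=str(pulse))
        for pulse, group in df.groupby("pulse", sort=False)
    ]
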