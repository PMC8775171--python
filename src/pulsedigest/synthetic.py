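"""Synthetic measurement generators emulating the wet-lab inputs.

Every analysis stage consumes a measured input: digestion time courses
(single-reactor tubes sampled over 0–180 min of the small-intestinal
phase), colorimetric plate readings, per-seed compression forces and binned
volumetric particle-size distributions.  The generators here produce each
of those with the statistical structure of the real measurements —
additive Gaussian assay noise on digested-%, mean-proportional scatter of
25-seed hardness batches, multimodal log-normal particle populations — so
the whole pipeline is testable without laboratory data.  Each generator is
a measurable inverse of its analysis stage: at zero noise, analysing the
generated data recovers the preset truth exactly.

Presets named after the study pulses (CP chickpea, PE pea, BB black bean)
carry the hardness-aligned point estimates as true parameter values; where
a value is never reported (raw hardness, chickpea/pea softening rates, the
black-bean logistic maximum rate) a documented realistic default is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assay import CalibrationCurve, MALTOSE_TO_STARCH
from .composition import ProximateComposition
from .kinetics import (
    DigestionTimeCourse,
    eval_fractional_conversion,
    eval_logistic,
)
from .psd import ParticleSizeDistribution
from .texture import HardnessProfile

__all__ = [
    "KineticTruth",
    "PSDMode",
    "PulsePreset",
    "PRESETS",
    "get_preset",
    "DEFAULT_DIGESTION_TIMES",
    "DEFAULT_COOK_TIMES",
    "DEFAULT_NOISE_SD",
    "DEFAULT_HARDNESS_CV",
    "truth_curve",
    "generate_digestion_timecourse",
    "generate_assay_plate",
    "generate_hardness_measurements",
    "generate_psd",
    "default_bin_edges",
]

#: small-intestinal sampling grid (min): one independent tube per time
DEFAULT_DIGESTION_TIMES = (0.0, 5.0, 10.0, 15.0, 30.0, 60.0, 90.0, 120.0, 180.0)
#: cook-time schedule for hardness profiling (min)
DEFAULT_COOK_TIMES = (0.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0)
#: additive Gaussian noise on digested-% observations
DEFAULT_NOISE_SD = 2.0
#: coefficient of variation of per-seed hardness around the time mean
DEFAULT_HARDNESS_CV = 0.10


@dataclass(frozen=True)
class KineticTruth:
    """True model and parameters for one analyte of one preset."""

    model: str  # "fractional_conversion" | "logistic"
    params: dict[str, float]

    def curve(self, t):
        if self.model == "fractional_conversion":
            p = self.params
            return eval_fractional_conversion(t, p["Ci"], p["Cf"], p["k"])
        if self.model == "logistic":
            p = self.params
            return eval_logistic(t, p["Cf"], p["kmax"], p["lambda"])
        raise ValueError(f"unknown model {self.model!r}")


@dataclass(frozen=True)
class PSDMode:
    """One log-normal particle population: median (µm), geometric SD, volume share."""

    median_um: float
    gsd: float
    share: float


@dataclass(frozen=True)
class PulsePreset:
    """True parameter set for one pulse, hardness-aligned sample state."""

    name: str
    kinetics: dict[str, KineticTruth]
    composition: ProximateComposition
    seedcoat_fraction: float
    psd_modes: dict[str, tuple[PSDMode, ...]]


def _fc(ci, cf, k):
    return KineticTruth("fractional_conversion", {"Ci": ci, "Cf": cf, "k": k})


PRESETS: dict[str, PulsePreset] = {
    # Chickpea, cooked 30 min to the hardness plateau; ICC digestion truths.
    "CP": PulsePreset(
        name="CP",
        kinetics={
            "starch": _fc(0.0, 91.67, 0.018),
            "bioaccessible_protein": _fc(0.0, 36.84, 0.021),
            "soluble_protein": _fc(25.0, 88.73, 0.039),
            "hardness": _fc(140.0, 42.0, 0.095),
        },
        composition=ProximateComposition(
            starch=39.73, protein=19.39, lipid=7.29, ash=2.17, moisture=3.89,
            basis="as-is", label="CP raw",
        ),
        seedcoat_fraction=0.123,
        psd_modes={
            "ICC": (PSDMode(118.0, 1.13, 1.0),),
            "WSM": (
                PSDMode(30.0, 1.5, 0.25),
                PSDMode(118.0, 1.13, 0.55),
                PSDMode(300.0, 1.3, 0.20),
            ),
        },
    ),
    # Pea, cooked 30 min; the largest, elliptical cotyledon cells.
    "PE": PulsePreset(
        name="PE",
        kinetics={
            "starch": _fc(0.0, 88.75, 0.015),
            "bioaccessible_protein": _fc(0.0, 34.35, 0.027),
            "soluble_protein": _fc(37.0, 95.50, 0.031),
            "hardness": _fc(135.0, 42.0, 0.085),
        },
        composition=ProximateComposition(
            starch=40.90, protein=19.73, lipid=2.79, ash=1.87, moisture=7.43,
            basis="as-is", label="PE raw",
        ),
        seedcoat_fraction=0.131,
        psd_modes={
            "ICC": (PSDMode(124.84, 1.13, 1.0),),
            "WSM": (
                PSDMode(30.0, 1.5, 0.25),
                PSDMode(124.84, 1.13, 0.52),
                PSDMode(300.0, 1.3, 0.23),
            ),
        },
    ),
    # Black bean, cooked 60 min; slow softener, lag-phase starch digestion,
    # the smallest and most spherical cotyledon cells.
    "BB": PulsePreset(
        name="BB",
        kinetics={
            "starch": KineticTruth(
                "logistic", {"Cf": 100.0, "kmax": 1.3, "lambda": 11.0}
            ),
            "bioaccessible_protein": _fc(0.0, 36.68, 0.015),
            "soluble_protein": _fc(30.0, 94.22, 0.016),
            "hardness": _fc(145.0, 42.0, 0.046),
        },
        composition=ProximateComposition(
            starch=33.34, protein=20.64, lipid=2.45, ash=3.70, moisture=7.23,
            basis="as-is", label="BB raw",
        ),
        seedcoat_fraction=0.103,
        psd_modes={
            "ICC": (PSDMode(104.66, 1.08, 1.0),),
            "WSM": (
                PSDMode(30.0, 1.5, 0.20),
                PSDMode(104.66, 1.08, 0.57),
                PSDMode(300.0, 1.3, 0.23),
            ),
        },
    ),
}


def get_preset(preset: str | PulsePreset) -> PulsePreset:
    if isinstance(preset, PulsePreset):
        return preset
    try:
        return PRESETS[preset]
    except KeyError:
        raise KeyError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}") from None


def truth_curve(preset: str | PulsePreset, analyte: str, t):
    """Evaluate a preset's true kinetic curve for one analyte."""
    p = get_preset(preset)
    if analyte not in p.kinetics:
        raise KeyError(f"preset {p.name!r} has no analyte {analyte!r}")
    return p.kinetics[analyte].curve(t)


def generate_digestion_timecourse(
    preset: str | PulsePreset,
    analyte: str,
    seed: int,
    times: Sequence[float] = DEFAULT_DIGESTION_TIMES,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_replicates: int = 2,
) -> DigestionTimeCourse:
    """Simulate single-reactor digestion sampling with additive Gaussian noise.

    One independent tube per (time, replicate); replicates are duplicate
    assay measurements.  Reproducible under a fixed seed; with
    ``noise_sd = 0`` the values equal the true curve exactly.
    """
    p = get_preset(preset)
    times = np.asarray(times, dtype=float)
    if times.min() < 0 or times.max() > 180:
        raise ValueError("digestion times must lie within [0, 180] min")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    truth = np.asarray(truth_curve(p, analyte, times), dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        noise = rng.normal(0.0, noise_sd, size=times.shape) if noise_sd > 0 else 0.0
        rows.append(
            pd.DataFrame(
                {"time_min": times, "value": truth + noise, "replicate": rep}
            )
        )
    return DigestionTimeCourse(
        analyte=analyte,
        observations=pd.concat(rows, ignore_index=True),
        label=f"{p.name} {analyte} synthetic",
    )


_ASSAY_BY_ANALYTE = {
    "starch": "DNS",
    "bioaccessible_protein": "OPA_TCA",
    "soluble_protein": "OPA_HYD",
}
_DILUTION_SERIES = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0)


def generate_assay_plate(
    tc: DigestionTimeCourse,
    calibration: CalibrationCurve,
    totals: dict[str, float],
    seed: int,
    absorbance_noise: float = 0.0,
    dilutions: Sequence[float] = _DILUTION_SERIES,
) -> pd.DataFrame:
    """Invert digested-% values into plate absorbance rows.

    Returns a table with columns ``sample_id, time_min, assay, absorbance,
    dilution_factor`` such that the assay conversions applied to it recover
    the time-course values (round-trip error <= 1e-9 at zero noise).  The
    smallest dilution placing the concentration inside the calibration range
    is chosen; a value not representable at any allowed dilution raises.

    ``totals`` supplies ``total_starch`` (starch) or ``nh2_total`` and
    ``nh2_initial`` (protein analytes), on the assay's common basis.
    """
    if tc.analyte not in _ASSAY_BY_ANALYTE:
        raise ValueError(f"no plate representation for analyte {tc.analyte!r}")
    assay_name = _ASSAY_BY_ANALYTE[tc.analyte]
    rng = np.random.default_rng(seed)
    lo, hi = calibration.valid_range
    rows = []
    for row in tc.observations.itertuples(index=False):
        if tc.analyte == "starch":
            conc = row.value / 100.0 * totals["total_starch"] / MALTOSE_TO_STARCH
        else:
            conc = row.value / 100.0 * totals["nh2_total"] + totals["nh2_initial"]
        # smallest dilution that brings the reading under the range ceiling;
        # readings below the floor stay at dilution 1 (near-blank wells)
        for dilution in dilutions:
            diluted = conc / dilution
            if diluted <= hi:
                break
        else:
            raise ValueError(
                f"concentration {conc:.4g} not representable in calibration range "
                f"[{lo}, {hi}] at dilutions {tuple(dilutions)}"
            )
        absorbance = (diluted - calibration.intercept) / calibration.slope
        if absorbance_noise > 0:
            absorbance += rng.normal(0.0, absorbance_noise)
        rows.append(
            {
                "sample_id": tc.label or tc.analyte,
                "time_min": row.time_min,
                "assay": assay_name,
                "absorbance": absorbance,
                "dilution_factor": dilution,
                "replicate": row.replicate,
            }
        )
    return pd.DataFrame(rows)


def generate_hardness_measurements(
    preset: str | PulsePreset,
    seed: int,
    cook_times: Sequence[float] = DEFAULT_COOK_TIMES,
    n_seeds: int = 25,
    cv: float = DEFAULT_HARDNESS_CV,
) -> HardnessProfile:
    """Simulate per-seed compression forces with mean-proportional scatter.

    Each seed's force is ``truth(t) * (1 + N(0, cv))`` truncated to stay
    positive, so the plateau's absolute scatter shrinks with the mean — the
    pattern seen in softening experiments.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    p = get_preset(preset)
    rng = np.random.default_rng(seed)
    rows = []
    for t in cook_times:
        mean = float(truth_curve(p, "hardness", t))
        scatter = rng.normal(0.0, cv, size=n_seeds) if cv > 0 else np.zeros(n_seeds)
        forces = np.maximum(mean * (1.0 + scatter), 1e-6)
        rows.append(
            pd.DataFrame(
                {
                    "cook_time_min": t,
                    "seed_index": np.arange(n_seeds),
                    "force_N": forces,
                }
            )
        )
    return HardnessProfile(
        measurements=pd.concat(rows, ignore_index=True),
        label=f"{p.name} hardness synthetic",
    )


def default_bin_edges(lo_um: float = 1.0, hi_um: float = 2000.0, n_bins: int = 120) -> np.ndarray:
    """Log-spaced size bin edges (µm) mimicking laser-diffraction binning."""
    return np.logspace(np.log10(lo_um), np.log10(hi_um), n_bins + 1)


def generate_psd(
    modes: Sequence[PSDMode],
    bin_edges: np.ndarray | None = None,
    label: str = "",
) -> ParticleSizeDistribution:
    """Deterministic multimodal log-normal volume distribution on bins.

    Each mode's analytic log-normal CDF mass is integrated over the bins and
    weighted by its volume share; the result is renormalised to sum to 100
    exactly (mass falling outside the binned range is redistributed
    proportionally).
    """
    shares = np.array([m.share for m in modes], dtype=float)
    if not np.isclose(shares.sum(), 1.0):
        raise ValueError(f"mode volume shares must sum to 1, got {shares.sum()}")
    edges = default_bin_edges() if bin_edges is None else np.asarray(bin_edges, dtype=float)
    log_edges = np.log(edges)
    volume = np.zeros(len(edges) - 1)
    for mode in modes:
        cdf = stats.norm.cdf(log_edges, loc=np.log(mode.median_um), scale=np.log(mode.gsd))
        volume += mode.share * np.diff(cdf)
    volume = volume / volume.sum() * 100.0
    return ParticleSizeDistribution(bin_edges=edges, volume_percent=volume, label=label)
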