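"""Config-driven end-to-end analysis runs.

One :class:`AnalysisConfig` describes a complete run: which input tables to
read (or which presets to simulate), how each analyte is modelled, the
joint-confidence-region settings, the texture tolerance and the
particle-size window.  :func:`run_analysis` executes the stages in order —
digested-% tables, kinetic fits with model discrimination, initial rates,
pairwise JCR overlap, composition ratios, ICC yields — and serialises every
result under the output directory.  Identical config and seed give
byte-identical numerical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import compute_frr, macronutrient_ratios, read_composition_csv
from .io import read_timecourses_csv, write_fit_json, write_timecourse_csv
from .jcr import RegionNotClosedError, jcr_boundary, jcr_overlap
from .kinetics import (
    FitError,
    discriminate_models,
    fit_kinetic_model,
    initial_reaction_rate,
)
from .psd import icc_yield, psd_summary, read_psd_csv
from .synthetic import (
    PRESETS,
    generate_digestion_timecourse,
    generate_hardness_measurements,
    generate_psd,
    get_preset,
)
from .texture import (
    fit_hardness_profile,
    hardness_reduction_percent,
    plateau_alignment_time,
    read_hardness_csv,
)

__all__ = ["AnalysisConfig", "run_analysis"]

logger = logging.getLogger("pulsedigest")

_DEFAULT_MODELS = {
    "starch": {"model": "auto", "fix_ci": 0.0},
    "bioaccessible_protein": {"model": "fractional_conversion", "fix_ci": None},
    "soluble_protein": {"model": "fractional_conversion", "fix_ci": None},
}


@dataclass
class AnalysisConfig:
    """Settings for one end-to-end run; mirror of the YAML config schema."""

    output_dir: str
    seed: int = 0
    timecourse_csv: str | None = None
    hardness_csv: str | None = None
    psd_csv: str | None = None
    composition_csv: str | None = None
    simulate: list[str] = field(default_factory=list)
    model_settings: dict = field(default_factory=lambda: dict(_DEFAULT_MODELS))
    jcr_pair: tuple[str, str] = ("k", "Cf")
    jcr_alpha: float = 0.05
    jcr_f_convention: str = "n-p"
    texture_tolerance_n: float = 3.0
    psd_window_um: tuple[float, float] = (76.0, 133.0)

    def __post_init__(self) -> None:
        for attr in ("timecourse_csv", "hardness_csv", "psd_csv", "composition_csv"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{attr}: {path} does not exist")
        for name in self.simulate:
            get_preset(name)
        self.jcr_pair = tuple(self.jcr_pair)
        self.psd_window_um = tuple(self.psd_window_um)
        merged = dict(_DEFAULT_MODELS)
        merged.update(self.model_settings or {})
        self.model_settings = merged

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _simulate_inputs(cfg: AnalysisConfig, inputs_dir: Path) -> None:
    """Generate every input table for the configured presets."""
    tc_frames, hard_rows, psd_rows, comp_rows = [], [], [], []
    for i, name in enumerate(cfg.simulate):
        preset = get_preset(name)
        for j, analyte in enumerate(sorted(preset.kinetics)):
            if analyte == "hardness":
                continue
            tc = generate_digestion_timecourse(
                preset, analyte, seed=cfg.seed + 1000 * i + j
            )
            df = tc.observations.rename(columns={"value": "value_percent"})
            df.insert(0, "analyte", analyte)
            df.insert(0, "sample_id", preset.name)
            tc_frames.append(df)
        profile = generate_hardness_measurements(preset, seed=cfg.seed + 1000 * i + 99)
        hdf = profile.measurements.copy()
        hdf.insert(0, "pulse", preset.name)
        hard_rows.append(hdf)
        for kind, modes in preset.psd_modes.items():
            dist = generate_psd(modes, label=f"{preset.name} {kind}")
            psd_rows.append(
                pd.DataFrame(
                    {
                        "sample": f"{preset.name} {kind}",
                        "bin_low_um": dist.bin_edges[:-1],
                        "bin_high_um": dist.bin_edges[1:],
                        "volume_percent": dist.volume_percent,
                    }
                )
            )
        c = preset.composition
        comp_rows.append(
            {"label": c.label, "starch": c.starch, "protein": c.protein,
             "lipid": c.lipid, "ash": c.ash, "moisture": c.moisture, "basis": c.basis}
        )
    pd.concat(tc_frames, ignore_index=True).to_csv(inputs_dir / "timecourses.csv", index=False)
    pd.concat(hard_rows, ignore_index=True).to_csv(inputs_dir / "hardness.csv", index=False)
    pd.concat(psd_rows, ignore_index=True).to_csv(inputs_dir / "psd.csv", index=False)
    pd.DataFrame(comp_rows).to_csv(inputs_dir / "composition.csv", index=False)
    cfg.timecourse_csv = str(inputs_dir / "timecourses.csv")
    cfg.hardness_csv = str(inputs_dir / "hardness.csv")
    cfg.psd_csv = str(inputs_dir / "psd.csv")
    cfg.composition_csv = str(inputs_dir / "composition.csv")


def run_analysis(cfg: AnalysisConfig) -> dict:
    """Run every configured stage; return and serialise the report bundle.

    Stage failures are recorded per stage in the report's ``status`` block
    rather than aborting the whole run.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: dict = {"version": __version__, "seed": cfg.seed, "status": {},
                    "settings": {k: v for k, v in asdict(cfg).items()}}
    try:
        logger.info("run started (seed=%d)", cfg.seed)

        if cfg.simulate:
            inputs_dir = out / "inputs"
            inputs_dir.mkdir(exist_ok=True)
            _simulate_inputs(cfg, inputs_dir)
            logger.info("simulated inputs for presets %s", cfg.simulate)
            report["status"]["simulate"] = "ok"

        # composition ratios
        if cfg.composition_csv:
            try:
                rows = []
                for comp in read_composition_csv(cfg.composition_csv):
                    ratios = macronutrient_ratios(comp)
                    rows.append(
                        {"label": comp.label, "frr": compute_frr(comp),
                         "starch_protein": ratios["starch_protein"],
                         "starch_frr": ratios["starch_frr"]}
                    )
                comp_df = pd.DataFrame(rows)
                comp_df.to_csv(out / "composition_ratios.csv", index=False)
                report["composition"] = rows
                report["status"]["composition"] = "ok"
            except Exception as exc:
                logger.error("composition stage failed: %s", exc)
                report["status"]["composition"] = f"failed: {exc}"

        # kinetic fits, rates, JCR
        if cfg.timecourse_csv:
            try:
                fits_dir = out / "fits"
                fits_dir.mkdir(exist_ok=True)
                fit_rows, fits, tcs = [], {}, {}
                for (sample, analyte), tc in read_timecourses_csv(cfg.timecourse_csv).items():
                    settings = cfg.model_settings.get(
                        analyte, {"model": "fractional_conversion", "fix_ci": None}
                    )
                    if settings["model"] == "auto":
                        decision = discriminate_models(tc, fix_ci=settings.get("fix_ci"))
                        fit = decision["fits"][decision["choice"]]
                        trace = {
                            k: v for k, v in decision["diagnostics"].items() if k != "errors"
                        }
                        logger.info("%s/%s: discrimination chose %s",
                                    sample, analyte, decision["choice"])
                    else:
                        fit = fit_kinetic_model(
                            tc, model=settings["model"], fix_ci=settings.get("fix_ci")
                        )
                        trace = None
                    fits[(sample, analyte)] = fit
                    tcs[(sample, analyte)] = tc
                    write_fit_json(fit, fits_dir / f"{sample}_{analyte}.json")
                    fit_rows.append(
                        {"sample_id": sample, "analyte": analyte, "model": fit.model,
                         **{f"param_{k}": v for k, v in fit.params.items()},
                         "initial_rate": initial_reaction_rate(fit),
                         "r2_adjusted": fit.r2_adjusted, "sse": fit.sse,
                         "discrimination": json.dumps(trace, default=str) if trace else ""}
                    )
                pd.DataFrame(fit_rows).to_csv(out / "kinetic_fits.csv", index=False)
                report["fits"] = fit_rows
                report["status"]["kinetics"] = "ok"
            except Exception as exc:
                logger.error("kinetics stage failed: %s", exc)
                report["status"]["kinetics"] = f"failed: {exc}"
                fits, tcs = {}, {}

            # pairwise JCR overlap among fits exposing the configured pair
            try:
                regions = {}
                for key, fit in fits.items():
                    if all(name in fit.free_names for name in cfg.jcr_pair):
                        try:
                            regions[key] = jcr_boundary(
                                fit, tcs[key], pair=cfg.jcr_pair, alpha=cfg.jcr_alpha,
                                f_convention=cfg.jcr_f_convention,
                            )
                        except RegionNotClosedError as exc:
                            logger.warning("JCR for %s did not close: %s", key, exc)
                overlaps = []
                keys = sorted(regions)
                for i, a in enumerate(keys):
                    for b in keys[i + 1:]:
                        if a[1] != b[1]:
                            continue  # compare like analytes only
                        res = jcr_overlap(regions[a], regions[b])
                        overlaps.append(
                            {"sample_a": a[0], "sample_b": b[0], "analyte": a[1],
                             **res}
                        )
                pd.DataFrame(overlaps).to_csv(out / "jcr_overlap.csv", index=False)
                report["jcr_overlap"] = overlaps
                report["status"]["jcr"] = "ok"
            except Exception as exc:
                logger.error("JCR stage failed: %s", exc)
                report["status"]["jcr"] = f"failed: {exc}"

        # texture
        if cfg.hardness_csv:
            try:
                texture_rows = []
                for profile in read_hardness_csv(cfg.hardness_csv):
                    fit = fit_hardness_profile(profile)
                    texture_rows.append(
                        {"pulse": profile.label,
                         **{f"param_{k}": v for k, v in fit.params.items()},
                         "hardness_reduction_percent": hardness_reduction_percent(fit),
                         "alignment_time_min": plateau_alignment_time(
                             fit, tolerance=cfg.texture_tolerance_n,
                             sampling_interval=profile.sampling_interval,
                         )}
                    )
                pd.DataFrame(texture_rows).to_csv(out / "texture.csv", index=False)
                report["texture"] = texture_rows
                report["status"]["texture"] = "ok"
            except Exception as exc:
                logger.error("texture stage failed: %s", exc)
                report["status"]["texture"] = f"failed: {exc}"

        # particle sizes
        if cfg.psd_csv:
            try:
                psd_rows = []
                for dist in read_psd_csv(cfg.psd_csv):
                    summary = psd_summary(dist)
                    psd_rows.append(
                        {"sample": dist.label,
                         "icc_yield_percent": icc_yield(dist, *cfg.psd_window_um),
                         "volume_weighted_mean_um": summary["volume_weighted_mean_um"],
                         "n_modes": summary["n_modes"]}
                    )
                pd.DataFrame(psd_rows).to_csv(out / "psd_summary.csv", index=False)
                report["psd"] = psd_rows
                report["status"]["psd"] = "ok"
            except Exception as exc:
                logger.error("PSD stage failed: %s", exc)
                report["status"]["psd"] = f"failed: {exc}"

        report["ok"] = all(str(v) == "ok" for v in report["status"].values())
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str)
        )
        logger.info("run finished: %s", "ok" if report["ok"] else "with failures")
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
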