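"""Schema-validated tabular IO for time courses and fit results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import DigestionTimeCourse, KineticFit

__all__ = [
    "SchemaError",
    "read_timecourse_csv",
    "read_timecourses_csv",
    "write_timecourse_csv",
    "write_fit_json",
    "read_fit_json",
]

_TC_COLUMNS = ("sample_id", "analyte", "time_min", "value_percent", "replicate")


class SchemaError(ValueError):
    """A CSV or JSON input violates the expected schema."""


def _numeric(df: pd.DataFrame, column: str, path) -> pd.Series:
    raw = df[column]
    try:
        return pd.to_numeric(raw, errors="raise")
    except (ValueError, TypeError):
        bad = raw[pd.to_numeric(raw, errors="coerce").isna()]
        row, value = bad.index[0], bad.iloc[0]
        hint = ""
        if isinstance(value, str) and "," in value:
            hint = " (locale-style decimal comma? use '.' as the decimal separator)"
        raise SchemaError(
            f"{path}: column {column!r}, row {row}: non-numeric value {value!r}{hint}"
        ) from None


def read_timecourses_csv(path) -> dict[tuple[str, str], DigestionTimeCourse]:
    """Read all (sample, analyte) time courses from one CSV.

    Expected columns: ``sample_id, analyte, time_min, value_percent,
    replicate``.  Returns a dict keyed by (sample_id, analyte).
    """
    df = pd.read_csv(path, dtype=str)
    missing = set(_TC_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    df["time_min"] = _numeric(df, "time_min", path)
    df["value_percent"] = _numeric(df, "value_percent", path)
    if (df["time_min"] < 0).any():
        row = int(df.index[df["time_min"] < 0][0])
        raise SchemaError(f"{path}: column 'time_min', row {row}: negative time")
    out: dict[tuple[str, str], DigestionTimeCourse] = {}
    for (sample, analyte), group in df.groupby(["sample_id", "analyte"], sort=False):
        obs = pd.DataFrame(
            {
                "time_min": group["time_min"].to_numpy(dtype=float),
                "value": group["value_percent"].to_numpy(dtype=float),
                "replicate": group["replicate"].to_numpy(),
            }
        )
        try:
            out[(sample, analyte)] = DigestionTimeCourse(
                analyte=analyte, observations=obs, label=str(sample)
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: sample {sample!r}: {exc}") from exc
    return out


def read_timecourse_csv(path) -> DigestionTimeCourse:
    """Read a CSV holding exactly one (sample, analyte) time course."""
    groups = read_timecourses_csv(path)
    if len(groups) != 1:
        raise SchemaError(
            f"{path}: expected a single (sample, analyte) group, found {len(groups)}; "
            "use read_timecourses_csv for multi-sample files"
        )
    (tc,) = groups.values()
    return tc


def write_timecourse_csv(tc: DigestionTimeCourse, path) -> None:
    df = tc.observations.rename(columns={"value": "value_percent"})
    df.insert(0, "analyte", tc.analyte)
    df.insert(0, "sample_id", tc.label)
    df.to_csv(path, index=False)


def write_fit_json(fit: KineticFit, path) -> None:
    """Serialise a fit (params, SEs, covariance, diagnostics) to JSON."""
    payload = {
        "model": fit.model,
        "params": fit.params,
        "standard_errors": fit.standard_errors,
        "covariance": np.asarray(fit.covariance).tolist(),
        "free_names": list(fit.free_names),
        "sse": fit.sse,
        "n_obs": fit.n_obs,
        "r2_adjusted": fit.r2_adjusted,
        "time_range": list(fit.time_range),
        "fixed": fit.fixed,
        "analyte": fit.analyte,
        "label": fit.label,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_fit_json(path) -> KineticFit:
    """Read a fit written by :func:`write_fit_json` (lossless round trip)."""
    data = json.loads(Path(path).read_text())
    try:
        return KineticFit(
            model=data["model"],
            params={k: float(v) for k, v in data["params"].items()},
            standard_errors={k: float(v) for k, v in data["standard_errors"].items()},
            covariance=np.asarray(data["covariance"], dtype=float),
            free_names=list(data["free_names"]),
            sse=float(data["sse"]),
            n_obs=int(data["n_obs"]),
            r2_adjusted=float(data["r2_adjusted"]),
            time_range=tuple(data["time_range"]),
            fixed={k: float(v) for k, v in data.get("fixed", {}).items()},
            analyte=data.get("analyte"),
            label=data.get("label", ""),
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: fit JSON missing field {exc}") from exc
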