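"""Empirical digestion and softening kinetics.

Two empirical models describe small-intestinal digestion time courses and
hardness decay during hydrothermal cooking:

* **Fractional conversion** (first-order approach to a plateau)::

      C(t) = Cf + (Ci - Cf) * exp(-k t)

  with initial value ``Ci``, final value ``Cf`` and rate constant ``k``
  (min^-1).  Used for starch and protein digestion and for hardness decay
  (where ``Cf`` is the residual hardness).

* **Lag-phase logistic** (sigmoid with an explicit lag ``lambda``)::

      C(t) = Cf / (1 + exp(4 kmax / Cf * (lambda - t) + 2))

  with plateau ``Cf`` (% digested), maximum rate ``kmax`` (% min^-1, the
  slope at the inflection) and lag duration ``lambda`` (min).  Captures the
  delayed onset of starch digestion caused by the intact cell-wall barrier.

Both are exposed as scikit-learn style regressors
(:class:`FractionalConversionModel`, :class:`LagLogisticModel`) fitted by
bounded trust-region nonlinear least squares with analytic Jacobians and a
Latin-hypercube multi-start.  Module-level functions
(:func:`fit_kinetic_model`, :func:`initial_reaction_rate`,
:func:`discriminate_models`, :func:`normalized_digestion_correlation`) wrap
the estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ANALYTES",
    "DigestionTimeCourse",
    "KineticFit",
    "FitError",
    "FractionalConversionModel",
    "LagLogisticModel",
    "eval_fractional_conversion",
    "eval_logistic",
    "evaluate_fit",
    "fit_kinetic_model",
    "initial_reaction_rate",
    "corrected_aic",
    "discriminate_models",
    "normalized_digestion_correlation",
]

ANALYTES = ("starch", "soluble_protein", "bioaccessible_protein", "hardness")

_EXP_CLIP = 700.0  # exp overflow guard for far-from-optimum parameter probes


class FitError(RuntimeError):
    """Nonlinear fit failed; carries the best SSE reached, if any."""

    def __init__(self, message: str, best_sse: float | None = None):
        super().__init__(message)
        self.best_sse = best_sse


# ---------------------------------------------------------------------------
# model functions


def eval_fractional_conversion(t, ci, cf, k):
    """Fractional conversion curve Cf + (Ci - Cf) exp(-k t)."""
    t = np.asarray(t, dtype=float)
    out = cf + (ci - cf) * np.exp(-np.clip(k * t, -_EXP_CLIP, _EXP_CLIP))
    return out if out.ndim else float(out)


def eval_logistic(t, starch_f, k_max, lag):
    """Lag-phase logistic curve Cf / (1 + exp(4 kmax/Cf (lambda - t) + 2))."""
    t = np.asarray(t, dtype=float)
    u = np.clip(4.0 * k_max / starch_f * (lag - t) + 2.0, -_EXP_CLIP, _EXP_CLIP)
    out = starch_f / (1.0 + np.exp(u))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# containers


@dataclass
class DigestionTimeCourse:
    """Per-tube observations of one analyte over digestion (or cooking) time.

    ``observations`` holds columns ``time_min``, ``value`` (% digested, or N
    for hardness) and ``replicate``; each row is one independently sampled
    reactor tube (or seed), so replicates enter fits individually.
    """

    analyte: str
    observations: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}; expected one of {ANALYTES}")
        df = pd.DataFrame(self.observations)
        required = {"time_min", "value"}
        if not required <= set(df.columns):
            raise ValueError(f"observations need columns {sorted(required)}")
        if "replicate" not in df.columns:
            df = df.assign(replicate=0)
        if (df["time_min"] < 0).any():
            raise ValueError("times must be >= 0 min")
        if not np.isfinite(df["value"]).all():
            raise ValueError("values must be finite")
        self.observations = df.reset_index(drop=True)

    @property
    def times(self) -> np.ndarray:
        return self.observations["time_min"].to_numpy(dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.observations["value"].to_numpy(dtype=float)

    def require_fittable(self, n_params: int) -> None:
        n_times = self.observations["time_min"].nunique()
        if n_times < 5:
            raise ValueError(f"need >= 5 distinct times to fit, got {n_times}")
        if len(self.observations) <= n_params:
            raise FitError(
                f"{len(self.observations)} observations cannot identify {n_params} parameters"
            )


@dataclass
class KineticFit:
    """A converged kinetic model fit.

    ``params`` always contains all model parameters (fixed ones included);
    ``free_names`` orders the jointly estimated subset to which
    ``covariance`` refers.  ``standard_errors`` are Jacobian-based; fixed
    parameters get SE 0.
    """

    model: Literal["fractional_conversion", "logistic"]
    params: dict[str, float]
    standard_errors: dict[str, float]
    covariance: np.ndarray
    free_names: list[str]
    sse: float
    n_obs: int
    r2_adjusted: float
    time_range: tuple[float, float]
    fixed: dict[str, float] = field(default_factory=dict)
    analyte: str | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def predict(self, t):
        return evaluate_fit(self, t)


def evaluate_fit(fit: KineticFit, t):
    """Evaluate a fitted curve at times ``t`` (min)."""
    p = fit.params
    if fit.model == "fractional_conversion":
        return eval_fractional_conversion(t, p["Ci"], p["Cf"], p["k"])
    if fit.model == "logistic":
        return eval_logistic(t, p["Cf"], p["kmax"], p["lambda"])
    raise ValueError(f"unknown model {fit.model!r}")


# ---------------------------------------------------------------------------
# estimators


class _KineticRegressorBase(RegressorMixin, BaseEstimator):
    """Shared fitting machinery: bounded least squares + LHS multi-start."""

    _model_name: str
    _param_names: tuple[str, ...]

    def __init__(self, n_starts: int = 10, random_state: int | None = 0):
        self.n_starts = n_starts
        self.random_state = random_state

    # subclasses provide: _free_names(), _heuristic_start(t, y),
    # _residuals(theta, t, y), _jacobian(theta, t, y), _bounds(),
    # _start_ranges(theta0), _assemble_params(theta)

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != y.shape:
            raise ValueError("X and y must have matching lengths")
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        free = self._free_names()
        if len(t) <= len(free):
            raise FitError(f"{len(t)} observations cannot identify {len(free)} parameters")

        lo, hi = self._bounds()
        starts = [self._heuristic_start(t, y)]
        if self.n_starts > 1:
            sampler = qmc.LatinHypercube(d=len(free), seed=self.random_state)
            unit = sampler.random(self.n_starts - 1)
            ranges = self._start_ranges(starts[0])
            for row in unit:
                theta = np.array(
                    [r_lo + u * (r_hi - r_lo) for u, (r_lo, r_hi) in zip(row, ranges)]
                )
                starts.append(theta)

        best = None
        for theta0 in starts:
            theta0 = np.clip(theta0, lo, hi)
            try:
                res = optimize.least_squares(
                    self._residuals,
                    theta0,
                    jac=self._jacobian,
                    bounds=(lo, hi),
                    args=(t, y),
                    method="trf",
                )
            except Exception:  # singular Jacobian at a bad start: try next
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            raise FitError("all multi-start least-squares attempts failed")

        theta = best.x
        n, p = len(t), len(free)
        sse = float(np.sum(best.fun**2))
        dof = n - p
        sigma2 = sse / dof if dof > 0 else np.nan
        jac = self._jacobian(theta, t, y)
        jtj = jac.T @ jac
        cov = sigma2 * np.linalg.pinv(jtj)
        cov = 0.5 * (cov + cov.T)  # enforce symmetry against pinv round-off
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - sse / ss_tot if ss_tot > 0 else np.nan
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else np.nan

        self.theta_ = theta
        self.free_names_ = list(free)
        self.params_ = self._assemble_params(theta)
        self.standard_errors_ = {
            **{name: float(s) for name, s in zip(free, se)},
            **{name: 0.0 for name in self._fixed_params()},
        }
        self.covariance_ = cov
        self.sse_ = sse
        self.n_obs_ = n
        self.r2_adjusted_ = float(r2_adj)
        self.time_range_ = (float(t.min()), float(t.max()))
        self.result_ = KineticFit(
            model=self._model_name,
            params=self.params_,
            standard_errors=self.standard_errors_,
            covariance=cov,
            free_names=list(free),
            sse=sse,
            n_obs=n,
            r2_adjusted=float(r2_adj),
            time_range=self.time_range_,
            fixed=self._fixed_params(),
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        return np.asarray(evaluate_fit(self.result_, np.asarray(X, dtype=float).reshape(-1)))

    def _fixed_params(self) -> dict[str, float]:
        return {}

    def initial_rate(self) -> float:
        check_is_fitted(self, "result_")
        return initial_reaction_rate(self.result_)


class FractionalConversionModel(_KineticRegressorBase):
    """First-order fractional conversion regressor C(t) = Cf + (Ci-Cf) e^{-kt}.

    Parameters
    ----------
    fix_ci : float or None
        If given, the initial value ``Ci`` is held at this value (e.g. 0 for
        starch digestion where no salivary amylase acts) and only ``Cf`` and
        ``k`` are estimated.
    n_starts : int
        Number of Latin-hypercube multi-start points (including the
        data-driven heuristic start).
    random_state : int or None
        Seed for the multi-start sampler (fitting itself is deterministic).
    """

    _model_name = "fractional_conversion"
    _param_names = ("Ci", "Cf", "k")

    def __init__(self, fix_ci: float | None = None, n_starts: int = 10,
                 random_state: int | None = 0):
        super().__init__(n_starts=n_starts, random_state=random_state)
        self.fix_ci = fix_ci

    def _free_names(self):
        return ("Cf", "k") if self.fix_ci is not None else ("Ci", "Cf", "k")

    def _fixed_params(self):
        return {} if self.fix_ci is None else {"Ci": float(self.fix_ci)}

    def _bounds(self):
        if self.fix_ci is not None:
            return np.array([-np.inf, 1e-8]), np.array([np.inf, np.inf])
        return np.array([-np.inf, -np.inf, 1e-8]), np.array([np.inf, np.inf, np.inf])

    def _split(self, theta):
        if self.fix_ci is not None:
            return float(self.fix_ci), theta[0], theta[1]
        return theta[0], theta[1], theta[2]

    def _heuristic_start(self, t, y):
        order = np.argsort(t)
        t_s, y_s = t[order], y[order]
        ci0 = float(np.mean(y_s[t_s == t_s[0]])) if self.fix_ci is None else float(self.fix_ci)
        cf0 = float(np.mean(y_s[t_s == t_s[-1]]))
        # log-linearise the first two thirds: ln|y - Cf| = ln|Ci - Cf| - k t
        k0 = np.nan
        if cf0 != ci0:
            cut = t_s[0] + 2.0 / 3.0 * (t_s[-1] - t_s[0])
            mask = (t_s <= cut) & (np.abs(y_s - cf0) > 1e-9 * max(1.0, abs(cf0 - ci0)))
            same_side = np.sign(y_s - cf0) == np.sign(ci0 - cf0)
            mask &= same_side
            if mask.sum() >= 2 and np.ptp(t_s[mask]) > 0:
                slope = np.polyfit(t_s[mask], np.log(np.abs(y_s[mask] - cf0)), 1)[0]
                if slope < 0:
                    k0 = -slope
        if not np.isfinite(k0) or k0 <= 0:
            span = t_s[-1] - t_s[0]
            k0 = 3.0 / span if span > 0 else 0.1
        if self.fix_ci is not None:
            return np.array([cf0, k0])
        return np.array([ci0, cf0, k0])

    def _start_ranges(self, theta0):
        *c_part, k0 = theta0
        spread = [max(10.0, 0.5 * abs(c)) for c in c_part]
        ranges = [(c - s, c + s) for c, s in zip(c_part, spread)]
        ranges.append((k0 / 10.0, k0 * 10.0))
        return ranges

    def _residuals(self, theta, t, y):
        ci, cf, k = self._split(theta)
        return eval_fractional_conversion(t, ci, cf, k) - y

    def _jacobian(self, theta, t, y):
        ci, cf, k = self._split(theta)
        e = np.exp(np.clip(-k * t, -_EXP_CLIP, _EXP_CLIP))
        d_ci = e
        d_cf = 1.0 - e
        d_k = -(ci - cf) * t * e
        cols = [d_cf, d_k] if self.fix_ci is not None else [d_ci, d_cf, d_k]
        return np.column_stack(cols)

    def _assemble_params(self, theta):
        ci, cf, k = self._split(theta)
        return {"Ci": float(ci), "Cf": float(cf), "k": float(k)}


class LagLogisticModel(_KineticRegressorBase):
    """Lag-phase logistic regressor C(t) = Cf / (1 + exp(4 kmax/Cf (lambda-t) + 2)).

    ``kmax`` is the tangent slope at the inflection; ``lambda`` (min, >= 0)
    is the lag duration, the intercept of that tangent with the time axis.
    """

    _model_name = "logistic"
    _param_names = ("Cf", "kmax", "lambda")

    def _free_names(self):
        return self._param_names

    def _bounds(self):
        return np.array([1e-8, 1e-8, 0.0]), np.array([np.inf, np.inf, np.inf])

    def _heuristic_start(self, t, y):
        means = pd.Series(y).groupby(pd.Series(t)).mean()
        tt, yy = means.index.to_numpy(dtype=float), means.to_numpy(dtype=float)
        cf0 = max(float(yy.max()), 1e-3)
        slopes = np.diff(yy) / np.maximum(np.diff(tt), 1e-9)
        kmax0 = float(slopes.max()) if len(slopes) and slopes.max() > 0 else cf0 / max(tt[-1], 1.0)
        # value at t = lambda is Cf/(1+e^2); first crossing locates the lag
        target = cf0 / (1.0 + np.exp(2.0))
        lag0 = 0.0
        above = np.nonzero(yy >= target)[0]
        if len(above) and above[0] > 0:
            i = above[0]
            frac = (target - yy[i - 1]) / max(yy[i] - yy[i - 1], 1e-12)
            lag0 = float(tt[i - 1] + frac * (tt[i] - tt[i - 1]))
        return np.array([cf0, kmax0, max(lag0, 0.0)])

    def _start_ranges(self, theta0):
        cf0, kmax0, lag0 = theta0
        return [
            (0.5 * cf0, 1.5 * cf0),
            (kmax0 / 10.0, kmax0 * 10.0),
            (0.0, max(4.0 * lag0, 30.0)),
        ]

    def _residuals(self, theta, t, y):
        cf, kmax, lag = theta
        return eval_logistic(t, cf, kmax, lag) - y

    def _jacobian(self, theta, t, y):
        cf, kmax, lag = theta
        u = np.clip(4.0 * kmax / cf * (lag - t) + 2.0, -_EXP_CLIP, _EXP_CLIP)
        eu = np.exp(u)
        denom = (1.0 + eu) ** 2
        # dC/du = -Cf e^u / (1+e^u)^2
        dc_du = -cf * eu / denom
        du_dcf = -4.0 * kmax * (lag - t) / cf**2
        du_dkmax = 4.0 * (lag - t) / cf
        du_dlag = np.full_like(t, 4.0 * kmax / cf)
        d_cf = 1.0 / (1.0 + eu) + dc_du * du_dcf
        return np.column_stack([d_cf, dc_du * du_dkmax, dc_du * du_dlag])

    def _assemble_params(self, theta):
        cf, kmax, lag = theta
        return {"Cf": float(cf), "kmax": float(kmax), "lambda": float(lag)}


# ---------------------------------------------------------------------------
# functional wrappers


def fit_kinetic_model(
    tc: DigestionTimeCourse,
    model: Literal["fractional_conversion", "logistic"] = "fractional_conversion",
    fix_ci: float | None = None,
    n_starts: int = 10,
    random_state: int | None = 0,
) -> KineticFit:
    """Least-squares fit of one kinetic model to a time course.

    All replicate observations enter the SSE individually.  ``fix_ci`` holds
    the fractional-conversion initial value fixed (only valid for that
    model).  Deterministic given data and settings.
    """
    if model == "fractional_conversion":
        est = FractionalConversionModel(fix_ci=fix_ci, n_starts=n_starts,
                                        random_state=random_state)
    elif model == "logistic":
        if fix_ci is not None:
            raise ValueError("fix_ci applies only to the fractional conversion model")
        est = LagLogisticModel(n_starts=n_starts, random_state=random_state)
    else:
        raise ValueError(f"unknown model {model!r}")
    tc.require_fittable(len(est._free_names()))
    est.fit(tc.times, tc.values)
    fit = est.result_
    fit.analyte = tc.analyte
    fit.label = tc.label
    return fit


def initial_reaction_rate(fit: KineticFit) -> float:
    """Tangent slope of the fitted curve at t = 0 (% min^-1 or N min^-1).

    Fractional conversion: ``k (Cf - Ci)``.  Logistic:
    ``4 kmax e^{u0} / (1 + e^{u0})^2`` with ``u0 = 4 kmax lambda / Cf + 2``.
    """
    p = fit.params
    if fit.model == "fractional_conversion":
        return p["k"] * (p["Cf"] - p["Ci"])
    if fit.model == "logistic":
        u0 = 4.0 * p["kmax"] * p["lambda"] / p["Cf"] + 2.0
        eu = np.exp(np.clip(u0, -_EXP_CLIP, _EXP_CLIP))
        return 4.0 * p["kmax"] * eu / (1.0 + eu) ** 2
    raise ValueError(f"unknown model {fit.model!r}")


def corrected_aic(sse: float, n_obs: int, n_fitted: int) -> float:
    """Small-sample corrected AIC with the noise variance counted as a parameter."""
    k = n_fitted + 1
    if n_obs - k - 1 <= 0:
        return np.inf
    return n_obs * np.log(sse / n_obs) + 2 * k + 2 * k * (k + 1) / (n_obs - k - 1)


def discriminate_models(
    tc: DigestionTimeCourse,
    fix_ci: float | None = 0.0,
    alpha: float = 0.05,
    n_starts: int = 10,
    random_state: int | None = 0,
) -> dict:
    """Choose between fractional conversion and the lag-phase logistic.

    The logistic is selected only when it finds a meaningful lag: the
    estimated ``lambda`` must be positive with its ``1 - alpha`` confidence
    interval excluding 0, *and* its corrected AIC must beat the fractional
    conversion fit.  Otherwise the fractional conversion model is kept.
    Returns the choice, both fits and a decision trace.
    """
    fits: dict[str, KineticFit] = {}
    errors: dict[str, str] = {}
    for model in ("fractional_conversion", "logistic"):
        try:
            fits[model] = fit_kinetic_model(
                tc, model=model,
                fix_ci=fix_ci if model == "fractional_conversion" else None,
                n_starts=n_starts, random_state=random_state,
            )
        except (FitError, ValueError) as exc:
            errors[model] = str(exc)
    if not fits:
        raise FitError("both candidate models failed to fit")
    if len(fits) == 1:
        (choice,) = fits
        return {"choice": choice, "fits": fits,
                "diagnostics": {"warning": f"only {choice} converged", "errors": errors}}

    fc, lg = fits["fractional_conversion"], fits["logistic"]
    lam, lam_se = lg.params["lambda"], lg.standard_errors["lambda"]
    dof = max(lg.n_obs - lg.n_free, 1)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, dof)
    ci = (lam - t_crit * lam_se, lam + t_crit * lam_se)
    aicc = {m: corrected_aic(f.sse, f.n_obs, f.n_free) for m, f in fits.items()}
    lag_significant = lam > 0 and ci[0] > 0
    choice = (
        "logistic"
        if lag_significant and aicc["logistic"] < aicc["fractional_conversion"]
        else "fractional_conversion"
    )
    return {
        "choice": choice,
        "fits": fits,
        "diagnostics": {
            "lambda_hat": lam,
            "lambda_ci": ci,
            "lambda_ci_excludes_zero": bool(lag_significant),
            "aicc": aicc,
            "errors": errors,
        },
    }


def normalized_digestion_correlation(
    starch_fit: KineticFit,
    protein_fit: KineticFit,
    grid: Sequence[float] | np.ndarray = None,
) -> dict:
    """Pair normalised starch vs protein digestion curves over a time grid.

    Each fitted curve is evaluated on the grid and divided by its own plateau
    (``Cf``), mapping both to [0, 1]; the Pearson correlation of the paired
    trajectory quantifies how tightly the two macronutrients' digestion
    progresses together.
    """
    if grid is None:
        grid = np.linspace(0.0, 180.0, 37)
    grid = np.asarray(grid, dtype=float)
    out = {}
    for name, fit in (("starch", starch_fit), ("protein", protein_fit)):
        cf = fit.params["Cf"]
        if cf <= 0:
            raise ValueError(f"{name} fit has plateau Cf <= 0; cannot normalise")
        out[name] = np.asarray(evaluate_fit(fit, grid)) / cf
    r, _ = stats.pearsonr(out["starch"], out["protein"])
    return {
        "times": grid,
        "starch_normalized": out["starch"],
        "protein_normalized": out["protein"],
        "pearson_r": float(r),
    }
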