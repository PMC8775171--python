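"""Joint confidence regions for jointly estimated kinetic parameter pairs.

Two nonlinear-regression parameters estimated from the same data are
correlated, so comparing samples by marginal confidence intervals can
mislead.  The joint confidence region (JCR) at level ``1 - alpha`` is the
set of parameter pairs whose SSE stays below the F-ratio threshold

    SSE(theta) <= SSE(theta_hat) * (1 + p/(n-p) * F(p, dfd, 1-alpha))

with ``p = 2`` jointly estimated parameters.  The conventional (Beale)
denominator degrees of freedom are ``dfd = n - p``; ``dfd = n - 1`` is
available as an alternative convention.  Two samples whose regions do not
overlap differ significantly in the parameter pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy import optimize, stats
from shapely.geometry import Point, Polygon
from skimage import measure

from .kinetics import (
    DigestionTimeCourse,
    KineticFit,
    eval_fractional_conversion,
    eval_logistic,
)

__all__ = [
    "JointConfidenceRegion",
    "RegionNotClosedError",
    "sse_threshold",
    "sse_contour",
    "jcr_boundary",
    "jcr_contains_truth",
    "jcr_overlap",
]


class RegionNotClosedError(RuntimeError):
    """The SSE contour did not close within the allowed grid expansions."""


@dataclass
class JointConfidenceRegion:
    """A closed SSE-contour region for one jointly estimated parameter pair."""

    param_pair: tuple[str, str]
    alpha: float
    sse_threshold: float
    boundary: np.ndarray  # (m, 2) closed polyline in parameter space
    center: tuple[float, float]
    grid_ranges: tuple[tuple[float, float], tuple[float, float]]
    grid_resolution: int
    source: KineticFit | None = None

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=float)
        poly = self.polygon()
        if not poly.is_valid or not poly.covers(Point(*self.center)):
            raise ValueError("boundary must be a valid polygon enclosing the point estimate")

    def polygon(self) -> Polygon:
        return Polygon(self.boundary)

    @property
    def area(self) -> float:
        return self.polygon().area


def sse_threshold(
    sse_hat: float,
    n_obs: int,
    alpha: float = 0.05,
    p: int = 2,
    f_convention: Literal["n-p", "n-1"] = "n-p",
) -> float:
    """F-ratio SSE threshold bounding the joint confidence region."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_obs <= p:
        raise ValueError("need more observations than jointly estimated parameters")
    dfd = n_obs - p if f_convention == "n-p" else n_obs - 1
    f_crit = stats.f.ppf(1.0 - alpha, p, dfd)
    return sse_hat * (1.0 + p / (n_obs - p) * f_crit)


def _model_sse_fn(
    fit: KineticFit, tc: DigestionTimeCourse, pair: tuple[str, str],
    profile_nuisance: bool,
) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """SSE over a grid of the pair, nuisance parameters fixed at (or profiled
    from) their estimates."""
    t, y = tc.times, tc.values
    base = dict(fit.params)
    nuisance = [n for n in fit.free_names if n not in pair]

    def curve(params: dict, tt):
        if fit.model == "fractional_conversion":
            return eval_fractional_conversion(tt, params["Ci"], params["Cf"], params["k"])
        return eval_logistic(tt, params["Cf"], params["kmax"], params["lambda"])

    if not nuisance or not profile_nuisance:

        def sse(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
            shape = np.broadcast(p1, p2).shape
            params = {
                k: (np.asarray(v, dtype=float)[..., None] if np.ndim(v) else v)
                for k, v in base.items()
            }
            params[pair[0]] = np.asarray(p1, dtype=float)[..., None]
            params[pair[1]] = np.asarray(p2, dtype=float)[..., None]
            pred = curve(params, t.reshape((1,) * len(shape) + (-1,)))
            return np.sum((pred - y) ** 2, axis=-1)

        return sse

    # profiled: minimise over nuisance parameters at each grid point
    def sse_profiled(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
        p1b, p2b = np.broadcast_arrays(np.asarray(p1, float), np.asarray(p2, float))
        out = np.empty(p1b.shape)
        for idx in np.ndindex(p1b.shape):
            fixed = dict(base)
            fixed[pair[0]] = p1b[idx]
            fixed[pair[1]] = p2b[idx]

            def resid(vec):
                trial = dict(fixed)
                trial.update(zip(nuisance, vec))
                return curve(trial, t) - y

            res = optimize.least_squares(resid, [base[n] for n in nuisance])
            out[idx] = float(np.sum(res.fun**2))
        return out

    return sse_profiled


def sse_contour(
    sse_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    center: tuple[float, float],
    half_widths: tuple[float, float],
    threshold: float,
    resolution: int = 201,
    max_expansions: int = 8,
) -> tuple[np.ndarray, tuple[tuple[float, float], tuple[float, float]]]:
    """Extract the closed SSE contour at ``threshold`` enclosing ``center``.

    The grid spans ``center +- half_widths`` and doubles until the contour
    closes inside it.  Returns the boundary polyline and the final grid
    ranges.  Works for any SSE surface, linear or nonlinear.
    """
    cx, cy = center
    hx, hy = half_widths
    for _ in range(max_expansions + 1):
        xs = np.linspace(cx - hx, cx + hx, resolution)
        ys = np.linspace(cy - hy, cy + hy, resolution)
        grid = sse_fn(xs[None, :], ys[:, None])  # rows: y, cols: x
        contours = measure.find_contours(grid, threshold)
        dx = xs[1] - xs[0]
        dy = ys[1] - ys[0]
        for contour in contours:
            closed = np.allclose(contour[0], contour[-1])
            if not closed:
                continue
            boundary = np.column_stack(
                [xs[0] + contour[:, 1] * dx, ys[0] + contour[:, 0] * dy]
            )
            poly = Polygon(boundary)
            if poly.is_valid and poly.covers(Point(cx, cy)):
                return boundary, ((xs[0], xs[-1]), (ys[0], ys[-1]))
        hx *= 2.0
        hy *= 2.0
    raise RegionNotClosedError(
        "SSE contour did not close around the point estimate; "
        "increase max_expansions or check the fit"
    )


def jcr_boundary(
    fit: KineticFit,
    tc: DigestionTimeCourse,
    pair: tuple[str, str] = ("k", "Cf"),
    alpha: float = 0.05,
    resolution: int = 201,
    half_width_se: float = 6.0,
    f_convention: Literal["n-p", "n-1"] = "n-p",
    profile_nuisance: bool = False,
) -> JointConfidenceRegion:
    """Joint confidence region for ``pair`` from a converged fit and its data.

    The SSE surface is evaluated on a grid spanning ``half_width_se``
    standard errors around the estimates (auto-expanded until the contour
    closes); parameters outside the pair are fixed at their estimates, or
    re-optimised per grid point when ``profile_nuisance`` is set.
    """
    for name in pair:
        if name not in fit.free_names:
            raise ValueError(f"{name!r} is not a jointly estimated parameter of this fit")
    threshold = sse_threshold(fit.sse, fit.n_obs, alpha=alpha, p=2,
                              f_convention=f_convention)
    center = (fit.params[pair[0]], fit.params[pair[1]])
    half = tuple(
        max(half_width_se * fit.standard_errors[name], 1e-6 * max(abs(fit.params[name]), 1.0))
        for name in pair
    )
    sse_fn = _model_sse_fn(fit, tc, pair, profile_nuisance)
    boundary, ranges = sse_contour(sse_fn, center, half, threshold, resolution=resolution)
    return JointConfidenceRegion(
        param_pair=pair,
        alpha=alpha,
        sse_threshold=threshold,
        boundary=boundary,
        center=center,
        grid_ranges=ranges,
        grid_resolution=resolution,
        source=fit,
    )


def jcr_contains_truth(
    fit: KineticFit,
    tc: DigestionTimeCourse,
    truth: dict[str, float],
    alpha: float = 0.05,
    f_convention: Literal["n-p", "n-1"] = "n-p",
    profile_nuisance: bool = False,
) -> bool:
    """Whether the JCR for ``truth``'s parameter pair covers those true values.

    Evaluates the SSE inequality directly at the true point, which is exact
    (no contour discretisation); used for coverage studies.
    """
    pair = tuple(truth)
    threshold = sse_threshold(fit.sse, fit.n_obs, alpha=alpha, p=2,
                              f_convention=f_convention)
    sse_fn = _model_sse_fn(fit, tc, pair, profile_nuisance)
    value = float(sse_fn(np.asarray(truth[pair[0]]), np.asarray(truth[pair[1]])))
    return value <= threshold


def jcr_overlap(a: JointConfidenceRegion, b: JointConfidenceRegion) -> dict:
    """Polygon intersection of two regions over the same parameter pair.

    Returns whether they overlap and the intersection area as a fraction of
    the smaller region (1.0 for identical regions, 0.0 for disjoint ones).
    """
    if a.param_pair != b.param_pair:
        raise ValueError(
            f"parameter pairs differ: {a.param_pair} vs {b.param_pair}"
        )
    pa, pb = a.polygon(), b.polygon()
    inter = pa.intersection(pb)
    smaller = min(pa.area, pb.area)
    fraction = inter.area / smaller if smaller > 0 else 0.0
    return {"overlaps": not inter.is_empty, "overlap_area_fraction": float(fraction)}
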