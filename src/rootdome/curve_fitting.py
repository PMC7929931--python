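"""Dome-curve model selection: five candidate families, AIC, cross-validation,
the catenary-closest ellipse, and the isometric catenary collapse.

The five dome functions, all even in x and anchored at the apex (y(0) = 0):

    parabola   y = a1 * x**2
    catenary   y = a2 * cosh(x/a2) - a2
    ellipse    y = b3 * (1 - sqrt(1 - (x/a3)**2))      (lower half, re-anchored)
    hyperbola  y = b4 * (sqrt(1 + (x/a4)**2) - 1)      (upward branch)
    cosine     y = -a5 * cos(b5*x) + a5

Each family is fitted by nonlinear least squares on the y-coordinate with a
multistart over documented parameter grids.  Families are compared by SSE, by
AIC = n*ln(SSE/n) + 2k (Gaussian errors, profiled variance; additive constants
cancel in delta-AIC), and by repeated 99/1 cross-validation (average held-out
MSE over N seeded splits).  Delta-AIC < 2 marks candidate best models.

Because the catenary parameter a sets both the apex curvature (1/a) and the
overall scale, dividing the coordinates of a catenary dome by its own fitted a
collapses every sample onto the parameter-free curve Y = cosh(X) - 1
(isometric collapse).  The "catenary-closest ellipse" is the ellipse dome
minimizing the mean squared vertical deviation from a given catenary over a
comparison window; its semi-axes scale linearly with a.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize

from .outline_geometry import StandardizedOutline

__all__ = [
    "CurveFamily",
    "FitResult",
    "CatenaryClosestEllipse",
    "CollapsedOutline",
    "FAMILIES",
    "FitError",
    "fit_family",
    "compare_families",
    "catenary_closest_ellipse",
    "isometric_collapse",
    "catenary_parameter_profile",
]

_PENALTY_SLOPE = 1e3  # continuous out-of-domain ramp for the ellipse (µm/µm)


class FitError(RuntimeError):
    """Nonlinear least squares failed to converge from every start."""


@dataclass(frozen=True)
class CurveFamily:
    name: str
    n_params: int
    evaluator: Callable[[np.ndarray, np.ndarray], np.ndarray]
    param_names: tuple[str, ...]

    def __call__(self, x: np.ndarray, params: np.ndarray) -> np.ndarray:
        return self.evaluator(np.asarray(x, float), np.asarray(params, float))


def _parabola(x, p):
    return p[0] * x**2


def _catenary(x, p):
    a = p[0]
    return a * np.cosh(x / a) - a


def _ellipse(x, p):
    a, b = p
    inside = 1.0 - (x / a) ** 2
    y = b * (1.0 - np.sqrt(np.clip(inside, 0.0, None)))
    # continuous penalty ramp outside |x| > a keeps the NLS objective finite
    return y + _PENALTY_SLOPE * np.clip(-inside, 0.0, None)


def _hyperbola(x, p):
    a, b = p
    return b * (np.sqrt(1.0 + (x / a) ** 2) - 1.0)


def _cosine(x, p):
    a, b = p
    return -a * np.cos(b * x) + a


FAMILIES: Mapping[str, CurveFamily] = {
    "parabola": CurveFamily("parabola", 1, _parabola, ("a1",)),
    "catenary": CurveFamily("catenary", 1, _catenary, ("a2",)),
    "ellipse": CurveFamily("ellipse", 2, _ellipse, ("a3", "b3")),
    "hyperbola": CurveFamily("hyperbola", 2, _hyperbola, ("a4", "b4")),
    "cosine": CurveFamily("cosine", 2, _cosine, ("a5", "b5")),
}


@dataclass(frozen=True)
class FitResult:
    family: CurveFamily
    params: np.ndarray
    sse: float               # µm²
    aic: float
    n_points: int
    converged: bool = True
    delta_aic: float = float("nan")
    cv_mse: float = float("nan")  # µm²
    sample_id: str = ""


@dataclass(frozen=True)
class CatenaryClosestEllipse:
    a_catenary: float
    a_ellipse: float
    b_ellipse: float
    closeness: float  # mean squared vertical deviation over the window, µm²
    window_halfwidth: float


@dataclass(frozen=True)
class CollapsedOutline:
    points: np.ndarray  # (n, 2) dimensionless (X, Y) = (x/a, y/a)
    a_used: float
    deviation: float    # RMS of Y - (cosh X - 1)
    sample_id: str = ""


# ---------------------------------------------------------------------------
# Fitting


def _aic(sse: float, n: int, k: int) -> float:
    sse = max(sse, 1e-300)
    return n * math.log(sse / n) + 2 * k


def _initial_grids(family: CurveFamily, x: np.ndarray,
                   y: np.ndarray) -> list[np.ndarray]:
    """Documented multistart grids, scaled to the data extent."""
    xmax = max(np.abs(x).max(), 1e-6)
    ymax = max(y.max(), 1e-6)
    if family.name == "parabola":
        return [np.array([ymax / xmax**2])]
    if family.name == "catenary":
        return [np.array([a]) for a in np.arange(5.0, 101.0, 5.0)]
    a_grid = xmax * np.geomspace(0.5, 8.0, 7)
    if family.name == "ellipse":
        return [np.array([a, b]) for a in np.maximum(a_grid, 1.01 * xmax)
                for b in ymax * np.geomspace(0.5, 8.0, 7)]
    if family.name == "hyperbola":
        return [np.array([a, b]) for a in a_grid
                for b in ymax * np.geomspace(0.25, 8.0, 7)]
    if family.name == "cosine":
        # frequency must keep the window within the first half-period rise
        return [np.array([a, f / xmax]) for a in ymax * np.geomspace(0.3, 4.0, 6)
                for f in np.geomspace(0.3, 3.0, 7)]
    raise KeyError(family.name)


def _fit_points(x: np.ndarray, y: np.ndarray, family: CurveFamily,
                starts: Sequence[np.ndarray] | None = None) -> tuple[np.ndarray, float, bool]:
    if family.name == "parabola":
        # linear least squares in a1, exact
        denom = float((x**4).sum())
        a1 = float((x**2 * y).sum() / denom) if denom > 0 else 0.0
        sse = float(((y - a1 * x**2) ** 2).sum())
        return np.array([a1]), sse, True

    def resid(p):
        return family(x, p) - y

    lo = np.full(family.n_params, 1e-8)
    hi = np.full(family.n_params, np.inf)
    grid = list(starts) if starts is not None else _initial_grids(family, x, y)
    if len(grid) > 6:
        # pre-screen the multistart grid by raw SSE, polish the best few
        sses = [float((resid(np.maximum(p0, 1e-6)) ** 2).sum()) for p0 in grid]
        grid = [grid[i] for i in np.argsort(sses)[:6]]
    best = None
    for p0 in grid:
        try:
            sol = least_squares(resid, np.maximum(p0, 1e-6), bounds=(lo, hi),
                                xtol=1e-13, ftol=1e-13, gtol=1e-13,
                                max_nfev=2000)
        except Exception:
            continue
        sse = float(2.0 * sol.cost)
        if best is None or sse < best[1] - 1e-15 or (
                abs(sse - best[1]) <= 1e-15
                and np.linalg.norm(sol.x) < np.linalg.norm(best[0])):
            best = (sol.x, sse, sol.success)
    if best is None:
        raise FitError(f"{family.name}: all starts failed")
    return best


def fit_family(std: StandardizedOutline, family: CurveFamily | str) -> FitResult:
    """Least-squares fit of one curve family to a standardized outline.

    SSE is the unnormalized sum of squared y-residuals; AIC uses the Gaussian
    profiled-likelihood form n*ln(SSE/n) + 2k with k = n_params.
    """
    if isinstance(family, str):
        family = FAMILIES[family]
    x, y = std.x, std.y
    if len(x) < family.n_params + 2:
        raise FitError(f"{family.name}: too few points ({len(x)})")
    params, sse, ok = _fit_points(x, y, family)
    return FitResult(family, params, sse, _aic(sse, len(x), family.n_params),
                     len(x), ok, sample_id=std.sample_id)


def compare_families(std: StandardizedOutline,
                     families: Sequence[str] | None = None,
                     cv_repeats: int = 100,
                     cv_test_fraction: float = 0.01,
                     seed: int | None = 0) -> list[FitResult]:
    """Fit all families, attach delta-AIC and repeated 99/1 cross-validation.

    Each CV repeat holds out ceil(cv_test_fraction * n) randomly chosen points
    (at least one), refits on the rest (warm-started at the full-data optimum),
    and scores the held-out MSE; cv_mse is the average over repeats.  A family
    that fails to fit is reported with infinite scores rather than dropped.
    """
    names = list(families) if families is not None else list(FAMILIES)
    rng = np.random.default_rng(seed)
    x, y = std.x, std.y
    n = len(x)
    n_test = max(1, math.ceil(cv_test_fraction * n))
    splits = [rng.choice(n, size=n_test, replace=False) for _ in range(cv_repeats)]

    results: list[FitResult] = []
    for name in names:
        fam = FAMILIES[name]
        try:
            base = fit_family(std, fam)
        except FitError:
            results.append(FitResult(fam, np.full(fam.n_params, np.nan),
                                     float("inf"), float("inf"), n, False,
                                     sample_id=std.sample_id))
            continue
        mses = []
        for test_idx in splits:
            mask = np.ones(n, bool)
            mask[test_idx] = False
            try:
                p, _, _ = _fit_points(x[mask], y[mask], fam, starts=[base.params])
                res = fam(x[test_idx], p) - y[test_idx]
                mses.append(float((res**2).mean()))
            except FitError:
                mses.append(float("inf"))
        results.append(replace(base, cv_mse=float(np.mean(mses))))

    best_aic = min(r.aic for r in results)
    return [replace(r, delta_aic=r.aic - best_aic) for r in results]


# ---------------------------------------------------------------------------
# Catenary-closest ellipse and isometric collapse


def _ellipse_catenary_msd(p: np.ndarray, xg: np.ndarray, cat: np.ndarray,
                          w: float) -> float:
    a, b = p
    if a <= w or b <= 0.0:
        return 1e12 + 1e6 * (max(w - a, 0.0) + max(-b, 0.0))
    diff = b * (1.0 - np.sqrt(1.0 - (xg / a) ** 2)) - cat
    return float((diff**2).mean())


def catenary_closest_ellipse(a_catenary: float, window_halfwidth: float,
                             n_grid: int = 401) -> CatenaryClosestEllipse:
    """Ellipse dome minimizing the mean squared vertical deviation from the
    catenary y = a cosh(x/a) - a over |x| <= window_halfwidth.

    Candidates whose semi-axis does not cover the window are rejected by a
    finite penalty.  The optimum scales linearly with a_catenary when the
    window does (dimensional analysis), so semi-axes plotted against a over a
    cohort are linear.
    """
    if a_catenary <= 0 or window_halfwidth <= 0:
        raise ValueError("a_catenary and window_halfwidth must be positive")
    a, w = float(a_catenary), float(window_halfwidth)
    xg = np.linspace(-w, w, n_grid)
    cat = a * np.cosh(xg / a) - a

    # coarse log grid, then simplex polish from the best few cells
    a_grid = w * np.geomspace(1.001, 40.0, 60)
    b_grid = max(cat.max(), 1e-9) * np.geomspace(0.3, 40.0, 60)
    vals = np.array([[_ellipse_catenary_msd(np.array([ae, be]), xg, cat, w)
                      for be in b_grid] for ae in a_grid])
    order = np.argsort(vals, axis=None)[:4]
    best = None
    for flat in order:
        i, j = np.unravel_index(flat, vals.shape)
        sol = minimize(_ellipse_catenary_msd, np.array([a_grid[i], b_grid[j]]),
                       args=(xg, cat, w), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 4000})
        if best is None or sol.fun < best.fun:
            best = sol
    ae, be = best.x
    return CatenaryClosestEllipse(a, float(ae), float(be), float(best.fun), w)


def isometric_collapse(std: StandardizedOutline, a: float) -> CollapsedOutline:
    """Rescale (x, y) -> (x/a, y/a) and score the RMS deviation from
    Y = cosh(X) - 1, the parameter-free catenary."""
    if a <= 0:
        raise ValueError("catenary parameter a must be positive")
    pts = std.points / a
    dev = pts[:, 1] - (np.cosh(pts[:, 0]) - 1.0)
    return CollapsedOutline(pts, float(a), float(np.sqrt((dev**2).mean())),
                            std.sample_id)


def catenary_parameter_profile(outlines: Sequence[StandardizedOutline]):
    """Table of (dome height h, fitted catenary a) per outline, sorted by h."""
    import pandas as pd

    rows = []
    for std in outlines:
        try:
            fit = fit_family(std, "catenary")
            rows.append((std.sample_id, std.height, float(fit.params[0]), ""))
        except FitError as exc:
            rows.append((std.sample_id, std.height, float("nan"), str(exc)))
    df = pd.DataFrame(rows, columns=["sample_id", "height_um", "a_um", "error"])
    return df.sort_values("height_um", ignore_index=True)
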