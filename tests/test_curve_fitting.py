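"""Five-family dome fits, AIC/CV model selection, ellipse proxy, collapse."""

import numpy as np
import pytest

from rootdome.curve_fitting import (FAMILIES, catenary_closest_ellipse,
                                    catenary_parameter_profile,
                                    compare_families, fit_family,
                                    isometric_collapse)
from rootdome.outline_geometry import RawOutline, StandardizedOutline, \
    unify_coordinates
from rootdome.synthetic_data import OutlineGeneratorSpec, generate_outline

from conftest import exact_outline

EXACT = {
    "parabola": (0.05,),
    "catenary": (30.0,),
    "ellipse": (60.0, 80.0),
    "hyperbola": (25.0, 40.0),
    "cosine": (30.0, 0.03),
}


# ---------------------------------------------------------------------------
# fit_family

@pytest.mark.parametrize("family,params", EXACT.items())
def test_exact_recovery_per_family(family, params):
    std = exact_outline(family, params)
    fit = fit_family(std, family)
    np.testing.assert_allclose(fit.params, params, rtol=1e-6)
    assert fit.sse < 1e-12


def test_point_permutation_invariance(catenary_std):
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(catenary_std.points))
    shuffled = StandardizedOutline("p", catenary_std.points[perm], 0)
    f1 = fit_family(catenary_std, "catenary")
    f2 = fit_family(shuffled, "catenary")
    np.testing.assert_allclose(f2.params, f1.params, atol=1e-6)


def test_noisy_catenary_matches_grid_search_oracle():
    rng = np.random.default_rng(7)
    std0 = exact_outline("catenary", (30.0,), height=50.0)
    noisy = StandardizedOutline(
        "n", std0.points + np.column_stack(
            [np.zeros(len(std0.points)), rng.normal(0, 1.0,
                                                    len(std0.points))]),
        std0.apex_index)
    fit = fit_family(noisy, "catenary")
    # brute-force oracle: refine a dense 1-d grid three times
    x, y = noisy.x, noisy.y

    def sse(a):
        return ((y - (a * np.cosh(x / a) - a)) ** 2).sum()

    lo, hi = 5.0, 100.0
    for _ in range(4):
        grid = np.linspace(lo, hi, 2001)
        vals = [sse(a) for a in grid]
        k = int(np.argmin(vals))
        lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    a_oracle = 0.5 * (lo + hi)
    assert fit.params[0] == pytest.approx(a_oracle, abs=1e-5)


def test_too_few_points_is_a_fit_error():
    from rootdome.curve_fitting import FitError
    std = StandardizedOutline("s", np.array([[-1.0, 1], [0, 0], [1, 1]]), 1)
    with pytest.raises(FitError):
        fit_family(std, "ellipse")


# ---------------------------------------------------------------------------
# compare_families

@pytest.mark.parametrize("family,params", EXACT.items())
def test_generating_family_wins_delta_aic(family, params):
    std = exact_outline(family, params)
    res = compare_families(std, cv_repeats=5, seed=0)
    by_name = {r.family.name: r for r in res}
    assert by_name[family].delta_aic == pytest.approx(0.0, abs=1e-9)
    assert by_name[family].cv_mse < 1e-12


def test_cv_is_seed_deterministic(catenary_std):
    r1 = compare_families(catenary_std, ["catenary", "parabola"],
                          cv_repeats=10, seed=42)
    r2 = compare_families(catenary_std, ["catenary", "parabola"],
                          cv_repeats=10, seed=42)
    assert [r.cv_mse for r in r1] == [r.cv_mse for r in r2]


def test_cv_calibrates_to_noise_variance_and_ranking():
    """With sigma = 1 µm y-noise, held-out MSE of the generating catenary
    family is ~ sigma^2, and the family ranking mirrors catenary <= ellipse
    < {parabola, hyperbola, cosine}."""
    rng = np.random.default_rng(123)
    mses = []
    rank_ok = 0
    n_rep = 12
    for _ in range(n_rep):
        std0 = exact_outline("catenary", (30.0,), height=50.0, spacing=7.0,
                             seed=int(rng.integers(2**31)))
        pts = std0.points.copy()
        pts[:, 1] += rng.normal(0, 1.0, len(pts))
        noisy = StandardizedOutline("n", pts, std0.apex_index)
        res = compare_families(noisy, cv_repeats=25,
                               seed=int(rng.integers(2**31)))
        by = {r.family.name: r.cv_mse for r in res}
        mses.append(by["catenary"])
        if (by["catenary"] <= by["ellipse"] * 1.05
                and by["ellipse"] < by["parabola"]
                and by["ellipse"] < by["hyperbola"]
                and by["ellipse"] < by["cosine"]):
            rank_ok += 1
    assert np.mean(mses) == pytest.approx(1.0, rel=0.5)
    assert rank_ok >= n_rep - 2


def test_failed_family_reported_with_infinite_scores():
    # three collinear-ish points cannot support a 2-parameter fit
    std = StandardizedOutline(
        "tiny", np.array([[-1.0, 1.0], [0.0, 0.0], [1.0, 1.0]]), 1)
    res = compare_families(std, ["catenary", "ellipse"], cv_repeats=2, seed=0)
    by = {r.family.name: r for r in res}
    assert np.isinf(by["ellipse"].aic)
    assert by["catenary"].delta_aic == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# catenary-closest ellipse

def test_closest_ellipse_scale_equivariance():
    r1 = catenary_closest_ellipse(1.0, 1.5)
    r2 = catenary_closest_ellipse(2.0, 3.0)
    assert r2.a_ellipse == pytest.approx(2 * r1.a_ellipse, rel=1e-4)
    assert r2.b_ellipse == pytest.approx(2 * r1.b_ellipse, rel=1e-4)
    # mean squared deviation carries µm²: scales as the square
    assert r2.closeness == pytest.approx(4 * r1.closeness, rel=1e-3)


def test_closest_ellipse_matches_brute_force_grid():
    res = catenary_closest_ellipse(1.0, 1.5)
    xg = np.linspace(-1.5, 1.5, 401)
    cat = np.cosh(xg) - 1.0

    def msd(ae, be):
        if ae <= 1.5:
            return np.inf
        return float(((be * (1 - np.sqrt(1 - (xg / ae) ** 2)) - cat) ** 2
                      ).mean())

    lo = np.array([1.5001, 0.1])
    hi = np.array([8.0, 10.0])
    for _ in range(4):
        A, B = np.meshgrid(np.linspace(lo[0], hi[0], 400),
                           np.linspace(lo[1], hi[1], 400), indexing="ij")
        V = np.vectorize(msd)(A, B)
        i, j = np.unravel_index(np.argmin(V), V.shape)
        da = (hi[0] - lo[0]) / 399
        db = (hi[1] - lo[1]) / 399
        # generous window: the valley is flat along a correlated direction
        lo = np.array([max(A[i, j] - 5 * da, 1.5001),
                       max(B[i, j] - 5 * db, 0.01)])
        hi = np.array([A[i, j] + 5 * da, B[i, j] + 5 * db])
    assert res.a_ellipse == pytest.approx(A[i, j], rel=1e-4)
    assert res.b_ellipse == pytest.approx(B[i, j], rel=1e-4)


def test_closest_ellipse_axes_linear_in_a():
    a_values = np.arange(10.0, 71.0, 10.0)
    rows = [catenary_closest_ellipse(a, 1.5 * a, n_grid=201)
            for a in a_values]
    for attr in ("a_ellipse", "b_ellipse"):
        yv = np.array([getattr(r, attr) for r in rows])
        r = np.corrcoef(a_values, yv)[0, 1]
        assert r**2 > 0.999


# ---------------------------------------------------------------------------
# isometric collapse

def test_exact_collapse_with_own_parameter():
    std = exact_outline("catenary", (4.0,), height=8.0, spacing=1.0)
    col = isometric_collapse(std, 4.0)
    assert col.deviation == pytest.approx(0.0, abs=1e-9)


def test_collapse_with_wrong_parameter_deviates():
    std = exact_outline("catenary", (4.0,), height=8.0, spacing=1.0)
    col = isometric_collapse(std, 8.0)
    # closed form at the sample points
    pts = std.points / 8.0
    expected = np.sqrt(np.mean(
        (pts[:, 1] - (np.cosh(pts[:, 0]) - 1.0)) ** 2))
    assert col.deviation == pytest.approx(expected, rel=1e-12)
    assert col.deviation > 0.01


def test_cohort_collapse_pooled_deviation():
    devs = []
    for a in (10.0, 30.0, 50.0, 70.0):
        std = exact_outline("catenary", (a,), height=1.2 * a)
        fit = fit_family(std, "catenary")
        devs.append(isometric_collapse(std, float(fit.params[0])).deviation)
    assert np.sqrt(np.mean(np.square(devs))) < 1e-6


# ---------------------------------------------------------------------------
# catenary parameter profile

def test_profile_truncation_invariance_and_sorting():
    outs = [exact_outline("catenary", (30.0,), height=h) for h in (50.0, 10.0)]
    df = catenary_parameter_profile(outs)
    assert list(df.height_um) == sorted(df.height_um)
    np.testing.assert_allclose(df.a_um, 30.0, rtol=1e-6)


def test_profile_empty_input():
    df = catenary_parameter_profile([])
    assert len(df) == 0
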