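"""Outline reading, coordinate unification and dome measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootdome.outline_geometry import (
    OutlineFormatError, OutlineGeometryError, RawOutline, close_outline,
    coefficient_of_variation, dome_measures, read_outlines, unify_coordinates,
    write_outlines)
from rootdome.synthetic_data import OutlineGeneratorSpec, generate_outline


# ---------------------------------------------------------------------------
# I/O

def test_csv_round_trip_is_lossless(tmp_path, v_outline):
    path = tmp_path / "o.csv"
    write_outlines([v_outline], path)
    (back,) = read_outlines(path)
    assert back.sample_id == "v"
    np.testing.assert_array_equal(back.points, v_outline.points)


def test_interleaved_samples_are_grouped_and_ordered(tmp_path):
    # hand-built CSV with three interleaved samples; oracle: parse by eye
    rows = ["sample_id,point_index,x_um,y_um"]
    for i in range(5):
        for sid in ("a", "b", "c"):
            rows.append(f"{sid},{4 - i},{i * 1.0},{i * 2.0}")
    path = tmp_path / "mix.csv"
    path.write_text("\n".join(rows) + "\n")
    outs = read_outlines(path)
    assert [o.sample_id for o in outs] == ["a", "b", "c"]
    for o in outs:
        # point_index descending in file -> sorted ascending on load
        np.testing.assert_allclose(o.points[:, 0], [4.0, 3.0, 2.0, 1.0, 0.0])


def test_missing_column_is_a_format_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("sample_id,point_index,x_um\na,0,1.0\n")
    with pytest.raises(OutlineFormatError, match="y_um"):
        read_outlines(path)


def test_short_sample_rejected_with_warning(tmp_path):
    rows = ["sample_id,point_index,x_um,y_um"]
    rows += [f"ok,{i},{i},{i * i}" for i in range(6)]
    rows += [f"tiny,{i},{i},{i}" for i in range(3)]
    path = tmp_path / "m.csv"
    path.write_text("\n".join(rows) + "\n")
    with pytest.warns(UserWarning, match="tiny"):
        outs = read_outlines(path)
    assert [o.sample_id for o in outs] == ["ok"]


def test_y_down_dialect_flips_sign(tmp_path, v_outline):
    path = tmp_path / "o.csv"
    write_outlines([v_outline], path)
    (flipped,) = read_outlines(path, dialect="y-down")
    np.testing.assert_allclose(flipped.points[:, 1], -v_outline.points[:, 1])


# ---------------------------------------------------------------------------
# Coordinate unification

def test_v_outline_is_a_fixed_point(v_outline):
    std = unify_coordinates(v_outline)
    np.testing.assert_allclose(std.points, v_outline.points, atol=1e-12)
    assert std.apex_index == 2


def test_translation_invariance(v_outline):
    shifted = RawOutline("v2", v_outline.points + np.array([10.0, 3.0]))
    std = unify_coordinates(shifted)
    np.testing.assert_allclose(std.points,
                               unify_coordinates(v_outline).points,
                               atol=1e-9)


def test_reversal_invariance(v_outline):
    rev = RawOutline("vr", v_outline.points[::-1])
    np.testing.assert_allclose(unify_coordinates(rev).points,
                               unify_coordinates(v_outline).points[::-1],
                               atol=1e-9)


def test_asymmetric_outline_against_hand_oracle():
    # six asymmetric points; apply the three steps by hand:
    pts = np.array([[1.0, 9.0], [2.0, 4.0], [3.0, 1.0],
                    [5.0, 2.0], [6.0, 5.0], [7.0, 8.0]])
    # (1) rotate 180 deg about the centroid c=(4, 4.8333...) -> 2c - p
    # (2) translate duplicates so min y(dup) = max y(orig) = 9:
    #     min y(dup) = 2*29/6 - 9; shift = 9 - (29/3 - 9)
    # (3) origin x = mean x of all = centroid x = 4; origin y = min y orig = 1
    expected = pts - np.array([4.0, 1.0])
    std = unify_coordinates(RawOutline("a", pts))
    np.testing.assert_allclose(std.points, expected, atol=1e-9)


def test_mirrored_closed_set_mean_x_is_zero(catenary_std):
    closed = close_outline(catenary_std)
    assert abs(closed.points[:, 0].mean()) < 1e-9


def test_collinear_outline_raises():
    pts = np.array([[0.0, y] for y in range(6)], dtype=float)
    with pytest.raises(OutlineGeometryError):
        unify_coordinates(RawOutline("col", pts))


# ---------------------------------------------------------------------------
# close_outline

def test_close_outline_doubles_points_and_is_pure(catenary_std):
    before = catenary_std.points.copy()
    closed = close_outline(catenary_std)
    assert closed.M == 2 * len(before)
    closed2 = close_outline(catenary_std)
    np.testing.assert_array_equal(closed.points, closed2.points)
    np.testing.assert_array_equal(catenary_std.points, before)


def test_close_outline_v_hand_construction(v_outline):
    std = unify_coordinates(v_outline)
    closed = close_outline(std)
    # duplicates: (-x, 2*4 - y) appended in index order
    expected_dup = np.array([[2.0, 4.0], [1.0, 7.0], [0.0, 8.0],
                             [-1.0, 7.0], [-2.0, 4.0]])
    np.testing.assert_allclose(closed.points[5:], expected_dup, atol=1e-12)


# ---------------------------------------------------------------------------
# dome measures

def test_rectangle_flanks_width_and_area():
    # vertical flanks at x = +-5: width 10, area 10*h at any cutoff
    pts = np.array([[-5.0, 8.0], [-5.0, 4.0], [-5.0, 0.0], [0.0, 0.0],
                    [5.0, 0.0], [5.0, 4.0], [5.0, 8.0]])
    std = unify_coordinates(RawOutline("r", pts))
    for h in (2.0, 4.0, 7.5):
        m = dome_measures(std, h)
        assert m.width == pytest.approx(10.0)
        assert m.area == pytest.approx(10.0 * h, rel=1e-9)


def test_triangle_width_by_similar_triangles():
    pts = np.array([[-4.0, 8.0], [-2.0, 4.0], [0.0, 0.0],
                    [2.0, 4.0], [4.0, 8.0]])
    std = unify_coordinates(RawOutline("t", pts))
    assert dome_measures(std, 4.0).width == pytest.approx(4.0)


def test_catenary_area_against_quadrature_oracle():
    from scipy.integrate import quad
    a, h = 20.0, 30.0
    spec = OutlineGeneratorSpec(family="catenary", params=(a,), height=h,
                                spacing=0.6, spacing_jitter=0.0, seed=0)
    std = unify_coordinates(generate_outline(spec))
    xh = a * np.arccosh(h / a + 1.0)
    oracle, _ = quad(lambda x: h - (a * np.cosh(x / a) - a), -xh, xh)
    m = dome_measures(std, h - 1e-9)
    assert m.area == pytest.approx(oracle, rel=2e-3)  # polygonal vs smooth


def test_measures_monotone_in_cutoff(catenary_std):
    hs = np.linspace(5.0, catenary_std.height, 12)
    ms = [dome_measures(catenary_std, h) for h in hs]
    areas = [m.area for m in ms]
    widths = [m.width for m in ms]
    assert np.all(np.diff(areas) >= -1e-9)
    assert np.all(np.diff(widths) >= -1e-9)


def test_cutoff_above_outline_raises(catenary_std):
    with pytest.raises(OutlineGeometryError):
        dome_measures(catenary_std, catenary_std.height + 1.0)


# ---------------------------------------------------------------------------
# coefficient of variation

def test_cv_constant_is_zero():
    assert coefficient_of_variation([10.0, 10.0, 10.0]) == 0.0


def test_cv_uses_sample_standard_deviation():
    # {9,10,11}: sample s.d. = 1, mean = 10 -> CV = 10%
    assert coefficient_of_variation([9.0, 10.0, 11.0]) == pytest.approx(10.0)


def test_cv_rejects_nonpositive_mean():
    with pytest.raises(ValueError):
        coefficient_of_variation([-1.0, 1.0])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(1.0, 1e3), min_size=2, max_size=30),
       st.floats(0.5, 50.0))
def test_cv_scale_invariance(values, k):
    assert coefficient_of_variation(values) == pytest.approx(
        coefficient_of_variation([k * v for v in values]), rel=1e-9, abs=1e-9)
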