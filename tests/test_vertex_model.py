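"""Vertex-model mechanics: energy, relaxation, division geometry."""

import numpy as np
import pytest

from rootdome.vertex_model import (FIXED, FREE, X_ONLY, Cell, EdgeData,
                                   ModelVariant, SimConfig, Tissue,
                                   build_initial_tissue, divide_cell, relax,
                                   short_axis_angle)
from rootdome.vertex_model.core import TissueGeometryError, edge_class


def square_cell(a0: float = 1.0, beta: float = 0.01,
                mobility: int = FREE) -> Tissue:
    verts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    mob = np.full(4, mobility, dtype=np.int8)
    cells = [Cell([0, 1, 2, 3], a0, "central", 0)]
    edges = {}
    for i, j in ((0, 1), (1, 2), (2, 3), (0, 3)):
        edges[(i, j)] = EdgeData(beta, edge_class(verts[i], verts[j]))
    return Tissue(verts, mob, cells, edges)


def random_tissue(seed: int = 0) -> Tissue:
    t = build_initial_tissue("wild_type")
    rng = np.random.default_rng(seed)
    jitter = rng.normal(0, 0.5, t.verts.shape)
    jitter[t.mobility == FIXED] = 0.0
    jitter[t.mobility == X_ONLY, 1] = 0.0
    t.verts = t.verts + jitter
    return t


# ---------------------------------------------------------------------------
# energy and forces

def test_unit_square_energy_closed_form():
    beta = 0.01
    t = square_cell(a0=1.0, beta=beta)
    # area term zero (A = A0 = 1); four unit edges each beta/2
    assert t.energy() == pytest.approx(4 * beta / 2.0, rel=1e-12)


def test_energy_is_bounded_below_by_zero_structure():
    t = square_cell(a0=1.0, beta=0.0)
    assert t.energy() == pytest.approx(0.0, abs=1e-15)


def test_forces_match_numerical_gradient():
    t = random_tissue(3)
    F = t.forces()
    eps = 1e-6
    rng = np.random.default_rng(0)
    for i in rng.choice(t.n_vertices, 8, replace=False):
        for d in (0, 1):
            if t.mobility[i] == FIXED or (t.mobility[i] == X_ONLY and d == 1):
                continue
            t.verts[i, d] += eps
            ep = t.energy()
            t.verts[i, d] -= 2 * eps
            em = t.energy()
            t.verts[i, d] += eps
            num = -(ep - em) / (2 * eps)
            assert F[i, d] == pytest.approx(num, rel=1e-4, abs=1e-8)


def test_negative_area_is_a_geometry_error():
    t = square_cell()
    t.cells[0].cycle = [0, 3, 2, 1]  # clockwise -> negative area
    t.invalidate()
    with pytest.raises(TissueGeometryError):
        t.energy()


# ---------------------------------------------------------------------------
# relaxation

def solve_free_rectangle(a0, beta_h, beta_v, c=1.0):
    """Stationarity of one rectangular cell: width w, height h free.
    E = (c/2)(wh - a0)^2/a0 + beta_h w^2 + beta_v h^2."""
    from scipy.optimize import fsolve

    def eqs(p):
        w, h = p
        press = c * (w * h - a0) / a0
        return [press * h + 2 * beta_h * w, press * w + 2 * beta_v * h]

    w, h = fsolve(eqs, [np.sqrt(a0), np.sqrt(a0)], xtol=1e-13)
    return w, h


@pytest.mark.parametrize("method", ["lbfgs", "euler"])
def test_single_cell_relaxes_to_analytic_rectangle(method):
    beta_h, beta_v = 0.002, 0.004
    t = square_cell(a0=56.0, beta=0.0)
    t.verts = np.array([[0.0, 0.0], [14.0, 0.0], [14.0, 4.0], [0.0, 4.0]])
    t.edges[(0, 1)] = EdgeData(beta_h, "h")
    t.edges[(2, 3)] = EdgeData(beta_h, "h")
    t.edges[(1, 2)] = EdgeData(beta_v, "v")
    t.edges[(0, 3)] = EdgeData(beta_v, "v")
    # pin one corner and the base line to remove rigid-body freedom
    t.mobility = np.array([FIXED, X_ONLY, FREE, FREE], dtype=np.int8)
    info = relax(t, tol=1e-10, method=method, dt=1.0, max_steps=400_000)
    assert info.converged
    w = t.verts[1, 0] - t.verts[0, 0]
    h = 0.5 * (t.verts[2, 1] + t.verts[3, 1])
    w_ref, h_ref = solve_free_rectangle(56.0, beta_h, beta_v)
    assert w == pytest.approx(w_ref, rel=1e-5)
    assert h == pytest.approx(h_ref, rel=1e-5)


def test_relax_never_increases_energy():
    t = random_tissue(7)
    e0 = t.energy()
    info = relax(t, tol=1e-7)
    assert info.e_final <= e0 + 1e-9
    assert info.residual < 1e-7


def test_euler_and_lbfgs_reach_the_same_equilibrium():
    t1, t2 = random_tissue(11), random_tissue(11)
    relax(t1, tol=1e-7, method="lbfgs")
    relax(t2, tol=1e-7, method="euler", dt=1.0, max_steps=200_000)
    assert np.abs(t1.verts - t2.verts).max() < 1e-2


def test_dt_halving_changes_equilibrium_below_tenth_micron():
    t1, t2 = random_tissue(5), random_tissue(5)
    relax(t1, tol=1e-6, method="euler", dt=1.0, max_steps=200_000)
    relax(t2, tol=1e-6, method="euler", dt=0.5, max_steps=400_000)
    assert np.abs(t1.verts - t2.verts).max() < 0.1


def test_mirror_symmetric_tissue_stays_symmetric():
    t = build_initial_tissue("wild_type")
    relax(t, tol=1e-9)
    v = t.verts
    flip = v * np.array([-1.0, 1.0])
    mismatch = max(np.abs(v - flip[None, i]).sum(axis=1).min()
                   for i in range(len(v)))
    assert mismatch < 1e-6


# ---------------------------------------------------------------------------
# division

def test_periclinal_split_of_unit_square():
    t = square_cell(a0=1.0)
    ia, ib = divide_cell(t, 0, "periclinal", noise_sd_deg=0.0,
                         rng=np.random.default_rng(0))
    areas = [t.cell_area(t.cells[ia]), t.cell_area(t.cells[ib])]
    np.testing.assert_allclose(areas, [0.5, 0.5], atol=1e-12)
    # interface is horizontal through the centroid
    k1, k2 = t.n_vertices - 2, t.n_vertices - 1
    np.testing.assert_allclose(t.verts[[k1, k2], 1], 0.5, atol=1e-12)
    assert t.cells[ia].target_area == pytest.approx(0.5)
    assert t.cells[ia].divisions_done == 1


def test_random_orientation_is_seeded_and_conserves_area():
    t1, t2 = square_cell(), square_cell()
    for t in (t1, t2):
        divide_cell(t, 0, "random", noise_sd_deg=0.0,
                    rng=np.random.default_rng(99))
    np.testing.assert_array_equal(t1.verts, t2.verts)
    total = sum(t1.cell_area(c) for c in t1.cells)
    assert total == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("w,h,expect_vertical_cut", [(4.0, 1.0, True),
                                                     (1.0, 4.0, False)])
def test_short_axis_of_rectangles(w, h, expect_vertical_cut):
    # the division line runs ALONG the short axis: a wide flat cell is cut
    # vertically (across its long axis), a tall cell horizontally
    t = square_cell()
    t.verts = np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]])
    ang = short_axis_angle(t, t.cells[0]) % np.pi
    vertical = abs(ang - np.pi / 2) < 1e-6
    assert vertical == expect_vertical_cut


def test_short_axis_matches_brute_force_on_irregular_hexagon():
    t = square_cell()
    poly = np.array([[0.0, 0.0], [3.0, -0.4], [5.2, 0.8], [4.8, 2.0],
                     [2.0, 2.4], [-0.5, 1.2]])
    t.verts = poly
    t.cells[0].cycle = [0, 1, 2, 3, 4, 5]
    t.invalidate()
    ang = short_axis_angle(t, t.cells[0]) % np.pi

    # brute force oracle on a dense point grid: the long axis minimizes the
    # second moment about the line through the centroid; the short axis is
    # perpendicular to it
    c = t.cell_centroid(t.cells[0])
    from matplotlib.path import Path as MplPath
    gx, gy = np.meshgrid(np.linspace(-1, 6, 701), np.linspace(-1, 3, 401))
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = MplPath(poly).contains_points(pts)
    P = pts[inside] - c
    grid = np.linspace(0, np.pi, 1801)[:-1]
    moments = [np.mean((P[:, 1] * np.cos(th) - P[:, 0] * np.sin(th)) ** 2)
               for th in grid]
    long_axis = grid[int(np.argmin(moments))]
    short_axis = (long_axis + np.pi / 2) % np.pi
    diff = min(abs(ang - short_axis), np.pi - abs(ang - short_axis))
    assert diff < np.deg2rad(1.0)


def test_division_registers_vertex_with_neighbor_cells():
    t = build_initial_tissue("wild_type")
    # divide cell 9 (central) anticlinally: the cut crosses its top edge,
    # which is shared with the overlay
    overlay = t.overlay()
    n_before = len(overlay.cycle)
    divide_cell(t, 9, "anticlinal", 0.0, np.random.default_rng(0))
    assert len(overlay.cycle) == n_before + 1


def test_total_area_conserved_across_division():
    t = build_initial_tissue("no_overlay")
    before = t.areas().sum()
    divide_cell(t, 10, "periclinal", 0.1, np.random.default_rng(1))
    assert t.areas().sum() == pytest.approx(before, abs=1e-9)


def test_adjacent_synchronous_divisions_share_the_interface_vertex():
    # both central cells divide periclinally at the same height: the second
    # cut must snap to the vertex the first inserted on the shared wall
    t = build_initial_tissue("wild_type")
    nv0 = t.n_vertices
    divide_cell(t, 9, "periclinal", 0.0, np.random.default_rng(0))
    divide_cell(t, 10, "periclinal", 0.0, np.random.default_rng(0))
    # 2 + 2 cuts, but one crossing reused -> 3 new vertices, not 4
    assert t.n_vertices == nv0 + 3


# ---------------------------------------------------------------------------
# initial tissue

def test_wild_type_initial_tissue_layout():
    t = build_initial_tissue("wild_type")
    tissue_cells = t.tissue_cells()
    assert len(tissue_cells) == 20
    roles = [c.role for c in tissue_cells]
    assert roles.count("central") == 2
    assert roles.count("flanking") == 2
    assert roles.count("peripheral") == 16
    np.testing.assert_allclose(t.areas()[:20], 56.0)
    assert t.verts[:, 0].min() == -140.0 and t.verts[:, 0].max() == 140.0
    overlay = t.overlay()
    assert overlay is not None
    assert overlay.target_area == pytest.approx(10080.0)
    assert t.cell_area(overlay) == pytest.approx(10080.0)


def test_variant_role_maps():
    shallow = build_initial_tissue("shallow_gradient")
    assert sum(c.role == "flanking" for c in shallow.tissue_cells()) == 6
    shallower = build_initial_tissue("shallower_gradient")
    assert sum(c.role == "flanking" for c in shallower.tissue_cells()) == 8
    wide = build_initial_tissue("increasing_central_zone")
    assert sum(c.role == "central" for c in wide.tissue_cells()) == 4
    bare = build_initial_tissue("no_overlay")
    assert bare.overlay() is None
    assert len(bare.tissue_cells()) == 20


def test_unknown_variant_rejected():
    with pytest.raises(ValueError):
        ModelVariant("mystery_variant")
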