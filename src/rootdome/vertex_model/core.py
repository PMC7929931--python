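"""Cell-vertex tissue mechanics: polygonal cells, energy, relaxation, division.

Cells are simple polygons sharing vertices and edges in a planar complex.  The
mechanical energy is the minimal standard vertex model consistent with an
area-elastic cell interior and length-tension walls:

    E = sum_cells (c/2) * (A_n - A0_n)**2 / A0_n + sum_edges (beta_ij/2) * L_ij**2

with area elasticity c = 1, per-edge wall extensibility beta_ij (µm;
horizontal edges 0.002, vertical 0.004 by default) and L_ij the edge length.
The area term is normalized by the target area, making the pressure a cell
exerts its relative area strain (see Tissue.energy for why).
Vertices move down the energy gradient (overdamped first-order dynamics)
subject to mobility constraints: free, x-displaceable only (basal vertices
pinned to the parent xylem at y = 0), or fully fixed (lateral clamps).

Equilibria can be reached either by the forward-Euler integrator on
dx/dt = -dE/dx (the dynamical reference, used to verify insensitivity to the
time step) or, by default, by L-BFGS-B minimization of the same energy with
the same analytic gradient, which reaches the identical equilibria orders of
magnitude faster on this stiffness ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FREE", "X_ONLY", "FIXED",
    "Cell", "EdgeData", "Tissue", "RelaxInfo",
    "TissueGeometryError", "RelaxationError",
    "relax", "divide_cell", "short_axis_angle",
]

FREE, X_ONLY, FIXED = 0, 1, 2

_ORIENTATIONS = ("periclinal", "anticlinal", "random", "short_axis")


class TissueGeometryError(RuntimeError):
    """Degenerate polygon, corrupted topology, or an impossible division."""


class RelaxationError(RuntimeError):
    """Energy increased beyond tolerance / relaxation failed to converge."""


@dataclass
class EdgeData:
    beta: float              # wall extensibility, µm
    klass: str               # "h" (horizontal) or "v" (vertical) at creation


@dataclass
class Cell:
    cycle: list[int]         # vertex indices, counter-clockwise
    target_area: float       # A0, µm²
    role: str                # central/flanking/peripheral/provascular/overlay
    lineage: int
    divisions_done: int = 0
    growing: bool = False
    growth_rate: float = 0.0          # dA0/dt, µm²/h
    division_threshold: float = np.inf  # area triggering the next division, µm²
    area_stiffness: float | None = None  # per-cell c override (overlay only)


def _edge_key(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


def edge_class(p: np.ndarray, q: np.ndarray) -> str:
    """Orientation class at creation: horizontal if |dy| <= |dx|."""
    d = q - p
    return "h" if abs(d[1]) <= abs(d[0]) else "v"


class Tissue:
    """Mutable polygonal-cell complex with cached force arrays."""

    def __init__(self, verts: np.ndarray, mobility: np.ndarray,
                 cells: list[Cell], edges: dict[tuple[int, int], EdgeData],
                 c_area: float = 1.0, time: float = 0.0,
                 dividing_zone: tuple[float, float] = (0.0, 0.0)):
        self.verts = np.asarray(verts, dtype=float)
        self.mobility = np.asarray(mobility, dtype=np.int8)
        self.cells = cells
        self.edges = edges
        self.c_area = float(c_area)
        self.time = float(time)
        self.dividing_zone = dividing_zone  # x-range of central+flanking files
        self._cache = None

    # -- bookkeeping --------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.verts)

    def tissue_cells(self) -> list[Cell]:
        return [c for c in self.cells if c.role != "overlay"]

    def overlay(self) -> Cell | None:
        for c in self.cells:
            if c.role == "overlay":
                return c
        return None

    def invalidate(self) -> None:
        self._cache = None

    def copy(self) -> "Tissue":
        t = Tissue(self.verts.copy(), self.mobility.copy(),
                   [replace(c, cycle=list(c.cycle)) for c in self.cells],
                   {k: replace(v) for k, v in self.edges.items()},
                   self.c_area, self.time, self.dividing_zone)
        return t

    def _arrays(self):
        if self._cache is None:
            idx, nxt, prv, cid = [], [], [], []
            for ci, cell in enumerate(self.cells):
                cyc = cell.cycle
                m = len(cyc)
                for k in range(m):
                    idx.append(cyc[k])
                    nxt.append(cyc[(k + 1) % m])
                    prv.append(cyc[(k - 1) % m])
                    cid.append(ci)
            ekeys = list(self.edges)
            self._cache = dict(
                idx=np.array(idx), nxt=np.array(nxt), prv=np.array(prv),
                cid=np.array(cid),
                ei=np.array([k[0] for k in ekeys], dtype=int),
                ej=np.array([k[1] for k in ekeys], dtype=int),
                ekeys=ekeys,
            )
        cache = self._cache
        cache["beta"] = np.array([self.edges[k].beta for k in cache["ekeys"]])
        return cache

    # -- geometry -----------------------------------------------------------

    def cell_area(self, cell: Cell) -> float:
        p = self.verts[cell.cycle]
        x, y = p[:, 0], p[:, 1]
        return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))

    def areas(self) -> np.ndarray:
        a = self._arrays()
        x, y = self.verts[:, 0], self.verts[:, 1]
        contrib = x[a["idx"]] * y[a["nxt"]] - x[a["nxt"]] * y[a["idx"]]
        out = np.zeros(len(self.cells))
        np.add.at(out, a["cid"], contrib)
        return 0.5 * out

    def cell_centroid(self, cell: Cell) -> np.ndarray:
        p = self.verts[cell.cycle]
        x, y = p[:, 0], p[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        area = 0.5 * cross.sum()
        if abs(area) < 1e-12:
            raise TissueGeometryError("degenerate polygon (zero area)")
        cx = ((x + xn) * cross).sum() / (6.0 * area)
        cy = ((y + yn) * cross).sum() / (6.0 * area)
        return np.array([cx, cy])

    # -- mechanics ----------------------------------------------------------

    def _cell_stiffness(self) -> np.ndarray:
        return np.array([self.c_area if c.area_stiffness is None
                         else c.area_stiffness for c in self.cells])

    def energy(self) -> float:
        """E = sum (c/2) (A_n - A0)^2 / A0 + sum (beta/2) L^2.

        The area term is normalized per cell size, so the pressure
        dE/dA = c (A - A0)/A0 is the relative area strain: cells of very
        different sizes (a 56 µm² meristem cell, the 10,080 µm² overlay)
        exert comparable pressures at comparable strains, and the area and
        wall-tension forces share a scale, which is what lets the wall
        anisotropy set cell aspect ratios at all."""
        a = self._arrays()
        areas = self.areas()
        if np.any(areas[[c.role != "overlay" for c in self.cells]] <= 0.0):
            raise TissueGeometryError("non-positive cell area")
        a0 = np.array([c.target_area for c in self.cells])
        e_area = 0.5 * float(
            (self._cell_stiffness() * (areas - a0) ** 2 / a0).sum())
        d = self.verts[a["ei"]] - self.verts[a["ej"]]
        e_edge = 0.5 * float((a["beta"] * (d**2).sum(axis=1)).sum())
        return e_area + e_edge

    def forces(self) -> np.ndarray:
        """F = -dE/dx per vertex, with mobility constraints applied."""
        a = self._arrays()
        areas = self.areas()
        a0 = np.array([c.target_area for c in self.cells])
        press = self._cell_stiffness() * (areas - a0) / a0  # dE/dA per cell
        x, y = self.verts[:, 0], self.verts[:, 1]
        # dA/dx_i = 0.5 (y_next - y_prev); dA/dy_i = 0.5 (x_prev - x_next)
        gx = 0.5 * (y[a["nxt"]] - y[a["prv"]]) * press[a["cid"]]
        gy = 0.5 * (x[a["prv"]] - x[a["nxt"]]) * press[a["cid"]]
        F = np.zeros_like(self.verts)
        np.add.at(F[:, 0], a["idx"], -gx)
        np.add.at(F[:, 1], a["idx"], -gy)
        d = self.verts[a["ei"]] - self.verts[a["ej"]]
        f = a["beta"][:, None] * d
        np.add.at(F, a["ei"], -f)
        np.add.at(F, a["ej"], f)
        F[self.mobility == FIXED] = 0.0
        F[self.mobility == X_ONLY, 1] = 0.0
        return F

    def max_force(self) -> float:
        return float(np.abs(self.forces()).max())


@dataclass(frozen=True)
class RelaxInfo:
    e_initial: float
    e_final: float
    residual: float
    n_iterations: int
    converged: bool


def _free_dof_mask(t: Tissue) -> np.ndarray:
    mask = np.ones((t.n_vertices, 2), dtype=bool)
    mask[t.mobility == FIXED] = False
    mask[t.mobility == X_ONLY, 1] = False
    return mask.ravel()


def relax(t: Tissue, tol: float = 1e-6, max_steps: int = 200_000,
          dt: float = 5e-3, method: str = "lbfgs") -> RelaxInfo:
    """Drive the tissue to mechanical equilibrium (max free-vertex force < tol).

    ``method='euler'``: explicit forward Euler on dx/dt = F with adaptive step
    acceptance — a step that raises the energy is rejected and retried at
    half the step size (so the energy is non-increasing across accepted
    steps), and the step recovers geometrically after accepted steps.
    ``method='lbfgs'`` (default): L-BFGS-B on the same energy and gradient.
    Mutates the tissue in place and returns convergence diagnostics.
    """
    e0 = t.energy()
    if method == "euler":
        e = e0
        h = dt
        it = 0
        while it < max_steps:
            F = t.forces()
            res = float(np.abs(F).max())
            if res < tol:
                return RelaxInfo(e0, e, res, it, True)
            trial = t.verts + h * F
            saved = t.verts
            t.verts = trial
            try:
                e_new = t.energy()
            except TissueGeometryError:
                e_new = np.inf
            if e_new <= e + 1e-12 * max(1.0, abs(e)):
                e = e_new
                h = min(h * 1.1, dt)
            else:
                t.verts = saved
                h *= 0.5
                if h < 1e-12:
                    raise RelaxationError(
                        "step size underflow: energy increases at every scale")
            it += 1
        return RelaxInfo(e0, t.energy(), t.max_force(), it, False)

    if method != "lbfgs":
        raise ValueError(f"unknown relaxation method {method!r}")

    from scipy.optimize import minimize

    mask = _free_dof_mask(t)
    x_full = t.verts.ravel().copy()

    def fun(z):
        x_full[mask] = z
        t.verts = x_full.reshape(-1, 2)
        try:
            e = t.energy()
        except TissueGeometryError:
            return 1e30, np.zeros(mask.sum())
        g = -t.forces().ravel()[mask]
        return e, g

    z0 = x_full[mask]
    nit = 0
    for attempt in range(6):
        sol = minimize(fun, z0, jac=True, method="L-BFGS-B",
                       options={"gtol": 0.3 * tol, "ftol": 1e-18,
                                "maxiter": 50_000, "maxcor": 20})
        nit += sol.nit
        z0 = sol.x
        fun(z0)
        res = t.max_force()
        if res < tol:
            e1 = t.energy()
            if e1 > e0 + 1e-9 * max(1.0, abs(e0)):
                raise RelaxationError("energy increased during relaxation")
            return RelaxInfo(e0, e1, res, nit, True)
    return RelaxInfo(e0, t.energy(), t.max_force(), nit, False)


# ---------------------------------------------------------------------------
# Cell division


def short_axis_angle(t: Tissue, cell: Cell) -> float:
    """Direction of the short principal axis of the cell polygon (rad).

    Principal axes of the uniform-density polygon second moments about the
    centroid; the division line runs along the short (minor) axis, i.e.
    perpendicular to the cell's long axis.
    """
    p = t.verts[cell.cycle] - t.cell_centroid(cell)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    ixx = (cross * (y**2 + y * yn + yn**2)).sum() / 12.0
    iyy = (cross * (x**2 + x * xn + xn**2)).sum() / 12.0
    ixy = (cross * (x * yn + 2 * x * y + 2 * xn * yn + xn * y)).sum() / 24.0
    if a < 0:
        ixx, iyy, ixy = -ixx, -iyy, -ixy
    # covariance-like matrix [[iyy? ...]] -> second moments of x and y
    cov = np.array([[iyy, ixy], [ixy, ixx]])
    w, v = np.linalg.eigh(cov)
    minor = v[:, 0]  # eigenvector of the smaller spatial variance
    return float(np.arctan2(minor[1], minor[0]))


def _division_angle(t: Tissue, cell: Cell, orientation: str,
                    noise_sd_deg: float, rng: np.random.Generator) -> float:
    if orientation == "periclinal":
        angle = 0.0
    elif orientation == "anticlinal":
        angle = np.pi / 2.0
    elif orientation == "random":
        angle = float(rng.uniform(0.0, np.pi))
    elif orientation == "short_axis":
        angle = short_axis_angle(t, cell)
    else:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    if noise_sd_deg > 0.0:
        angle += float(rng.normal(0.0, np.deg2rad(noise_sd_deg)))
    return angle


def _line_polygon_crossings(t: Tissue, cell: Cell, center: np.ndarray,
                            direction: np.ndarray, eps: float = 1e-7):
    """The two boundary crossings of the centroid line, one on each side.

    A crossing that falls (within ``eps`` µm) on an existing vertex snaps to
    that vertex and reuses it — this happens systematically when adjacent
    cells divide in the same synchronous batch and their interfaces meet at a
    shared wall.  Returns two hits [(cycle position, vertex id or None,
    point), ...] sorted by cycle position, or None if the cut is degenerate
    (misses the polygon, or runs along an edge).
    """
    cyc = cell.cycle
    m = len(cyc)
    nrm = np.array([-direction[1], direction[0]])
    dist = np.array([float(np.dot(t.verts[v] - center, nrm)) for v in cyc])
    on_line = np.abs(dist) < eps

    hits = []  # (cycle position, vertex id or None, point, t along line)
    for k in range(m):
        if on_line[k]:
            pt = t.verts[cyc[k]]
            hits.append((k, cyc[k], pt.copy(),
                         float(np.dot(pt - center, direction))))
    for k in range(m):
        k1 = (k + 1) % m
        if on_line[k] or on_line[k1]:
            continue
        dp, dq = dist[k], dist[k1]
        if dp * dq >= 0.0:
            continue
        s = dp / (dp - dq)
        p, q = t.verts[cyc[k]], t.verts[cyc[k1]]
        pt = p + s * (q - p)
        hits.append((k, None, pt, float(np.dot(pt - center, direction))))
    pos = [h for h in hits if h[3] > 0.0]
    neg = [h for h in hits if h[3] <= 0.0]
    if not pos or not neg:
        return None
    a = min(pos, key=lambda h: h[3])
    b = max(neg, key=lambda h: h[3])
    if a[1] is not None and b[1] is not None:
        key = _edge_key(a[1], b[1])
        if key in t.edges:
            return None  # the cut would run along an existing edge
    return sorted([a[:3], b[:3]], key=lambda h: h[0])


def _insert_vertex_on_edge(t: Tissue, i: int, j: int, new: int) -> None:
    """Register vertex ``new`` between adjacent vertices i, j in every cell
    (including the overlay) and split the edge record."""
    for cell in t.cells:
        cyc = cell.cycle
        m = len(cyc)
        for k in range(m):
            a, b = cyc[k], cyc[(k + 1) % m]
            if (a, b) == (i, j) or (a, b) == (j, i):
                cyc.insert(k + 1, new)
                break
    data = t.edges.pop(_edge_key(i, j))
    t.edges[_edge_key(i, new)] = replace(data)
    t.edges[_edge_key(new, j)] = replace(data)


def divide_cell(t: Tissue, cell_index: int, orientation: str = "short_axis",
                noise_sd_deg: float = 0.1,
                rng: np.random.Generator | None = None,
                beta_h: float = 0.002, beta_v: float = 0.004,
                max_retries: int = 8) -> tuple[int, int]:
    """Split a cell by a line through its geometric center.

    The division plane passes through the polygon centroid at the requested
    orientation (periclinal = horizontal, anticlinal = vertical, random =
    uniform on [0, pi), short_axis = minor principal axis) plus Gaussian
    angular noise.  Two new vertices are inserted at the boundary crossings
    and registered with every neighboring cell; the new interface edge gets
    the extensibility matching its geometric orientation class.  Each daughter
    inherits the mother's role and lineage and receives target area A_n/2.
    Degenerate cuts are retried with re-sampled noise.  Returns the two
    daughter cell indices (the first reuses the mother's slot).
    """
    rng = rng if rng is not None else np.random.default_rng()
    cell = t.cells[cell_index]
    if cell.role == "overlay":
        raise TissueGeometryError("the overlay cell does not divide")
    center = t.cell_centroid(cell)
    area = t.cell_area(cell)
    if area <= 0:
        raise TissueGeometryError("cannot divide a degenerate cell")

    crossings = None
    for attempt in range(max_retries):
        # escalate the angular jitter if the cut keeps degenerating (grazing
        # vertices, running along an edge, or missing a sliver polygon)
        trial_noise = noise_sd_deg if attempt == 0 else max(
            noise_sd_deg, 0.5 * attempt)
        angle = _division_angle(t, cell, orientation, trial_noise, rng)
        direction = np.array([np.cos(angle), np.sin(angle)])
        crossings = _line_polygon_crossings(t, cell, center, direction)
        if crossings is not None and not (
                crossings[0][1] is not None
                and crossings[0][1] == crossings[1][1]):
            break
        crossings = None
    if crossings is None:
        raise TissueGeometryError("division line misses the polygon")

    cyc = list(cell.cycle)
    ids = []
    for k, vid, pt in crossings:
        if vid is not None:
            ids.append(vid)
            continue
        ea, eb = cyc[k], cyc[(k + 1) % len(cyc)]
        new = t.n_vertices
        on_base = abs(pt[1]) < 1e-9 and all(
            t.mobility[v] in (X_ONLY, FIXED) for v in (ea, eb))
        t.verts = np.vstack([t.verts, pt[None, :]])
        t.mobility = np.append(
            t.mobility, np.int8(X_ONLY if on_base else FREE))
        _insert_vertex_on_edge(t, ea, eb, new)
        ids.append(new)
    n1, n2 = ids

    # rebuild the two daughter cycles from the mother's (now updated) cycle
    cyc = list(cell.cycle)
    a1, a2 = cyc.index(n1), cyc.index(n2)
    if a1 > a2:
        a1, a2 = a2, a1
        n1, n2 = n2, n1
    cyc_a = cyc[a1:a2 + 1]             # n1 ... n2
    cyc_b = cyc[a2:] + cyc[:a1 + 1]    # n2 ... n1
    iface = edge_class(t.verts[n1], t.verts[n2])
    t.edges[_edge_key(n1, n2)] = EdgeData(
        beta_h if iface == "h" else beta_v, iface)

    half = 0.5 * area
    daughter_a = replace(cell, cycle=cyc_a, target_area=half,
                         divisions_done=cell.divisions_done + 1)
    daughter_b = replace(cell, cycle=cyc_b, target_area=half,
                         divisions_done=cell.divisions_done + 1)
    t.cells[cell_index] = daughter_a
    t.cells.append(daughter_b)
    t.invalidate()

    total_after = t.cell_area(daughter_a) + t.cell_area(daughter_b)
    if abs(total_after - area) > 1e-9 * max(1.0, area):
        raise TissueGeometryError("area not conserved across division")
    return cell_index, len(t.cells) - 1
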