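"""Staged growth program of the lateral-root-primordium simulation.

The tissue starts as a flat file of 20 cells (14 µm wide, 4 µm tall, target
area 56 µm²) spanning x in [-140, 140] µm, clamped at both lateral ends,
basal vertices sliding on y = 0, and (except in the no-overlay variant) an
overlaying parental mass of target area 36 µm x 20 cells x 14 µm/cell =
10,080 µm² pressing from above until the dome reaches 40 µm.

Division timing is area-triggered: a cell divides when its area reaches twice
the target it was born with (Gaussian threshold noise, s.d. 5.6 µm²), its
target area having grown linearly in time between events.  Orientation
follows the wild-type program — central files divide periclinally, then
anticlinally, then periclinally (the four-layer stage), then along their
short axis until the central lineage reaches the stage-VII cell count; each
flanking file divides periclinally once; peripheral files never divide.  The
final phase switches the two central basal cells to rapid provascular
expansion with their vertical walls softening from 0.002 to 0.0005 µm.

Variants perturb one rule each: extra low-division-rate flanking files
(shallow / shallower gradient), a wider central zone, uniformly random
division angles in the central domain, or no overlay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..outline_geometry import RawOutline, StandardizedOutline, unify_coordinates
from .core import (FREE, FIXED, X_ONLY, Cell, EdgeData, RelaxationError,
                   Tissue, TissueGeometryError, divide_cell, edge_class,
                   relax)

__all__ = [
    "SimConfig", "ModelVariant", "Snapshot", "VARIANTS",
    "build_initial_tissue", "run_simulation", "extract_dome_outline",
    "apical_chain",
]

VARIANTS = ("wild_type", "shallow_gradient", "shallower_gradient",
            "increasing_central_zone", "randomized_division", "no_overlay")


@dataclass(frozen=True)
class SimConfig:
    """Tunable parameters of the growth simulation (units in comments)."""

    n_files: int = 20                 # initial cell files
    cell_width: float = 14.0          # µm
    init_target: float = 56.0         # initial A0, µm² (=> 4 µm tall files)
    c_area: float = 1.0               # µm^-2
    beta_h: float = 0.002             # µm, horizontal edges
    beta_v: float = 0.004             # µm, vertical edges
    beta_v_pv_start: float = 0.002    # µm, provascular vertical walls at ramp start
    beta_v_pv_end: float = 0.0005     # µm, ... at ramp end
    overlay_thickness: float = 36.0   # µm
    overlay_removal_height: float = 40.0  # µm (apical y)
    rate_normal: float = 5.6          # dA0/dt, µm²/h
    rate_provascular: float = 28.0    # µm²/h
    trigger_sd: float = 5.6           # division-threshold noise, µm²
    plane_noise_sd_deg: float = 0.1   # division-plane angular noise
    central_program: tuple[str, ...] = ("periclinal", "anticlinal", "periclinal")
    stage_vii_central_target: int = 32
    pv_duration: float = 10.0         # h, beta ramp span
    dt_growth: float = 0.5            # h
    snapshot_interval: float = 2.0    # h
    stop_height: float = 55.0         # µm (apical y)
    max_time: float = 120.0           # h
    relax_tol: float = 1e-6           # force tolerance
    relax_method: str = "lbfgs"
    crop_margin: float = 0.75         # µm above the apron for outline cropping
    # variant knobs
    extra_flanking_per_side: int = 2      # shallow gradient
    extra_flanking_shallower: int = 3     # shallower gradient
    central_files_wide: int = 4           # increasing central zone

    @classmethod
    def reduced(cls, **overrides) -> "SimConfig":
        """Scaled-down study configuration used by the test/acceptance runs:
        fewer trigger-phase divisions and a shorter provascular phase keep a
        full run in the tens of seconds while exercising every stage."""
        base = dict(stage_vii_central_target=24, pv_duration=8.0,
                    stop_height=52.0, snapshot_interval=2.0, max_time=100.0)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class ModelVariant:
    name: str
    config: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        if self.name not in VARIANTS:
            raise ValueError(f"unknown variant {self.name!r}")


@dataclass
class Snapshot:
    time: float
    tissue: Tissue
    outline: StandardizedOutline | None
    height: float  # apical y maximum, µm


def _role_map(name: str, cfg: SimConfig) -> dict[int, str]:
    n = cfg.n_files
    mid = n // 2
    central = {mid - 1, mid}
    flank_per_side = 1
    if name in ("shallow_gradient",):
        flank_per_side = 1 + cfg.extra_flanking_per_side
    elif name == "shallower_gradient":
        flank_per_side = 1 + cfg.extra_flanking_shallower
    elif name == "increasing_central_zone":
        w = cfg.central_files_wide
        central = set(range(mid - w // 2, mid + (w + 1) // 2))
    left = min(central)
    right = max(central)
    roles = {}
    for i in range(n):
        if i in central:
            roles[i] = "central"
        elif left - flank_per_side <= i < left or right < i <= right + flank_per_side:
            roles[i] = "flanking"
        else:
            roles[i] = "peripheral"
    return roles


def build_initial_tissue(variant: ModelVariant | str,
                         seed: int | None = None) -> Tissue:
    """Flat 20-cell file with roles per variant, plus the overlay cell."""
    if isinstance(variant, str):
        variant = ModelVariant(variant)
    cfg = variant.config
    n = cfg.n_files
    w = cfg.cell_width
    h0 = cfg.init_target / w
    x0 = -0.5 * n * w

    xs = x0 + w * np.arange(n + 1)
    bottom = np.column_stack([xs, np.zeros(n + 1)])
    top = np.column_stack([xs, np.full(n + 1, h0)])
    verts = np.vstack([bottom, top])
    mobility = np.full(len(verts), FREE, dtype=np.int8)
    mobility[0] = mobility[n] = FIXED           # basal corners
    mobility[1:n] = X_ONLY                       # basal interior: y pinned
    mobility[n + 1] = mobility[2 * n + 1] = FIXED  # apical lateral clamps

    roles = _role_map(variant.name, cfg)
    cells: list[Cell] = []
    edges: dict[tuple[int, int], EdgeData] = {}

    def add_edge(i, j):
        key = (i, j) if i < j else (j, i)
        if key not in edges:
            k = edge_class(verts[i], verts[j])
            edges[key] = EdgeData(cfg.beta_h if k == "h" else cfg.beta_v, k)

    for i in range(n):
        b0, b1 = i, i + 1
        t1, t0 = n + 2 + i, n + 1 + i
        cycle = [b0, b1, t1, t0]
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            add_edge(a, b)
        role = roles[i]
        cells.append(Cell(cycle, cfg.init_target, role, lineage=i,
                          growing=role in ("central", "flanking"),
                          growth_rate=cfg.rate_normal
                          if role in ("central", "flanking") else 0.0))

    zone_files = [i for i in range(n) if roles[i] != "peripheral"]
    zone = (xs[min(zone_files)], xs[max(zone_files) + 1])

    if variant.name != "no_overlay":
        y_top = h0 + cfg.overlay_thickness
        cr = len(verts)
        cl = cr + 1
        verts = np.vstack([verts, [[xs[-1], y_top], [xs[0], y_top]]])
        mobility = np.append(mobility, np.array([FIXED, FIXED], dtype=np.int8))
        cycle = list(range(n + 1, 2 * n + 2)) + [cr, cl]
        a0 = cfg.overlay_thickness * cfg.n_files * cfg.cell_width
        for i, j in ((2 * n + 1, cr), (cr, cl), (cl, n + 1)):
            key = (i, j) if i < j else (j, i)
            edges[key] = EdgeData(0.0, edge_class(verts[i], verts[j]))
        cells.append(Cell(cycle, a0, "overlay", lineage=-1))

    t = Tissue(verts, mobility, cells, edges, c_area=cfg.c_area,
               dividing_zone=zone)
    for c in t.cells:
        if c.role == "overlay":
            continue
        assert t.cell_area(c) > 0, "initial cycles must be counter-clockwise"
    return t


# ---------------------------------------------------------------------------
# Outline extraction


def _boundary_edges(t: Tissue) -> dict[tuple[int, int], int]:
    count: dict[tuple[int, int], int] = {}
    for cell in t.tissue_cells():
        cyc = cell.cycle
        for k in range(len(cyc)):
            a, b = cyc[k], cyc[(k + 1) % len(cyc)]
            key = (a, b) if a < b else (b, a)
            count[key] = count.get(key, 0) + 1
    return {k: v for k, v in count.items() if v == 1}


def apical_chain(t: Tissue) -> list[int]:
    """Ordered boundary vertex ids along the apical surface, left to right
    (overlay excluded, basal y = 0 vertices excluded)."""
    eps = 1e-9
    y = t.verts[:, 1]
    edges = [k for k in _boundary_edges(t) if y[k[0]] > eps and y[k[1]] > eps]
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    if not adj:
        return []
    ends = [v for v, nb in adj.items() if len(nb) == 1]
    if len(ends) != 2:  # unexpected topology: fall back to x-order
        return sorted(adj, key=lambda v: (t.verts[v, 0], t.verts[v, 1]))
    start = min(ends, key=lambda v: t.verts[v, 0])
    chain = [start]
    prev = None
    while True:
        nxt = [v for v in adj[chain[-1]] if v != prev]
        if not nxt:
            break
        prev = chain[-1]
        chain.append(nxt[0])
        if len(chain) > len(adj):
            raise RuntimeError("apical boundary is not a simple chain")
    return chain


def tissue_height(t: Tissue) -> float:
    """Apical surface maximum y (µm above the basal line)."""
    chain = apical_chain(t)
    if not chain:
        return 0.0
    return float(t.verts[chain, 1].max())


def extract_dome_outline(t: Tissue, crop_margin: float = 0.75,
                         crop: bool = True) -> StandardizedOutline | None:
    """Standardized outline of the simulated dome.

    The apical boundary chain is flipped (the simulated apex points up, the
    standardized frame wants it at minimal y) and passed through the unified
    coordinate procedure.  With ``crop=True`` the flat peripheral apron is
    trimmed: only the contiguous run of vertices around the apex rising more
    than ``crop_margin`` above the apron level is kept, which mirrors how
    dome outlines are delineated on micrographs.  Returns None while the
    tissue is still flat (no dome above the apron).
    """
    chain = apical_chain(t)
    if len(chain) < 5:
        return None
    pts = t.verts[chain]
    if crop:
        k = min(3, len(pts) // 4)
        apron = float(np.median(np.concatenate([pts[:k, 1], pts[-k:, 1]])))
        lvl = apron + crop_margin
        apex = int(np.argmax(pts[:, 1]))
        if pts[apex, 1] < lvl + 0.5:
            return None  # still flat
        lo = apex
        while lo > 0 and pts[lo - 1, 1] > lvl:
            lo -= 1
        hi = apex
        while hi < len(pts) - 1 and pts[hi + 1, 1] > lvl:
            hi += 1
        # keep one shoulder junction on each side: the dome foot anchors the
        # flanks the way the basal-most digitized junctions do on micrographs
        lo = max(lo - 1, 0)
        hi = min(hi + 1, len(pts) - 1)
        pts = pts[lo:hi + 1]
    if len(pts) < 5:
        return None
    raw = RawOutline("simulated", np.column_stack([pts[:, 0], -pts[:, 1]]))
    return unify_coordinates(raw)


# ---------------------------------------------------------------------------
# Growth program


def _orientation_for(cell: Cell, variant: str,
                     program: tuple[str, ...]) -> str | None:
    if cell.role in ("central", "provascular"):
        if variant == "randomized_division":
            return "random"
        d = cell.divisions_done
        return program[d] if d < len(program) else "short_axis"
    if cell.role == "flanking":
        return "periclinal" if cell.divisions_done == 0 else None
    return None


def _central_count(t: Tissue) -> int:
    return sum(1 for c in t.cells if c.role in ("central", "provascular"))


def _may_divide(cell: Cell, variant: str, cfg: SimConfig,
                central_count: int) -> bool:
    if cell.role == "flanking":
        return cell.divisions_done == 0
    if cell.role == "provascular":
        return True  # same trigger-based cycle continues during expansion
    if cell.role == "central":
        if cell.divisions_done < len(cfg.central_program):
            return True
        return central_count < cfg.stage_vii_central_target
    return False


def _set_threshold(cell: Cell, cfg: SimConfig, rng: np.random.Generator) -> None:
    cell.division_threshold = 2.0 * cell.target_area + float(
        rng.normal(0.0, cfg.trigger_sd)) if cfg.trigger_sd > 0 else \
        2.0 * cell.target_area


def _remove_overlay(t: Tissue) -> None:
    ov = t.overlay()
    if ov is None:
        return
    others: set[int] = set()
    for c in t.tissue_cells():
        others.update(c.cycle)
    exclusive = [v for v in ov.cycle if v not in others]
    for k in range(len(ov.cycle)):
        a, b = ov.cycle[k], ov.cycle[(k + 1) % len(ov.cycle)]
        key = (a, b) if a < b else (b, a)
        if (a in exclusive or b in exclusive) and key in t.edges:
            del t.edges[key]
    t.cells.remove(ov)
    # orphan vertices keep their slots (FIXED, forceless) to avoid reindexing
    for v in exclusive:
        t.mobility[v] = FIXED
    t.invalidate()


def _start_provascular(t: Tissue, cfg: SimConfig) -> list[Cell]:
    basal = [c for c in t.cells
             if c.role == "central"
             and any(abs(t.verts[v, 1]) < 1e-9 for v in c.cycle)]
    basal.sort(key=lambda c: abs(t.cell_centroid(c)[0]))
    chosen = basal[:2]
    for c in t.cells:
        if c.role == "central":
            c.growing = False
            c.growth_rate = 0.0
    for c in chosen:
        c.role = "provascular"
        c.growing = True
        c.growth_rate = cfg.rate_provascular
    return chosen


def _pv_beta_ramp(t: Tissue, cfg: SimConfig, frac: float) -> None:
    beta = cfg.beta_v_pv_start + (cfg.beta_v_pv_end - cfg.beta_v_pv_start) * frac
    for c in t.cells:
        if c.role != "provascular":
            continue
        cyc = c.cycle
        for k in range(len(cyc)):
            a, b = cyc[k], cyc[(k + 1) % len(cyc)]
            key = (a, b) if a < b else (b, a)
            if t.edges[key].klass == "v":
                t.edges[key].beta = beta


def run_simulation(variant: ModelVariant | str,
                   config: SimConfig | None = None,
                   seed: int = 0,
                   keep_tissues: bool = True) -> list[Snapshot]:
    """Run one growth simulation and return the snapshot series.

    Deterministic for a given (variant, config, seed): thresholds and division
    angles are drawn from a single seeded generator in cell-index order.  A
    snapshot is emitted after the initial relaxation, after every division
    batch, at the snapshot interval, and at the end.  If a relaxation fails
    the run aborts, returning the snapshots so far.
    """
    if isinstance(variant, str):
        cfg = config if config is not None else SimConfig()
        variant = ModelVariant(variant, cfg)
    elif config is not None:
        variant = replace(variant, config=config)
    cfg = variant.config
    rng = np.random.default_rng(seed)

    t = build_initial_tissue(variant)
    for c in t.cells:
        if c.growing:
            _set_threshold(c, cfg, rng)
    relax(t, tol=cfg.relax_tol, method=cfg.relax_method)

    snaps: list[Snapshot] = []

    def emit():
        h = tissue_height(t)
        outline = extract_dome_outline(t, cfg.crop_margin)
        snaps.append(Snapshot(t.time, t.copy() if keep_tissues else t,
                              outline, h))
        return h

    emit()
    last_snap = 0.0
    pv_started = False
    pv_t0 = 0.0
    overlay_present = t.overlay() is not None

    while t.time < cfg.max_time:
        t.time += cfg.dt_growth
        for c in t.cells:
            if c.growing:
                c.target_area += c.growth_rate * cfg.dt_growth
        if pv_started:
            frac = min(1.0, (t.time - pv_t0) / cfg.pv_duration)
            _pv_beta_ramp(t, cfg, frac)
        try:
            relax(t, tol=cfg.relax_tol, method=cfg.relax_method)
        except RelaxationError:
            emit()
            break

        areas = t.areas()
        count = _central_count(t)
        to_divide = [i for i, c in enumerate(t.cells)
                     if c.growing and areas[i] >= c.division_threshold
                     and _may_divide(c, variant.name, cfg, count)]
        divided = False
        for i in to_divide:
            cell = t.cells[i]
            orient = _orientation_for(cell, variant.name, cfg.central_program)
            if orient is None:
                continue
            try:
                ia, ib = divide_cell(t, i, orient, cfg.plane_noise_sd_deg,
                                     rng, cfg.beta_h, cfg.beta_v)
            except TissueGeometryError:
                continue  # degenerate cut: the cell retries next step
            for j in (ia, ib):
                d = t.cells[j]
                d.growing = _may_divide(d, variant.name, cfg,
                                        _central_count(t))
                if d.role == "flanking" and d.divisions_done >= 1:
                    d.growing = False
                if d.growing or d.role in ("central", "provascular"):
                    d.growth_rate = (cfg.rate_provascular
                                     if d.role == "provascular"
                                     else cfg.rate_normal)
                _set_threshold(d, cfg, rng)
            divided = True
        if divided:
            relax(t, tol=cfg.relax_tol, method=cfg.relax_method)

        # stage transitions
        if (not pv_started
                and _central_count(t) >= cfg.stage_vii_central_target
                and all(c.divisions_done >= len(cfg.central_program)
                        for c in t.cells
                        if c.role in ("central", "provascular"))):
            _start_provascular(t, cfg)
            pv_started = True
            pv_t0 = t.time

        h = tissue_height(t)
        if overlay_present and h >= cfg.overlay_removal_height:
            _remove_overlay(t)
            overlay_present = False
            relax(t, tol=cfg.relax_tol, method=cfg.relax_method)
            divided = True  # force a snapshot

        if divided or (t.time - last_snap) >= cfg.snapshot_interval - 1e-9:
            emit()
            last_snap = t.time

        if h >= cfg.stop_height:
            break
        if pv_started and (t.time - pv_t0) >= cfg.pv_duration and not any(
                c.growing for c in t.cells):
            break
        if not any(c.growing for c in t.cells) and not pv_started:
            # central target met before all program divisions: stop safeguard
            break

    if snaps and snaps[-1].time != t.time:
        emit()
    return snaps
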