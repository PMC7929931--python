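"""Force decomposition along the simulated dome outline at equilibrium.

At mechanical equilibrium the force that the growing tissue exerts on each
outline vertex (interior wall tensions plus the area elasticity of adjacent
cells — everything except the outline's own edge tensions) is balanced by the
outline.  Writing the tangent direction as t = (cos th, sin th), that load F
is decomposed obliquely into a vertical and a tangential component,

    F = W * (0, 1) + T * (cos th, sin th),

so T = F_x / cos(th) and W = F_y - T * sin(th).  This mirrors the statics of
a hanging chain: for a catenary-shaped dome under a vertical, uniform load
the vertical component W is uniform over the loaded span (and drops to zero
outside it), the tangential component vanishes at the apex by symmetry and
its magnitude grows toward the periphery as the horizontal thrust divided by
cos(th) — inverse proportionality to the cosine of the tangent angle.  The
vertical load is reported both raw and normalized by its spatial average
over the dividing zone (the x-extent of the central, flanking and
provascular cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Tissue
from .simulation import apical_chain

__all__ = ["ForceProfile", "decompose_forces", "EquilibriumError",
           "dividing_zone_extent"]


class EquilibriumError(RuntimeError):
    """decompose_forces called on a tissue that is not at equilibrium."""


@dataclass(frozen=True)
class ForceProfile:
    x: np.ndarray                 # outline vertex positions, µm
    y: np.ndarray
    load_x: np.ndarray            # non-outline force on the vertex
    load_y: np.ndarray
    vertical_load: np.ndarray     # W of the oblique decomposition
    tangential_tension: np.ndarray  # |T| of the oblique decomposition
    theta: np.ndarray             # tangent angle from horizontal, rad
    edge_tension: np.ndarray      # mean beta*L of the two outline edges
    normalized_load: np.ndarray   # W / mean W over the dividing zone
    dividing_zone: tuple[float, float]
    balance_residual: float       # max |total force| over outline vertices

    def zone_mask(self) -> np.ndarray:
        lo, hi = self.dividing_zone
        return (self.x >= lo) & (self.x <= hi)

    def dome_mask(self) -> np.ndarray:
        """Vertices on the dome proper, excluding the flat apron and the
        dome-foot transition (where the outline turns onto the apron and the
        chain picture does not apply)."""
        rel = self.y - self.y.min()
        return rel > max(3.0, 0.2 * rel.max())

    def load_cv(self) -> float:
        """CV of the vertical load over the loaded span (dividing zone on the
        dome): the uniformity measure of the load distribution."""
        w = self.vertical_load[self.zone_mask() & self.dome_mask()]
        if len(w) < 2 or abs(w.mean()) < 1e-15:
            return float("nan")
        return float(np.std(w) / abs(np.mean(w)))

    def smoothed_components(self) -> tuple[np.ndarray, np.ndarray]:
        """(1/cos(theta), |T|) over the dome using a 3-point running mean of
        the load along the outline — a discrete-to-continuum estimate that
        suppresses the vertex-scale alternation caused by individual interior
        walls pulling at discrete angles."""
        Fx = np.convolve(self.load_x, [0.25, 0.5, 0.25], mode="same")
        m = self.dome_mask()
        T = np.abs(Fx / np.cos(self.theta))
        return 1.0 / np.cos(self.theta[m]), T[m]

    def tension_cosine_r2(self) -> float:
        """R^2 of |tangential| load component against 1/cos(theta) over the
        dome: the hanging-chain inverse-cosine signature."""
        m = self.dome_mask()
        if m.sum() < 4:
            return float("nan")
        inv = 1.0 / np.cos(self.theta[m])
        T = self.tangential_tension[m]
        if np.ptp(inv) < 1e-12:
            return float("nan")
        return float(np.corrcoef(inv, T)[0, 1] ** 2)


def dividing_zone_extent(t: Tissue) -> tuple[float, float]:
    """Current x-extent of the dividing-zone cells (central + flanking +
    provascular); falls back to the initial zone if none are left."""
    xs: list[float] = []
    for c in t.cells:
        if c.role in ("central", "flanking", "provascular"):
            xs.extend(t.verts[v, 0] for v in c.cycle)
    if not xs:
        return t.dividing_zone
    return (float(min(xs)), float(max(xs)))


def decompose_forces(t: Tissue, tol: float = 1e-4) -> ForceProfile:
    """Oblique vertical/tangential decomposition of the load on each interior
    outline vertex; requires mechanical equilibrium (residual < tol)."""
    residual = t.max_force()
    if residual >= tol:
        raise EquilibriumError(
            f"residual force {residual:.3g} exceeds tolerance {tol:.3g}")

    chain = apical_chain(t)
    if len(chain) < 3:
        raise EquilibriumError("no apical outline to decompose")

    F_total = _raw_forces(t)
    rows = []
    balance = 0.0
    for k in range(1, len(chain) - 1):
        i = chain[k]
        left, right = chain[k - 1], chain[k + 1]
        f_out = np.zeros(2)
        t_mags = []
        for j in (left, right):
            key = (i, j) if i < j else (j, i)
            beta = t.edges[key].beta
            d = t.verts[j] - t.verts[i]
            f_out += beta * d          # pull toward the neighbor
            t_mags.append(beta * float(np.hypot(*d)))
        load = F_total[i] - f_out
        tan = t.verts[right] - t.verts[left]
        theta = float(np.arctan2(tan[1], tan[0]))
        if theta > np.pi / 2:
            theta -= np.pi
        elif theta < -np.pi / 2:
            theta += np.pi
        T = float(load[0]) / np.cos(theta)
        W = float(load[1]) - T * np.sin(theta)
        rows.append((t.verts[i, 0], t.verts[i, 1], load[0], load[1],
                     W, abs(T), theta, float(np.mean(t_mags))))
        balance = max(balance, float(np.abs(F_total[i]).max()))

    arr = np.array(rows)
    x, y, lx, ly, W, Tm, th, et = arr.T
    zone = dividing_zone_extent(t)
    in_zone = (x >= zone[0]) & (x <= zone[1])
    denom = W[in_zone].mean() if in_zone.any() else np.nan
    return ForceProfile(x, y, lx, ly, W, Tm, th, et, W / denom, zone, balance)


def _raw_forces(t: Tissue) -> np.ndarray:
    """Forces with constraints released (the decomposition wants the full
    force an outline vertex feels), then re-masked only at clamped vertices
    for the balance bookkeeping."""
    saved = t.mobility.copy()
    t.mobility = np.zeros_like(saved)
    try:
        F = t.forces()
    finally:
        t.mobility = saved
    F_masked = F.copy()
    F_masked[saved == 2] = 0.0
    F_masked[saved == 1, 1] = 0.0
    return F_masked
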