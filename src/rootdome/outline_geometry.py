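"""Reading, standardizing and measuring root-tip outlines.

An outline is the ordered sequence of cell-junction positions along the outer
surface of a root tip, digitized on a median longitudinal section (micrometres).
Before any shape analysis the outlines are brought into a common frame with the
dome apex at the origin by a three-step procedure: (1) duplicate the junction
points rotated by 180 degrees, (2) translate the duplicates vertically so that
the maximum y of the originals equals the minimum y of the duplicates (the two
halves then join into a closed curve), and (3) take the mean x of all points
(originals plus duplicates) and the minimum y of the originals as the new
origin.  In the resulting frame the apex sits at (0, 0) and y increases away
from the tip, so a catenary dome reads directly as y = a cosh(x/a) - a.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

__all__ = [
    "RawOutline",
    "StandardizedOutline",
    "ClosedOutline",
    "DomeMeasure",
    "OutlineFormatError",
    "OutlineGeometryError",
    "read_outlines",
    "write_outlines",
    "unify_coordinates",
    "close_outline",
    "dome_measures",
    "coefficient_of_variation",
]

MIN_POINTS = 5


class OutlineFormatError(ValueError):
    """Malformed outline file (missing columns, bad structure)."""


class OutlineGeometryError(ValueError):
    """Degenerate outline geometry (collinear, out-of-range cutoff, ...)."""


@dataclass(frozen=True)
class RawOutline:
    """Ordered junction points of one sample, as digitized (µm)."""

    sample_id: str
    points: np.ndarray  # (n, 2) float
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise OutlineFormatError(f"{self.sample_id}: points must be (n, 2)")
        if len(pts) < MIN_POINTS:
            raise OutlineFormatError(
                f"{self.sample_id}: need >= {MIN_POINTS} points, got {len(pts)}"
            )
        if np.any(~np.isfinite(pts)):
            raise OutlineFormatError(f"{self.sample_id}: non-finite coordinates")
        dup = np.all(np.diff(pts, axis=0) == 0.0, axis=1)
        if np.any(dup):
            raise OutlineFormatError(f"{self.sample_id}: duplicate consecutive points")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class StandardizedOutline:
    """Outline in the unified frame: apex at (0, 0), y >= 0 away from the tip."""

    sample_id: str
    points: np.ndarray  # (n, 2) float, ordered along the outline
    apex_index: int
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def height(self) -> float:
        """Dome height h: maximal y of the outline (µm)."""
        return float(self.points[:, 1].max())


@dataclass(frozen=True)
class ClosedOutline:
    """Closed curve: original junctions plus their rotated/translated copies."""

    points: np.ndarray  # (M, 2), one full traversal
    n_original: int

    @property
    def M(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class DomeMeasure:
    """Width and enclosed area of the dome below a height cutoff."""

    height_cutoff: float  # µm
    area: float  # µm²
    width: float  # µm


# ---------------------------------------------------------------------------
# I/O


def read_outlines(path: str | Path, dialect: str = "y-up") -> list[RawOutline]:
    """Read outlines from CSV (columns sample_id, point_index, x_um, y_um) or JSON.

    ``dialect='y-down'`` flips the sign of y on load, for digitizations whose
    y-axis points into the root tip.  Samples with fewer than five points are
    rejected with a warning.  Within each sample, points are sorted by
    point_index; sample order follows first appearance in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("y-up", "y-down"):
        raise OutlineFormatError(f"unknown dialect {dialect!r}")
    flip = -1.0 if dialect == "y-down" else 1.0

    records: list[tuple[str, np.ndarray, dict]] = []
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        if not isinstance(data, list):
            raise OutlineFormatError("JSON outline file must be a list of records")
        for rec in data:
            try:
                sid = str(rec["sample_id"])
                pts = np.asarray(rec["points"], dtype=float)
            except (KeyError, TypeError) as exc:
                raise OutlineFormatError(f"bad JSON outline record: {exc}") from exc
            records.append((sid, pts, dict(rec.get("metadata", {}))))
    else:
        df = pd.read_csv(path)
        required = {"sample_id", "point_index", "x_um", "y_um"}
        missing = required - set(df.columns)
        if missing:
            raise OutlineFormatError(f"{path.name}: missing columns {sorted(missing)}")
        for sid, grp in df.groupby("sample_id", sort=False):
            grp = grp.sort_values("point_index")
            pts = grp[["x_um", "y_um"]].to_numpy(dtype=float)
            records.append((str(sid), pts, {}))

    out: list[RawOutline] = []
    for sid, pts, meta in records:
        pts = pts * np.array([1.0, flip])
        try:
            out.append(RawOutline(sid, pts, meta))
        except OutlineFormatError as exc:
            warnings.warn(f"rejected sample {sid!r}: {exc}")
    return out


def write_outlines(outlines: Iterable[RawOutline | StandardizedOutline],
                   path: str | Path) -> None:
    """Write outlines to the standard CSV layout at full float precision."""
    rows = []
    for o in outlines:
        for i, (x, y) in enumerate(np.asarray(o.points, dtype=float)):
            rows.append((o.sample_id, i, repr(float(x)), repr(float(y))))
    df = pd.DataFrame(rows, columns=["sample_id", "point_index", "x_um", "y_um"])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Coordinate unification


def _mirror(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Steps (1)-(2): rotate by pi about the centroid, translate vertically so
    that max y(original) == min y(duplicate).  Returns (original, duplicate)."""
    c = points.mean(axis=0)
    dup = 2.0 * c - points  # 180-degree rotation about the centroid
    dy = points[:, 1].max() - dup[:, 1].min()
    dup = dup + np.array([0.0, dy])
    return points, dup


def unify_coordinates(raw: RawOutline) -> StandardizedOutline:
    """Unify the coordinate frame of a digitized outline (3-step procedure).

    The rotation center of step (1) is the centroid of the original points;
    combined with the step-(3) re-centering on the mean x of all (original and
    duplicated) points, the final frame is exactly ``x - mean(x)``,
    ``y - min(y)`` of the originals, hence invariant to input translation and
    to point-order reversal.
    """
    pts = raw.points
    if np.ptp(pts[:, 0]) < 1e-12:
        raise OutlineGeometryError(f"{raw.sample_id}: outline collinear in x")
    orig, dup = _mirror(pts)
    allpts = np.vstack([orig, dup])
    origin_x = allpts[:, 0].mean()
    origin_y = orig[:, 1].min()
    std = orig - np.array([origin_x, origin_y])
    apex_index = int(np.argmin(std[:, 1]))
    # sanity: mean x of the mirrored closed set is 0 by construction
    assert abs((allpts[:, 0] - origin_x).mean()) < 1e-9
    return StandardizedOutline(raw.sample_id, std, apex_index, dict(raw.metadata))


def close_outline(std: StandardizedOutline) -> ClosedOutline:
    """Close the standardized outline by appending the rotated duplicate half.

    The duplicate of point (x, y) is (-x, 2*ymax - y); traversing originals
    then duplicates in index order walks the closed curve exactly once.
    """
    pts = std.points
    ymax = pts[:, 1].max()
    dup = np.column_stack([-pts[:, 0], 2.0 * ymax - pts[:, 1]])
    closed = np.vstack([pts, dup])
    return ClosedOutline(closed, n_original=len(pts))


# ---------------------------------------------------------------------------
# Dome measures


def _flank_crossings(pts: np.ndarray, h: float) -> list[float]:
    """x-positions where the piecewise-linear outline crosses y == h."""
    xs = []
    x, y = pts[:, 0], pts[:, 1]
    for i in range(len(pts) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - h) * (y1 - h) < 0.0:
            t = (h - y0) / (y1 - y0)
            xs.append(float(x[i] + t * (x[i + 1] - x[i])))
        elif y0 == h:
            xs.append(float(x[i]))
    if y[-1] == h:
        xs.append(float(x[-1]))
    return xs


def dome_measures(std: StandardizedOutline, height_cutoff: float) -> DomeMeasure:
    """Dome width and area below ``height_cutoff`` (µm above the apex).

    Width is |x_right - x_left| at the cutoff, interpolated linearly along each
    flank; if a flank crosses the cutoff more than once the outermost crossing
    is used (with a warning).  Area is the polygon area enclosed by the outline
    below the cutoff and the chord at the cutoff.
    """
    pts = std.points
    if not (0.0 < height_cutoff <= pts[:, 1].max()):
        raise OutlineGeometryError(
            f"cutoff {height_cutoff} outside (0, {pts[:, 1].max()}]"
        )
    apex = std.apex_index
    left = pts[: apex + 1]
    right = pts[apex:]
    sides = []
    for flank in (left, right):
        xs = _flank_crossings(flank, height_cutoff)
        if not xs:
            raise OutlineGeometryError("flank does not reach the cutoff height")
        if len(xs) > 1:
            warnings.warn("non-monotone flank: using outermost crossing")
        sides.append(max(xs, key=abs))
    width = abs(sides[1] - sides[0])

    poly = Polygon(np.vstack([pts, pts[0]]))
    if not poly.is_valid:
        poly = poly.buffer(0.0)
    xlim = np.abs(pts[:, 0]).max() + 1.0
    clipped = poly.intersection(box(-xlim, -1.0, xlim, height_cutoff))
    return DomeMeasure(height_cutoff, area=float(clipped.area), width=width)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV (%) = sample s.d. (n-1 denominator) x 100 / mean."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("mean must be positive")
    return float(v.std(ddof=1) * 100.0 / mean)
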