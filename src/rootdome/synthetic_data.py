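"""Synthetic junction-point outlines with the statistical structure the
analysis assumes.

The generator emulates the digitization of a root-tip median section: points
are laid along a chosen dome curve at cell-scale arc-length intervals
(default 10 µm mean with 20% jitter, matching typical epidermal cell sizes),
truncated at the dome height, and perturbed by isotropic Gaussian positional
noise.  Cohorts draw the per-sample catenary parameter a log-normally with a
prescribed mean and CV — log-normal keeps a positive at the CVs seen across
root classes (roughly 7-14%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .curve_fitting import FAMILIES
from .outline_geometry import RawOutline, write_outlines

__all__ = [
    "OutlineGeneratorSpec",
    "CohortSpec",
    "generate_outline",
    "generate_cohort",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class OutlineGeneratorSpec:
    family: str = "catenary"
    params: tuple[float, ...] = (30.0,)   # family parameters, µm (see curve_fitting)
    height: float = 50.0                  # dome height, µm
    spacing: float = 10.0                 # mean junction spacing, µm
    spacing_jitter: float = 0.2           # s.d. of spacing as a fraction of the mean
    noise_sd: float = 0.0                 # isotropic positional noise, µm
    seed: int = 0
    sample_id: str = "synthetic"

    def __post_init__(self):
        if self.spacing <= 0 or self.height <= 0 or self.noise_sd < 0:
            raise ValueError("spacing and height must be > 0, noise_sd >= 0")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class CohortSpec:
    K: int = 12
    a_mean: float = 30.0                  # mean catenary parameter, µm
    a_cv: float = 8.5                     # CV of a, percent
    base: OutlineGeneratorSpec = field(default_factory=OutlineGeneratorSpec)
    seed: int = 0
    prefix: str = "sample"

    def __post_init__(self):
        if self.K < 1 or self.a_cv < 0:
            raise ValueError("K >= 1 and a_cv >= 0 required")


def _half_width(family: str, params: tuple[float, ...], height: float) -> float:
    """x > 0 with y(x) == height, for each dome family."""
    p = np.asarray(params, float)
    if family == "parabola":
        return float(np.sqrt(height / p[0]))
    if family == "catenary":
        return float(p[0] * np.arccosh(height / p[0] + 1.0))
    if family == "ellipse":
        a, b = p
        if height > b:
            raise ValueError("height exceeds the ellipse semi-axis b")
        return float(a * np.sqrt(1.0 - (1.0 - height / b) ** 2))
    if family == "hyperbola":
        a, b = p
        return float(a * np.sqrt((height / b + 1.0) ** 2 - 1.0))
    if family == "cosine":
        a, b = p
        if height > 2.0 * a:
            raise ValueError("height exceeds the cosine amplitude 2*a5")
        return float(np.arccos(1.0 - height / a) / b)
    raise KeyError(family)


def generate_outline(spec: OutlineGeneratorSpec) -> RawOutline:
    """Sample one outline: arc-length-spaced junctions along the curve from the
    left flank over the apex to the right flank, plus noise.

    Junctions are laid out symmetrically about the apex (the apex junction is
    always included, as are both flank endpoints at y = height), so that for
    zero positional noise the coordinate-unification procedure is an exact
    identity and curve parameters are exactly recoverable.  Positional noise
    is what breaks the bilateral symmetry in realistic cohorts.  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    fam = FAMILIES[spec.family]
    p = np.asarray(spec.params, float)
    xw = _half_width(spec.family, spec.params, spec.height)

    # arc length s(x) from the apex outward on the right half
    xg = np.linspace(0.0, xw, 2001)
    yg = fam(xg, p)
    ds = np.sqrt(1.0 + np.gradient(yg, xg) ** 2)
    s = cumulative_trapezoid(ds, xg, initial=0.0)
    half = s[-1]

    positions = [0.0]
    while positions[-1] < half:
        step = rng.normal(spec.spacing, spec.spacing_jitter * spec.spacing)
        positions.append(positions[-1] + max(step, 0.2 * spec.spacing))
    right = np.clip(np.array(positions), 0.0, half)
    right[-1] = half
    xs_right = np.interp(right, s, xg)
    xs = np.concatenate([-xs_right[:0:-1], xs_right])
    ys = fam(xs, p)
    pts = np.column_stack([xs, ys])
    if spec.noise_sd > 0:
        pts = pts + rng.normal(0.0, spec.noise_sd, pts.shape)
    meta = {"family": spec.family,
            "params": ",".join(repr(v) for v in spec.params)}
    return RawOutline(spec.sample_id, pts, meta)


def generate_cohort(spec: CohortSpec) -> list[RawOutline]:
    """K catenary outlines with per-sample a drawn log-normally (mean a_mean,
    CV a_cv percent); sample seeds derive from the cohort seed."""
    rng = np.random.default_rng(spec.seed)
    cv = spec.a_cv / 100.0
    if cv > 0:
        sigma2 = np.log(1.0 + cv**2)
        mu = np.log(spec.a_mean) - sigma2 / 2.0
        a_values = rng.lognormal(mu, np.sqrt(sigma2), spec.K)
    else:
        a_values = np.full(spec.K, spec.a_mean)
    out = []
    for j, a in enumerate(a_values):
        sub = int(rng.integers(0, 2**31 - 1))
        if spec.base.family == "catenary":
            params: tuple[float, ...] = (float(a),)
        else:
            # isometric size variation for non-catenary families: length-like
            # parameters scale with a/a_mean, inverse-length ones (parabola a1,
            # cosine b5) with its reciprocal
            scale = float(a) / spec.a_mean
            inv = {"a1", "b5"}
            params = tuple(
                v / scale if name in inv else v * scale
                for v, name in zip(spec.base.params,
                                   FAMILIES[spec.base.family].param_names))
        s = OutlineGeneratorSpec(
            family=spec.base.family, params=params, height=spec.base.height,
            spacing=spec.base.spacing, spacing_jitter=spec.base.spacing_jitter,
            noise_sd=spec.base.noise_sd, seed=sub,
            sample_id=f"{spec.prefix}_{j:03d}")
        out.append(generate_outline(s))
    return out


def make_fixture_suite(out_dir: str | Path) -> list[Path]:
    """Write the canonical fixture files (exact-family outlines, a noisy
    cohort, a degenerate case) plus a manifest; byte-identical across runs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    written: list[Path] = []

    exact_specs = {
        "parabola": (0.05,), "catenary": (30.0,), "ellipse": (60.0, 80.0),
        "hyperbola": (25.0, 40.0), "cosine": (30.0, 0.03),
    }
    for fam, params in exact_specs.items():
        spec = OutlineGeneratorSpec(family=fam, params=params, height=40.0,
                                    noise_sd=0.0, seed=11,
                                    sample_id=f"exact_{fam}")
        path = out_dir / f"exact_{fam}.csv"
        write_outlines([generate_outline(spec)], path)
        manifest[path.name] = asdict(spec)
        written.append(path)

    cohort = CohortSpec(K=12, a_mean=30.0, a_cv=8.5,
                        base=OutlineGeneratorSpec(noise_sd=1.0), seed=7,
                        prefix="noisy")
    path = out_dir / "noisy_cohort.csv"
    write_outlines(generate_cohort(cohort), path)
    manifest[path.name] = asdict(cohort)
    written.append(path)

    # degenerate: minimal 5-point V outline
    v = RawOutline("v_outline", np.array([[-2.0, 4.0], [-1.0, 1.0], [0.0, 0.0],
                                          [1.0, 1.0], [2.0, 4.0]]))
    path = out_dir / "v_outline.csv"
    write_outlines([v], path)
    manifest[path.name] = {"kind": "hand-written V outline"}
    written.append(path)

    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written
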