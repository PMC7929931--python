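"""Orchestration of the analysis stages with reproducible run manifests.

`run_full_analysis` chains the morphometric stages on an outline file:
dome measures and their CVs, the Fourier shape-reproducibility report,
per-sample five-family fits with delta-AIC and cross-validated MSE, and the
isometric collapse.  `run_simulation_study` runs the vertex-model variants
over seeds and aggregates catenary fit quality by dome-height bin, the
Fig-style cross-variant ordering table, and force profiles.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curve_fitting import (FAMILIES, compare_families, fit_family,
                            isometric_collapse)
from .outline_geometry import (RawOutline, StandardizedOutline,
                               close_outline, coefficient_of_variation,
                               dome_measures, read_outlines, unify_coordinates)
from .shape_fourier import (fourier_expand, normalize_shape,
                            reproducibility_index, to_polar)
from .vertex_model import (ModelVariant, SimConfig, decompose_forces,
                           run_simulation)

__all__ = ["RunManifest", "run_full_analysis", "run_simulation_study",
           "HEIGHT_BIN_EDGES", "height_bin"]

HEIGHT_BIN_EDGES = (10.0, 30.0, 50.0)


def height_bin(h: float, edges: Sequence[float] = HEIGHT_BIN_EDGES) -> str:
    prev = 0.0
    for e in edges:
        if h < e:
            return f"{prev:g}<=h<{e:g}" if prev else f"h<{e:g}"
        prev = e
    return f"{prev:g}<=h"


@dataclass
class RunManifest:
    command: str
    config: Mapping
    seeds: list[int]
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    tool_version: str = "0.1.0"
    timestamp: str = ""

    def record(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def write(self, out_dir: Path) -> Path:
        self.timestamp = _time.strftime("%Y-%m-%dT%H:%M:%S")
        p = out_dir / "manifest.json"
        p.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")
        return p


def _standardize_all(outlines: Sequence[RawOutline]) -> list[StandardizedOutline]:
    return [unify_coordinates(o) for o in outlines]


def run_full_analysis(outlines_path: str | Path, out_dir: str | Path,
                      height_cutoff: float | None = None,
                      families: Sequence[str] | None = None,
                      cv_repeats: int = 100, n_modes: int = 200,
                      seed: int = 0) -> dict:
    """Measure, shape-analyze, fit and collapse one outline file.

    Writes measures.csv, shape_report.json, fits.csv, collapsed.csv and
    summary.json (plus a manifest) under ``out_dir`` and returns the summary
    dict.  Deterministic for a given seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw = read_outlines(outlines_path)
    if not raw:
        raise ValueError(f"no usable outlines in {outlines_path}")
    stds = _standardize_all(raw)
    manifest = RunManifest(
        command=f"run_full_analysis({Path(outlines_path).name})",
        config=dict(height_cutoff=height_cutoff, cv_repeats=cv_repeats,
                    n_modes=n_modes, seed=seed),
        seeds=[seed])

    # dome measures at a common cutoff (default: 80% of the lowest dome)
    hmax = min(s.height for s in stds)
    cutoff = height_cutoff if height_cutoff is not None else 0.8 * hmax
    cutoff = min(cutoff, hmax)
    measures = pd.DataFrame(
        [(s.sample_id, cutoff, m.area, m.width)
         for s, m in ((s, dome_measures(s, cutoff)) for s in stds)],
        columns=["sample_id", "height_cutoff_um", "area_um2", "width_um"])
    measures.to_csv(out_dir / "measures.csv", index=False)

    # shape reproducibility
    shapes = [normalize_shape(fourier_expand(to_polar(close_outline(s)),
                                             n_modes, s.sample_id))
              for s in stds]
    if len(shapes) >= 2:
        rep = reproducibility_index(shapes)
        shape_report = {"K": rep.K, "index": rep.index}
    else:
        shape_report = {"K": len(shapes), "index": None}
    (out_dir / "shape_report.json").write_text(
        json.dumps(shape_report, indent=2) + "\n")

    # five-family fits
    fam_names = list(families) if families is not None else list(FAMILIES)
    rows = []
    rng = np.random.default_rng(seed)
    for s in stds:
        sub = int(rng.integers(0, 2**31 - 1))
        for r in compare_families(s, fam_names, cv_repeats=cv_repeats,
                                  seed=sub):
            rows.append({
                "sample_id": s.sample_id, "family": r.family.name,
                **{n: v for n, v in zip(r.family.param_names, r.params)},
                "sse": r.sse, "aic": r.aic, "delta_aic": r.delta_aic,
                "cv_mse": r.cv_mse, "n_points": r.n_points})
    fits = pd.DataFrame(rows)
    fits.to_csv(out_dir / "fits.csv", index=False)

    # isometric collapse with each sample's own fitted catenary a
    crows = []
    devs = []
    for s in stds:
        a = float(fits[(fits.sample_id == s.sample_id)
                       & (fits.family == "catenary")]["a2"].iloc[0])
        col = isometric_collapse(s, a)
        devs.append(col.deviation)
        for X, Y in col.points:
            crows.append((s.sample_id, a, X, Y))
    pd.DataFrame(crows, columns=["sample_id", "a_um", "X", "Y"]).to_csv(
        out_dir / "collapsed.csv", index=False)

    best = (fits.sort_values("delta_aic").groupby("sample_id").first()
            .family.value_counts().to_dict())
    candidate_set = sorted(
        fits[fits.delta_aic < 2.0].family.unique().tolist())
    summary = {
        "n_samples": len(stds),
        "area_cv_percent": coefficient_of_variation(measures.area_um2)
        if len(stds) >= 2 else None,
        "width_cv_percent": coefficient_of_variation(measures.width_um)
        if len(stds) >= 2 else None,
        "shape_reproducibility_index": shape_report["index"],
        "best_family_counts": best,
        "delta_aic_lt2_families": candidate_set,
        "mean_cv_mse_by_family":
            fits.groupby("family").cv_mse.mean().to_dict(),
        "collapse_rms_mean": float(np.mean(devs)),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    for name in ("measures.csv", "shape_report.json", "fits.csv",
                 "collapsed.csv", "summary.json"):
        manifest.record(out_dir / name)
    manifest.write(out_dir)
    return summary


def run_simulation_study(variants: Sequence[str], seeds: Sequence[int],
                         config: SimConfig | None = None,
                         out_dir: str | Path | None = None,
                         cv_repeats: int = 20,
                         with_forces: bool = False) -> dict:
    """Run each variant over each seed; bin catenary fit quality by height.

    Returns {"runs": per-run rows, "table": per (variant, bin) mean cv_mse,
    "forces": per-run force summaries (if requested)}; writes study.csv /
    ordering.csv / forces.csv under out_dir when given.
    """
    cfg = config if config is not None else SimConfig()
    rows = []
    force_rows = []
    for vname in variants:
        for seed in seeds:
            snaps = run_simulation(ModelVariant(vname, cfg), seed=seed)
            for s in snaps:
                if s.outline is None:
                    continue
                try:
                    fit = compare_families(s.outline, ["catenary"],
                                           cv_repeats=cv_repeats,
                                           seed=seed)[0]
                except Exception:
                    continue
                h = s.outline.height  # dome height above the apron
                rows.append(dict(
                    variant=vname, seed=seed, time=s.time, height=h,
                    bin=height_bin(h), a_um=float(fit.params[0]),
                    cv_mse=fit.cv_mse, sse=fit.sse,
                    apex_offset=_apex_offset(s.outline)))
            if with_forces and snaps:
                last = snaps[-1]
                try:
                    prof = decompose_forces(last.tissue,
                                            tol=10 * cfg.relax_tol)
                except Exception:
                    continue
                force_rows.append(dict(
                    variant=vname, seed=seed, height=last.height,
                    load_cv_zone=prof.load_cv(),
                    tension_r2=prof.tension_cosine_r2()))

    runs = pd.DataFrame(rows)
    table = (runs.groupby(["variant", "bin"]).cv_mse.mean().reset_index()
             if len(runs) else pd.DataFrame())
    out = {"runs": runs, "table": table,
           "forces": pd.DataFrame(force_rows)}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = RunManifest("run_simulation_study",
                               config=asdict(cfg), seeds=list(seeds))
        runs.to_csv(out_dir / "study.csv", index=False)
        table.to_csv(out_dir / "ordering.csv", index=False)
        manifest.record(out_dir / "study.csv")
        manifest.record(out_dir / "ordering.csv")
        if with_forces:
            out["forces"].to_csv(out_dir / "forces.csv", index=False)
            manifest.record(out_dir / "forces.csv")
        manifest.write(out_dir)
    return out


def _apex_offset(std: StandardizedOutline) -> float:
    """|x| of the outline apex: bilateral-symmetry diagnostic."""
    return float(abs(std.points[std.apex_index, 0]))
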