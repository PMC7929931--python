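# rootdome

Morphometrics and growth simulation of plant root-tip domes.

The apical dome of a growing root — the primary root tip of many angiosperm
species, or an *Arabidopsis* lateral root primordium (LRP) pushing through its
parent root — has a remarkably reproducible outline.  This package implements
the quantitative pipeline for that observation and the tissue-mechanical model
that explains it:

1. **Outline standardization.**  Digitized cell-junction outlines are brought
   into a unified frame (apex at the origin, y pointing into the root body) by
   duplicating the points rotated by 180°, joining the halves into a closed
   curve, and re-centering on the mean x / minimal y.
2. **Radial Fourier shape analysis.**  The closed outline's polar radius
   r(α), parameterized by normalized perimeter α, is expanded in a Fourier
   series r(α) = c₀ + Σ cₙ cos(2πnα − Φₙ); dividing by the mean radius c₀
   removes size.  The cohort shape-reproducibility index
   S₂^½ = √( (1/K) Σⱼ ∫₀¹ (r̂ⱼ − r̄̂)² dα ) is a few percent for root-tip-like
   cohorts.
3. **Dome-curve model selection.**  Five symmetric dome functions — parabola
   y = a₁x², catenary y = a₂cosh(x/a₂) − a₂, ellipse, hyperbola, cosine — are
   fitted by nonlinear least squares and compared by SSE, by
   AIC = n·ln(SSE/n) + 2k, and by repeated 99%/1% cross-validation.  The
   catenary and its "catenary-closest ellipse" (semi-axes linear in a) win.
4. **Isometric collapse.**  Because a is both the reciprocal apex curvature
   and the overall scale, plotting (x/a, y/a) collapses every dome onto the
   parameter-free curve Y = cosh X − 1.
5. **Cell-vertex growth simulation.**  A polygonal-cell tissue with energy
   E = Σ (c/2)(Aₙ−A₀)²/A₀ + Σ (β/2)L² grows an LRP dome from a flat file of
   20 cells under the observed division program (periclinal → anticlinal →
   periclinal in the central zone, one periclinal division in the flanking
   files, none at the periphery; then area-triggered short-axis divisions and
   rapid provascular expansion) beneath an overlaying parental mass.  The
   emerging dome is catenary-shaped, its fitted a falls as it grows, and
   perturbing the rules (wider low-division-rate flanks, randomized division
   angles) degrades the catenary fit — the in-silico analogs of *puchi-1* and
   *aur1 aur2* mutants.

The study's confocal-derived coordinates are not publicly deposited, so a
synthetic-outline generator (`rootdome.synthetic_data`) emulates them:
junctions at cell-scale spacing along a chosen dome curve, Gaussian
digitization noise, log-normal per-sample size variation, cohort structure.

## Worked example

```python
from rootdome.synthetic_data import CohortSpec, OutlineGeneratorSpec, generate_cohort
from rootdome.outline_geometry import unify_coordinates
from rootdome.curve_fitting import compare_families, fit_family, isometric_collapse

cohort = generate_cohort(CohortSpec(K=3, a_mean=30.0, a_cv=8.5,
                                    base=OutlineGeneratorSpec(noise_sd=1.0),
                                    seed=7))
for raw in cohort:
    std = unify_coordinates(raw)
    ranked = sorted(compare_families(std, cv_repeats=50, seed=1),
                    key=lambda r: r.delta_aic)
    best = ranked[0]
    a = float(fit_family(std, "catenary").params[0])
    col = isometric_collapse(std, a)
    print(f"{std.sample_id}: best={best.family.name} "
          f"dAIC<2: {[r.family.name for r in ranked if r.delta_aic < 2]} "
          f"a={a:.1f} µm, collapse RMS={col.deviation:.4f}")
```

prints

```
sample_000: best=catenary dAIC<2: ['catenary'] a=29.7 µm, collapse RMS=0.0607
sample_001: best=ellipse dAIC<2: ['ellipse'] a=30.5 µm, collapse RMS=0.0678
sample_002: best=catenary dAIC<2: ['catenary', 'ellipse'] a=29.5 µm, collapse RMS=0.0583
```

— on noisy catenary outlines the winner alternates between the catenary and
the catenary-closest ellipse (they are nearly the same curve), the fitted a
recovers the generating 30 µm scale, and rescaling by each sample's own a
lands every outline on Y = cosh X − 1 to ~6% RMS at this 1 µm noise level
(exactly 0 for noiseless outlines).

The numbered drivers under `analysis/` run the full study — cohort
generation, reproducibility statistics, model selection, isometric collapse,
wild-type simulation, perturbation comparison — writing tables under
`results/`:

```bash
python analysis/01_generate_cohorts.py
python analysis/02_size_and_shape_reproducibility.py
...
```

A thin CLI wraps the same library calls:
`rootdome synth|measure|shape|fit|collapse|simulate|study|analyze --help`.

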