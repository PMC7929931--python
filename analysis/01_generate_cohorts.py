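#!/usr/bin/env python
"""Generate the synthetic root-tip outline cohorts used by the downstream
analyses: three Arabidopsis-like root classes (primary root, mature lateral
root, emerged lateral root) with class-specific catenary parameter means and
CVs, cell-scale junction spacing and 1 µm digitization noise.

Writes results/cohorts/<class>.csv plus a combined file.
"""

from pathlib import Path

from rootdome.outline_geometry import write_outlines
from rootdome.synthetic_data import (CohortSpec, OutlineGeneratorSpec,
                                     generate_cohort)

OUT = Path(__file__).resolve().parent.parent / "results" / "cohorts"

# class presets: (K, mean a [µm], CV of a [%], seed); the primary root is
# larger (mean a ~50% above the laterals) and more variable
CLASSES = {
    "primary_root": (12, 45.0, 14.0, 101),
    "mature_lr": (12, 30.0, 7.2, 102),
    "emerged_lr": (11, 30.0, 8.5, 103),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    combined = []
    for name, (k, a_mean, a_cv, seed) in CLASSES.items():
        spec = CohortSpec(K=k, a_mean=a_mean, a_cv=a_cv,
                          base=OutlineGeneratorSpec(height=50.0,
                                                    noise_sd=1.0),
                          seed=seed, prefix=name)
        cohort = generate_cohort(spec)
        write_outlines(cohort, OUT / f"{name}.csv")
        combined.extend(cohort)
        print(f"{name}: {k} outlines, mean a {a_mean} µm, CV(a) {a_cv}%")
    write_outlines(combined, OUT / "all_classes.csv")
    print(f"wrote {len(combined)} outlines under {OUT}")


if __name__ == "__main__":
    main()
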