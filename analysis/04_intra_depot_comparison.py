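#!/usr/bin/env python
"""Paired-sphere comparison of fat fraction inside the depot.

Within each subject, one sphere (diameter 5% of the in-plane field of view)
is placed at the voxel of highest FDG uptake in the depot and one in a
region without discernible uptake; the fat fraction in the PET-negative
sphere is compared with the PET-positive sphere by a paired t test. Active
BAT is expected to be leaner. Writes results/paired_spheres.csv.
"""

from pathlib import Path

import pandas as pd

from batquant import analyze_subject_mr, make_cohort, make_phantom, paired_t

import sys
from importlib import import_module
sys.path.insert(0, str(Path(__file__).resolve().parent))
COHORT_SPECS = import_module("01_simulate_cohorts").COHORT_SPECS

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    records, specs = make_cohort(COHORT_SPECS[2], with_phantom_specs=True)
    rows = []
    for rec, spec in zip(records, specs):
        ph = make_phantom(spec)
        res = analyze_subject_mr(ph, reconstruction="multiecho")
        if res.ff_sphere_pos is None:
            continue
        rows.append({"id": rec.id,
                     "ff_sphere_positive": round(res.ff_sphere_pos.mean, 1),
                     "ff_sphere_negative": round(res.ff_sphere_neg.mean, 1)})
    df = pd.DataFrame(rows)
    out = RESULTS / "paired_spheres.csv"
    df.to_csv(out, index=False)

    t, dof, p = paired_t(df.ff_sphere_negative, df.ff_sphere_positive)
    mean_neg = df.ff_sphere_negative.mean()
    mean_pos = df.ff_sphere_positive.mean()
    print(df.to_string(index=False))
    print(f"\nFF in the PET-negative sphere: {mean_neg:.0f} +/- "
          f"{df.ff_sphere_negative.std():.0f} per mille vs {mean_pos:.0f} "
          f"+/- {df.ff_sphere_positive.std():.0f} in the PET-positive "
          f"sphere (paired t({dof}) = {t:.2f}, p = {p:.2e}).")
    print("Metabolically active BAT is consistently leaner than the "
          "surrounding depot.")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
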