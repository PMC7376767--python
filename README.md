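# batquant

Quantification of human brown adipose tissue (BAT) activity from Dixon MRI
fat fraction and [18F]FDG-PET uptake.

## The problem

Active BAT in the supraclavicular depot is the principal site of
cold-induced thermogenesis in adult humans. The reference method for
quantifying its activity — static FDG-PET after mild cold exposure — is
expensive and carries a radiation dose, so MRI-derived tissue fat fraction
(FF) has been proposed as a surrogate: thermogenic adipocytes hold less
triglyceride per voxel, and their FF is correspondingly lower. Evaluating
that surrogate requires a chain of quantitative steps, each of which this
package implements as a tested, reusable unit:

1. **Dixon water–fat separation.** From dual-echo in-/out-of-phase
   magnitudes, `W = (IP + OP)/2`, `F = (IP − OP)/2` (with an explicit
   dominant-species flag, since magnitudes cannot distinguish W > F from
   F > W); or from complex multi-echo data by voxelwise least squares on

   ```
   s(TEn) = (W + F · Σp αp e^{i 2π fp TEn}) · e^{i 2π ψ TEn} · e^{−R2* TEn}
   ```

   with a six-peak triglyceride spectrum (αp, fp), B0 field map ψ, and
   optional R2*. The fat fraction is `FF = 1000·F/(W+F)` in per mille (‰).
2. **SUV mapping.** PET activity concentration (Bq/ml) is normalised by
   injected dose per gram of body weight: `SUV = C / (D/w)` in g/ml, with
   explicit F-18 decay correction (`T½ = 109.77 min`) when the dose is not
   referenced to scan start.
3. **Segmentation.** The supraclavicular adipose tissue (scAT) is the
   intersection of a manual anatomical outline, an FF window of 400–1000‰
   (or a CT window of −190…−10 HU on the PET/CT path), and a body mask,
   eroded by one voxel against partial-volume effects; its metabolically
   active part additionally satisfies SUV ≥ 1.5 g/ml. A paired-sphere tool
   (diameter 5% of the in-plane field of view) contrasts FF at the hottest
   PET voxel against a region without discernible uptake.
4. **Cohort statistics.** Paired t tests for the within-subject sphere
   comparison; per-cohort OLS of SUVmean on FF; pooled regression after
   within-cohort z-scaling; multiple regression adding age, BMI, and
   cold-induced thermogenesis `CIT = 100·(EE_cold − EE_warm)/EE_warm` as
   standardized predictors.

No imaging data ships with the package. A synthetic-phantom and cohort
generator (`batquant.synthetic`) produces co-registered multi-echo MR, PET,
and CT volumes with known ground truth and cohorts with a controllable
standardized FF→SUV slope, so the entire chain is validated end to end.

## Worked example

```python
from batquant import (PhantomSpec, make_phantom, analyze_subject_mr, paired_t)

pos, neg = [], []
for seed in range(16):                    # a 16-subject synthetic cohort
    phantom = make_phantom(PhantomSpec(seed=1000 + seed))
    result = analyze_subject_mr(phantom, reconstruction="multiecho")
    pos.append(result.ff_sphere_pos.mean)
    neg.append(result.ff_sphere_neg.mean)

t, df, p = paired_t(neg, pos)
print(f"FF PET-negative {sum(neg)/16:.0f} vs PET-positive {sum(pos)/16:.0f} "
      f"per mille: t({df}) = {t:.1f}, p = {p:.1e}")
```

prints

```
FF PET-negative 697 vs PET-positive 599 per mille: t(15) = 42.3, p = 5.0e-17
```

i.e. on default phantoms (white-adipose FF 700‰, BAT blobs at 600‰, MR SNR
50) the pipeline recovers the designed ~100‰ intra-depot contrast: the
metabolically active tissue is consistently leaner, and the paired t test
rejects decisively.

The numbered drivers under `analysis/` run the full study arc on synthetic
cohorts and write their tables to `results/`:

```sh
python analysis/01_simulate_cohorts.py        # two cohorts (17 + 16 subjects)
python analysis/02_reconstruct_fat_fraction.py
python analysis/03_segment_depot.py
python analysis/04_intra_depot_comparison.py  # paired spheres + t test
python analysis/05_cohort_regressions.py      # simple / pooled / multiple OLS
```

A `batquant` command-line interface wraps the same functions for NIfTI
volumes on disk (`batquant simulate | dixon | suv | segment-mr | segment-ct
| stats`); see `batquant --help`.

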