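# lungmorph

Morphometric complexity biomarkers for lung parenchyma on chest CT, with
a survival-association stage for relating them to radiation pneumonitis
(RP) outcomes after thoracic radiotherapy.

Interstitial abnormalities — fibrosis, emphysema, ground-glass change —
simplify the intricate spatial architecture of healthy parenchyma.
`lungmorph` quantifies that architecture on the **Normal Attenuation
Area** (NAA: voxels with HU in (−950, −700], taken as intact parenchyma)
of a CT volume through three indices:

* **Box-counting fractal dimension** — the power-law exponent
  FD_box = slope of log N(ε) vs log(1/ε), where N(ε) counts the ε-cubes
  needed to cover the NAA mask. Measures space-filling.
* **Lacunarity** — Λ(ε) = σ²/μ² of the gliding-box mass distribution.
  Measures spatial heterogeneity ("gappiness").
* **MST fractal dimension** — h in S(m) = C·m^(−1/h), where S(m) is the
  mean edge length of the minimum spanning tree over m + 1 voxels
  sampled from the NAA, with distances measured as geodesic shortest
  paths *through* the mask. Measures connectivity and structure.

The survival stage dichotomizes each index at the cohort median and fits
Kaplan–Meier / log-rank comparisons and Cox proportional-hazards models
(Efron ties, Wald 95% CIs, Harrell's C, Schoenfeld-residual PH checks)
for the hazard of the lower-complexity stratum.

Because no clinical images or outcomes ship with the package, a phantoms
module generates every validation input: fractal voxel sets with known
dimension (Menger sponge, Mandelbrot percolation, cube/slab/line), HU
volumes whose NAA is a prescribed mask, and synthetic cohorts with
stated hazard ratios. See `docs/methods.md` for the models, defaults and
limitations.

## Worked example

Compute the three indices of a level-3 Menger sponge rendered as an HU
volume (the NAA of the rendering is exactly the sponge):

```python
import lungmorph as lm

sponge = lm.menger_sponge(3)                 # 8000 voxels on a 27^3 grid
vol = lm.mask_to_hu(sponge, seed=0)          # HU volume; NAA == sponge
mask = lm.naa_mask(vol)                      # recovers all 8000 voxels

box = lm.estimate_box_dimension(mask, [1, 3, 9, 27])
print(box.counts, round(box.fd_box, 4))      # [8000, 400, 20, 1] 2.7268

lac = lm.lacunarity_curve(mask, [3, 9])
print(round(lac.aggregate, 4))               # 0.3563

mst = lm.estimate_mst_dimension(mask, seed=17)
print(round(mst.h, 4))                       # 2.3929
```

The box counts fall on the exact self-similar ladder (20^(3−k) cubes at
ε = 3^k), so FD_box equals log 20 / log 3 ≈ 2.7268 to machine precision.
The MST dimension 2.39 sits between a flat slab (≈1.9) and a solid cube
(≈2.75) at the same settings — the sponge is more space-filling than a
surface but gappier than a solid.

Cohort-level association on a simulated cohort (175 subjects, true
hazard ratio 2.3 for the below-median MST stratum):

```python
df = lm.simulate_cohort(lm.CohortSpec(n_subjects=175, hr_low_stratum=2.3, seed=43))
report = lm.run_cohort(df, config=lm.RunConfig(grade_thresholds=(2,)))
```

```
 grade      model      index  n_upper  n_lower  hr_lower  ci_low  ci_high     p  c_index
     2 unadjusted     boxdim       88       87     1.093   0.642    1.860 0.744    0.505
     2   adjusted     boxdim       88       87     1.099   0.617    1.955 0.749    0.595
     2 unadjusted lacunarity       88       87     1.735   1.011    2.977 0.046    0.578
     2   adjusted lacunarity       88       87     1.820   1.013    3.268 0.045    0.657
     2 unadjusted        mst       88       87     2.283   1.298    4.015 0.004    0.588
     2   adjusted        mst       88       87     2.283   1.262    4.131 0.006    0.637
```

The median split yields the 88/87 strata; the index that carries the
simulated hazard (MST) recovers HR ≈ 2.28 with a CI excluding 1, while
the weakly correlated companion indices show attenuated or null effects.

## Command line

```bash
lungmorph phantom --kind menger --level 3 --out sponge.nii.gz
lungmorph segment --volume ct.nii.gz --out naa.nii.gz
lungmorph boxdim --mask naa.nii.gz --epsilons 1,2,4,8 --out box.csv
lungmorph lacunarity --mask naa.nii.gz --out lac.csv
lungmorph mstdim --mask naa.nii.gz --nr 16,32,64,128,256,512 --reps 8 --seed 17 --out mst.csv
lungmorph cohort-sim --n-subjects 175 --hr 2.3 --seed 1 --out cohort.csv
lungmorph run-cohort --cohort cohort.csv --out report.csv
```

CT input may be a NIfTI file or a DICOM series directory (HU rescale
applied, slices sorted by patient position). Every run writes a JSON
manifest of the resolved parameters and seeds.

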