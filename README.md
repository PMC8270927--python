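# plaquekit

Quantitative analysis of carotid atherosclerotic plaque composition versus
inflammation, for imaging scientists working with combined PET/MRI
protocols. The package links two tissue surrogates measured by 4-point
Dixon quantitative MRI — fat fraction (FF, lipid-rich necrotic core) and
R2\* (intraplaque hemorrhage) — to ^18^F-FDG uptake quantified as
standardized uptake value (SUV) and target-to-blood-pool ratio (TBR), and
ships a ground-truth digital phantom so the whole chain is testable without
any patient data.

## The model

Voxel composition follows the magnitude Dixon signal model at echo times
`Te = 3.6, 7.2, 10.8, 14.4` ms (out/in/out/in-phase at 3 T):

    S(Te) = |W + F·cos(2π·Te / 2.4)| · e^(−R2*·Te)

with `FF = F/(W+F)` and a single effective R2\* per voxel. Maps are fitted
by closed-form log-ratio initialization plus bounded nonlinear least
squares. Plaque masks drawn on T1-weighted anatomy are carried between
scanner grids by a nonreflective similarity transform (translation,
rotation, isotropic scale) found by a (1+1) evolution strategy scoring
joint-histogram mutual information; cross-session slice stacks are paired
at the carotid bifurcation landmark. Under the mask, each voxel is
neighbour-averaged within the mask, and only slice means and whole-mask
means enter the statistics. PET quantification uses
`SUV = activity·weight/dose`, a six-point venous blood pool, and
`TBR = plaque SUV_mean / blood SUV_mean` with the whole-plaque SUV_mean
formed slice-first. Associations are Pearson correlations with two-sided
t-based p-values (permutation cross-check included).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Each script in `examples/` runs one capability end to end. The full
chain on a synthetic subject:

```bash
python examples/02_fit_dixon.py
```

```
fitted voxels: 2268
whole-plaque FF:   fitted 0.1132  truth 0.1138
whole-plaque R2*:  fitted 44.39  truth 44.65  (s^-1)
median fit residual: 1.92e-04 (sum of squares, a.u.)
```

At 2% Rician noise the masked whole-plaque means track the phantom truth to
well under a percent of their scale; the residual reflects the injected
noise, not model mismatch. `examples/04_pet_tbr.py` quantifies the rendered
PET study of the same subject and then recomputes the published 12-patient
TBR table:

```
plaque SUV_mean 1.53  SUV_max 1.93
blood-pool SUV_mean (6 points): 1.15
TBR: 1.32
...
group TBR mean 1.49 +/- SD 0.48 over n=12
```

Every per-patient TBR recomputed from the printed plaque and blood-pool
SUV_means agrees with the printed value within 0.02, and the group summary
reproduces 1.49 ± 0.48. `examples/05_correlate_study.py` simulates a
12-subject cohort with uptake independent of composition and shows the
group correlations staying inside the n=12 null band — the pipeline does
not manufacture association.

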