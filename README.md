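# scbkit

Ambient-subtracted sclera chromaticity for smartphone neonatal jaundice
screening.

Neonatal jaundice — the yellowing of skin and sclerae as bilirubin
accumulates — is routinely screened by eye or with transcutaneous
bilirubinometers, both of which have serious limitations (inter-observer
variation, cost, skin-pigment bias). A smartphone can measure sclera
colour objectively, but three confounders stand in the way: skin
pigmentation, ambient light, and camera spectral response. `scbkit`
implements a screening pipeline that addresses all three:

1. **Sclera, not skin** — the sclera accumulates bilirubin but carries no
   melanin, so its colour tracks serum bilirubin across skin tones.
2. **Screen-as-flash ambient subtraction** — a flash/no-flash raw image
   pair is captured with the front camera, the phone screen acting as the
   flash. In linear sensor space, illuminant contributions add:

   I_k^{A+F}(x) − I_k^{A}(x) = Î_k^{F}(x),   k ∈ {R, G, B}

   so subtracting the no-flash frame leaves the scene as lit by the screen
   alone, with the ambient light removed exactly.
3. **Device independence** — a one-time 3×3 linear characterization,
   optimised for the known screen illuminant, maps camera RGB to CIE XYZ.
   Chromaticities x = X/(X+Y+Z) etc. are invariant to exposure, screen
   brightness and phone–eye distance.

The chromaticity is then mapped to a **Scleral-Conjunctival Bilirubin
(SCB)** estimate (μmol/L) with one of two linear models:

- SCB_JECI = m·JECI + n, where JECI = z_D65 − z is the Jaundice Eye
  Colour Index (0 at the D65 white point, positive for yellow sclerae);
- SCB_xy = p·x + q·y + r, a multiple regression on both free
  chromaticity coordinates.

Screening performance against total serum bilirubin (TSB) is quantified
with ROC curves, Youden-optimal cut-offs, sensitivity/specificity/PPV/NPV
with exact (Clopper–Pearson) confidence intervals, and Bland–Altman
agreement.

Because clinical raw-image data cannot be bundled, `scbkit` includes a
**spectral image-formation simulator** that renders ground-truthed
flash/no-flash Bayer-mosaic pairs from first principles (bilirubin-
dependent sclera reflectance, warm/cool/fluorescent ambients, a
D65-balanced screen, Gaussian camera sensitivities, shot/read noise and
quantization). Every stage of the pipeline is tested against this
simulator's exact ground truth.

## Worked example

Simulate a 37-subject study, estimate chromaticities, fit and screen:

```sh
scbkit simulate cohort --n 37 --seed 1 --out-dir scratch/cohort
scbkit estimate-chromaticity scratch/cohort/manifest.csv \
    -c scratch/cohort/characterization.json -o scratch/subjects.csv
scbkit fit-scb scratch/subjects.csv -o scratch/fit.json
scbkit screen scratch/subjects.csv -o scratch/screen.json
```

The `fit-scb` step prints the SCB_xy model summary, e.g.:

```
{
 "model": {
  "family": "xy",
  "p": 4350.469806512426,
  "q": 2404.6324856332226,
  "r": -2169.323691434399
 },
 "pearson_r": 0.9422680079593752,
 "pearson_p": 3.3216890524424748e-18,
 "loocv_rmse_umol_per_L": 36.82391821609637,
 "n": 37
}
```

`pearson_r` is the correlation between the model's SCB predictions and
the blood-test TSB over the cohort; `loocv_rmse_umol_per_L` is the
leave-one-out cross-validated prediction error in μmol/L (each subject
predicted by a model fit on the other 36). `scratch/screen.json` then
reports, per TSB decision threshold (205 and 250 μmol/L by default), the
AUC, the Youden-optimal SCB cut-off, the confusion matrix at that
cut-off and the derived metrics with 95% CIs.

The same analysis is available as a library:

```python
from scbkit.pipeline import characterize_camera, cohort_to_records, analyze_records
from scbkit.simulate import simulate_cohort

cohort = simulate_cohort(37, seed=1)
M = characterize_camera(cohort.camera, cohort.screen)
records, excluded = cohort_to_records(cohort, M)
report = analyze_records(records)
```

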