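# Methods

## The measurement model

A linear camera records, for channel k ∈ {R, G, B} at a scene point,

    I_k = a · ∫ E(λ) S(λ) Q_k(λ) dλ

where E is the illuminant spectral power, S the surface reflectance,
Q_k the channel sensitivity, and a a geometry/optics scale factor. The
integrand is linear in E, so a frame captured under ambient-plus-screen
illumination minus a frame captured under ambient alone equals, pre-noise,
the frame that the screen alone would have produced. This subtraction is
the core of the method: it replaces an unknown ambient illuminant with a
known one (the phone screen), after which a one-time screen-optimised
3×3 RGB→XYZ characterization yields device-independent colour.

Everything downstream uses chromaticity, (x, y, z) = (X, Y, Z)/(X+Y+Z),
which cancels the unknowns a, exposure, screen radiance and phone–eye
distance (anything that scales all channels equally). Yellowness is
summarised by the Jaundice Eye Colour Index, JECI = z_D65 − z, zero for a
neutral (D65-chromaticity) sclera and increasing as bilirubin absorbs
blue light. Two linear models map chromaticity to a Scleral-Conjunctival
Bilirubin estimate in μmol/L: SCB_JECI = m·JECI + n (one predictor) and
SCB_xy = p·x + q·y + r (both free coordinates). Both are fit by ordinary
least squares — the default reading of "linear regression"; nothing in the
data here motivates robust or weighted variants. Model quality is
reported as Pearson correlation with TSB (for SCB_xy, the correlation of
its predictions with TSB, i.e. the multiple correlation coefficient) and
leave-one-out cross-validated RMSE, the honest generalization error for
cohorts of tens of subjects.

### Assumptions the subtraction needs

- linear sensor response (raw capture; only black-level subtraction and
  scaling to the saturation level are applied — no demosaic, white
  balance or tone curve);
- identical exposure for the two frames, or signals rescaled by the
  exposure ratio before subtracting;
- no saturated sample in either region of interest;
- a static scene and static ambient between the two captures.

Violations are data, not exceptions: a pair whose post-subtraction
triplet has any negative channel (ambient changed) or any channel below
1% of the normalized bit-depth range (flash signal too weak) is rejected
with a reason code, and a subject with no surviving triplet is reported
unmeasurable. The 1% threshold is interpreted on the normalized scale
(0.01 of white_level − black_level) and applied per triplet, not per
channel — a triplet with one unusable channel has no usable chromaticity.
Channel medians are taken directly over colour-filter-array sites (the
two green sites pooled into one sample set), and multiple pairs/ROIs per
subject are median-aggregated.

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| threshold_frac | 0.01 | fraction of DN range | post-subtraction validity filter |
| TSB decision thresholds | 205, 250 | μmol/L | clinical screening thresholds |
| SCB cut-off | Youden-optimal | μmol/L | ties break toward the lower cut-off (higher sensitivity) |
| D65 white point | x 0.31272, y 0.32903 | — | JECI zero point |
| wavelength grid | 380–780, 5 nm | nm | trapezoidal spectral integration |

Positivity conventions are strict: the condition is TSB > threshold and
the test is SCB > cut-off; ties count as negative. Confidence intervals
on sensitivity/specificity/PPV/NPV are exact Clopper–Pearson; a metric
with a zero denominator is reported as undefined rather than zero.
Negative SCB predictions are reported (flagged) rather than truncated so
that ROC and Bland–Altman analyses see the raw model output. The ROC
sweep uses the observed SCB values plus ±∞ sentinels with trapezoidal
AUC, which makes the AUC identical to the normalized Mann–Whitney
statistic (asserted in tests).

## Colorimetry

The CIE 1931 2° colour-matching functions are evaluated from the
piecewise-Gaussian analytic fit of Wyman, Sloan & Shirley (JCGT 2013),
clipped at zero (the x̄ fit has a ~2·10⁻³ negative excursion near
500 nm). The fit reproduces the tabulated observer to well under 0.01 in
chromaticity for smooth spectra, which is the regime this pipeline works
in; no data tables need shipping. Spectral products are integrated by
the trapezoid rule on a uniform 5 nm grid over 380–780 nm
(convergence-tested: halving the step moves tristimulus values by
< 0.1%).

Device characterization minimizes unweighted squared XYZ error over a
synthetic training card (neutral greys, broad Gaussian bump/notch
colours, and a graded series of blue-absorbing yellows spanning the
sclera colours of interest), rendered under the screen illuminant. No
perceptual weighting or white-point constraint is applied; the objective
is pluggable. For a camera satisfying the Luther condition (sensitivities
that are linear combinations of the matching functions) the fit residual
is zero to machine precision; for the generic Gaussian-sensitivity camera
the residual is real and is larger for narrowband colours outside the
training card — both behaviours are asserted in tests.

## The simulator

The simulator exists so that every pipeline stage can be tested against
exact ground truth without clinical data. It renders the full chain:
spectral scene → per-channel integrals → gain/exposure scaling → Bayer
mosaic → Poisson shot noise and Gaussian read noise → black level →
clipping at the saturation level → integer quantization. Pre-noise
renders are additive across illuminants to 1e-12, which is the physical
premise of the subtraction and is asserted as an invariant.

Model components, all configurable:

- **Sclera**: S(λ) = S₀(λ) · 10^(−ε(λ)·TSB), with S₀ a flat reflectance
  (default 0.85, optional mild blue tint for thin neonatal sclerae) and
  ε a Gaussian absorption band at 460 nm (width 35 nm, peak optical
  density 10⁻³ per μmol/L, i.e. OD 0.5 at TSB 500). Bilirubin absorbs
  blue light; only this monotone TSB→yellowness link matters for testing
  the pipeline, not the exact band shape.
- **Screen**: a broadband (6500 K blackbody) base carrying ~70% of the
  luminance plus three RGB Gaussian peaks, with the peak weights solved
  so the white lands exactly on the D65 chromaticity. This emulates a
  high-CRI LCD; its smoothness keeps metamerism against daylight small
  (≈0.002 JECI on chart patches), which is a property a screen
  illuminant must have for chart ground truth measured under daylight to
  be recoverable.
- **Ambients**: 2700 K blackbody (warm LED), a blue-pump + phosphor
  cool-white LED solved to the D65 x coordinate (≈6500 K), and a spiky
  fluorescent approximation (phosphor base plus mercury-like lines).
- **Camera**: Gaussian sensitivities at 600/540/465 nm (generic mobile
  sensor) or the matching functions themselves (Luther camera, for
  exactness tests); 10-bit output, black level 64, white level 1023,
  read noise 1 DN, shot noise via a Poisson electron count at
  10 e⁻/DN. "Low"-noise rendering (0.2 DN read, 100 e⁻/DN) gives
  per-site SNR well above 100 at working signal levels.
- **Chart**: yellowness patches whose blue-absorption strength is
  root-found so each patch's chromaticity under a smooth daylight-like
  reference illuminant (a tilted 6500 K blackbody solved to have exactly
  the D65 chromaticity) hits a target JECI to 1e-12; the JECI = 0 patch
  is plain white by construction.

### The simulated cohort

`simulate_cohort` emulates a neonatal-unit screening study: TSB drawn
lognormally with median 180 μmol/L (σ_log = 0.5, clipped to 30–500),
matching the skewed severity distribution of babies referred for a blood
test; one ambient per subject (warm/cool/fluorescent at a random
intensity 0.05–0.35 of the screen's white-patch signal, itself 0.45 of
the DN range); 1–3 flash/no-flash pairs per subject with the screen
radiance and shading varying per pair the way phone–eye distance varies
between captures; biological scatter as a lognormal (σ = 0.12)
per-subject bilirubin-deposition efficiency plus a small baseline tint
jitter, so colour tracks TSB strongly but not perfectly. All randomness
flows through one seeded generator; a fixed seed reproduces the cohort
bit-for-bit, frames included.

What the simulator does **not** emulate — and what passing tests
therefore do not show about real data: spatial sclera texture (vessels,
specular highlights, eyelashes: ROIs here are uniform patches, so the
median's robustness is exercised only logically), subject motion between
captures, ambient drift within a capture, vendor raw-format quirks,
camera nonlinearity, and the true bilirubin deposition physiology (the
linear-in-chromaticity TSB link is built in, so recovered correlations
near 0.96 say the pipeline is unbiased and noise-robust, not that real
sclerae behave this linearly — the clinical correlation is known to be
substantially lower).

## Problem sizes and numerical choices

The cohort experiments use 200 subjects on 8×8 mosaics and the chart
experiments 16×16 mosaics — sizes chosen so chromaticity estimates are
quantization-limited rather than pixel-count-limited, since a uniform
noiseless patch quantizes identically at every site. Exactness tests
render well-exposed frames (signals high in the 10-bit range, below
saturation) as the capture protocol prescribes; at mid-range signals the
deterministic ±0.5 DN rounding alone can move chromaticity by ~1e-3.
Root-finds (chart strength, illuminant tilts, LED balance) use Brent or
Powell-type solvers with tolerances far below the quantities' meaningful
precision. Degenerate inputs fail loudly: constant-JECI regressions,
collinear (x, y) designs, single-class ROC data, zero-variance
correlations, all-invalid subjects, zero-sum chromaticity normalization.

## Known limitations

- The two SCB models are deliberately linear; the systematic
  underestimation of high TSB visible in Bland–Altman analysis is an
  inherent regression-to-the-mean property of OLS prediction (asserted
  as such in tests) and would need a larger cohort and richer models to
  address.
- The characterization is optimal only for the screen illuminant; the
  pipeline deliberately reuses it for the no-subtraction baseline, which
  is part of why that baseline degrades under coloured ambients.
- The analytic CMF fit is not suitable for narrowband stimuli (laser-like
  spectra) where its ~1% local errors matter.
- ROI masks are inputs; no automatic sclera segmentation is provided.
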