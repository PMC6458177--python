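# Methods

This note documents the models, numerical choices and limitations behind
`mammodose`. It is written for a reader who wants to know exactly what the
package computes and what its tests do — and do not — demonstrate.

## 1. The three AGD formalisms

All three estimates share the same physical target: the mean absorbed dose
to the fibroglandular tissue of the compressed breast (AGD, in mGy).

**Dance pathway.** `AGD = IAK · g · c · s`. IAK is the incident air kerma
at the breast entrance surface *without* backscatter (mGy); no backscatter
correction is applied anywhere in the package. `g` (dimensionless mGy/mGy)
converts IAK to AGD for a 50 % glandular breast and is tabulated on a
thickness × HVL grid covering 20–110 mm and 0.3–0.8 mm Al. `c` corrects for
glandularity ≠ 50 % and equals 1 at 50 % by construction. `s` is a scalar
per anode/filter pair with s(Mo/Mo) ≡ 1. Queries outside the stated
thickness/HVL validity ranges raise range errors rather than extrapolate.

The population ("Dance") glandularity is tabulated per age group and
thickness. Only the 40–49 and 50–64 group profiles exist; ages outside map
to the nearest group (< 40 → 40–49, ≥ 65 → 50–64). The policy is a
configurable object (`AgeGroupPolicy`). The 50–64 profile is the printed
reference table (100 % at 20 mm falling to 3 % at 110 mm); the 40–49
profile is assembled from published cohort means by thickness class at
documented class-representative thicknesses (see §2), because no nodewise
table for that group is available. Age influences the c-factor only through
this glandularity pathway.

**Wu pathway.** `AGD = X_ese · DgN`. In clinical data the vendor already
evaluated this; the default mode is pass-through of the header value. In
compute mode (used for synthetic cohorts) the glandularity entering DgN is
the *densest-region* estimate, mirroring vendor exposure-control behaviour:
`min(2 · GPW, cap)` with cap 100 % by default ("double-capped"); the
densest-region value approaches the whole-breast glandularity for very
dense and extremely fatty breasts and is roughly twice it otherwise. The
package ships no true Wu/Boone DgN coefficients (deliberately out of
scope); the default DgN is a *Dance-equivalent* table, `g·c·s` per unit
IAK, so compute-mode Wu results are approximate by construction. A
consequence worth knowing: with this stand-in the synthetic vendor/
personalized ratio cannot reverse above ~65 mm the way real vendor doses
do, because that reversal originates in skin-layer and spectrum model
differences between the Wu and Dance Monte-Carlo breast models which the
stand-in does not carry. Users may supply real DgN tables (long-form CSV
rows or any callable).

**Personalized pathway.** Identical to the Dance formula, but `c` is
evaluated at the individually measured percent-by-weight glandularity
(GPW). For equal inputs and equal glandularity the Dance and personalized
AGDs are identical — the two methods differ only through the glandularity
estimate. This identity is unit-tested.

Per record the three pairwise ratios satisfy
`(dance/wu)·(wu/volpara) = dance/volpara` exactly; the suite asserts it to
1e-12 on a 10⁴-exposure cohort.

## 2. The factor tables and their interpolation

Tables load from a long-form CSV
(`table_name, glandularity_pct, thickness_mm, hvl_mm_al, anode, filter,
age_group, role, value`); the packaged default contains every printed value
of the published reference grid plus the paired population/personalized
c-points by thickness class. The `role` column (dance/volpara) keeps those
pairs linked so the printed percentage dose ratios
(`round(100·c_dance/c_volpara)`, 87…104) can be recomputed from the stored
values — the suite checks all 14.

*g*: bilinear interpolation on the rectangular grid (hand-rolled scalar
bilinear; generic N-d interpolators dominated the per-exposure runtime).
Exact at nodes, bounded by bracketing nodes.

*c*: the printed data are scattered — a reference curve (one glandularity
per thickness, three HVLs) plus isolated class points at single HVLs. The
surface is structured as one glandularity profile per thickness node:

- anchors tabulated across HVL interpolate linearly in HVL;
- isolated single-HVL anchors are carried to other HVLs by scaling with
  the reference-curve shape at that thickness (the ratio
  c_ref(t, h)/c_ref(t, h_anchor));
- the definitional anchor c(50 %) = 1 is added wherever the table does not
  pin 50 % itself;
- a profile that pins only a single glandularity (the 40 mm node, where
  the reference glandularity is exactly 50 %) borrows its glandularity
  shape from the nearest richer profiles, rescaled through the pinned
  value;
- profiles are piecewise linear in glandularity with end-clamping (a
  clamped query is counted and logged), and the two profiles bracketing
  the query thickness are blended linearly.

This construction is exact at every stored node, strictly decreasing in
glandularity (a convex combination of monotone profiles), and cannot
overshoot bracketing anchors. Class-representative thicknesses for the
isolated points are 23 / 32.5 / 44.5 / 53.5 / 62 / 75 / 90 mm (class
midpoints; 23 and 90 for the open-ended classes). Caveat: the isolated
c-points are cohort means, not true surface nodes, so between nodes the
surface is a plausible interpolant, not physics.

*s*: defaults are Mo/Mo 1.000, Mo/Rh 1.017, Rh/Rh 1.061, Rh/Al 1.044,
W/Rh 1.042, W/Ag 1.042, taken from the published s-factor literature;
unknown pairs raise a lookup error listing the supported ones.

## 3. Image-based density estimation

The breast is modelled as two tissues. With pixel values linear in imparted
energy, the dense-tissue thickness along a ray is
`h_d = ln(P/P_fat) / (μ_fat − μ_dense)`; for a dense pixel both the
logarithm and the denominator are negative, so h_d ≥ 0 as written. Raw
values below 0 (noise above the adipose reference) clamp to 0; values above
the recorded thickness clamp down; both are counted and logged. Defaults:
μ_fat 0.046 /mm, μ_dense 0.080 /mm (effective values at ~20 keV).

VBD = 100 · Σ h_d · pixel area / (breast area · recorded thickness). The
VBD→GPW conversion removes a subcutaneous adipose layer (5 mm per side,
configurable) from the column, assumes the dense tissue lies within that
core, and weights by mass densities ρ_fat 0.93 and ρ_dense 1.04 g/cm³
(standard literature values; the true vendor conversion is unpublished, so
this is a documented stand-in with exposed parameters). The conversion is
monotone in VBD and reduces to the identity in the equal-density,
zero-layer limit; both properties are tested, and the numerical inverse
(bisection) is used when generating cohorts.

P_fat comes either from phantom ground truth (`known_reference`) or from an
upper percentile (default 99th) of interior pixel values — under the
two-tissue model the fattiest columns are brightest. On an all-dense image
the percentile strategy necessarily mistakes dense tissue for fat: on a
uniform 40 %-VBD phantom the estimate collapses to 0 % (the error equals
the uniform dense thickness). The test suite pins this failure mode
explicitly; real use requires a visible fatty region, which is also true of
the production algorithms this emulates.

Segmentation is out of scope: phantoms carry exact masks
(interior/edge/background), and user images are expected to supply masks.
A 15 % error in recorded breast thickness moves the slab-phantom VBD by
about 3 percentage points downward (tested as a bounded, direction-checked
effect); the magnitude depends on the phantom.

Phantoms are forward-projected with `P = P₀·exp(−μ_fat·(t−h_d) −
μ_dense·h_d)`, optional multiplicative Gaussian noise, elliptical or
full-frame breast shapes and rectangular dense inserts; generation is
deterministic under a seed and ground truth (dense map, VBD, P_fat) is
attached. On noiseless phantoms the inversion is exact per pixel and VBD
matches construction truth to well under 0.5 percentage points at 0.1 mm
pixels.

## 4. The synthetic cohort generator

The generator's defaults are the study conditions the analysis assumes; all
parameters live in `CohortParams` and are serialized into the run sidecar
together with every latent truth.

- **n** 3050 exposures, alternating CC/MLO view labels.
- **Age**: truncated normal on [18, 80] y whose *post-truncation* mean and
  nominal SD are 57.9 and 11.9 y (the location parameter is solved for,
  since asymmetric truncation shifts a clipped normal's mean by about
  −1 y).
- **Thickness**: truncated normal on [20, 110] mm, post-truncation mean
  57 mm, SD 13.5 mm — chosen analytically so the four thickness classes
  (20–40 / 41–60 / 61–80 / >80 mm) carry ≈ 10.6 / 48.0 / 37.2 / 4.2 % of
  exposures, matching the published bin counts (322/1464/1135/129); a
  generator test holds the shares to ±5 points.
- **HVL**: class-representative values 0.380 / 0.380 / 0.397 / 0.414 /
  0.430 / 0.459 / 0.459 mm Al over the classes bounded at 26, 39, 50, 57,
  67 and 83 mm, plus N(0, 0.005 mm) jitter, clipped to [0.34, 0.50] —
  beam quality hardens with thickness, as exposure control does.
- **Glandularity** (the "measured" GPW): 59.6 − 0.332·age −
  0.431·thickness + ε, clipped to [0, 100]. The residual ε is zero-mean
  with SD 8.4 and a standardized-lognormal shape (shape 0.8): glandularity
  is non-negative and right-skewed, so a skewed residual with a bounded
  lower tail is the more faithful family (Gaussian is available via
  shape = 0). The SD was calibrated once so that the OLS refit on a large
  default cohort gives R² ≈ 0.39; with these defaults only ~3 % of draws
  clip at 0. Clipping still attenuates refits slightly (large-cohort
  expectations ≈ −0.416 and −0.322 for the thickness and age
  coefficients); both stay within three reported standard errors of the
  generating values, which the suite asserts at n = 3050.
- **IAK**: log-normal with median 0.8·exp(0.028·(t−20)) mGy and σ_log
  0.25 — an exposure-control-like rise from ≈ 0.8 mGy at 20 mm to ≈ 10 mGy
  at 110 mm.
- **Spectrum**: Mo/Mo-dominated below 40 mm, Mo/Rh at mid thickness,
  Rh/Rh above 60 mm, with randomized assignment.
- **Vendor AGD**: generated through the Wu compute pathway (densest-region
  glandularity into the configured DgN table, default Dance-equivalent),
  so the vendor column is internally consistent rather than copied.

All randomness flows from one seed through named substreams (one per
field), so adding a field never perturbs existing draws, and identical
seeds reproduce cohorts exactly (tested). Age and thickness are drawn
independently — their real correlation is unknown — and this is a known
fidelity limitation, as is the Dance-equivalent vendor AGD.

**What passing tests show / do not show.** The generator reproduces the
*marginals and the regression structure* the analysis assumes, so green
tests demonstrate that the pipeline's algebra, interpolation, inversion and
statistics are correct, and that qualitative patterns forced by the
glandularity-model gap (population/personalized dose ratio < 1 for thin
breasts, ≈ 1 for the thickest class; personalized densities concentrated in
the lowest quartile category while population densities spread) emerge for
the right structural reasons. They do not certify cohort-specific published
statistics — class-mean ratios, Pearson correlations, extreme values —
which depend on the unavailable patient sample and are deliberately not
asserted.

## 5. Comparison analysis

- Thickness classes 20–40 / 41–60 / 61–80 / >80 mm, assigned after
  rounding to integer mm (round-half-even); values below 20 mm go to the
  lowest class with a warning. SDs use the sample (n−1) denominator.
- Density categories are glandularity quartile bins (0–25 / 25–50 /
  50–75 / 75–100 %); boundary values fall to the lower bin, exact 0 to
  category 1. Vendor-style volumetric thresholds are intentionally not the
  default.
- The glandularity regression is ordinary least squares
  (`statsmodels.OLS`) of GPW on age and thickness, reporting coefficients,
  standard errors, R² and the overall-F p-value; a constant response
  yields zero slopes with R² defined as 0.
- Correlations are Pearson r with two-sided p (`scipy.stats.pearsonr`);
  zero variance raises rather than returning NaN.
- `AGDComparison` / `AGDComparisonResults` wrap the stage in a
  model-object interface (`from_dataframe`/`from_records`/`from_csv`,
  `fit()`, `summary()`, `plot_ratio_vs`).

## 6. Pipeline and I/O

`run_pipeline` executes read/simulate → dosimetry → comparison and writes
the report bundle (AGD table, ratio summary, regression, category counts,
correlations, human-readable summary) plus the resolved config and a
manifest (library versions, seed, config hash). Identical config and seed
reproduce outputs byte for byte (tested). Records that cannot complete a
method are skipped with per-record logged reasons (or fail fast,
configurable); skips are written to the bundle. DICOM reading touches
headers only; ages parse from DICOM age strings or fall back to birth/study
dates truncated to whole years; the vendor dose tag (stored in dGy) is
scaled to mGy; private density tags are mapped per software version through
`DicomTagMap`.

## 7. Problem sizes and tolerances

Default verification sizes were chosen to keep the full suite fast while
leaving no statistical check underpowered: factor-node checks are exact
(bit-level equality on stored values); closure/linearity run on 10⁴
synthetic exposures at 1e-12 tolerance; the density inversion runs on a
600×600 phantom at 0.1 mm pixels with a 0.5-point VBD tolerance; the
regression recovery runs at the study size n = 3050 against 3× the
reported standard errors (±3.144 / ±0.042 / ±0.036 for intercept / age /
thickness).

## 8. File formats

Factor tables and cohorts travel as long-form/flat CSV (schemas in §2 and
the cohort module); phantom projections as 16-bit TIFF plus a YAML sidecar
(pixel size, recorded thickness, quantization scale, optional P_fat ground
truth) and a PNG label mask (0 background / 1 interior / 2 edge). The
uint16 quantization changes recovered VBD by well under 0.1 percentage
points on the test phantoms. DICOM is read-only and header-only. Report
bundles are CSV/JSON plus PNG figures.
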