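# Methods

## The indexes

The choroid's volume distribution across the macula is summarised by two
log-ratio indexes computed from ETDRS-grid choroidal volumes:

* vertical CSDI = ln(V_superior / V_inferior)
* horizontal CSDI = ln(V_temporal / V_nasal)

where each directional volume sums the inner and outer quadrant subfields on
that side (the central subfield belongs to no direction). The log-ratio
makes the index dimensionless, symmetric in interpretation (±x mean the same
degree of tilt in opposite directions) and invariant to overall choroidal
size; it is undefined when a directional volume is ≤ 0, which the code
treats as an error rather than clamping — non-positive sector volumes do not
occur in healthy eyes and indicate corrupt input.

CSDIs are always computed from volumes. For opposing sectors of equal area
the volume ratio equals the mean-thickness ratio, but rasterized areas of
opposing sectors differ slightly on coarse grids, so the volume definition
is the one implemented. Internally values are kept in double precision;
only human-readable displays round to three decimals.

## ETDRS geometry and rasterization

The grid is the standard ETDRS partition: circles of 1, 3 and 6 mm diameter
(configurable) centred on the fovea, quadrants split at the 45° diagonals.
Masks are rasterized by **pixel-centre assignment**: a pixel belongs to the
subfield containing its centre, with half-open radial bins [0, c/2), [c/2,
i/2), [i/2, o/2) and half-open angular bins starting at 45°, so boundary
pixels are assigned deterministically. No partial-pixel weighting is
applied; the convergence test shows rasterized areas within 0.5% of the
analytic circle/annular-sector areas at 0.01-mm spacing, and within ~5% for
the outer quadrants on the 31-B-scan device raster (0.24 mm line spacing).

Coordinates are anatomical — +x temporal, +y superior — and laterality is
resolved once, at mask construction (OS mirrors the horizontal axis).
Everything downstream is laterality-free, and the same anatomical surface
yields bit-identical CSDIs processed as OD or OS.

The fovea is a real-valued (sub-pixel) index supplied with the map; fovea
detection is out of scope. If the 6-mm circle does not fit on the raster
the geometry raises a truncation error naming the clipped subfields instead
of silently integrating a partial sector.

## Volumetrics

Subfield volume is the Riemann sum `Σ thickness_μm × 10⁻³ × pixel_area_mm²`
over the subfield's pixels on the native raster (no resampling between
B-scans; anisotropic pixel area honoured), and mean thickness is
`10³ × volume / area`, the identity device software uses, so the two
representations interconvert exactly. Maps with missing (NaN) or negative
values inside the 6-mm disc are rejected with a count of offending pixels —
mirroring the practice of excluding artefacted scans rather than imputing;
values above 1200 μm warn as biologically implausible. Subfoveal thickness
is read at the pixel centre nearest the fovea. When two observers measure
the same eye, the element-wise mean of their summaries is the analysis
value, and the paired summaries feed the reproducibility statistics.

## Reproducibility statistics

* **ICC**: single-measure, two-way random effects, absolute agreement —
  ICC(A,1), computed via `pingouin.intraclass_corr`; the 95% CI is the
  standard F-based interval (McGraw & Wong) evaluated at full precision
  from the ANOVA mean squares. Single measures (not average) were chosen
  because each rating entering the table is one observer's measurement.
  An independent explicit sums-of-squares oracle verifies the estimate in
  the tests.
* **Bland–Altman**: limits of agreement mean(d) ± 1.96·SD(d) with the
  sample SD (ddof = 1) of per-subject differences d = A − B.
* **Coefficient of reproducibility**: defined here as CR = 1.96·SD(d), the
  Bland–Altman repeatability coefficient. An alternative convention
  (2.77 × within-subject SD) exists; the 1.96·SD(diff) form is the one
  whose simulated magnitudes match published inter-observer figures for
  manual choroidal segmentation (≈17–24 μm) at plausible noise levels.

## Distribution tests

One-sample t (two-sided, against 0) and Shapiro–Wilk come from scipy. The
Kolmogorov–Smirnov test is run against a normal with *estimated* mean/SD,
which invalidates the classical KS null; the p-value is therefore
Lilliefors-corrected using a seeded Monte-Carlo null (default 10⁴
standard-normal samples of the same size, each standardized exactly as the
data), matching the behaviour of common statistics packages. The naive KS
p-value against the fitted normal remains available behind a flag. The
Monte-Carlo p uses the (1 + exceedances)/(n_mc + 1) estimator, so it is
never exactly zero.

## Screened regression

For each outcome (vertical or horizontal CSDI), every candidate covariate is
first fit in a univariate OLS; covariates with univariate P < 0.10 enter a
single multivariable OLS. All variables — binary covariates included,
coded 0/1 — are z-scored on the sample before fitting, so coefficients are
standardized betas (outcome-SD per covariate-SD) with p-values identical to
the unstandardized fits. Complete cases only; fewer than 10 cases per
candidate covariate warns; a screened design with condition number above
10⁸ is an error naming the covariates. No multiple-testing correction is
applied and ordinary (not robust or cluster-aware) standard errors are
used, replicating the conventional workflow; both choices are limitations —
in particular, p-values downstream of the screen inherit its selection
optimism, and cohorts containing relatives (e.g. twin studies) violate the
independence assumption.

## Synthetic data

The generator defines the study conditions under which the pipeline is
validated:

* **Surface**: t(x,y) = peak·exp(−(x²+y²)/(2s²)) + gₓx + g_y y + ε with the
  dome peak at the fovea (population 296.6 ± 97.2 μm), dome scale s = 6 mm
  (a gentle decline over the 6-mm grid), and optional iid pixel noise ε.
  This family is an artifact choice: sector integrals of both terms are
  closed-form, giving every test an analytic oracle, and a target CSDI h
  inverts exactly to a gradient g = (V/K)·tanh(h/2) (V the symmetric sector
  volume, K the sector's first moment √2(R³−r₀³)/3 × 10⁻³). It does not
  emulate choroidal vasculature texture, watershed anatomy, or
  diurnal variation, so passing tests certify the *pipeline*, not any
  biological claim.
* **Observer error**: per-observer independent smooth fields — standard
  normal draws on a ~1.5-mm control grid, cubic-spline upsampled and
  rescaled to a pixel SD of 9.6 μm (the default). The amplitude was
  calibrated so the SD of paired subfield mean-thickness differences is
  ≈ 9 μm, i.e. CR ≈ 17.6 μm, inside the published 17–24 μm range; outer
  subfields average more area and therefore show smaller CRs than inner
  ones, a wider spread than published per-subfield tables.
* **Cohort**: n = 363 by default; covariates drawn independently from the
  reference marginals (age 48.5 ± 13.8 y, axial length 23.68 ± 1.03 mm,
  IOP 14.4 ± 2.8 mmHg, subfoveal thickness 296.6 ± 97.2 μm clipped at
  30 μm, HDL-C 53.6 ± 11.9, LDL-C 193.8 ± 35.3 mg/dL, BMI 23.7 ± 3.1
  kg/m²; male 38.8%, hypertension 17.6%, diabetes 5.5%, alcohol 59.0%,
  smoking 28.7%). Each CSDI is mean + sd·(Σβⱼzⱼ + √(1−Σβⱼ²)·ε) with
  population-standardized covariates, targets 0.062 ± 0.206 (vertical) and
  0.138 ± 0.226 (horizontal), and default links age→vertical +0.129,
  subfoveal→vertical −0.104, axial→horizontal +0.215, subfoveal→horizontal
  −0.283, age→horizontal −0.105. Links with Σβ² > 1 are rejected as
  infeasible. Real covariates are correlated (the generator's are not), so
  simulated univariate and multivariable betas coincide in expectation
  here, unlike in real cohorts.
* **Two generation paths** with the same statistical contract: a direct
  draw of the CSDIs (fast; used for large replicate counts) and full
  thickness-map realisation, where the drawn subfoveal thickness becomes
  the dome peak and the drawn CSDIs are inverted into tilt gradients; the
  maps path reproduces the direct path's CSDIs to ~10⁻³ on the device
  raster, tying the statistical tests to the geometric pipeline.

All generators take explicit seeds and are bit-reproducible.

## Numerical and testing choices

* Test problem sizes: analytic-area and oracle comparisons run on a
  701×701 grid at 0.01 mm; Monte-Carlo checks use 100–300 replicates
  (Lilliefors calibration 150 trials × 1000-sample nulls; parameter
  recovery 200 replicates at n = 363). These sizes keep the full suite
  under a minute while leaving comfortable statistical margins.
* The cohort-moment convergence check at n = 10,000 asserts the sample
  mean within 3 standard errors of the target (2% of a mean of 0.062 would
  be below one SE even at that n) and the SD within 2% relative.
* The one-pixel-wide half-open diagonal bins leave a ~10⁻³ residual in
  "exactly zero" CSDI checks on fine rasters; tolerances reflect that.
* Degenerate inputs fail loudly: zero-variance ICC tables, constant
  samples in normality/t tests, n < 2 Bland–Altman, collinear screened
  designs, non-positive directional volumes.

## Known limitations

CSDIs summarise only the tilt of the distribution, not finer topography.
The generator's independence assumptions (between covariates, between
subjects) are simplifications — no twin/family correlation structure is
modelled. The smooth observer-error field is calibrated only to the
printed reproducibility magnitude, not to any measured spatial covariance
of real segmentation disagreement.
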