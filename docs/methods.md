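# Methods

## Instrument model

The package targets a push-broom imaging spectrometer mounted over a
conveyor-fed imaging chamber. A scanning mirror exposes one spatial
line (320 detector pixels) per step; 500 steps cover the 2,500 mm
chamber height at 5 mm per pixel, and 320 pixels span the 1,600 mm
width, so pixels are 5 mm squares. Each pixel records 243 spectral
bands. The spectral axis is built as 243 uniformly spaced band centers
spanning 550–1700 nm **inclusive**, giving a spacing of
1150/242 ≈ 4.752 nm. The camera's nominal interval of 4.77 nm is kept
as metadata only: 243 steps of 4.77 nm starting at 550 nm would end
near 1704.9 nm, inconsistent with the stated endpoint, and of the three
quantities (count, endpoint, interval) only the interval is described
as nominal. Cubes are stored as ENVI-style 16-bit unsigned BIL files
with a plain-text header; only this one configuration is supported, and
the reader/writer round-trips bit-exactly (unknown header keys are
preserved verbatim).

## Reflectance extraction

Apparent reflectance is the band-wise ratio of plant digital numbers to
the paired blank-chamber reference scan. Because both scans share the
lamp spectrum and the illumination field, the ratio cancels both — this
is an exact algebraic property of the simulator and holds on real data
to the extent the chamber is stable between the two scans. Choices:

- Ratios are clipped to [0, 1] after division; reflectance is treated
  as fractional by definition. Pre-clip values are not retained.
- Voxels with zero reference intensity are flagged invalid, never
  clipped or imputed, and are excluded from every downstream average.
- NDVI uses the bands nearest 705 and 750 nm (the grid has no exact
  bands there; the nearest centers are ≈706.8 and ≈749.6 nm). Distance
  ties break toward the lower band index.
- Segmentation is a strict threshold, NDVI > 0.20, with no
  morphological cleanup: thresholding alone is the defined procedure.
  An empty mask raises an error identifying the plant rather than
  producing a silent zero-pixel spectrum.
- The mean spectrum averages masked, valid pixels per band and records
  the per-band contributing count; a band with no valid masked pixels
  is flagged invalid rather than filled in.

## PLS1 calibration

One model per trait (PLS1), computed by NIPALS on mean-centered,
unscaled data. Reflectance bands share a common scale, so autoscaling
would only amplify noise bands; centering alone is the spectroscopic
default. For a single response NIPALS is non-iterative per factor:
weight w_a ∝ Xᵀy, score t_a = Xw_a, loadings p_a, q_a by least squares,
then deflation. The regression vector is B = W(PᵀW)⁻¹q. At full rank
the fit coincides with ordinary least squares (checked in the tests
against the pseudoinverse); scores are mutually orthogonal to 1e-8
relative tolerance.

Factor selection is leave-one-out cross-validation over 1..12 factors
(additionally capped at n − 2 so every fold is fittable, and at the
band count). The selected size is the smallest count attaining the
minimum RMSE_CV; counts whose RMSE_CV lies within 1e-9 of the response
scale of the minimum are treated as tied, so noise-free data resolve to
the true rank instead of accumulating numerically spurious factors. The
fold loop contains no randomness: identical inputs give identical
curves. Rank-deficient folds truncate gracefully and pad with the last
fittable model.

The calibration/validation split is stratified by species × treatment
with a seeded permutation per stratum; largest-remainder rounding
alternates the extra plant of odd strata so the default 120-plant
design splits exactly 60/60 while per-stratum counts differ by at most
one. A Welch two-sample test per trait (α = 0.05, no multiplicity
correction, advisory only) checks that the halves do not differ
systematically. PCA screening (mean-centered SVD) flags plants with any
of the first three component scores more than 3 SD from the mean;
flagged plants are retained by default — the flag is advisory, and a
`drop` policy is available on the command line.

## Evaluation statistics

- **RMSE** uses divisor N.
- **RPD** = SD/RMSE with the **sample** SD (divisor N − 1) of the
  measured values of the evaluated set. The mixed convention is
  deliberate and documented because switching either divisor moves RPD
  at the second decimal for N = 60.
- **MAPE** here is the mean absolute error divided by the **mean of the
  measured values of the evaluated set**, × 100 — a set-mean-normalised
  error, not the per-observation percentage error. Cross-validation
  statistics use the calibration set's mean; validation statistics the
  validation set's.
- **R²** defaults to the squared Pearson correlation between measured
  and predicted values; 1 − SSres/SStot is available via
  `mode="ssr"` (the two differ when predictions are biased). Squared
  Pearson is the default because the statistic is defined as a
  correlation between measured and predicted values.
- **RPD bands**: < 1.5 poor; 1.5–2.0 fair/screening; 2.0–3.0 good;
  > 3.0 quantitative. Band boundaries belong to the lower band. A
  perfect model (RMSE = 0) reports an infinite-RPD flag, not a number.

## Simulator

The simulator emulates the structure of a two-experiment greenhouse
campaign, not its biology:

- **Design**: 120 plants = 2 species × (water experiment: control /
  limited × 15, nutrient experiment: low / medium / high × 10).
- **Chemistry**: treatment-shifted truncated normal draws per trait.
  Water content is hard-truncated to each species' realistic span
  (maize 79.6–91.0%, soybean 68.2–81.9%) and pooled N to 0.96–5.68%;
  responsive nutrients order low < medium < high. Fresh weight is drawn
  per species/treatment and dry weight constructed so
  WC = (W_fresh − W_dry)/W_fresh × 100 holds exactly in floating point.
  Na and B get flat treatment multipliers and species-independent base
  levels: nothing in the design correlates with them.
- **Spectra**: a smooth per-species vegetation baseline (low visible
  reflectance, logistic red edge near 714/719 nm, NIR plateau 0.50/0.42,
  water troughs at 970/1240/1450 nm with the 1450 nm trough deepest)
  plus linear trait responses from the frozen, versioned calibration
  `loadings_v1.yaml` (water content deepens the water troughs, nitrogen
  the visible chlorophyll region; Na and B have zero loading), plus
  band-wise Gaussian noise (default SD 0.002 reflectance — "low noise"),
  clipped to [0.01, 0.99]. Linearity in traits is a deliberate choice:
  it makes trait recovery an achievable target for a linear calibration
  and is verified by finite differencing.
- **Scenes**: a blob-like silhouette (~25% fill), a smooth illumination
  field varying ~1.7× across the chamber, a halogen-like lamp spectrum
  (2600 K Planck curve, peak-normalised), full scale 30,000 DN,
  Gaussian detector noise (SD 15 DN), rounded to 16-bit. The background
  is a flat reflector at 0.05 — an invention (no chamber-background
  spectra exist to copy) labelled synthetic in the dataset manifest; its
  NDVI ≈ 0 makes segmentation non-trivial but reliable.
- **Problem sizes**: the default cube is 40 × 40 pixels × 243 bands.
  This preserves every structural property the pipeline exercises
  (masking, illumination cancellation, per-band averaging) at a dataset
  size convenient for routine runs; the full 500 × 320 instrument
  geometry is available through `SimulationConfig`/`CubeGeometry`. A
  `mini` preset (8 plants, 16 × 16 × 24 cubes) serves quick end-to-end
  runs.
- **Reproducibility**: all per-plant streams are spawned from the
  master seed via `SeedSequence`; the same seed yields a byte-identical
  bundle.

### What the simulator does and does not show

Passing the end-to-end tests shows the pipeline is internally
consistent: geometry and grids are honoured, normalization inverts the
rendering exactly up to digitisation, the PLS machinery recovers
linear signal where it exists (validation R² ≥ 0.9 for every loaded
trait at default noise) and cannot manufacture signal where none exists
(Na/B stay at R² ≤ 0.3, RPD < 1.5). It does **not** show that real leaf
chemistry is linearly encoded in reflectance, nor calibrate real
scattering, canopy geometry, specular highlights, or inter-trait
biological correlation — real campaigns must expect lower accuracy and
trait-dependent performance.

## Known limitations

- Only 16-bit BIL cubes (no BIP/BSQ, compression or streaming).
- Whole-plant chemistry: no spatially resolved per-pixel prediction.
- No preprocessing transforms (derivatives, SNV) or nonlinear learners;
  PLS1 only, by design.
- The LOOCV tie tolerance (1e-9 × SD(y)) is far below any real
  cross-validation difference but matters for exactly low-rank inputs.
- Whether real specular highlights produce reflectance ratios above 1
  (here clipped) cannot be validated against the simulator, which
  rarely clips.
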