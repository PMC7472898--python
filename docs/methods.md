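# Methods

## Problem and model

Conventional fractional anisotropy (FA) from diffusion tensor imaging
confounds two tissue properties: the microscopic anisotropy of the
axonal microdomains and the mesoscopic dispersion of their
orientations. In white matter with crossing or fanning fibres, FA can
fall (or, when one crossing bundle degenerates, rise) without any
change in the microstructure itself. Tensor-valued diffusion encoding
resolves the ambiguity at acquisition time: combining conventional
linear tensor encoding (LTE, b-tensor `b n n^T`) with spherical tensor
encoding (STE, b-tensor `(b/3) I`) yields a microscopic fractional
anisotropy (uFA) that is independent of orientation dispersion.

The estimation route implemented here represents each powder-averaged
decay by the Laplace transform of a gamma distribution of apparent
diffusivities,

    E(b) = s0 * (1 + b * mu2 / MD)^(-MD^2 / mu2),

fitted jointly to the direction-averaged LTE decay and the
repetition-averaged STE decay with shared `s0` and mean diffusivity
`MD`, and shape-specific variances `mu2_LTE` and `mu2_STE`. For a
mixture of Gaussian microdomains the LTE powder decay carries the full
diffusional variance (isotropic heterogeneity plus, per anisotropic
domain, a within-domain orientation variance `(4/45) (d_par -
d_perp)^2`), while the STE decay carries only the isotropic part.
Their difference `dmu2 = mu2_LTE - mu2_STE` isolates microscopic
anisotropy, and

    uFA = sqrt(3/2) * (1 + (2/5) (MD^2 + mu2_STE) / dmu2)^(-1/2).

For a single axisymmetric domain this equals the FA of that domain's
tensor — the identity the test suite checks (zeppelin with
`d_par = 1.7e-3`, `d_perp = 0.2e-3` mm^2/s: FA = uFA = 0.8704).

## Acquisition protocols

Two protocols are emulated:

* tensor-valued: six shells at b = 100/500/900/1200/1600/2000 s/mm^2,
  15 LTE directions per shell and 15 STE repetitions per shell (180
  volumes). The "15 repetitions" of the STE acquisition is read as 15
  per b-value set, mirroring the LTE layout; this multiplicity is a
  stated interpretation, not a derived fact.
* multi-shell DTI: b = 300/1000/2000 s/mm^2 in 6/50/50 directions plus
  three b = 0 volumes (109 volumes). Only the b = 0 and b = 1000 images
  enter the tensor fit.

Directions are generated by electrostatic repulsion on the sphere from
a seeded random start (deterministic; minimum pairwise angle > 5
degrees at the default counts). STE is modelled as an ideal isotropic
b-tensor: the analysis uses only the b-tensor, not the physical qMAS
waveform, so waveform time-dependence and exchange effects are outside
the model. b = 0 entries are stored as linear encodings with a zero
matrix so one record type covers every volume.

## Fitting

**DTI.** Weighted log-linear least squares (weights = squared signal)
per voxel on the b = 0 + b = 1000 subset; at least six non-collinear
directions are required (rank check on the symmetric outer products).
Negative eigenvalues are clamped to zero and flagged rather than
refitted; non-positive signals flag the voxel out of the map.

**Gamma decay.** Bound-constrained nonlinear least squares on
`(s0, MD, mu2_LTE, mu2_STE) >= 0` with analytic Jacobian, unweighted
residuals on the linear signal scale, initialised from log-quadratic
cumulant fits of each series. "Non-negative least squares" is read as
these bound constraints: the model is nonlinear in its parameters, so
linear NNLS does not apply without a kernel dictionary. Below
`mu2 < 1e-12 mm^4/s^2` the decay is evaluated as the monoexponential
limit `s0 exp(-b MD)`. Upper bounds: `MD <= 3.5e-3` mm^2/s (free
water), `mu2 <= 1e-4` mm^4/s^2. Two equivalent implementations exist:
a per-voxel scipy fit (the reference) and a vectorised damped
Gauss-Newton used by the map pipeline; the test suite checks their
agreement. uFA is clamped to [0, 1] and `dmu2 <= 0` maps to 0 (not
NaN) so ROI means stay defined; QC counters keep the flag counts.
Smoothing (Gaussian, 1.25 mm FWHM default, sigma = FWHM/sqrt(8 ln 2))
is applied to the signal volume before powder averaging, i.e. the
pipeline order is smooth -> average -> fit.

The gamma representation is exact for gamma-distributed diffusivities
but approximate for the erf-shaped powder decay of an actual
axisymmetric domain: on noiseless, ideally averaged zeppelin decays
over the six b-values the estimated uFA carries a bias of about +0.019
(measured by the tests and the acceptance script, bound 0.05 asserted).
This bias is shared across environments, so comparisons between
environments and groups are unaffected.

## Synthetic voxel environments

Voxels are mixtures of axisymmetric Gaussian microdomains (default
healthy zeppelin `d_par = 1.7e-3`, `d_perp = 0.2e-3` mm^2/s — standard
healthy white-matter magnitudes; no diffusivities are prescribed by
the study design) plus an optional isotropic compartment. Canonical
environments:

| label | construction |
|---|---|
| A | one coherent population |
| B | two equal orthogonal populations |
| C | Watson-dispersed fan (kappa = 4, 30 discrete orientations) |
| D | A with `d_par - d_perp` shrunk by `(1 - damage)` and an isotropic fraction `0.15 * damage` at 2.0e-3 mm^2/s |
| E | B with one population's anisotropy shrunk as in D, volume fractions kept |
| F | lesion: 85% isotropic at 2.0e-3 mm^2/s |

Damage in D also applies to C in cohort phantoms. Environment E
deliberately has no isotropic growth: the scenario it illustrates —
degeneration of one crossing bundle raising voxel FA while lowering
uFA — is driven by the anisotropy loss of that bundle, and an added
fast isotropic compartment would dilute the voxel tensor and mask the
FA rise. The FA rise only dominates the crossing geometry once the
degenerated bundle has lost most of its anisotropy, so the qualitative
environment table is evaluated at damage 0.8; uFA falls monotonically
with damage at every level.

Noise is Rician: each value is replaced by `|v + e1 + i e2|`,
`e ~ N(0, s0/SNR)`, with SNR defined at b = 0 (default 50, a typical
in-vivo magnitude at these voxel sizes).

## Synthetic cohorts

Each subject carries a latent damage score in [0, 1]:

    damage = base(group) + 0.0025 (age - 45) + 0.02 log1p(lesion_ml)
             + N(0, 0.035),  clipped to [0, 1]

with `base = 0.05 / 0.10 / 0.12` for HC / RRMS / PPMS. Ages are
truncated normals matching the cohort marginals (43.5 +- 12.0 / 40.2 +-
8.9 / 57.7 +- 5.0 years, bounds 18-80); lesion loads are log-normal
with group medians 6.5 / 17.6 ml; SDMT preserves the group marginals
(50.5 / 57.2 / 45.9, sd 7.5 / 11.0 / 9.8) while coupling to the
centred damage latent at -40 points per unit damage; EDSS is a noisy
affine transform of damage (18 points per unit above 0.04, sd 1.0)
rounded to the 0-10 half-point grid. No group means for NAWM uFA/FA
were available to anchor the effect sizes, so the damage couplings are
free parameters chosen once to give uFA group gaps of roughly
0.02-0.05 — the magnitude visible in in-vivo NAWM bar plots — and
recoverable clinical correlations; they were not revisited afterwards.

FA, but not uFA, additionally depends on each subject's physiological
crossing-fibre fraction (ROI baselines 0.40 NAWM / 0.10 CING / 0.60
SLF / 0.50 CST, subject jitter sd 0.12, disease-independent). This is
the mechanism that makes the FA group effect weaker than the uFA
group effect in the simulations — the dissociation of interest.

Per-subject phantoms are compact labelled grids (default 8 x 4 x 1
voxels, 2.5 mm isotropic; left/right split on the first axis; one row
per tract, one generic NAWM row) with lesion voxels (environment F)
in proportion to lesion load, excluded from the NAWM and tract masks.
These sizes keep a 67-subject replicate at a few seconds while leaving
every ROI non-empty; they are the package's default study size, and
all statistics scale with them. A closed-form path
(`closed_form_roi_table`) produces the same per-subject ROI table from
the exact mixture moments plus measurement noise (sd 0.010 uFA, 0.012
FA) and is used where many hundreds of replicate cohorts are needed
(null calibration).

What the generator does **not** emulate: real brain geometry, partial
volume with CSF/grey matter, motion/susceptibility artefacts, exchange
or time-dependent diffusion, and non-Gaussian compartments. Passing
tests therefore demonstrate correctness of the estimation and
statistics machinery under the stated forward model, not in-vivo
validity of the acquisition.

## Statistics

The hemisphere-by-group repeated-measures ANOVA uses the classical
split-plot decomposition with covariates (age, sex) in both strata:
the group effect is tested on subject hemisphere-means with Sum-coded
Type-III sums of squares; the hemisphere effect and
hemisphere-by-group interaction are tested on hemisphere differences
(the hemisphere main effect is the covariate-adjusted mean
difference). This matches SPSS Type-III behaviour on balanced designs
and is the declared reference on unbalanced ones. Pairwise group
contrasts are covariate-adjusted t-tests from the same linear model,
Bonferroni-corrected with m = number of pairwise contrasts (3).

Correlations: Pearson (EDSS treated as interval-scaled, as in the
reported analyses; a Spearman alternative exists), Spearman via
rank-then-Pearson with average ranks for ties, partial Pearson by
residualising both variables on the controls with p from the t
transform on n - 2 - k degrees of freedom. Zero-variance inputs yield
a flagged, undefined result instead of an exception. Histograms
default to 64 uniform bins on [0, 1] (binning is a free choice),
density-normalised per subject before unweighted group averaging.
Mask erosion uses the 6-connected structuring element. The
FA-threshold analysis restricts the mask to FA > t for t in
{0, 0.2, 0.4, 0.6} and recomputes both metric means; empty thresholds
are flagged rows, never dropped.

## Reproducibility

One master seed drives everything; per-subject and per-stage streams
are split from it by counters via `numpy.random.SeedSequence`, so
cohorts are reproducible under parallel generation. Maps are written
as float32 NIfTI-1, masks as uint8; the pipeline report embeds a hash
of the run configuration.

## Known limitations

* The gamma representation bias (+0.02 at healthy-WM anisotropy)
  grows with `b * dmu2`; at much stronger anisotropy or higher
  b-values the shared-bias assumption across environments weakens.
* The log-linear DTI fit at b = 1000 on multi-exponential crossing
  voxels underestimates the mean-tensor FA; orderings asserted by the
  tests are those of the fitted maps.
* EDSS is generated as a coarsened continuous variable; its ordinal
  pathology (floor effects, uneven step usage) is not modelled.
* Phantom hemispheres are exchangeable by construction, so hemisphere
  main effects are null in simulation; the hemisphere stratum of the
  ANOVA is validated against the GLM oracle, not against a simulated
  hemisphere effect.
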