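# Methods

This note documents the models, numerical choices and known limitations of
`uavqtl`. Units are centimetres for all distances and elevations, days for
time, and 1-based base pairs for genomic coordinates.

## Surface modelling

**Rasters.** A raster is a row-major grid with a six-term affine transform
(north-up by construction in the simulator), a nodata sentinel that
propagates through arithmetic, and cell values referring to cell centres.
Single-band rasters round-trip through the ESRI ASCII grid text format.

**Variogram.** The empirical semivariogram of the bare-ground points is
binned into up to 15 equal-width lag classes out to half the maximum
pairwise distance and fitted by bounded least squares
(`scipy.optimize.curve_fit`) with a nugget + partial-sill + range
parameterisation. The default family is exponential with the conventional
"effective range" scaling γ(h) = c₀ + c·(1 − e^(−3h/a)), so `range_` is the
distance at which 95% of the sill is reached; spherical and Gaussian models
are available. A zero-variance point set returns a flagged nugget-only model
and kriging then short-circuits to the constant surface.

**Ordinary kriging.** Each target cell is predicted from its 16 nearest
points (the full system when n ≤ 16) by solving the standard ordinary-kriging
system with the unbiasedness constraint, giving weights that sum to one and
exact interpolation at data points when the nugget is zero. The per-cell
(k+1)×(k+1) systems are assembled and solved in batched chunks
(`numpy.linalg.solve` over ~20k cells at a time), which kriges a ~1.3-million
cell field DEM from 1332 points in well under a minute on one CPU. Singular
neighborhoods fall back to per-target solves and yield nodata cells, which
are counted in the log. Tests verify the neighborhood path against an
independent dense-system solve to 1e−8 relative tolerance on ≤ 50 points.

**CSM.** CSM = DSM − DEM cellwise; negative cells — interpolation noise, as
heights below ground are unphysical — are clamped to zero and counted in the
log. Clamping is the only nonlinearity.

**Segmentation.** ExG is computed on chromatic coordinates
(r, g, b) = (R, G, B)/(R+G+B), hence invariant to uniform illumination
scaling; pixels with R+G+B = 0 become nodata. The default mask threshold is
Otsu's method on the valid-pixel histogram (parameter-free); a fixed
threshold is available. With well-separated soil/canopy modes Otsu's
quantised optimum can sit a histogram bin inside a cluster tail, so the
guaranteed property is that the threshold lies strictly between the cluster
means, not that classification is pixel-perfect.

## Height extraction

The per-plot reducer is the "maximum adjacent pixel" statistic: the maximum,
over masked vegetation pixels whose centres lie inside the plot polygon, of
the window-mean (default 3×3) of the CSM. Window means are nodata-aware
(valid-count normalised, reflected edges). With window = 1 this is the plain
masked maximum; a p-th percentile reducer (default p = 99) is offered as the
common alternative in the sorghum/wheat literature. A plot with no
vegetation pixel yields a missing value, logged, never fatal. Line values
are the mean over a line's plots. Validation regresses ruler heights on UAV
heights by OLS per flight; the pooled mode concatenates stage pairs first.

## Synthetic study design

The simulator emulates a 252-line maize inbred panel (117 temperate TEM,
135 tropical TST) phenotyped by four flights at growth stages V5/V12/V15/R,
days 24/45/57/80 after sowing.

**Field.** One three-row plot per line: 2 m rows, 65 cm row spacing,
8 plants per row, laid out 18 plots per field row with 80/65 cm alleys and a
2 m margin, 4 cm/pixel rasters by default (between the ~1.1 cm orthomosaic
and ~2.3 cm DSM resolutions such surveys report, and tractable on one CPU).
Terrain is a sum of six random cosines with wavelengths 1.5–4× the field
span (≥ 30 m), rescaled so the maximum deviation equals `relief_amplitude`
(default 10 cm) — the gentle undulation of a levelled trial field. Short
wavelengths would make bare-ground interpolation across plot-sized gaps
unfaithful to such a field.

**Growth.** Each group follows a logistic curve H(t) = K/(1+e^(−r(t−t0))):
TEM K = 205 cm, t0 = 48 d; TST K = 235 cm, t0 = 53 d; r = 0.115/d both.
These reproduce the canonical temperate/tropical pattern under temperate
day-lengths: TEM taller at stages 1–3 (group means ≈ 12/85/151 vs
8/68/146 cm), TST overtaking at flowering (≈ 225 vs 200 cm), and higher TST
growth-rate ratios over the 1→2 and 3→4 intervals. Per-line deviations are
log-normal on K (cv 7%) and r (cv 5%), Gaussian on t0 (sd 1 d), plus a
stage-1 "seedling vigor" log-normal factor (sd 0.35, clipped at ±4 sd to
preserve per-line monotone growth) capturing the large independent spread of
establishment-phase heights; it makes stage 1 the noisiest stage
(CV ≈ 40%) and leaves PH_2–PH_3 the most correlated height pair (r ≈ 0.76),
the structure reported for real mid-season panels. A single logistic family
cannot additionally null out the group contrast in the 2→3 growth ratio, so
the simulator shows a 2→3 difference where real panels may not — none of the
tests assert that contrast.

**Flights.** Canopy is rendered as one flat-topped bump per plant,
h·(1 − (ρ/R)⁴) within radius R, combined by maximum, so the per-plot DSM
maximum equals the tallest plant's height exactly (the analogue of ruler
measurement) with sub-millimetre pixel-sampling error — a cosine cap would
lose ~1% of a 2.5 m plant to apex curvature at 4 cm pixels. `canopy_cover`
scales R, with 1 meaning closed canopy (the radius then covers the whole
plot polygon); the per-stage defaults 0.4/0.7/0.85/0.95 mimic progressive
canopy closure, which the source literature does not quantify. RGB flights
colour canopy (60,160,60) and soil (135,110,95) with 5-DN Gaussian noise —
linearly separable under ExG by construction, because segmentation should be
exercised, not fragile. DSM noise is additive Gaussian (default sd 2 cm,
matching reported DSM accuracies); photogrammetric matching artefacts are
out of scope. Bare points are sampled outside the plot polygons buffered by
the canopy radius, since leaves overhang plot boundaries.

**Genotypes.** Balding–Nichols two-subpopulation structure: ancestral
frequencies uniform on the MAF range (default 0.05–0.5), group frequencies
Beta-distributed with differentiation parameter F (default fst 0.05),
dosages Binomial(2, p_group), placed uniformly on 10 chromosomes of 50 Mb —
a maize-like genome scaled to desk size. **Planted QTLs** add
Σ effect×dosage (mean-centred, so group contrasts are untouched) plus
Gaussian noise scaled so the genetic share of the added variance hits the
target h²; in the pipeline, traits without planted effects receive no extra
environmental noise, because measurement noise already enters through the
rendered flights.

All generators are pure functions of (parameters, seed); the pipeline spawns
independent per-stage streams from one configured seed, so a config + seed
pair reproduces every output byte-for-byte.

## Association mapping

The scan is a per-SNP ordinary linear model, phenotype ~ dosage
(+ covariates), fitted on complete cases: covariates are projected out once
through an orthonormal basis (collinear columns dropped with a warning) and
all complete-dosage SNPs are then fitted in a single vectorised pass;
SNPs with missing calls fall back to per-SNP complete-case fits. p-values
are two-sided t-tests on the dosage coefficient. This documented GLM +
PC-covariate scan stands in for iterative mixed-model methods (FarmCPU-style
algorithms), which are external published machinery; what is implemented
here is the surrounding protocol — MAF > 0.05 QC computed within the
analysed group (strict inequality), top-5 principal components of the
standardised dosage matrix for the combined group (missing dosages
mean-imputed for PCA only), and the adjusted Bonferroni cutoff P ≤ 1/N
(inclusive). Kinship adjustment is likewise out of scope. Calibration is
verified empirically: a permutation-null scan holds the p < 0.05 fraction
inside the binomial 99% band, and under fst = 0.1 structure with a
group-correlated phenotype shift the PC-adjusted genomic inflation factor
stays in [0.8, 1.2] while the unadjusted scan inflates.

**QTL intervals.** Each significant SNP spawns a closed 1-based interval
±100 kb, clipped at position 1; overlapping intervals on a chromosome are
unioned, the peak being the lowest-p significant SNP (ties broken by lowest
position, for determinism). Across trait/group scans, overlapping QTLs
always merge; QTLs separated by under 1 Mb merge only when the caller sets
an explicit flag, because that rule in practice encodes cross-study evidence
this package cannot look up. Merging happens within each scan first, then
across scans. BED output converts to 0-based half-open coordinates.

## Problem sizes and test scope

Unit tests run on a 36-line field at 4–6 cm pixels; the acceptance checks
use the full 252-plot design (two kriged DEMs of ~1.3 M cells, ~35 s each),
50 replicate scans of 10,000 SNPs for recovery power, and a 5000-SNP
permutation null. `scripts/acceptance.py` repeats the full-design pipeline
plus 20 recovery replicates in under a minute each.

## Limitations

- The simulator's RGB and canopy geometry are deliberately idealised;
  passing tests demonstrate the pipeline's correctness against known truth,
  not robustness to photogrammetric stitching errors, lodging, shadows or
  mixed pixels in real imagery.
- Early-stage extraction is biased slightly upward under noise (the masked
  maximum of a noisy surface), visibly so when plants are ~10 cm — the same
  effect that degrades early-stage validation in real surveys.
- The 1/N "adjusted Bonferroni" cutoff is lenient by design; scans at desk
  scale produce the expected handful of false-positive intervals alongside
  planted loci.
- Universal/co-kriging, anisotropic variograms, LD-aware interval rules and
  candidate-gene annotation are out of scope.
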