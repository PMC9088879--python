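# Methods

`stentfai` measures the peri-stent perivascular fat attenuation index (FAI)
on coronary CT angiography volumes and runs the downstream in-stent
restenosis (ISR) statistics. Because no patient-level dataset accompanies
the study population it emulates, the package ships first-class synthetic
generators — a CT phantom with exact geometric ground truth and a cohort
sampler calibrated to published group summaries — so every stage is
testable end to end.

## The measurement model

**Perivascular shell.** The perivascular adipose tissue (PVAT) around a
stented segment is defined geometrically from the vessel centerline: a
voxel belongs to the shell iff the orthogonal projection of its center
onto the centerline polyline lands within the stent's longitudinal extent
and its radial distance r satisfies R < r ≤ R + D, where R = stent
diameter/2 (the outer stent surface) and D = multiplier × stent diameter
(default multiplier 1, the conventional "one vessel diameter" PVAT band).
We interpret the radial rule as a *thickness D measured outward from the
stent surface*; the alternative reading (outer radius = one diameter from
the centerline) would make the band only half a diameter thick and is
rejected. The longitudinal extent defaults to the stent segment alone; a
`stent±5mm` option includes the 5 mm edge segments that the restenosis
definition also covers.

**FAI.** The FAI is the plain mean attenuation of shell voxels inside the
adipose window −190 to −30 HU, both endpoints inclusive. Inflammation
shifts perivascular fat from the lipid phase (near −190 HU) toward the
aqueous phase (near −30 HU), so *less negative FAI = more inflamed*.
Contrast-filled lumen (≈350 HU) and metal struts (≈800 HU) fall outside
the window and can never contaminate the mean; voxels at or inside the
stent radius are additionally excluded by geometry. A histogram-weighted
variant of the index exists in the literature; absent a published formula
we implement the plain mean and note the choice here. A measurement with
zero in-window voxels raises an error rather than returning a number — it
corresponds to the artifact-corrupted stents such studies exclude.

**Restenosis degree.** Lumen diameters are profiled on planes orthogonal
to the centerline over the stent plus 5 mm edges. Each plane is resampled
by trilinear interpolation (0.2 mm pixels by default); the lumen is the
connected component of contrast-range pixels (180 ≤ HU < 600) containing
the plane center, and the diameter is the equivalent-circle value
2·√(area/π), which is robust to pixelation compared with caliper calls.
The upper bound excludes metallic struts and blooming, which sit well
above contrast. The normal proximal reference diameter is the *median*
over the window [start−10 mm, start−5 mm] (the study names only a "normal
proximal lumen"; the median resists edge artifacts). Degree of ISR =
100·(reference − minimal)/reference, clipped to 0 when the minimum exceeds
the reference; ISR is called at ≥50 % diameter stenosis (the conventional
angiographic threshold — the study does not print its cutoff; it is
configurable). A stent whose reference window would reach proximal to the
ostium raises a `proximal-exclusion` error, mirroring the cohort's
exclusion of stents within 10 mm of the vessel origin.

## Centerline extraction

The lumen mask is 3D-thinned (scikit-image) and the unique longest path
between skeleton endpoints is taken; a branching skeleton with no unique
longest path is an error. Thinning of binary tubes can annihilate or
fragment sections whose cross-section lacks a central voxel, so when the
skeleton is empty, fragmented, or covers less than 80 % of the mask's
geodesic diameter, the package instead takes the minimum-cost path between
the two geodesically farthest mask voxels on the 26-connected voxel graph,
with edge costs penalising distance from the Euclidean-distance-transform
ridge (squared inverse-EDT weighting) — a standard medial-axis path.
Either path is then recentred on perpendicular cross-section centroids
(two passes; end tangents are borrowed from the interior, where thinning
corners make them unreliable), smoothed with a 5-point moving average and
resampled at 0.5 mm. The endpoint nearest the volume boundary is labeled
the ostium and defines arc length 0. On the straight-tube phantom this
pipeline recovers the analytic axis to well under half a voxel
(test-verified), and on a helical vessel the mean deviation stays under
one voxel.

Cross-section frames are propagated along the curve by minimal rotations
(parallel transport), which avoids in-plane twist; the initial in-plane
axis is the canonical axis least parallel to the first tangent,
orthogonalised.

## The phantom generator

The phantom voxelizes an analytic vessel (straight along a grid axis, or a
helix around the central z-axis) by the **voxel-center rule**: each voxel
takes the attenuation of the tissue at its center, with no partial-volume
weighting. This makes membership exactly reproducible by a brute-force
oracle, which the tests exploit (FAI equality to machine precision on a
32³ grid). Partial volume is emulated only through optional Gaussian image
noise, applied last; truth masks are noise-free.

Radial structure, inside out: contrast lumen (350 HU) of radius 1.65 mm,
optionally narrowed by a cosine-bump stenosis; vessel wall / neointima
(60 HU) out to the stent radius 2.1 mm; metal struts (800 HU) as sparse
rings (pitch 1.5 mm, width 0.3 mm, radial thickness 0.25 mm) — stents are
wire meshes, and a solid metal tube would both be unphysical and corrupt
threshold-based diameter reads on every in-stent slice; perivascular fat
sampled i.i.d. per voxel from N(fat mean, fat SD), spatially white by
design since the FAI is a histogram statistic; soft-tissue background
N(40, 10) HU. Defaults give a 4.2 mm × 28 mm stent (the cohort means) on
an isotropic 0.5 mm grid — near the scanner's 0.625 mm collimation but
rounder for analytic checks. A `fat_fraction` below 1 dilutes the fat
compartment with an out-of-window contaminant (≈15 HU) to emulate
non-adipose admixture. The truth object carries the analytic centerline,
lumen/stent/shell masks, the attenuation parameters actually used, and
the minimal in-stent and proximal reference diameters.

**Accuracy note.** Diameter profiling is voxel-limited: the half-narrowed
stenosis (throat radius 0.825 mm) reads 50 ± 5 % only for spacings
≤ 0.4 mm; at 0.5 mm the throat is quantized too coarsely and the degree
underreads. The degree-recovery test therefore runs at 0.4 mm. FAI
measurement has no such limit — mis-assigned boundary voxels are
out-of-window tissue and drop out of the mean.

## The cohort generator

Each patient row draws binary covariates from Bernoulli laws and
continuous covariates from normals, using the published group-wise
proportions and mean ± SD values (ISR n=52 vs non-ISR n=65; FAI
−78.1 ± 6.2 vs −87.2 ± 7.3 HU; the full laboratory panel; vessel and
segment frequencies; stent length/diameter; months since PCI).
Covariates are mutually independent — the source tables publish no
covariances — so multivariable results on synthetic cohorts reflect that
idealisation. Within the ISR group, (degree of ISR, FAI) pairs come from
a bivariate normal at Pearson ρ = 0.579 with the degree clipped to
[0, 100] % (Gaussian copula; at the default 50.3 ± 21.5 % parameters the
clipping affects under 2 % of the mass and attenuates the sample
correlation negligibly, which the tests confirm). The degree's
distributional form is not published; the truncated normal is our
assumption. Two simulated observer readings (subject value + N(0,
0.85 HU) noise each) support the inter-rater ICC analysis; 0.85 HU is the
rater-noise level at which the variance-ratio 49/(49+0.7225) ≈ 0.985
matches the published inter-rater agreement.

What passing tests show, and don't: the generators reproduce the *printed
summary distributions* under normality. They contain no scanner physics
(beam hardening, motion, blooming beyond the strut rings), no
cross-covariate structure, and no real anatomical variation, so green
tests validate the estimators and the measurement geometry, not clinical
performance on real CCTA.

## The statistical chain

* **Group comparisons** — Welch t by default (the source names no test;
  Student is available), chi-square without continuity correction for
  2×k tables, switching to Fisher's exact test when any expected 2×2 cell
  is below 5. Two identical zero-variance samples return p = 1 by
  convention. No multiple-testing correction is applied, matching the
  emulated analysis.
* **LASSO selection** — L1-penalised logistic regression on internally
  standardised features, glmnet-style: 100 penalties log-spaced over four
  decades down from λ_max = max|Xᵀ(y−ȳ)|/n (the smallest all-zero
  penalty), 10-fold stratified seeded CV on binomial deviance, model 1 at
  λ_min and model 2 at λ_1se (largest λ within one SE of the minimum
  deviance). Fits use saga with warm starts along the descending path,
  path tolerance 1e-4 (verified against 1e-7 on the strong-signal
  design), pinned shuffling seed for reproducibility; coefficients are
  reported on the original scale; non-convergence is flagged, never
  silent.
* **Adjusted logistic regression** — maximum-likelihood fit
  (statsmodels), Wald 95 % CIs exp(β ± 1.96·SE). FAI enters per +1 HU, so
  OR > 1 means higher (less negative, more inflamed) FAI raises ISR odds.
  Separation is flagged (|β| > 15, SE > 100, or non-finite SE) with a
  warning; quasi-separated fits can report finite but huge SEs, so
  convergence flags alone are not trusted.
* **ROC / cutoff** — AUC by the Mann–Whitney identity with half credit
  for ties (higher FAI = positive/ISR orientation), 95 % CI by DeLong's
  structural-components estimator, cutoff by Youden's J with ties broken
  toward higher specificity (the source prints a cutoff without naming
  its criterion; Youden is assumed). Closed-form binormal helpers supply
  analytic sensitivities/specificities for calibration checks. Subgroup
  ROCs are computed per vessel; one-class strata are reported as
  undefined, not errors.
* **Correlation** — Pearson r with Fisher-z 95 % CI (SE 1/√(n−3)) and a
  two-sided t test on n−2 df.
* **Agreement** — ICC(2,1): two-way random effects, absolute agreement,
  single measures, from the two-way ANOVA mean squares with the
  McGraw–Wong F-based CI. Constant ratings are degenerate and flagged.
* **Missing data** — complete-case only throughout (the emulated study
  excluded patients lacking laboratory data).

## Pipeline, sizes and determinism

`run_pipeline` chains phantom validation (per-condition phantoms measured
through the full centerline→shell→window path), cohort simulation, and
the statistical chain into one JSON report that echoes every configured
default for provenance. All randomness flows from one seed through
`numpy` `SeedSequence` children; with a fixed seed the report is
byte-identical across runs (test-enforced), and every numeric in it is
checked finite. The test and acceptance workloads use phantom grids of
40×40×100 voxels at 0.5 mm (0.4 mm for the degree-recovery check), 100
phantoms for the measurement-calibration check, and 500–1000 replicates
for the simulation-based summaries; these sizes give Monte-Carlo error
comfortably inside each stated tolerance.

## Known limitations

* No bifurcations, multi-vessel trees, overlapping stents, strut-level
  segmentation, or blooming correction — the emulated cohort excluded
  such cases, and the geometry assumes a single tubular vessel.
* The weighted FAI-score correction for technical/anatomical/biological
  factors is out of scope; the index here is the unadjusted mean.
* Equivalent-circle diameters assume near-circular lumens; eccentric
  restenosis would be summarised, not resolved.
* Voxel-center voxelization means sub-voxel structures (thin struts,
  tight throats) are quantized; see the accuracy note above.
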