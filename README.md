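# stentfai

Peri-stent perivascular fat attenuation index (FAI) measurement and
in-stent restenosis (ISR) statistics on coronary CT angiography.

Coronary inflammation shifts the CT attenuation of perivascular adipose
tissue (PVAT) from the lipid phase (near −190 HU) toward the aqueous phase
(near −30 HU). The FAI captures this as the mean attenuation of fat-window
voxels in a shell around the vessel — here, around an implanted stent —
and a less negative FAI flags the inflammatory milieu associated with
restenosis. `stentfai` is aimed at imaging researchers who want a tested,
fully reproducible reference implementation of that measurement chain and
of the statistics used to evaluate it, without access to any vendor
platform or patient data.

## What it computes

Given a CT volume, a vessel centerline and a stent annotation
(vessel, extent, diameter d):

* **PVAT shell** — voxels whose centers project longitudinally into the
  stent extent and lie at radial distance R < r ≤ R + D from the
  centerline, with R = d/2 and D = d (one stent diameter of fat, measured
  outward from the stent surface);
* **FAI** — mean HU of shell voxels within the adipose window
  [−190, −30] HU, inclusive;
* **lumen profile and degree of ISR** — equivalent-circle diameters on
  perpendicular cross-sections over the stent ± 5 mm edges;
  degree = 100·(d_prox − d_min)/d_prox against the median proximal
  reference diameter, ISR called at ≥ 50 %;
* **cohort statistics** — Welch/Student group tests, chi-square/Fisher,
  cross-validated LASSO selection (λ_min and λ_1se models), covariate-
  adjusted logistic odds ratios, ROC AUC with DeLong CIs and Youden
  cutoffs, per-vessel subgroup ROC, Pearson correlation with Fisher-z
  CIs, and inter-rater ICC(2,1).

Because the clinical dataset it emulates is not public, the package also
ships calibrated synthetic generators: a stented-vessel CT phantom with
exact ground-truth masks, and a patient-cohort sampler matching the
published group summaries (52 ISR vs 65 non-ISR patients; FAI
−78.1 ± 6.2 vs −87.2 ± 7.3 HU; the full covariate panel). See
`docs/methods.md` for the model and its assumptions.

## Worked example

```python
import stentfai as sf

# an ISR-condition phantom: inflamed fat at -78.1 +/- 6.2 HU
cfg = sf.PhantomConfig(fat_mean=-78.1, fat_sd=6.2, seed=42)
vol, truth = sf.generate_phantom(cfg)
cl = sf.extract_centerline(truth.lumen_mask, vol.spacing)
m = sf.measure_peristent_fai(vol, cl, truth.annotation)

# a synthetic cohort at the published group parameters
df = sf.generate_cohort(sf.CohortConfig(seed=7))
roc = sf.roc_curve_auc(df.peri_stent_fai_hu, df.isr)
cut, sens, spec = sf.youden_cutoff(roc)
isr = df[df.isr == 1]
r, ci, p = sf.pearson_with_ci(isr.degree_of_isr_pct, isr.peri_stent_fai_hu)
```

prints (via the obvious f-strings):

```
FAI = -78.08 HU over 25088 adipose voxels (shell 3136 mm3, in-window fraction 1.000)
AUC = 0.883 (95% CI 0.824-0.942); Youden cutoff -85.4 HU: sens 88.5%, spec 75.4%
degree-FAI Pearson r = 0.425 (95% CI 0.17-0.63, p = 0.0017)
```

The measured FAI lands on the configured fat mean because lumen contrast,
struts and soft tissue all fall outside the adipose window; the AUC and
correlation are single-seed draws from a 117-patient simulation, so they
scatter around their population values (≈ 0.83 and 0.579) from seed to
seed.

A command-line interface wraps the same steps:

```bash
stentfai simulate-phantom --out phantom/ --seed 1
stentfai measure --volume phantom/phantom.nii.gz \
    --centerline phantom/centerline.csv --annotation phantom/annotation.yaml
stentfai simulate-cohort --out cohort.csv --seed 1
stentfai stats --cohort cohort.csv --out report.json --seed 1
stentfai run --out results/ --seed 1        # end-to-end pipeline
```

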