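# Methods

## Spectral model and composite vectors

Each plaque is characterized by three emission spectra, one per
conformation-sensitive dye (curcumin, FSB, BF-188), acquired in a lambda scan
of 40 steps spanning 385–780 nm with a 15-nm-wide sliding detection window.
The default wavelength grid places 40 channel centers evenly on
[385, 780] nm inclusive (spacing ≈ 10.13 nm); the 15 nm figure is treated as
the detection-window *width*, not the channel spacing, and the grid is
configurable for data acquired on other conventions. Input spectra not on the
grid are linearly interpolated; spectra that do not cover the grid span raise
a missing-coverage error rather than extrapolating.

Each dye's spectrum is divided by its own maximum (per-dye, not global,
normalization — absolute brightness varies with dye load and optics and is
not a strain property), and the three unit-peak blocks are concatenated into
a 120-value composite vector. The concatenation order is drawn once per
analysis run from a seeded generator and applied uniformly to every plaque:
a per-plaque random order would destroy the vector space, while any fixed
order is an isometry, so all distances — and hence the PCA eigenvalues and
every downstream statistic — are independent of which order was drawn.
Identically zero spectra (a dye that failed to bind) are retained and
flagged; exclusion is a pipeline policy, not a library decision.

To avoid biasing the eigenspace toward heavily sampled patients, at most 30
composite vectors per patient (uniform random subset, seeded) enter the
analysis. `subsample_robustness_check` refits the space with no cap, with the
cap at several seeds, and with the minority cohort oversampled, and reports
the sign-aligned score correlations and MANOVA agreement between runs.

## PCA strain space

The strain space is a mean-centered PCA (full SVD) over composite vectors.
Component signs are fixed by making each component's largest-magnitude
loading positive, so runs are deterministic across platforms. Component
numbering in the API is 1-based, matching the convention that "PC2" is the
second component.

The study design anticipates a microscope-calibration change partway through
acquisition; its spectral effect is large relative to strain differences, so
the first principal component absorbs it. Analyses therefore retain PCs 2–3
by default for the eigenspace, centroids, and MANOVA, and PCs 2–4 for
heterogeneity; both sets are configurable. On the synthetic benchmark the
generator has three strain-relevant directions (two shared-mixing axes plus
the DS-unique contrast), so the frozen experiment configurations in
`strainspec.experiments` use PCs 2–4 throughout.

## KDE coverage regions and membership

"Shared" strain space is defined per reference cohort as a super-level set of
a Gaussian KDE (Scott's bandwidth by default) fitted on that cohort's scores.
The density threshold is the (1 − coverage) empirical quantile of the
reference points' own estimated densities, so at least ⌈coverage·N⌉ reference
points lie inside by construction; the default coverage is 0.995. An
alternative calibration (`calibration="mass"`) picks the level whose
super-level set integrates to the stated probability mass on a mesh grid; the
quantile construction is the default because its reference-coverage guarantee
is exact and sample-based. The 30/60/90% contours drawn on eigenspace
figures use the same quantile construction and have no classification role.

Query plaques are labeled by the four-way partition of the ADNC and AD
regions (`in_ADNC_region`, `in_AD_region`, `in_both`, `outside_both`);
plaques outside both are candidate cohort-unique strains.

## Weighted RMSD heterogeneity

For retained components with explained-variance proportions
(w_x, w_y, w_z) frozen from the fitted space:

    d_i  = √( (x_i−x̄)² w_x² + (y_i−ȳ)² w_y² + (z_i−z̄)² w_z² )
    RMSD = √( Σ_{i=1..N} d_i² / (N−1) )

The weights enter *squared* inside the distance, exactly as displayed — w
therefore acts linearly on each coordinate's contribution to d_i. The
per-patient statistic uses the patient's plaque scores about the patient
centroid with N the patient's vector count; the per-cohort statistic uses
patient centroids about the cohort centroid with N the patient count. The
N − 1 denominator is kept for all N ≥ 2; with fewer than two points the
statistic is undefined and reported as NaN, never zero.

## Cohort statistics

One-way MANOVA uses Wilks' Λ = det(E)/det(E+H) from the within- and
between-group cross-product matrices of patient centroids, with Rao's F
approximation for the p-value (exact for two groups or up to two response
dimensions; the implementation is cross-checked against statsmodels' MANOVA
in the test suite). det(E+H) ≤ 0 raises a singular-scatter error with
guidance to reduce dimensionality; det(E) = 0 with det(E+H) > 0 is complete
separation and returns Λ = 0, p = 0. Centroid–covariate association uses
ordinary least squares (Pearson r, two-sided p), dropping missing covariates
pairwise. Categorical attributes use Mann–Whitney (two groups, exact method
when tie-free and n ≤ 40) or Kruskal–Wallis; when every value is identical
there is nothing to discriminate and p = 1 by policy. No multiple-testing
correction is applied by default (a Benjamini–Hochberg option exists),
mirroring nominal per-test reporting.

## Pathology scoring

X_Aβ and X_tau grades (0–4) are assigned from plaque and mature-NFT
densities averaged over three 1-mm² fields. The tau cutpoints are
1 / 5 / 12 / 25 NFTs per mm²; shared interval boundaries belong to the
higher score, which keeps the grade monotone in the count. The amyloid rows
are not an exhaustive partition of count space (e.g., exactly one plaque and
no dense core matches no row), so scoring evaluates each row's lower-bound
conditions and returns the highest satisfied score; counts matching no row
score 0 and carry a `gap_flag`. These conventions are documented choices,
the only monotone total extension of the printed rules, not an inference of
scorer intent.

## Segmentation

Plaques are segmented on the total-intensity projection (pixel-wise sum over
all channels of all dyes) — the projection choice is a documented default;
per-dye masks are equally possible upstream. Otsu thresholding is the
parameter-free default, with a fixed threshold available; connected
components (8-connectivity default) outside configurable area bounds
(default [50, 50000] px at 512×512) are removed, and survivors are relabeled
1..K in raster order of each component's first pixel. Exclusion of
false-positive objects is file-driven (label ids or ROI polygons; a label
overlapped > 50% by an ROI is removed) so the manual curation step is
reproducible. Analysis is 2-D on the single optical plane per field; mean
spectra are channel-wise means over each label's pixels, which makes
extraction linear in stack intensity.

## Synthetic-data generator

The generator defines the study conditions for all benchmarks:

* **Archetypes.** Each dye has a base emission shape (1–2 Gaussian peaks,
  widths 40–80 nm, drawn on the grid interior); an archetype perturbs every
  base peak center by up to ±`peak_shift_nm` (default 35 nm; the frozen
  experiments use 5–15 nm) with mild width/amplitude modulation, and redraws
  until every pair of archetypes differs in at least one dye's peak channel.
  Strain identity is thus a subtle *joint* 3-dye signature — single-dye
  separability would make the concatenation pointless.
* **Hierarchy.** Patients per cohort, a uniform plaques-per-patient range
  (default 10–40, exercising the 30-vector cap on both sides), plaque
  archetypes drawn from per-cohort mixture weights, optionally restricted to
  some cohorts (the DS-unique archetype). Per-cohort Dirichlet
  concentrations add patient-level mixture jitter; ordered concentrations
  (DS most variable) emulate ordered cohort heterogeneity.
* **Noise and brightness.** Additive Gaussian channel noise with sd =
  `noise_sd` × the profile peak (default 0.05), clipped at zero; a lognormal
  per-patient brightness factor (σ = 0.3) that per-dye max-normalization
  must remove. Intensity distributions are a free modeling choice — the
  acquisition hardware's true plaque-brightness distribution is not
  documented — and are documented, not fitted.
* **Batch gain.** Batch-B patients' spectra are multiplied by a smooth
  linear tilt in wavelength, 1 + m·(2t − 1) floored at 0.05, t the position
  in the span. A wavelength-dependent gain changes spectral shape and so
  survives max-normalization (a flat gain would not); at the magnitudes used
  in the experiments (m = 1.2–1.5) it dominates PC1 the way a calibration
  change does. Patients alternate batches within cohort, keeping batch
  balanced and uncorrelated with cohort.
* **Covariates.** Aβ40/Aβ42/pTau concentrations and a simulated tau grade
  are linear in the patient's realized loading on a designated archetype
  plus Gaussian noise — the simplest structure sufficient to test the
  centroid-regression stage.
* **Image scenes.** Disks with radial falloff 1 − (d/r)², a broad background
  autofluorescence hump, and pixel noise; truth masks label each plaque and
  overlapping pairs are flagged in the metadata. Plaque morphology beyond
  radial falloff (cored vs diffuse structure) is deliberately not modeled.
* **Pathology counts.** For any (X_Aβ, X_tau) target pair, counts are drawn
  from the interior of the corresponding rule intervals (0.2/mm² margins at
  shared boundaries), so scoring them recovers the targets by construction.

What passing synthetic tests do *not* show: real plaque spectra have
autofluorescence residues, focus and depth effects, dye-batch chemistry
variation, and plaque-morphology structure that the generator omits; the
benchmarks validate the statistical machinery, not instrument-specific
robustness.

## Frozen experiment conditions

`strainspec.experiments` fixes the benchmark configurations:

* *Strain recovery*: 3 cohorts × 14 patients, 15–25 plaques each, archetype
  peak shift 15 nm, noise 0.04, batch gain 1.2, DS-unique weight 0.3,
  99.5% regions in PCs 2–4.
* *Heterogeneity ordering*: 4 shared archetypes, 20 patients per cohort,
  25–35 plaques, Dirichlet concentrations DS = 1, AD = 8, ADNC = none.
* *Batch isolation*: peak shift 5 nm, gain 1.5, noise 0.03 — the regime
  "batch effect large relative to strain differences".
* *MANOVA calibration*: 2000 two-group null replicates, n = 30 per group,
  2-D.
* *Segmentation*: 20 scenes of 7 high-SNR disks (radius 8–16 px) at
  256 × 256 with background 0.02 and pixel noise 0.05.

Problem sizes are chosen so each experiment completes in seconds to about a
minute on one CPU while leaving clear statistical margins.

## Reproducibility

All randomness flows through `numpy.random.default_rng`. The pipeline
expands a single global seed into per-stage seeds via
`SeedSequence([global_seed, stage_index])`, records every randomized choice
(dye order, cap subsets, oversampling) in the run manifest alongside SHA-256
checksums of all outputs, and reruns with identical configuration are
byte-identical.

## Known limitations

* Eigenspaces fitted on different datasets are not aligned (no Procrustes);
  comparisons are only valid within one fitted space.
* The KDE regions assume the retained-score distribution is amenable to a
  global Gaussian bandwidth; heavily multimodal references with very
  different cluster scales may over-smooth.
* Rao's F is approximate for more than three groups in more than two
  dimensions.
* The amyloid scoring gap/boundary conventions, the segmentation projection
  choice, and the quantile (vs mass) KDE calibration are all documented
  defaults for under-specified steps, selectable in configuration.
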