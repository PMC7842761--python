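# Methods

## The model and its assumptions

The package treats per-animal counts of fos+ cells in R brain regions as a
snapshot of regional activation, and defines the *coactivation* of two
regions within one experimental condition as the Spearman rank correlation
of their counts across that condition's animals. Working on ranks is
deliberate: fos counts are heteroskedastic across regions and their scale
depends on staining and counting choices, while the scientific claim —
"these two regions go up and down together across animals" — is ordinal.
Two consequences follow. First, the pooled mean normalization applied
before the matrices, x' = (x − mean_r)/(max_r − min_r) per region, cannot
change any downstream number (any strictly increasing per-region map
leaves ranks, hence the Z_obs table, unchanged; the pipeline asserts this
to 1e−12). It is kept because it makes the per-condition matrices and any
derived visualizations comparable across regions. Second, the analysis is
robust to outlier animals in a way Pearson matrices would not be.

Conditions are compared edge-wise with Fisher's transformation,
z = atanh(r), whose sampling variance is approximately 1/(n − 3) for
bivariate-normal data, giving the standardized difference

Z_obs = (z₁ − z₂) / √(1/(n₁ − 3) + 1/(n₂ − 3)).

Assumptions worth stating: (i) animals are independent within and between
conditions; (ii) n − 3 > 0 per group, so every group needs at least 4
animals, and at 6–7 animals per condition (the design's realistic size)
the per-edge test has meaningful power only for large correlation changes —
Z_obs is used descriptively, as an effect-size ranking, not as a
family-wise-corrected inference; (iii) the 1/(n − 3) variance is an
approximation for rank correlations, adequate at the |r| ≤ 0.9 range the
analysis operates in (the null-calibration experiment measures the
resulting type-I error directly: with n = 30 per group the empirical rate
of |Z_obs| > 1.96 sits in 0.04–0.065).

Missing regional measurements (a section lost at histology) are handled
pairwise-complete: each pair uses the animals with both regions present
and carries its own effective n into the Z_obs denominator. Pairs with
fewer than 4 complete observations, or with zero rank variance, are
reported as unavailable — never as r = 0, which would masquerade as a
finding. Perfect correlations (possible at n = 7) are clamped to
±(1 − 1e−7) before atanh, with a warning, so edges stay finite.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `display_threshold` | 1.96 | |Z_obs| needed to retain an edge; the two-sided 5% normal quantile. 0 reproduces "show every difference". |
| `comparisons` | 4 planned contrasts | cycle effect in controls, stress effect within each phase, cycle effect under stress |
| `fdr` | off | adds Benjamini–Hochberg q-values per comparison; retention stays threshold-based because the statistic is used descriptively |
| OLM thresholds | 10 s / 5 s / 1 s / 0.5–2.0 | the task's published exclusion rules; the <1 s single-object rule is checked in both training and testing (the conservative reading; configurable) |
| phase-call cutoffs | cornified ≥ 75% & nucleated ≤ 15% → estrus; nucleated strict plurality ≥ 40% → early proestrus | numeric operationalization of the qualitative cytology pattern; config-exposed because labs differ |
| detection limit | 3 pg/ml | ELISA functional sensitivity; below-limit values either kept as extrapolated or zeroed |

Hub score = per-region sum of retained |Z_obs| (plus retained degree). It
is a display-threshold-dependent summary, chosen for transparency over
centrality measures that need a fully weighted graph.

## What the synthetic cohorts emulate — and what they do not

The generator reproduces the *statistical structure* the analysis assumes:
a 2 × 2 design (default 7 animals/condition), 11 regions, counts with
condition-dependent inter-region rank correlation, occasional missing
regions, phase-typical smear compositions, detection-limit-censored
estradiol, and group-structured exploration times. Counts are produced by
a Gaussian copula: latent multivariate normals with Pearson matrix
ρ = 2 sin(πρ_s/6) — the exact Spearman→Pearson relation for bivariate
normals — pushed through Φ and the inverse CDF of each region's marginal
(Poisson by default; negative-binomial available because real fos counts
are overdispersed). Elementwise-valid target matrices can be jointly
infeasible, so the converted matrix is repaired by eigenvalue clipping at
1e−8 and re-normalization to unit diagonal. Discreteness attenuates the
realized rank correlation; with count means ≥ 50 the attenuation is below
0.05 and the copula hits its targets within ±0.05 at n = 5000 (measured,
not assumed).

Not emulated: spatial structure within regions, litter or batch effects,
correlated missingness (missingness is independent uniform per
animal × region, with a floor of one measured region per animal), the
hormone assay's optical-density noise, or video-tracking artifacts in the
behavioral logs. Passing tests therefore demonstrate that the *pipeline*
is correct and calibrated under its own assumptions — not that those
assumptions hold in any particular dataset.

Defaults that stand in for unpublished distributions were chosen once, on
biological grounds: per-region count means default to 100 (fos counts in
the tens-to-hundreds); smear Dirichlet concentrations (1, 15, 2) for
estrus and (10, 3, 5) for early proestrus reproduce cornified-dominated
vs nucleated-rich compositions; estradiol is log-normal with median
9 pg/ml (early proestrus) vs 1.8 pg/ml (estrus, log-sd 0.5), placing the
majority of estrus draws below the 3 pg/ml limit; behavioral group
means mirror the published group structure, with the planted OLM
preference ratio 1.0 in the impaired (high-E2 stressed) group and 1.6 in
intact groups. One global seed fans out into independent named streams
(fos, behavior, smears, hormones) via `SeedSequence.spawn`, so adding
draws to one stream never shifts another.

## Numerical choices and degenerate inputs

- Ties get midranks; the implementation (scipy ranking + Pearson of
  ranks) is verified against an independent brute-force oracle (explicit
  sort-and-average ranking, textbook Pearson sum formula) to 1e−10.
- Undefined ratios in behavior use explicit sentinels: displaced/0 → +inf
  with a warning flag, 0/0 → NaN (and such sessions are excluded by the
  5 s rule anyway). Undefined correlations raise
  `UndefinedCorrelationError` rather than returning 0.
- A region constant across all animals scales to all-zeros rather than
  0/0; a region entirely missing is an error naming the region.
- Cycle onset is the first day of a maximal consecutive early-proestrus
  run (the study timed the stressor to proestrus entry); fewer than two
  onsets yields an empty list, not an error.
- Z_obs denominators always use the pair-specific effective n, not the
  group size, so missingness never silently inflates precision.

## Design choices where the design was open

- Only estrus and early proestrus are classified; other cycle phases fall
  to `indeterminate` because the study's design used only these two and
  stated no rules for the others.
- No multiple-testing correction by default: the differential networks
  are descriptive maps, and correcting 55 edges at n = 7 would simply
  blank them; the BH option exists for users who want q-values.
- Estimator-style surfaces (`fit`/`transform`/`predict`,
  `get_params`) were chosen so the scaler, phase classifier, scorers and
  network analysis compose with sklearn pipelines and grid search; the
  module-level functions remain the simplest entry points.
- Experiment sizes in the verification suites (20,000 null replicates at
  n = 30; 500 recovery cohorts at n = 200; 50 invariance cohorts) were
  sized to estimate the measured rates to well under their acceptance
  margins.

## Known limitations

- The Fisher variance is asymptotic and normal-theoretic; at n = 6–7 the
  per-edge test is honest about direction but weak, and the networks
  should be read as effect-size maps.
- Pairwise-complete matrices need not be jointly positive semidefinite;
  this is irrelevant for edge-wise Z_obs but would matter if the matrices
  were fed to methods requiring a valid joint correlation matrix.
- The phase-call cutoffs are a stated convention, not a community
  standard; sensitivity to them can be explored via the classifier's
  parameters.
- The copula generator controls rank correlation, not higher-order
  dependence; it cannot emulate, e.g., tail-dependent coactivation.
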