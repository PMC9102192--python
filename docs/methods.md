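# Methods

This note documents the models implemented in `cafkit`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions that affect results.

## Subtype prototype rule

Each of the four HNSCC mRNA categories is a signed signature over the
marker features:

| category | signature |
|---|---|
| basal (BA) | *TP63*+, *EGFR*+, *SOX2*− |
| mesenchymal (ME) | *VIM*+, *DES*+, *TP63*− |
| classical (CL) | *SOX2*+, *NFE2L2*+, smoking+ |
| atypical (AT) | *SOX2*+, p16+ |

Every feature is z-scored across the cohort (sd with denominator n−1;
the choice is immaterial at cohort sizes of ~55 but is fixed for
reproducibility). A category's score is the mean of sign × z over its
signature; the patient takes the arg-max category. "Low X" is encoded as
sign −1 on the standardised value — the direction is part of the rule,
the arithmetic encoding is ours.

Two points were genuinely open and are config-exposed:

- **Binary covariates.** Smoking and p16 are z-scored like expression
  by default (reading "standardised" as applying to all features);
  `standardize_binary=False` uses raw 0/1 instead. With z-scoring a rare
  positive covariate contributes a large positive z, which is the
  behaviour that makes the p16+/AT association decisive.
- **Ties.** Exact or near ties (top two scores within 1e-12) resolve by
  the fixed priority AT > BA > CL > ME and set a `tied` flag. Ties are
  measure-zero under continuous inputs; the rule only matters for
  degenerate data (e.g. all-zero z).

Standardisation makes assignments invariant to adding a constant to any
one gene and to patient order; negating a patient's z vector negates all
four scores.

## Colony quantification

Registration is an exhaustive search over integer translations within a
configurable radius (default ±32 px), maximising the normalised
cross-correlation of grayscale (channel-mean) overlaps; ties break by
smallest |dy|+|dx|, then row-major order. Sub-pixel shifts and rotation
are out of scope — plates photographed on a fixed rig move by
translation, and the ROI transfer only needs pixel precision. A best
correlation below 0.2 flags "poor registration" without failing.

Segmentation is a single fixed blue-channel threshold applied to every
image in a batch. The threshold is a required configuration item, not a
constant of the method; the polarity (stain bright vs dark) is a switch
because real stain/background contrast can invert. Area fraction is
counted over ROI pixels only, after shifting the ROI by the registration
offset; ROI pixels falling outside the frame leave the denominator.
Lowering the threshold can only grow the mask, so the area fraction is
monotone in the threshold.

The colony-supporting call is a two-sided Welch t-test of treated vs
control covered fractions: supporting means p < 0.05 with a higher
treated mean, suppressing the mirror case. Degenerate zero-variance
groups short-circuit (identical → p = 1; distinct constants → p = 0).

## Hertz–Sneddon fitting

Forward model, force in nN, indentation δ in µm, E in Pa:

    F = c(θ) · E/(1 − ν²) · δ² · 10⁻³
    c_cone = (2/π)·tanθ        c_pyramid = 0.7453·tanθ

The four-sided pyramid prefactor (Bilodeau) is the default geometry for
silicon-nitride probes; θ is a required config value (probe datasheet
territory), ν defaults to 0.5 (incompressible cell) and is exposed.
Indentation is computed from piezo height without cantilever-deflection
correction — the supported export format carries force vs height and no
spring constant; this overestimates δ slightly at high loads and is a
documented approximation.

The fit fixes the baseline F0 as the median force over the first 20% of
the approach (the far-from-surface region), then scans candidate
contact points z0 on a grid at every 2% of the height span. At each z0
the modulus has a closed-form least-squares solution (the model is
linear in E given z0), and the residual is evaluated over the whole
curve; the best grid point is refined by bounded 1-D minimisation
between its neighbours. Contact-point handling dominates fit quality,
which is why it gets the grid + refinement rather than a joint nonlinear
solve with arbitrary initialisation. Non-convergence (returned, never
raised): fewer than 10 post-contact samples, E at the bounds
[1 Pa, 1 MPa], or relative improvement over the baseline-only model
below 1% — the latter catches flat/no-contact curves. Baseline offsets
are absorbed exactly by F0 and height translations by z0.

Force maps are summarised as the median E over converged fits inside
the cell mask, with the converged fraction reported; the median is
robust to the occasional substrate pixel leaking into the mask.

## RT-DC processing

Events pass iff area ∈ [70, 2000] µm² **and** porosity ∈ [1.00, 1.05]
(closed intervals). Exclusions are attributed to the area rule first and
the porosity rule for area-passing events, so rule counts plus retained
count equal the input count and the filter is idempotent. Measurements
with fewer than 1000 retained events are flagged. Per-measurement
summaries are medians; a treatment's value is the mean over its
duplicate measurements. The deformation→modulus conversion is a
published lookup performed upstream; a precomputed modulus column is
consumed, never recomputed. AFM-vs-RT-DC agreement is a plain Pearson
correlation on paired per-sample values.

## Cohort statistics

- **ΔΔCt**: ΔCt = Ct_target − Ct_ref (PSMB2); the per-gene control ΔCt
  is the arithmetic mean over control samples; log2 fold change = −ΔΔCt,
  fold change = 2^(−ΔΔCt).
- **Fisher exact (r×c)**: full recursive enumeration of tables with the
  observed margins, two-sided p as the total probability of tables no
  more probable than the observed one (relative slack 1e-7 against
  floating-point noise) — the probability-mass convention of mainstream
  statistics environments; other two-sided definitions exist. The table
  is transposed internally when that shortens the row-by-row
  enumeration. Totals above 500 are refused; `fisher_exact_auto`
  additionally bounds the enumeration count and falls back to a seeded
  permutation Monte-Carlo p (add-one estimator) for wide tables whose
  enumeration is intractable.
- **Clustering**: the five-gene lactate panel is z-scored per gene
  (constant genes contribute zero), samples clustered with Ward linkage
  on Euclidean distance, the tree cut at k = 2. Cluster 1 is defined as
  the cluster with lower mean standardised panel expression, making the
  labels deterministic under sample reordering and per-gene affine
  rescaling. Metric, linkage and scaling are package choices; only the
  two-cluster contract is fixed.
- **Survival**: Kaplan–Meier product-limit curves per group with the
  two-sample (or k-sample) log-rank test; Cox proportional-hazards fits
  via lifelines with Efron tie handling. Stepwise selection is
  bidirectional by partial-likelihood AIC starting from the full model,
  taking the best single add/drop until no move improves AIC; the empty
  model's AIC is computed from the null partial log-likelihood.
  Covariates whose single-covariate fit fails (separation,
  non-convergence, zero variance) are flagged and excluded from the
  search rather than aborting it. No multiple-testing correction is
  applied anywhere; the p < 0.05 convention is preserved deliberately.

## Synthetic-data generator

One global seed; each generator draws from its own substream
(`SeedSequence(seed, spawn_key)`), so outputs are byte-identical under
regeneration and independent of the order in which generators run.

- **Cohort** (default n = 55, mixture 18/11/14/12 AT/BA/CL/ME — the
  packaged cohort's composition): signature markers shifted ±Δ (default
  Δ = 3 sd) on gene-specific baselines, noise sd 0.5, non-signature
  genes pure noise. Smoking is forced for CL-planted and p16 for
  AT-planted patients (flip probability 0.05) **only when Δ ≠ 0**:
  covariate forcing is part of the planted signal, so the Δ = 0
  configuration is genuinely uninformative and classifier accuracy sits
  at chance. Background rates (smoking 0.4, p16 0.15) echo the packaged
  cohort. Lactate-cluster membership is Bernoulli(0.3); cluster 2 has
  its panel genes shifted +4 sd and hazard multiplied by 3. Survival is
  exponential (baseline 10⁻³/day) with independent Uniform(0, c)
  censoring, c solved numerically so the expected censored fraction
  equals the configured rate (default 0.3).
- **Colony plates** (192×192 px, 5–15 disks of radius 6–18 px):
  background blue 100, colony blue 160 (contrast margin 60, so a fixed
  threshold of 130 sits 6 noise-sd from both sides at pixel noise 5).
  The truth fraction is counted on the rendered disk-union mask inside
  the centred half-size ROI; each well image is the reference content
  translated by a known integer shift (±8 px) plus fresh pixel noise.
- **Force curves** (400 samples over a 3 µm descending approach,
  contact point at 35–60% of span, force noise 0.02 nN, E = 1000 Pa):
  built from the same forward model the fitter inverts, which is what
  makes the noiseless round-trip a 0.1%-level identity and the noisy
  batch a genuine recovery experiment. Force maps place a circular
  1 kPa cell on a 100 kPa substrate.
- **RT-DC** (2000 events, 60% in gate): in-gate events draw area from a
  clipped Normal(150, 30) and porosity Uniform(1.00, 1.05); contaminants
  are debris (area < 70), clusters (area > 2000) or damaged cells
  (porosity > 1.05), so every contaminant violates at least one bound
  and the gate recovers the planted set exactly.
- **qPCR**: Ct_target = Ct_ref + baseline ΔCt − log2FC + noise
  (sd 0.2, 6 replicates), so ΔΔCt recovers the planted fold change in
  expectation exactly.

What the generator does **not** emulate: batch effects, gene–gene
correlation beyond the planted structure, heteroscedastic qPCR noise,
cantilever deflection and adhesion in force curves, optical artefacts
or uneven illumination in plate images, and any association between a
patient's subtype and their lactate cluster. Passing recovery tests
therefore demonstrates correctness of the computations under the stated
models, not robustness to real-data pathologies.

## Problem sizes and runtime

Tests and the acceptance script use: 200-patient cohorts for recovery,
200-curve AFM batches, 6 plate images at 192×192 px, 2000 RT-DC events,
1000-replicate t-test calibrations, 20-seed stepwise-Cox simulations at
n = 300, and exhaustive Fisher cross-checks over all 2×2 tables with
total ≤ 30. These sizes give stable pass/fail behaviour at the stated
tolerances while keeping the full suite around a minute on one CPU.

## Known limitations

- Registration is integer-translation only; scenes with rotation or
  scale change need external pre-alignment.
- The Hertz–Sneddon fit assumes a homogeneous elastic half-space and
  small-deflection force-vs-height data; viscoelasticity and adhesion
  are out of scope.
- The exact Fisher test is enumeration-based; tables that are both
  large-margin and wide fall back to Monte Carlo rather than the
  network algorithm.
- Stepwise selection by AIC inherits the usual instability of stepwise
  procedures near the inclusion boundary; selection rates, not single
  runs, are the meaningful output.
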