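# Methods

This note documents the statistical and numerical conventions the package
implements, the choices made where the underlying screening methodology left
them open, and what the synthetic-data generators do and do not emulate.

## Data model

A screening campaign is three tables keyed by isolate id. "Not detected"
(ND) is a first-class state throughout: a quantitative trait field holds
either a `Measurement` (mean ± SE over n replicates, n = 3 by default) or
nothing. ND is never coerced to zero at parse time; each downstream consumer
decides its meaning (the bonitur scorer awards 0 points, prevalence counts
it as negative, extremes ignore it). In the inhibition matrix, absent cells
mean "no activity observed", represented as NaN in the backing DataFrame and
excluded from all counts.

Cells of the form `mean ± se` keep both parts; everything downstream of
parsing operates on the means, and SEs ride along for reporting and
round-trips. Cross-table reconciliation (`validate_roster`) is report-based:
duplicate ids, ids missing from one table, out-of-range values and
tissue-vs-code contradictions are listed, never raised, because a screening
dataset with clerical inconsistencies is still analyzable.

## Assay arithmetic

* **Calibration.** Standard curves are fitted by ordinary least squares with
  a free intercept. Blank correction of absorbances is not guaranteed in
  practice, so the intercept is estimated rather than forced through the
  origin. At least 3 standards spanning ≥ 2 distinct concentrations are
  required; r² < 0.98 triggers a `CalibrationQualityWarning` rather than an
  error. Inverted concentrations below zero are flagged and accompanied by a
  zero-censored companion value; the raw value is preserved for QC.
* **Siderophore percentage.** The CAS-shuttle expression is computed as
  100·(Ar − As)/Ar — the subtraction grouped before the division. This is
  the only dimensionally sensible reading (Ar is the reference absorbance,
  and the quantity must be 0 when As = Ar and 100 when As = 0).
* **Percent inhibition.** 100·(C − T)/C. A test diameter exceeding the
  control yields a negative value (the pathogen grew better); this is
  allowed and left to the caller to flag, since discarding it would hide a
  real observation.
* **Chlorophyll.** The DMSO-extract equations are linear, so negative
  outputs can occur at extreme absorbance ratios; they are flagged, not
  clamped.
* **Replicate summaries.** SE = sd/√n with the sample (n − 1) standard
  deviation.

## The bonitur scale

The 41-point additive scale bins IAA at (15, 30] µg/ml and phosphate
solubilization at (100, 200] µg/ml into 1/2/3 points, awards 1 point per
positive binary trait (ammonia, N₂ fixation, ACC deaminase, siderophore,
chitinase — a detected quantitative value counts as positive), and bins each
pathogen's inhibition percentage at (10, 30], (30, 60], (60, 100] into
0–3 points.

Two conventions needed fixing where the published footnote is ambiguous or
self-contradictory:

* **Bins are upper-inclusive.** The published score table assigns 2 points
  to a 60.0% inhibition — the only boundary value the data exercise — which
  fixes (30, 60] rather than [30, 60).
* **The phosphate bins close the 200–300 gap.** The printed footnote maps
  "3 ≥ 300", leaving 200–300 µg/ml unmapped, yet the published table awards
  3 points to isolates at 213–258 µg/ml. The scale therefore uses
  (200, ∞) → 3.

Ranking is dense (totals 34, 32, 31, 31, 21 → ranks 1, 2, 3, 3, 4) and
invariant under order-preserving transformations of the totals.

The audit never corrects: recomputed cards are compared cell-wise with the
published table and every disagreement is listed, together with a check that
each published row's own points sum to its printed total. On the packaged
tables the audit flags DNLA13 (two inhibition cells printed with the wrong
bin) and VCRA2 (a phosphate cell one bin low, several inhibition cells off,
and printed points summing to 28 against a printed total of 30). These are
properties of the printed source; reproducibility tooling must surface, not
hide, them.

## Campaign summaries

Prevalence uses detection as positivity — no magnitude threshold — because
that is what the campaign's own counts reflect. Percentages are rounded
half-up to two decimals. Extremes return *all* isolates attaining a tied
extreme so results do not depend on row order. The ≥ 1-pathogen antagonist
count is the size of the union of the per-pathogen inhibitor sets; on the
packaged matrix it is 28, one more than the prose summary of the source
(the matrix, as the per-isolate record, wins).

## Pot-trial statistics

* **ANOVA.** Classic (equal-variance) one-way ANOVA from the Fisher
  sums-of-squares decomposition, run per parameter per timepoint; p-values
  come from the upper tail of F(k−1, N−k). Degenerate inputs follow the
  natural limits — all values identical gives F = 0, p = 1; zero
  within-group variance with unequal means gives F = ∞, p = 0 (a library
  routine returning NaN here would silently drop real, if pathological,
  signal). The implementation is cross-checked against
  `scipy.stats.f_oneway` in the test suite. No correction is applied across
  the nine parameters; p-values are raw and reported as such.
* **Fold change.** log₂(treatment mean / control mean), means over
  replicates — not per-replicate ratios — matching the convention of
  comparing group means; antisymmetric by construction.
* **PCA.** Parameters mix counts, centimetres, grams and mg/g, so columns
  are standardized and the correlation matrix eigendecomposed. Explained
  percentages are eigenvalues over their sum (= the number of parameters),
  sorted descending; tiny negative eigenvalues from floating-point are
  clipped at zero. A constant column is a hard error naming the column.

## Synthetic data

The generators produce campaigns and trials with the statistical structure
the analysis assumes, at the scale of the packaged campaign:

* **Screen.** 51 isolates by default; per-trait detection probabilities
  equal to the packaged campaign's observed prevalences (e.g. IAA 27/51,
  phosphate 25/51); detected values drawn uniformly within the printed
  min–max ranges (IAA 4.0–43.8 µg/ml, phosphate 61.1–289.7 µg/ml, ammonia
  0.9–5.9 µmol/ml, siderophore 10–61.2%); genus and tissue drawn from the
  campaign's composition; inhibition cells active independently at the
  packaged matrix's density (132/510 ≈ 26%) with values in 26.1–92.2%.
  Uniform-in-range is a stated default, not an inference — only ranges are
  published. Log-uniform is available.
* **Trial.** 4 treatments × 2 timepoints × 5 replicates; each value =
  control mean × treatment fold change × lognormal noise with configured CV
  (8% by default, mean-1 noise so expectations equal the configured
  products). Default fold changes sit inside the published 1.3–5.3 band with
  the consortium strongest. Control means are plausible young-chili pot
  values chosen once (e.g. 12 cm shoot, 0.25 g dry shoot at 35 days); they
  anchor scale only, since fold-change and ANOVA results are
  scale-invariant.
* **Seeding.** One integer master seed; each generator draws from
  `default_rng([stream_id, seed])` with a fixed per-component stream id, so
  adding a generator never perturbs existing outputs. Outputs are
  deterministic at the level of emitted text files.

What the generators deliberately omit: correlation among traits,
genus-dependent trait distributions, phylogenetic signal, and
timepoint-dependent treatment effects. Tests passing on synthetic data
therefore demonstrate the pipeline's arithmetic and calibration, not the
biological realism of any particular campaign.

The published pot-trial figures (PC1 ≈ 83–84%, the per-parameter fold-change
ranges) were printed without their raw replicates and cannot be recomputed;
they inform the generator's configuration and the statistical stages are
instead validated by properties: type-I error calibration of the ANOVA stage
(5,000 null simulations of 3 groups × 5 replicates; rejection rate within
0.05 ± 0.01), pooled log₂ fold-change recovery within 3 SE on configured
trials, and PCA explained variances matching a dense eigensolver to 1e-8.

## Problem sizes in the test suite

The suite runs the full 51-isolate fixtures everywhere, 10,000-isolate
generation for prevalence convergence, 5,000 null ANOVA simulations, and
10,000 randomized bonitur profiles for the monotonicity/bound property —
each chosen as the smallest size at which the property being tested is
statistically sharp.

## Known limitations

* The bonitur scale is the fixed additive scale described above;
  alternative weightings or multi-criteria methods are out of scope (the
  rule set is configuration, so other campaigns can redefine bins and
  traits).
* No post-hoc tests, mixed models or repeated-measures structure in the
  trial stage; harvests are analyzed independently per timepoint.
* No diversity indices or rarefaction in the campaign summaries.
* Sequence data (16S identification, accession handling, trees) are out of
  scope; genus labels are consumed as given.
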