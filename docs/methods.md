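# Methods

This note records the models, estimators, defaults and numerical choices
behind `ecselect`, and what the synthetic-data validation does and does
not demonstrate.

## Cq data model and plumbing

A `CqMatrix` is an assays × samples table of quantification cycles.
Detected values must be finite and lie in [0, max_cycles] (default 40);
undetected wells ("Undetermined"/empty in delimited exports) are stored
as NaN, never as 0. A reported Cq of exactly 40 is kept as a numeric
value — no automatic late-Cq cutoff is applied, because any such cutoff
is a policy decision, exposed instead through the "expressed" threshold
of the screening stage.

**Replicate collapsing.** Wells sharing a (sample, assay) key — including
inter-run repeats — are pooled and summarized by the arithmetic mean of
the detected replicates; Cq is already a log-scale quantity, so the
arithmetic mean corresponds to a geometric mean of linear abundances.
Sets whose sample SD (n−1 denominator) exceeds the policy threshold
(default 0.28 cycles) are flagged and *excluded*; there is no
best-2-of-3 rescue, because any rescue rule would have to be invented.

**Inter-assay calibration.** The IAC is one physical sample re-run on
every plate. Each plate's offset is its IAC mean Cq minus the
well-count-weighted global IAC mean, subtracted from every Cq on the
plate. The correction is additive in Cq space, so within-plate contrasts
are untouched and the weighted offsets sum to zero. Calibration uses
replicate-level records (which carry plate ids) and must precede any
pooling of one sample across plates.

**Summaries** report mean ± SD, min, max and range = max − min per assay
and group, rounded to 3 decimals for display only; all computation is at
full precision.

## Global-mean-expression screening

For sample j the global mean GM_j is the mean Cq of all *expressed*
assays (detected and Cq < cutoff; default 35, configurable — "expressed"
has no universal definition). Control wells (snoRNAs, negative controls)
are excluded from GM_j but still scored against it, and the U6
quadruplicate is collapsed to one assay (mean of detected wells) before
ranking. The stability score of assay i is SD_j(Cq_ij − GM_j) with the
n−1 denominator (the screens this targets have n ≈ 20). Because GM_j
absorbs any per-sample additive shift, the score is invariant to the
shared RNA-loading effect — the nuisance the method exists to remove.
Candidate eligibility additionally requires detection in 100 % of
samples: a control that drops out is useless regardless of its score.
Ties are broken lexicographically and reported.

## geNorm

Cq is converted to relative quantities
Q_ij = (1 + E_i/100)^(anchorCq_i − Cq_ij) with E = 100 % by default
(stability analysis is efficiency-agnostic; measured efficiencies are
accepted when available) and the per-assay minimum Cq as anchor so
max Q = 1. The anchor cancels in every ratio, so all geNorm outputs are
anchor-invariant (tested). Pairwise variation V_jk is the SD (n−1) of
log2(Q_j/Q_k) across samples; M_j is the mean of V_jk over k ≠ j; with
exactly two candidates both carry M = V_jk. Stepwise exclusion drops the
highest-M assay (ties broken by name, recorded) and recompute until two
remain. Normalization factors NF_n are per-sample geometric means of the
n most stable candidates' quantities; V(n/n+1) = SD(log2 NF_n/NF_{n+1}).
The recommended n is the smallest with V < 0.15 (the canonical
heuristic); when no V clears the cutoff — typical for noisy clinical
panels — the n minimizing V is recommended and labelled as such. Log
base 2 throughout. Missing candidate values are an error, not imputed:
an EC undetected anywhere is disqualified upstream.

## Model-based stability (NormFinder-style)

Log2 expression is modelled as y_igj = α_ig + β_gj + ε_igj with
ε ~ N(0, σ²_ig): gene/group means, a shared per-sample effect, and
gene-specific noise. The sample effect is removed exactly by subtracting
each sample's mean over the k candidates (so all outputs are invariant
to per-sample Cq shifts, and to per-assay location shifts).

*Finite-gene variance correction.* Centring couples the genes: the naive
variance of the centred data satisfies
E[s²_ig] = σ²_ig(1 − 2/k) + σ̄²_g/k. Averaging over genes gives
E[s̄²_g] = σ̄²_g (k−1)/k, hence the unbiased-by-construction estimator

    σ̂²_ig = (k·s²_ig − (k/(k−1))·s̄²_g) / (k − 2),

truncated at zero (the correction can go negative at small n; k ≥ 3 is
required). Published descriptions of this correction vary, so the
implementation is validated by parameter recovery on simulated cohorts
— per (assay, group), the median estimate over 200 seeds falls within
25 % of the generating variance for moderately noisy genes — and by the
invariants above, rather than by matching any historical spreadsheet.
The exact formula is carried in the result metadata.

*Bias estimation is test-then-shrink.* The inter-group contrast d_ig
(equal group weights, Σ_g d_ig = 0) enters the stability value only when
the gene's own standardized contrast max_g |d_ig|/SE(d_ig) clears the
Bonferroni-corrected two-sided normal quantile at 0.05/k; surviving
contrasts are shrunk by γ̂²/(γ̂² + Var d_ig) with the pooled moment
estimate γ̂² = max(0, mean(d²) − mean(Var d)). The hard threshold exists
because sample centring leaks every contrast — real or sampled — equally
into all genes (Σ_i d_ig = 0), so an un-thresholded |d| term makes
candidate comparison under homogeneous expression a race between
sampling-noise draws rather than between variances. The threshold is
asymmetric by design: silencing a borderline bias merely defers to the
variance criterion (correct under the null), while admitting one injects
noise into the ranking.

*Composition.* ρ_i = mean_g(|d̃_ig| + sqrt(model Var d_ig)), where the
model variance is built from the corrected σ̂² of the gene itself; the
centring noise shared by the whole panel cancels when any candidate is
used as a normalizer and therefore must not discriminate between
candidates. With one group ρ_i = σ̂_i. The best pair treats two genes as
their log-scale mean: contrasts average, variance contributions halve,
the same |bias| + SE composition applies, and the search is exhaustive.
Two genes with opposite group biases can beat both members — the formal
rationale for two-control normalization.

## Validation statistics

*Difference testing* applies a Lilliefors (KS with estimated parameters)
normality gate per group at α = 0.05; both groups Gaussian → Welch t
(unequal variances, matching unbalanced 40/20 designs), otherwise
Mann-Whitney U. Groups smaller than 5 or with zero spread skip the gate
and count as normal (the gate has no power there). An optional log10
transform is available for RQ-scale data and is applied by the
EC-sensitivity experiment.

*Equivalence testing* reports the group difference on the log2 expression
scale (expression = −Cq, so positive = more abundant in the first group)
with a symmetric two-sided Welch interval (default 95 %); equivalence at
a fold bound F means the whole interval lies within ±log2 F. The bounds
±1 and ±1.58 correspond to 2-fold and 3-fold (log2 3 = 1.58 to 2 dp); the
working bound is the 3-fold one. A `tost` mode tightens the interval to
90 %, making the verdict an exact two-one-sided-tests procedure at
α = 0.05. The verdict is monotone in the bound by construction.

*Variance comparison* uses Bartlett's test across candidates' Cq
distributions, with per-assay SD intervals from the chi-square
distribution at the Bonferroni-adjusted level α/m.

## Quantification

Efficiency comes from the OLS slope of Cq on log10 input
(E = (10^(−1/slope) − 1)×100; acceptance band 90–110 %). Relative
quantities follow the comparative-CT formula; multi-control strategies
aggregate by the geometric mean of the controls' linear quantities
(arithmetic mean in Cq space), which is idempotent under duplicated
controls and reduces exactly to 2^(−ΔΔCT) at 100 % efficiency. Missing
efficiencies default to 100 % with a logged warning. The calibrator
defaults to a per-assay control-group-mean pseudo-sample (no named
calibrator is canonical); a named sample can be supplied. Differential
expression of RQ values is tested on the log10 scale.

## Synthetic cohorts: what they emulate and what they do not

A well follows
Cq = B_i + S_j + δ_i·1[case] + π_plate + ε_ij + η_ijr with
S_j ~ N(0, τ²) shared across assays (RNA loading; default τ = 0.5
cycles), gene noise ε ~ N(0, σ_i²), plate shifts π ~ N(0, plate_sd²)
and replicate jitter η ~ N(0, σ_rep²). Gaussian noise on the Cq (log)
scale is the assumption under which the normality-gated t-tests are the
intended path. Generation is a pure function of (spec, seed), and the
ground-truth record reconstructs every sample's expected Cq exactly.

The default validation design (40 cancer / 20 control, triplicates,
3 plates with IAC wells, plate_sd 0.2) pins the candidate controls to
published blood-cohort summaries: baselines are the control-group means,
the U6-like control carries the published +0.569-cycle case shift (the
control group more abundant), and σ_i is chosen so sqrt(τ² + σ_i²)
matches the published total SDs (miR-16 1.246, miR-425 1.324, U6 0.60
against its ≈0.78 per-group SDs, whose marginal 0.848 is inflated by the
group gap). Three targets emulate the quantification experiment: a true
null (miR-93-like, σ 0.5), a modest shift (miR-181a-like, +0.4 cycles)
and a strong one (miR-652-like, +2 cycles ≙ 4-fold). The screen design
fixes its 384-well panel parameters from a dedicated panel seed; the ten
designed near-global-mean assays get small increasing σ so a stable
ordering exists, and detection dropout is a free parameter (no array
detection-call rule is canonical).

Not emulated: hemolysis and cell-composition effects, probe
cross-hybridization, fluorescence-curve artifacts, non-Gaussian heavy
tails. Passing the simulation suite therefore demonstrates correctness
of the statistics under their own model, not robustness to those
real-data pathologies.

## Operating characteristics (problem sizes)

The acceptance script and test suite measure, per run: oracle
equivalence against brute-force recomputation (100–1,000 random
instances ≤ 6 assays × 10 samples; agreement to ~1e−9), stable-pair
recovery on 200 seeded cohorts (geNorm ≈ 100 %, model-based ≈ 97 %),
variance recovery (median relative error ≈ 6 %), null calibration over
1,000 cohorts (rejection 5 % ± 2 %, 3-fold equivalence ≈ 100 %), and the
biased-normalizer pattern over 500 cohorts. Under the published noise
scale the two Welch-test legs of that pattern (flagging the +0.57-cycle
biased control at n = 40/20, and the induced false positive in a null
target) each run at ≈ 0.7 power — noncentrality ≈ 0.57/0.21 ≈ 2.7 — so
the *joint* pattern reproduces in ≈ 55 % of cohorts, while its
directional content (false-positive rate under the biased control far
above the ≈ 5 % under unbiased controls; the strong target significant
everywhere) holds essentially always. Raising the joint rate would
require quieter data than the published cohort exhibits.

## Known limitations

- The model-based stability values are not bit-compatible with the
  historical spreadsheet add-in (by design; the correction and
  thresholding are documented above and in result metadata).
- Only two-group designs are supported for the bias decomposition.
- No absolute quantification or Pfaffl-ratio variants; no instrument
  binary formats; no fluorescence-curve processing.
- The published stability values themselves (M ≈ 0.9–1.25, V = 0.185,
  model-based 0.038–0.102) derive from undeposited patient data and are
  treated as qualitative references only.
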