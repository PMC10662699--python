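# Methods

`glycoprm` implements a serum-glycoproteomics biomarker verification
analysis — PRM quantification QC and normalization, consensus feature
selection, multi-model classification with ensemble voting — together with a
synthetic study-design generator that makes every stage testable at desk
scale. This note records the statistical model, the parameter choices and
the decisions taken where the design was genuinely open.

## Quantification model

A PRM run measures, per peptide, the integrated XIC area of the endogenous
("light") precursor and, for IS-quantified peptides, of a stable-isotope
("heavy") internal standard. Because the TiO₂ glycopeptide enrichment
precedes heavy-peptide spiking, a run's enrichment recovery multiplies all
light and reference-glycopeptide areas but not the heavy areas. The summed
XIC of 30 high-abundance reference glycopeptides, `C`, is taken as
proportional to that recovery.

Processing order is fixed as: IS correction → enrichment normalization →
replicate averaging.

* **IS correction**: `Lₙ′ = (H̄ₙ / Hₙ) · Lₙ`, where `H̄ₙ` is the cohort mean
  heavy area of peptide *n*. Any per-run global instrument-response factor
  cancels because light and heavy share it. `H̄ₙ` is computed over QC-retained
  runs only (excluded runs are defective by definition) and can be passed
  explicitly to hold the cohort constant fixed.
* **Enrichment normalization**: areas are divided by `C_run / C̄`, with `C̄`
  the mean reference sum over the retained run set (again overridable).
  This cancels the per-run recovery for all peptides, including the three
  label-free ones that skip IS correction.
* **Averaging**: duplicate runs surviving QC are averaged per peptide; a
  peptide missing from one replicate uses the available replicate; a peptide
  missing from every run of a sample is imputed at half the cohort minimum
  for that peptide and flagged in the matrix provenance.

Note on the scale-invariance properties: multiplying one run's recovery by
*k* leaves its normalized areas exactly unchanged *given fixed cohort
constants* (`C̄`, `H̄ₙ`). When the constants are recomputed from the perturbed
data, every sample rescales by the same global factor — a relabelling of
units, not a violation — which is why the invariance tests pass the
constants explicitly.

## Replicate QC

Duplicate concordance uses the scaled relative difference of the reference
sums, `SRD = (C₁ − C₂)/(mean(C₁, C₂)·√2)`; |SRD| > 0.50 (slightly more than
a twofold recovery difference, which gives |SRD| ≈ 0.47) drops the
replicate with lower recovery. Separately, any run with
`C < mean(C) − 2·SD(C)` is dropped. Open choices resolved here, all
configurable:

* the 2-SD rule is one-sided (low recoveries only);
* mean and SD are computed over **all** runs before any exclusion, in a
  single pass (no iteration);
* the concordance rule is applied first, and a run is dropped for exactly
  one reason. In a duplicate design a run far enough below the 2-SD
  threshold while its partner is normal almost always violates the SRD rule
  too, so for paired runs the concordance rule is the operative mechanism;
  the 2-SD rule matters for singleton runs.

## Synthetic study designs

The generator emulates the verification design: `n_pca = 79` and
`n_bph = 84` subjects, duplicate runs each (326 runs), a 32-peptide panel
(29 IS-quantified + 3 label-free), 30 reference glycopeptides, and clinical
covariates. Defaults are the study conditions; everything is configurable.

* **Clinical markers** are lognormal, parameterized per group by matching
  the published median exactly and the IQR *ratio*
  (`σ = ln(q₃/q₁)/(2·z₀.₇₅)`): clinical markers are strictly positive and
  right-skewed, and only medians/IQRs are available. fPSA is derived as
  `ftPSA/100 × tPSA` times a 5% lognormal error so the free/total ratio
  stays internally consistent; its own median is implied, not imposed.
  Gleason grades: 26 of 79 PCa are 3+3 (NAG); the aggressive strata follow
  the published 22/16/15 proportions.
* **Peptide baselines** are log-uniform over five orders of magnitude
  (10⁴–10⁹ area units), mirroring the panel's blood-concentration range.
  Between-subject biological variation is lognormal with σ = 0.40 — a
  typical serum-protein between-individual CV; without it classification
  would be trivially perfect. Planted PCa/BPH fold-changes default to the
  discovery-phase estimates carried in the packaged panel file (2.42 down
  to 1.09 for the discovery-derived peptides, 1.0 for the spectral-library
  additions); the AG/NAG sub-analysis plants FC 1.2 on the seven
  aggressiveness-panel peptides.
* **Run effects**: per-run enrichment recovery is lognormal with σ = 0.10;
  measurement (XIC integration) noise σ = 0.08 per observation; heavy-spike
  pipetting error σ = 0.05 per run. Heavy areas never see the enrichment
  factor (standards are spiked after enrichment).
* **Injected failures**: a discordant pair is planted by setting replicate
  2's recovery to replicate 1's divided by 2.6, which pins the planted
  |SRD| at ≈ 0.63 — deterministically beyond the 0.50 rule rather than at
  the mercy of two independent draws. The published QC outcome reports only
  the combined result (131 pairs + 32 singletons retained from 163
  duplicates), not the per-rule split, so the default plants all 32
  failures as discordant pairs (`frac_discordant_runs = 32/163`,
  `frac_low_recovery_runs = 0`); low-recovery injection is available as a
  separate knob.
* **Reproducibility**: one RNG stream per dataset seeded from the config,
  with cohort and run sub-streams spawned deterministically; identical
  config + seed reproduces tables byte-for-byte. An `enrichment_scale` hook
  multiplies chosen runs' recovery after all draws, isolating a pure
  scaling for the invariance tests.

**Which planted features count as recoverable.** The truth sidecar lists the
features a raw-scale selector can in principle see: those whose *population
point-biserial correlation* with the group label is ≥ 0.25, computed in
closed form from the planted lognormal parameters
(`E = med·e^{σ²/2}`, `V = E²(e^{σ²}−1)`,
`r = |E₁−E₀|·√(p(1−p)) / √(p(1−p)(E₁−E₀)² + pV₁ + (1−p)V₀)`). The raw-scale
correlation — not the log-scale standardized shift — is the operative
quantity: a marker with a large log-scale separation but a heavy-tailed
null arm (proPSA's BPH IQR spans 87–440) has r ≈ 0.1 and is genuinely
invisible to these selectors. Under the defaults the recoverable set is the
seven peptides with FC ≥ 1.31 plus prostate dimension, tPSA and ftPSA.

**What the generator does not emulate** — and hence what passing tests do
and do not show about real sera: clinical covariates and peptides are
mutually independent given the diagnosis (real PSA forms are strongly
inter-correlated, and co-regulated proteins covary), there are no batch or
drift effects, no interference or integration errors beyond lognormal
noise, no informative missingness, and the planted effects are exact
multiplicative shifts. Independence of a dozen real effects makes the
synthetic classification task easier than the measured cohort: the
random-forest AUC saturates near 1.0 where the real-data figure was 0.93.
The tests therefore validate the *procedure* (bookkeeping, formulas,
orderings, invariances, recovery of planted signal) rather than the
real-data effect sizes, which require the measured cohort.

## Candidate filters

The sequon detector implements N-X-[S/T] with X ≠ P (the proline exclusion
is standard sequon biochemistry; a flag disables it). Missed cleavages
follow the trypsin K/R-not-before-P convention with the C-terminal residue
excluded. Fold-change comparisons are inclusive (≥), since the published
lists retain a candidate printed exactly at the rescue boundary. The
missed-cleavage tolerance defaults to 1: the published retained lists
include one peptide with a single internal missed cleavage, and the
discovery searches allowed up to two.

Three packaged candidates have no detectable sequon in the printed peptide:
two have their glycosite within two residues of the C-terminus (the S/T of
the motif belongs to the next tryptic peptide) and one printed site is
non-canonical. The filter therefore accepts an annotated glycosite (an N at
the stated position) as evidence when motif detection fails; detection
always wins when present.

The final 32-peptide verification panel is an explicit, editable file — not
a derived object — because the assay-development exclusions rest on
empirical solubility and peak-shape grounds. It encodes 29 IS-quantified
plus 3 label-free peptides across 29 proteins (the protein count is always
computed from the file, never asserted).

## Consensus feature selection

Five selectors vote; a variable needs ≥ 4 of 5 votes. Per-method choices:

* Pearson: |r| ranking, gated at the correlation test's two-sided p < 0.05
  (unadjusted).
* Chi-square: statistic on min-max-scaled features (the test requires
  non-negative inputs); pure capped ranking — the pseudo-p-value of this
  statistic on scaled continuous data is not calibrated, so it is not used
  as a gate.
* RFE: step 1, L2-logistic base estimator with balanced class weights, on
  standardized features.
* L1-logistic: regularization chosen by 5-fold CV, nonzero coefficients
  truncated to the cap by |coefficient| ("Logistics" in the published
  grid).
* Random forest: 500 trees, impurity importances, gated at the 95th
  percentile of importances from a single label-permuted refit.

Each method is capped at 20 selections. The gates exist because the cap
alone cannot confer specificity: with 37 variables and a 20-slot quota,
ungated selectors fill their quota even on pure noise and roughly a dozen
variables reach 4 votes under label permutation; with the gates the null
consensus is ~0–2. Weak-but-real features typically land at exactly 4 votes
with the forest abstaining — the same pattern visible in the published
selection grid. Tie-breaks everywhere are by feature name after score;
selectors sort columns canonically before fitting so the result never
depends on the caller's column order. Feature selection runs on the full
143-sample model-building set by default (the split-ambiguity is a
leakage-sensitivity knob, not resolved here).

## Classification and evaluation

* Grey-zone holdout: 20 samples drawn uniformly (seeded) from tPSA ∈ [4, 10]
  ng/mL; the remaining 143 split 70/30 stratified by label (100/43). The
  PCa-only AG/NAG analysis splits its 79 samples 70/30 (55/24) and uses
  four models (no SVM).
* Models: random forest (500 trees), logistic regression, KNN (k = 5),
  RBF-SVM and decision tree (unlimited depth); scale-sensitive models sit
  behind a standardizer; everything is seeded.
* Metrics: AUC, F1, accuracy, specificity, sensitivity (positive class =
  PCa, or AG in the sub-analysis), predictions at the 0.5 probability
  cutoff; 95% CIs from a stratified bootstrap of the test set (2000
  resamples by default, seeded).
* The univariate baseline is the ROC of raw tPSA values (a single-threshold
  family, no model); the fast DeLong test with midrank structural
  components compares it against the best multivariate model. The
  implementation is cross-checked in the tests against a brute-force
  pairwise-concordance AUC and an exhaustively enumerated
  structural-components variance.
* Voting: models are refit on all 143 build samples before classifying the
  grey zone. Hard voting takes the majority with ties broken toward the
  disease class (a false negative costs more than a false positive in a
  screening context); soft voting weights each model's vote by its test-set
  F1, same tie-break.
* The AG sub-analysis selects its own consensus features; when fewer than
  3 variables reach 4 votes at this small cohort size, the pipeline falls
  back to the top 8 by vote count and mean rank.

## Problem sizes and numerical notes

The test suite and the acceptance script run the full 163-sample design;
the recovery study uses 10 seeded replicates (the 50-replicate version of
the same check is a configuration change, not a code change). Degenerate
cases are defined rather than left to chance: zero-vote grids and empty
candidate tables return empty results; non-positive reference sums, heavy
areas, single-class training labels and >2 runs per sample raise; a
degenerate DeLong variance returns p = 1 when the AUCs agree and NaN with a
warning otherwise. Floating-point invariances (scale cancellation) are
asserted at 1e-9 relative; exact oracles (concordance AUC, enumerated
DeLong components) at 1e-10 or tighter.

## Known limitations

Raw-MS processing (peak integration, interference detection,
retention-time alignment) is out of scope; the pipeline starts from peak
areas. The synthetic cohort's independence assumptions (above) upper-bound
classifier performance; the AG/NAG sub-analysis at n = 79 with planted
FC 1.2 effects is intentionally marginal and its AUC varies widely across
split seeds, mirroring the instability expected at that sample size. The
precursor-level accounting of the published assay (62 precursors for 32
peptides: charge states and oxidized forms) is not modeled.
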