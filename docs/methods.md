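# Methods

## Centroid-correlation classification

Each sample is assigned by Pearson correlation to the nearest of K subtype
centroids over the genes shared between the matrix and the centroid table.
A cohort run requires at least 80% of centroid genes (and at least 3) to
be present; below that the classifier refuses rather than silently
correlating over a sliver of the signature.

Confidence gating uses two thresholds applied in a fixed order: a sample
whose maximum correlation falls below 0.15 is *low confidence* (this takes
precedence), otherwise a sample whose best-minus-second correlation gap is
below 0.06 is *mixed*, otherwise *high*. Mixed samples carry their argmax
("dominant") subtype, which downstream analyses may include alongside
high-confidence calls or not (`dominant_subtype_table(include=...)`).
Argmax ties break to the earlier centroid column — a probability-zero
event for continuous data, fixed deterministically for testability.
Samples with zero variance over the shared genes have undefined
correlations and are gated low with a warning instead of aborting the run.

Per-gene median centering of the matrix across cohort samples is on by
default (`center_genes=True`) because PAM-style centroids are built from
centered data. It is configurable because centroid tables on the raw log2
scale — including the ones our generator emits — should be correlated
against raw values; everything in this package that classifies synthetic
cohorts therefore passes `center_genes=False`.

## Cross-classification enrichment

For labellings A and B over their shared samples, cell (a, b) with overlap
k is tested one-sided for over-representation: p = P(X ≥ k) with X
hypergeometric (population N = shared samples, successes = margin of a,
draws = margin of b). Depletion is not tested. Benjamini–Hochberg
adjustment spans all cells of one enrichment matrix jointly — the most
conservative family when a single comparison matrix is reported. A Pearson
chi-square without continuity correction (dof = (r−1)(c−1)) summarises the
overall association; a warning is emitted when any expected count is
below 5. Samples missing from either labelling are dropped, not imputed.

## Signature scores and group tests

A signature score is the arithmetic mean of a sample's log2 expression
over the signature genes present in the matrix; absent genes are excluded
(no imputation), and coverage below 50% of the set is an error naming the
missing genes. Raw log2 values are averaged by default; a z-score option
standardises each gene across samples first for users who prefer
scale-free scores. Kruskal–Wallis (always tie-corrected, chi-square
approximation; exact small-sample p is not attempted) compares any score
across groups, with BH-FDR across scores when several are tested against
one grouping. The degenerate all-identical-scores case returns H = 0,
p = 1 with a warning rather than an exception.

## Recurrence-risk scores

The 21-gene recurrence score subtracts each sample's mean over the five
housekeeping genes (ACTB, GAPDH, GUSB, RPLP0, TFRC) from the sixteen
scored genes, forms the published weighted group scores (HER2, estrogen,
proliferation, invasion) and singleton terms (CD68, GSTM1, BAG1), and
combines them linearly. All coefficients ship in an editable YAML file
(`heterosub/models/oncotype.yaml`) citing their source; nothing is
hard-coded. Two deliberate deviations from the clinical RT-PCR assay,
both because log2 microarray values are not on the RT-PCR
reference-normalized scale and no published rescaling rule exists:

* the group floors (HER2 group at 8, proliferation at 6.5) are off by
  default (`apply_group_thresholds=False`);
* the 0–100 clinical rescaling is not applied; the unscaled score with
  cohort-tertile risk groups is the default, and fixed cut points can be
  supplied for rescaled data.

For probe-level arrays, probes are collapsed to genes by maximum standard
deviation, with a pin list forcing specific probes (the packaged model
pins probe 203507_at for CD68, which lacks a gene-level annotation on the
relevant platform).

The centroid-correlation risk score is Σₖ βₖ·corr(sample, centroidₖ) with
correlations computed exactly as in the classifier; the packaged
coefficient file carries the published intrinsic-subtype weights
(Basal 0.05, Her2 0.12, LumA −0.34, LumB 0.23) and the centroid table is a
user input. Tertile risk groups cut at the 1/3 and 2/3 score quantiles
(ties share a group; an all-tied cohort collapses to one group with a
warning).

## Survival

Kaplan–Meier estimation and the k-group log-rank test are delegated to
lifelines; censored observations shrink the risk set without producing
steps. Harrell's C is computed by explicit pair enumeration so the
usable-pair count can be reported: a pair is usable iff the shorter
observed time carries an event and the times differ, or the times tie
with discordant event status; tied-time tied-status pairs are excluded;
risk ties score 0.5. The confidence interval is a normal approximation
with SE = √(C(1−C)/m) over the m usable pairs; pairs are not independent,
so this is an approximation, and the method string is attached to every
result. Categorical risk groups are mapped to integer ranks via an
explicit user-supplied order (low < intermediate < high for risk groups;
subtype labels require the caller to state a prognostic order — there is
no canonical ordering of unordered subtypes, so none is assumed).
Treatment stratification is a row filter applied before analysis, not a
model covariate.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth per sample:

* **Centroids.** K centroids over a common gene universe. Every centroid
  shares a per-gene baseline `baseline_mean + N(0, gene_baseline_sd)`
  (default 8 ± 1 log2 units); subtype k's disjoint block of
  `n_signature_genes_per_subtype` genes (default 20 of 500) additionally
  sits `effect_size` (default 2 log2 units, i.e. 4-fold) above it. The
  shared baseline makes distinct centroids strongly positively correlated
  (≈0.85 at the defaults), as real centroid tables are — without it,
  near-even mixtures would be trivially separable and the mixed gate
  untestable.
* **Samples.** 40 per subtype by default (200 total, a mid-sized cohort).
  Pure samples are their centroid plus i.i.d. Gaussian noise (default SD
  1 log2 unit); a fraction `frac_mixed` (default 0.10) are convex
  combinations `w·c_a + (1−w)·c_b` with w = `mix_weight` (default 0.60,
  constrained > 0.5 so the dominant centroid is unique); a fraction
  `frac_null` (default 0.05) are baseline plus noise with no subtype
  signal — and no gene baselines, so they correlate with nothing and
  exercise the low-confidence gate. Exact zeros can be injected per gene
  to exercise the >30%-zeros filter (zeros, not dropout: matching the
  log-RSEM missing-value convention the filter is written for).
* **Labels and survival.** A secondary categorical label copies the true
  subtype with probability `secondary_label_agreement` (default 0.7) and
  is uniform otherwise, giving the enrichment stage a known association.
  Survival is exponential per subtype — 0.03 events/month for all
  subtypes except TA at 0.09, encoding one threefold-hazard
  poor-prognosis group — with independent exponential censoring (default
  0.02/month); null samples use the mean hazard, which the generator must
  define because they have no subtype. Gene–gene correlation beyond the
  shared baseline, batch effects and platform probe structure are
  deliberately not modelled, so passing tests demonstrate correctness of
  the statistics, not robustness to those real-data artefacts.

A single integer seed drives everything through
`SeedSequence(seed).spawn()` with a fixed stream order (centroid
baselines, roles, noise, zeros, labels, events, censoring), so identical
parameters and seed give bit-identical cohorts and changing one knob does
not perturb unrelated draws.

## Numerical and I/O choices

* "Missing value" means exact numeric 0; NA tokens in input files are
  rejected, not imputed (the analysis filters rather than imputes). The
  zero filter removes genes with zeros in strictly more than 30% of
  samples; a gene at exactly 30% is retained.
* All standard deviations use the n−1 denominator; variable-gene
  selection keeps genes with SD strictly above the cutoff, preserving
  input order.
* Duplicate feature rows and probe-collapse both keep the highest-SD row;
  ties break to the lexicographically smaller identifier, logged.
* Matrix writers emit floats as `%.17g` and readers parse with
  round-trip precision, and the correlation kernel fixes its memory
  layout, so a pipeline re-run from intermediate files is byte-identical
  to the in-memory run.
* Floating-point caveat: "correlation exactly 1" for a sample equal to
  its centroid is asserted to 1e−12, the precision of the vectorised
  Pearson computation.

## Pipeline sizes and runtime

The default test and acceptance runs use desk-scale problems: 500 genes ×
200–500 samples for classification experiments, 100 simulated two-arm
cohorts (25–50 samples/arm) for the log-rank calibration, and exhaustive
enumeration up to N = 30 for the hypergeometric oracle. These sizes give
stable Monte-Carlo estimates (binomial SE ≤ 5 percentage points on the
reported rates) while the whole suite runs in well under a minute.

## Known limitations

* The generator's effect size and noise are free parameters chosen to
  represent a moderately noisy microarray cohort, not estimates fitted to
  any real data set.
* The concordance CI is a binomial-type approximation; a full
  U-statistic variance would be tighter for heavily censored data.
* The recurrence score on log2 microarray data is rank-informative but
  not on the clinical 0–100 scale; fixed clinical cut points should only
  be used with data rescaled by the user.
* GSEA-style competitive gene-set testing is out of scope; signature
  mean scoring is the supported per-sample summary.
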