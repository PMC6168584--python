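# Methods

`deltanet` analyses longitudinal blood-biomarker cohorts in which each
participant has a baseline and a follow-up draw, panels differ between
participants, and the quantity of interest is the per-participant change
(delta) in each biomarker.  This note records the statistical model behind
each stage, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions that
matter for reproducing results.

## Pairing and quality control

For each (participant, biomarker) series the baseline is the earliest
measurement and the follow-up is the earliest measurement at least
`min_gap_days` (default 30) whole days later; a `latest` strategy is
available for users who prefer the longest horizon.  The earliest-qualifying
rule is the default because it is deterministic and maximises the number of
usable pairs.  Dates are calendar dates; gaps are whole-day differences.

Plausibility limits remove lab-upload anomalies (a fasting glucose of
15 mg/dL is an artifact, not a finding).  `qc.derive_limits` computes, per
biomarker, the 0.5 and 99.5 percentiles of a user-supplied population
reference sample, refusing biomarkers with fewer than 200 reference values
or a degenerate (constant) sample.  The percentile definition is fixed to
linear interpolation between closest order statistics (numpy's default),
because percentile conventions differ across ecosystems and the limits must
be reproducible.  A pair is removed when its baseline *or* follow-up falls
strictly outside the limits; bounds are inclusive (the conservative
reading); removal is always per-(participant, biomarker), never
whole-participant.  The bundled `data/plausibility_limits.yaml` contains
wide physiological bounds written for the synthetic presets; real cohorts
should derive limits from a reference population such as a national health
survey.

## Delta-correlation network

For every unordered biomarker pair, Spearman's rank correlation is computed
over the pairwise-complete participants (both deltas observed).  Ties get
average ranks; rho is the Pearson correlation of the ranks; the two-sided
p-value uses the t approximation with n−2 degrees of freedom, which is
standard at cohort scale (an exact view for very small n is available by
permutation outside this package's scope).  Pairs with fewer than `min_n`
(default 10) shared participants, or a degenerate rank vector, are flagged
untestable and excluded from both the network and the correction family —
so the Benjamini–Hochberg family is exactly the set of tested pairs (780
for a fully-testable 40-biomarker panel).  q-values use the standard
step-up; edges are entries with q < 0.05 (configurable), weighted by the
signed rho.  Deltas are raw differences, not percent changes.

The stratified sensitivity analysis (`sensitivity_compare`) reports the
Pearson correlation between the rho vectors of two correlation tables over
their shared testable pairs — high values indicate the network is not
driven by the stratifying factor (sex, retest interval, subsampling).

## Community detection

The dissimilarity is d = 1 − |rho|, so strongly correlated changes of
either sign are close.  Agglomeration uses average linkage by default (the
conventional companion of correlation-based distances; complete and single
are selectable) via scipy, which is deterministic for a given input.
Untestable pairs enter the distance matrix at the maximal distance 1
(rho = 0) with a warning, so the matrix is always complete.

Correlation dendrograms rarely admit one clean cut height, so the tree is
decomposed adaptively:

1. **Static stage.** Merges above `h_min + cut_height_fraction · (h_max −
   h_min)` (default fraction 0.99 of the merge-height *range*) are removed;
   the surviving subtrees are candidate branches.  Using the range rather
   than the absolute maximum height makes the degenerate tree (all merges
   at one height) a single cluster, which is the only defensible answer for
   a homogeneous distance matrix.
2. **Gap stage.** A branch whose root merge sits far above everything
   inside it — gap to the highest internal child merge exceeding
   `split_gap_fraction` (default 0.5) of the root height — is split into
   its children, recursively.  The gap is measured against the root height
   rather than the branch's internal height range because for a tight,
   homogeneous branch the internal range is pure noise scale and a
   range-relative rule oversplits clean clusters.
3. **Dissolution.** Candidates smaller than `min_cluster_size` (default 3)
   are dissolved: each member joins the nearest retained cluster by average
   distance provided that distance is within the cluster's top merge
   height, otherwise it is left unassigned (label 0).

Cluster labels are arbitrary positive integers; partitions should be
compared up to relabeling (adjusted Rand index).  This is an adaptive
branch decomposition in the spirit of dynamic dendrogram-cutting methods;
exact label-for-label agreement with any particular reference
implementation is not claimed — correctness is established by
planted-structure recovery and by agreement with a static cut whenever a
static cut is clean.

## Out-of-range change analysis

Each biomarker has one clinical direction of risk and a strict threshold
(sex-specific where conventional cutoffs differ; see
`data/range_rules.yaml`, 17 biomarkers with Quest-style cutoffs, e.g.
vitamin D < 30, LDL > 130, ALT > 46 male / > 29 female).  A participant is
out-of-range when the baseline is strictly beyond the threshold; boundary
values are in range because the cutoffs are printed as strict inequalities.
Biomarkers flagged `sex_stratified` (testosterone, free testosterone) are
analysed per sex; participants of unknown sex are excluded only from
sex-specific rules and retained everywhere else.

Vitamin D is designated seasonal: pooled baseline and follow-up values are
regressed on a binary summer indicator (June–September), and the estimated
coefficient is subtracted from summer-dated values before change testing
(both endpoints independently, so a both-summer pair keeps its delta).  The
shipped default offset for simulation presets is 2.5 in the biomarker's
native units.  The change table reports medians of the values used for
testing alongside raw (unadjusted) medians, since the adjustment is a
testing device rather than a correction of the measurements.

Changes are tested with the two-sided Wilcoxon signed-rank test.  Zero
differences are dropped before ranking (the classical treatment; Pratt's
method is available).  For effective n ≤ 25 the p-value is exact, computed
by convolving the signed-rank-sum distribution on a doubled-rank integer
grid — this stays exact under ties, which enumeration-based checks confirm.
Larger samples use the normal approximation with continuity and tie
correction.  All-zero differences return p = 1, flagged as "no change".
Only biomarkers (or sex strata) with at least `min_group` (default 20)
out-of-range participants are tabulated; p-values are deliberately not
multiplicity-corrected, and omitted groups are logged.  BMI change between
enrollment and follow-up uses the classical paired t-test.

No adjustment for regression to the mean is attempted: selecting
participants on extreme baselines guarantees some drift back toward the
population mean on retest, so the change table is descriptive, not causal.

## Intervention association

For a focal biomarker (vitamin D and LDL by default), every participant
with a delta is classified improved (any nonzero change opposite the
direction of risk — a delta of exactly 0 is not improvement) or not, over
the entire population, not only the out-of-range subset.  Participants with
no recorded choices count as non-choosers of every intervention.  For each
of the `top_k` (default 10) most frequently chosen interventions (ties
broken lexicographically) the improved × chose 2×2 table is tested with the
Pearson chi-square statistic (no continuity correction).

The Monte-Carlo p-value simulates the margins-fixed null: with both margins
fixed, the top-left count is hypergeometric, and `p_mc = (1 + #{simulated ≥
observed}) / (B + 1)` with B = 10,000 by default and a mandatory explicit
seed.  Because the statistic at fixed margins is monotone in the integer
|n11·N − r1·c1|, the ≥ comparison is done on that integer, so ties at the
observed value are counted exactly rather than at the mercy of float
rounding.  The asymptotic chi-square(1) p is reported alongside.  The two
agree closely wherever the asymptotic approximation is trustworthy —
tail p-values, or large tables — but for mid-range p the exact conditional
null is discrete and the atom at the observed table contributes a
difference of order φ(z)/σ(n11), which can exceed 0.01 for moderate
margins; this is a property of the chi-square approximation, not of the
simulation.  BH correction runs across the scanned family, with nominal
(uncorrected p_mc < 0.05) flags reported separately.

## Synthetic cohorts

The generator samples, per participant: a panel (one of several biomarker
subsets with configured weights); independent normal baselines per
biomarker; a delta vector from a multivariate normal whose correlation
matrix is block-structured (`r_within` inside each block, `r_between`
elsewhere; validated positive semi-definite at construction, before any
sampling); a baseline date with a configurable summer probability (default
0.33, membership derived from the actual date); a follow-up date at a
log-normal gap (median 150 days, log-SD 0.5, emulating the right-skewed
retest intervals of subscription cohorts); and intervention choices from a
logistic model whose log-odds are boosted (default +1) when the targeted
biomarker is out of range at baseline.  Follow-up = baseline + delta +
planted intervention shifts + seasonal offset when the draw date is in
summer (baseline dates get the offset analogously).  Out-of-range
enrichment comes from placing preset baseline means near the clinical
thresholds, not from truncation, keeping every marginal normal.

Because deltas are multivariate normal, the population Spearman correlation
implied by a planted Pearson r is (6/π)·asin(r/2) — e.g. 0.683 for r = 0.7
— and all recovery checks compare against this transformed value, not r.

The `paperlike` preset reflects the study conditions this package targets:
40 biomarkers, ~1000 participants, 7 overlapping panels, 10 blocks of
plausibly co-regulated biomarkers (Pearson 0.3–0.55 within, 0 between), a
+2.5 summer offset on vitamin D, and ten interventions, four with planted
shifts (vitamin D supplement +8 on vitamin D; oatmeal −6, green tea −4,
dairy −2 on LDL — sized so the strong effect is detectable at n ≈ 300
uptake-adjusted, while the weak ones sit in the low-power regime) and six
null.  The `tiny` preset (6 biomarkers, 50 participants) runs the whole
pipeline in seconds and backs the demo data and smoke tests.

What the generator does *not* emulate: non-normal marginals (real CK or
hsCRP are heavy-tailed), baseline-dependent deltas (hence no regression to
the mean), drop-out correlated with health status, adherence, assay
batch effects, or more than two draws per participant.  Passing the
recovery and calibration tests therefore demonstrates that the estimators
are correct under the stated model, not that real cohorts satisfy the
model.

## Numerical conventions and degenerate inputs

- Exactly monotone rank vectors snap to rho = ±1 with p = 0.
- BH on an empty family returns an empty vector; p-values outside [0, 1]
  are rejected.
- `correlate_all` requires ≥ 2 biomarker columns; a fully-untestable matrix
  yields an empty entry table.
- Constant reference samples and one-season seasonal data are refused with
  explicit errors rather than producing degenerate limits or offsets.
- Zero-margin 2×2 tables are untestable; zero-variance paired differences
  make the t-test degenerate.
- All simulation entry points take a single integer seed; identical config
  plus seed reproduces byte-identical cohorts and pipeline artifacts.

## Problem sizes used in the test and acceptance suites

Simulation studies in the shipped suites use: 100 replicates at n = 2000
for seasonal-offset recovery; 50 replicate cohorts at n = 1000 with 40
biomarkers for null network calibration; 50 replicates of 4 × 5-biomarker
blocks at n = 1000 for structure recovery; 5000 replicates at n = 100 for
Wilcoxon level checks; and 50 replicates at n = 2000 for intervention
detection with 20-test null families.  These sizes give Monte-Carlo
standard errors comfortably below the asserted tolerances while keeping a
full run in the low minutes on one core.
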