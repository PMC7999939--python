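# Methods

This note documents the statistical procedures, the synthetic-data model, the
numerical choices, and the design decisions taken where the underlying
procedure left room for interpretation.

## Study design being modelled

One embryo transfer (ET) is the sample unit. It links three measurements —
a spent culture-medium (CM) sample from a 24 h single-embryo culture
(Day-6 → Day-7), and recipient plasma drawn on Day-0 and Day-7 of the
synchronisation cycle — to nested binary pregnancy outcomes at gestational
Day-40, Day-62 and birth (birth ⇒ Day-62 ⇒ Day-40). Discovery data are
semi-quantitative internal-standard (IS) response ratios from GC-qTOF;
validation data are absolute concentrations from targeted quantification.
Recipients come from two breeds analysed as blocks (Asturiana de los Valles,
a beef breed, and Holstein, dairy) plus crossbreds, which are excluded from
the plasma blocks. Embryos are either morulae or early blastocysts at Day-6;
this stage is a controlled, fixed factor used to stratify the pair scores.

## Univariate screen

Per metabolite and endpoint, an open-vs-pregnant comparison with a normality
gate: Shapiro–Wilk at α = 0.05 within each outcome group (Shapiro–Wilk is
location/scale-invariant, so centring on the group mean is implicit); one-way
ANOVA if both groups pass, Kruskal–Wallis otherwise. The gate α and the
choice of per-group testing are configurable. Fixed-effect checks for bull
breed and Day-6 stage apply the same chosen test across those factor levels,
one factor at a time (no two-way model: the factors are reported per-factor
in the source tables, and at N = 36 an interaction model would be
overparameterised).

Multiplicity control is Bonferroni by default across the metabolite family
of one compartment/block/endpoint, with Benjamini–Hochberg available. A
metabolite is a *candidate* when raw p < α and adjusted p < α.

Fold change is log2(mean(open)/mean(pregnant)) — positive when open
recipients carry more. The fold-change values printed in the source tables
do not follow from log2 or ln of the printed group-mean ratios and their
generating formula is not documented; this package reports its own log2
definition and makes no attempt to reverse-engineer the printed numbers.

Gross outliers are removed before testing: a value is dropped when it exceeds
`threshold_fold` (default 100) times the mean of the remaining values,
evaluated simultaneously for all samples so two mutually-supporting extremes
below the threshold both survive. The one documented deletion in the source
study was at 1200× the mean; 100 is deliberately more conservative while
still only firing on data-entry-scale anomalies. Every removal is logged.
Missing values are dropped pairwise per metabolite; a metabolite is skipped
(with a logged warning) when any group falls below 3 observations.

## ROC single-biomarker discovery

AUC uses the Mann–Whitney rank formulation, ties counted ½, with
orientation auto-detected per metabolite (AUC ≥ 0.5 always; `pregnant_high`
vs `pregnant_low` recorded). The operating cutoff is chosen among midpoints
of adjacent distinct values plus ±∞ as the point closest (Euclidean distance
in (sensitivity, specificity) space) to the perfect-classifier corner; ties
break by maximal Youden J, then by the lower threshold. The source figures
describe the cutoff only as "closest to the left-hand corner" of the ROC
plot; the standard closest-to-(0,1) criterion on FPR/TPR axes is the reading
implemented. Confidence intervals are a stratified percentile bootstrap
(B = 1000 by default, seeded; resampling within class so resamples are never
single-class); the percentile interval is clipped to contain the point
estimate. The discovery t-test is Welch's on untransformed concentrations
(pooled-variance optional). Selection: AUC > 0.650 and t-test p < 0.05.

## Boolean pair F1

The combined-biomarker procedure:

1. *Pregnant range* — inclusive [min, max] of the pregnant group's
   concentrations in the cohort being scored. A percentile-trimmed variant is
   not provided as a default because the range is the defining primitive;
   outlier removal upstream already guards the endpoints.
2. *Boolean call* — sample is true iff its value lies inside the range,
   boundaries inclusive on both ends; a missing measurement gives a missing
   call and excludes the sample from pair scoring.
3. *OR combination* — the pair's call is the element-wise disjunction of the
   CM call and the plasma call (truth table F·F=F, T·F=T, F·T=T, T·T=T),
   samples inner-joined on ET id.
4. *Confusion and F1* — pregnancy is the positive class; TP = pregnant and
   called true, TN = open and called false; F1 = 2TP/(2TP+FP+FN), printed to
   three decimals with half-up rounding.
5. *Significance* — stratified 2×2 chi-square on calls × outcome:
   χ² = (|Σᵢ(aᵢ − Eᵢ)| − ½)² / ΣᵢVᵢ with aᵢ the TP cell and Eᵢ, Vᵢ from the
   stratum margins. The Cochran variance r₁r₂c₁c₂/n³ is used rather than the
   hypergeometric r₁r₂c₁c₂/(n²(n−1)): the two differ by a factor (n−1)/n per
   stratum (negligible at n = 13–36), and the Cochran form makes a single
   stratum reduce *exactly* to the Yates-corrected chi-square, which keeps
   the aggregate and stratified modes on one consistent scale. The continuity
   correction is on by default and toggleable. Strata with a zero margin are
   skipped and logged; if all strata are degenerate (e.g. every sample called
   true) the pair's F1 is still reported but its p is undefined (NaN).
6. *Modes* — aggregate (one stratum, the pooled cohort) or stratified by
   Day-6 stage (blastocyst/morula), where pregnant ranges are re-derived per
   stratum — the stage-specific concentration ranges are the stated reason
   the stratified score can beat the aggregate one — F1 comes from the pooled
   confusion counts, and the chi-square runs across the two strata. A
   shared-range variant can be obtained by passing aggregate-derived ranges
   through the frozen-range scorer.
7. *ND rule* — a pair is "not determined" when its combined correct-call
   count (TP+TN) is lower than the larger solo correct-call count of its two
   members, each computed with the same stratification. ND pairs keep their
   internal scores for auditing but the report withholds F1 and p.

Because OR-combination can only add true calls, a pair's recall never drops
below either member's, but its precision usually does. When one member is a
near-perfect single biomarker, the pair almost always trips the ND rule —
visible in the worked example and in the validation reports on synthetic
data. The procedure rewards *complementary moderate* biomarkers, not
redundant strong ones.

Ranking in `score_all_pairs` is by F1 descending, then p ascending; the ND
flag does not affect rank, only reporting.

## Validation

Selected pairs are re-scored on an independent cohort. Default policy
`refit_in_validation` re-derives pregnant ranges within the validation
cohort, making the score invariant to any positive rescaling of the
validation matrix — required because discovery units (dimensionless IS
ratios) and validation units (absolute concentrations) are incommensurable.
`frozen_from_discovery` applies the stored numeric ranges verbatim and
refuses to run across different units. Under the frozen policy the ND rule
is not applied (solo ranges are not part of the stored pair state). Both
aggregate and stage-stratified modes are reported per pair, with ND decided
per mode independently. A configurable below-LOD filter excludes metabolites
with more than 50% of validation values under a declared detection limit
(the mechanism behind dropping an embryo metabolite measured near the
detection limit).

## Synthetic cohort generator

The generator reproduces the design so the pipeline is testable without the
non-public study data. What it emulates:

* 36 ETs, breeds 13/17/6 (AV/Holstein/cross), bull breed random AV/Holstein,
  Day-6 stage Bernoulli(0.5) morula vs early blastocyst.
* Outcomes as a Markov chain D40 → D62 → birth with default rates 0.61,
  0.95, 0.90 — chosen so the expected endpoint denominators (≈22/36 at
  Day-40, ≈21 at Day-62, ≈19 at birth) match the group sizes the candidate
  tables report, giving roughly balanced open/pregnant groups.
* Panels of 37 CM and 71 plasma metabolites (the two plasma days share one
  panel and per-metabolite baselines); one uncollected Day-0 plasma sample
  (row dropped, id logged).
* Concentrations are lognormal: per-metabolite log-locations drawn once per
  panel from Normal(6, 1) (units arbitrary), sample noise Gaussian on the
  natural-log scale with σ = 0.5. Concentrations are positive and
  heavy-tailed like IS ratios; no distributional model is documented for the
  real data, so lognormal is a modelling choice.
* Planted effects: an entry (metabolite, compartment, endpoint, log2FC,
  optional breed restriction) shifts the log-mean by ±log2FC·ln2/2 for
  open/pregnant samples at that endpoint, so the expected open−pregnant
  difference of log2 concentrations equals log2FC exactly. With the default
  σ the standardized difference for log2FC = 2 is 2.77, i.e. a true AUC of
  ≈0.975 — strong enough that the end-to-end recovery benchmarks are about
  the pipeline, not about borderline power.
* Optional recipient-breed separation confined to Day-0 plasma (AV up,
  Holstein down on the log scale), mirroring where breed structure was
  observed; off by default.
* An optional low-rank correlation term among metabolites (rank and strength
  knobs), off by default: no within-cohort correlation structure is
  documented, so independence is the default and the knob is uncalibrated.
* The validation generator fixes breed to Holstein (default N = 19), draws
  from a separate named seed substream (independent of the discovery cohort
  under the same root seed), keeps the effect structure, and flags absolute
  units with a fixed calibration rescaling (default ×0.25) that changes
  numeric scale only.

Randomness is organised as named substreams off one root seed (records, each
matrix, missingness), so enlarging one panel does not perturb anything else,
and identical config + seed reproduces tables bitwise.

What the generator does **not** emulate: metabolite–metabolite correlation
calibrated to real plasma/CM, batch and instrument drift, censoring at the
detection limit, non-lognormal tails, or any dependence of outcome on breed
or stage beyond the planted effects. Passing tests on synthetic cohorts
therefore demonstrate that the *procedures* are implemented and calibrated
correctly (type-I error, effect recovery, selection bias), not that the
study's specific biomarkers would replicate.

## Pipeline and benchmarks

Discovery analyses CM on the aggregate cohort and plasma within breed
(crossbreds excluded, count logged); endpoints are analysed independently
(nesting is a data invariant, not a modelling constraint). Pair scoring runs
within breed using ROC-selected candidates; the stratified mode is attempted
only for blocks of at least 14 ETs (the smaller beef-breed block cannot
populate both stage strata reliably). Every run writes a manifest with the
seed and a SHA-256 hash of the canonical config; outputs are TSV plus logs,
and reruns are byte-identical.

The benchmark quantifies two honesty checks at the study's dimensions
(200 replicates for null runs, 100 for planted runs, sizes chosen to keep a
full benchmark under a couple of minutes on one CPU):

* **Null calibration** — with no planted effects, the univariate screen's
  pooled per-metabolite rejection rate at p < 0.05 sits inside the exact
  binomial 95% band around 5%, and the Bonferroni family-wise error stays at
  or below its band.
* **Selection inflation** — the best of ~2600 pair chi-squares under a global
  null is significant far more often than 5% (≈10% even with the continuity
  correction and the many degenerate all-true pairs), and the maximum pair F1
  distribution is reported. This inflation is a property of the published
  procedure (no multiplicity control is applied over the pair search) and is
  reported rather than corrected, because correcting it would change the
  method being implemented. The validation module's generalization gap —
  mean out-of-sample F1 of the discovery-best pair below its discovery
  value — is the complementary demonstration.

## Numerical choices and degenerate inputs

* Cutoff search uses midpoints of adjacent distinct values plus ±∞; corner
  distances and Youden J are rounded to 12 decimals before tie comparison to
  avoid float-noise tie inversions.
* F1 printed values use decimal half-up rounding to 3 places (0.8125 → 0.813).
* Constant metabolite vectors raise an insufficient-variance error; a group
  constant within one group routes to the rank test.
* Bootstrap with n_boot < 100 logs a warning; benchmark runs with fewer than
  50 replicates log a warning.
* All-true (or all-false) combined calls leave the chi-square undefined; the
  pair is reported with F1 and a NaN p rather than being silently dropped.
* Seeds are kept below 2³¹ everywhere they are derived.

## Known limitations

* The printed fold-change convention of the source tables is not reproduced
  (formula undocumented); both this package's log2 definition and an
  externally supplied value can be carried in reports.
* Whether the per-class correct counts in the source tables were computed at
  the closest-to-corner cutoff or a Youden cutoff is unstated;
  closest-to-corner is implemented.
* The aggregate-mode pregnant ranges are derived within the breed block being
  scored (matching the breed-separated plasma analysis); a whole-cohort
  variant would give different aggregate scores.
* Multivariate exploration (PLS-DA/sPLS-DA/SVM/RF panels) is out of scope:
  those are off-the-shelf algorithms run in a third-party platform, not part
  of the procedure implemented here.
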