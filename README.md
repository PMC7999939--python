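# embryomet

Combined embryo/recipient metabolite biomarker discovery for predicting
pregnancy outcomes of bovine embryo transfer (ET).

## The problem

When a single in vitro-produced, vitrified/warmed embryo is transferred to a
recipient heifer, whether the pregnancy reaches term depends on *both* sides:
the embryo and the recipient. Metabolites quantified non-invasively — in the
spent culture medium (CM) of a 24 h single-embryo culture, and in recipient
plasma drawn at Day-0 and Day-7 of the synchronisation cycle — each carry part
of the signal. `embryomet` implements a discovery pipeline that screens both
compartments separately and then combines one embryo metabolite with one
recipient metabolite into a single rule-based predictor, scored at three
nested pregnancy endpoints (gestational Day-40, Day-62, birth).

The pipeline stages are:

1. **Univariate screening** (`embryomet.screen`) — per metabolite, a
   Shapiro–Wilk normality gate routes an open-vs-pregnant comparison to
   one-way ANOVA or Kruskal–Wallis; Bonferroni (or Benjamini–Hochberg)
   multiplicity control; log2 fold changes open/pregnant; per-factor checks of
   bull breed and Day-6 embryonic stage; gross-outlier removal with logging.
2. **ROC biomarker discovery** (`embryomet.roc`) — rank-based AUC with
   auto-detected orientation, stratified percentile-bootstrap confidence
   interval, closest-to-corner optimal cutoff, per-class correct counts, and
   the selection rule AUC > 0.650 with Welch t-test p < 0.05.
3. **Boolean pair scoring** (`embryomet.pairs`) — the combined-biomarker
   procedure. For each metabolite, a sample is called *true* when its
   concentration lies inside the inclusive [min, max] range of the pregnant
   group. Calls from one CM metabolite and one plasma metabolite are
   OR-combined and tallied against the outcome; the pair is scored by

   F1 = 2·TP / (2·TP + FP + FN),

   with pregnancy as the positive class, either on the pooled cohort
   ("aggregate") or re-deriving ranges within each Day-6 embryonic stage
   ("stratified B/M"). Significance is a stratified 2×2 chi-square
   (Cochran–Mantel–Haenszel family, 0.5 continuity correction; one stratum
   reduces exactly to the Yates-corrected chi-square). A pair whose combined
   correct-call count is below the better of its members alone is reported
   **ND** (not determined).
4. **Validation** (`embryomet.validate`) — selected pairs are re-scored on an
   independent Holstein cohort (targeted, absolute-quantification data), with
   pregnant ranges refit within the cohort by default (numeric cutoffs cannot
   transfer across measurement units; a frozen-range policy exists and
   refuses cross-unit use).
5. **Synthetic cohorts** (`embryomet.simulate`) — the study's raw data are not
   public, so a generator reproduces the design: 36 ETs (13 Asturiana de los
   Valles, 17 Holstein, 6 crossbred), a 36×37 CM matrix, 35×71 / 36×71 plasma
   matrices (one Day-0 sample uncollected), nested Markov outcomes, lognormal
   concentrations with plantable log2 fold-change effects, and a 19-ET
   Holstein validation cohort in absolute units.
6. **Driver and CLI** (`embryomet.pipeline`, `embryomet.cli`) — breed-block
   orchestration (CM analysed on the aggregate cohort, plasma within breed,
   crossbreds excluded and logged), determinism by seed, manifest files with
   config hashes, and null/power benchmarks.

## Worked example

Simulate a discovery cohort with one planted embryo biomarker and one planted
Day-0 plasma biomarker (log2 fold change 2 between open and pregnant at
birth), run discovery, and validate:

```python
from embryomet import CohortConfig, Effect
from embryomet.pipeline import RunConfig, run_discovery, run_validation, roc_table

cfg = RunConfig(
    cohort=CohortConfig(
        seed=2,
        effect_table=(
            Effect("CM_M01", "CM", "birth", 2.0),
            Effect("PL_M01", "plasma_d0", "birth", 2.0),
        ),
    ),
    endpoints=("birth",),
    n_boot=200,
)
bundle = run_discovery(cfg)
table = roc_table(bundle.roc[("CM", "aggregate", "birth")])
print(table[table.selected].round(3).to_string(index=False))
```

```
metabolite endpoint   auc            ci  orientation  cutoff  p_ttest correct_open correct_pregnant  selected
    CM_M01    birth 0.997 [0.991-1.000] pregnant_low 149.016    0.000        17/17            18/19      True
    CM_M15    birth 0.709 [0.517-0.854] pregnant_low 329.701    0.011        11/17            14/19      True
    CM_M25    birth 0.690 [0.501-0.873] pregnant_low 201.885    0.050        12/17            13/19      True
```

The planted metabolite `CM_M01` is recovered with AUC 0.997 (pregnant
concentrations lower than open, as planted); the cutoff classifies 17/17 open
and 18/19 pregnant ETs correctly. Two noise metabolites also clear the
selection threshold — exactly the false-discovery behaviour the benchmark
quantifies. Validating the best pairs on an independent 19-ET Holstein cohort:

```python
report = run_validation(cfg, bundle)
print(report.table[["cm_metabolite", "plasma_metabolite", "mode",
                    "true_count", "f1", "p", "nd"]].head(4).to_string(index=False))
```

```
cm_metabolite plasma_metabolite           mode true_count f1 p nd
       CM_M01            PL_M01 stratified_b_m
       CM_M01            PL_M01      aggregate      17/19      ND
       CM_M01            PL_M04 stratified_b_m
       CM_M01            PL_M04      aggregate      12/19      ND
```

Here every pair is reported ND: with a near-perfect single CM biomarker, the
OR-combination can only add false positives, so the pair identifies fewer
correct calls (17/19) than the CM metabolite alone (18/19) and the report
withholds F1 and p. This is the procedure's built-in guard against pairs that
are worse than their parts; pairs of two moderate biomarkers, as in the
original study, escape it. Blank rows mark pairs whose stratified 2×2 table
was degenerate (every sample called true), where no significance is defined.

The same run from a shell:

```sh
embryomet validate --seed 2 --out runs/demo
embryomet benchmark --scenario null --replicates 200 --seed 1 --out runs/null.json
```

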