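"""End-to-end orchestration: simulate -> screen -> ROC -> pairs -> validate.

The discovery driver follows the breed-block strategy of the study design:
culture-medium metabolites are analysed on the aggregate cohort (embryo
biomarkers are meant to generalise across recipient breeds), while recipient
plasma is analysed within breed (AV and Holstein separately; crossbred
recipients are excluded from the plasma blocks and the exclusion is logged).
Pair scoring runs within breed; the Day-6-stage-stratified mode is attempted
only where the breed block is large enough to populate both strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io as emio
from .datatypes import (
    Cohort,
    CohortConfig,
    Effect,
    MetaboliteMatrix,
    PairF1Result,
    RocResult,
    records_frame,
)
from .errors import (
    ConfigurationError,
    DegenerateLabelsError,
    InsufficientDataError,
    UndefinedTestError,
)
from .pairs import AGGREGATE, STRATIFIED, pairs_table, score_all_pairs
from .roc import evaluate_metabolite, format_counts
from .screen import candidates_table, screen_matrix
from .simulate import generate_cohort, generate_validation_cohort
from .validate import REFIT, ValidationReport, validate_pairs

logger = logging.getLogger(__name__)

PLASMA_BREEDS = ("AV", "Holstein")


@dataclass
class RunConfig:
    """Settings for one end-to-end run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    endpoints: Sequence[str] = ("d40", "d62", "birth")
    plasma_days: Sequence[str] = ("d0", "d7")
    alpha: float = 0.05
    auc_threshold: float = 0.650
    adjust_method: str = "bonferroni"
    outlier_threshold: float = 100.0
    stratify_min_n: int = 14
    n_boot: int = 200
    validation_n: int = 19

    def validate(self) -> None:
        if not self.endpoints:
            raise ConfigurationError("endpoints: must be non-empty")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha: must lie in (0, 1)")
        if not 0 < self.auc_threshold < 1:
            raise ConfigurationError("auc_threshold: must lie in (0, 1)")
        self.cohort.validate()


@dataclass
class DiscoveryBundle:
    """Artifacts of one discovery run."""

    cohort: Cohort
    candidates: dict
    roc: dict
    pairs: dict
    log: list[str]
    config_hash: str


def _roc_block(
    matrix: MetaboliteMatrix,
    outcomes: pd.Series,
    *,
    endpoint: str,
    config: RunConfig,
    seed_offset: int,
) -> list[RocResult]:
    results = []
    for j, name in enumerate(matrix.metabolite_names):
        vals = matrix.metabolite(name)
        idx = vals.index.intersection(outcomes.index)
        try:
            res = evaluate_metabolite(
                vals.loc[idx].to_numpy(dtype=float),
                outcomes.loc[idx].astype(bool).to_numpy(),
                metabolite=name,
                endpoint=endpoint,
                n_boot=config.n_boot,
                seed=(seed_offset + j) % 2**31,
                auc_threshold=config.auc_threshold,
                alpha=config.alpha,
            )
        except (DegenerateLabelsError, InsufficientDataError) as exc:
            logger.info("roc: skipped %s at %s (%s)", name, endpoint, exc)
            continue
        results.append(res)
    return results


def roc_table(results: Sequence[RocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metabolite": [r.metabolite for r in results],
            "endpoint": [r.endpoint for r in results],
            "auc": [r.auc for r in results],
            "ci": [f"[{r.ci_low:.3f}-{r.ci_high:.3f}]" for r in results],
            "orientation": [r.orientation for r in results],
            "cutoff": [r.cutoff for r in results],
            "p_ttest": [r.p_ttest for r in results],
            "correct_open": [format_counts(r.correct_open) for r in results],
            "correct_pregnant": [format_counts(r.correct_pregnant) for r in results],
            "selected": [r.selected for r in results],
        }
    )


def run_discovery(config: RunConfig, outdir: str | Path | None = None) -> DiscoveryBundle:
    """Run the full discovery pipeline on a simulated cohort.

    Deterministic given ``config.cohort.seed``. Returns candidate screens,
    ROC biomarker tables and scored pairs per breed block and endpoint.
    """
    config.validate()
    cohort = generate_cohort(config.cohort)
    frame = records_frame(cohort.records)
    log: list[str] = list(cohort.log)

    n_cross = int((frame["breed"] == "cross").sum())
    if n_cross:
        log.append(f"plasma breed blocks: excluded {n_cross} crossbred recipient(s)")

    covariates = frame[["bull_breed", "day6_stage"]]
    candidates: dict = {}
    rocs: dict = {}
    pairs: dict = {}

    for endpoint in config.endpoints:
        outcomes = cohort.outcomes(endpoint)

        # CM: aggregate cohort.
        cm_key = ("CM", "aggregate", endpoint)
        candidates[cm_key] = screen_matrix(
            cohort.cm,
            outcomes,
            covariates,
            endpoint=endpoint,
            alpha=config.alpha,
            method=config.adjust_method,
            outlier_threshold=config.outlier_threshold,
        )
        rocs[cm_key] = _roc_block(
            cohort.cm, outcomes, endpoint=endpoint, config=config, seed_offset=0
        )
        cm_selected = [r.metabolite for r in rocs[cm_key] if r.selected]

        for breed in PLASMA_BREEDS:
            breed_ids = frame.index[frame["breed"] == breed]
            plasma_selected: dict[str, list[str]] = {}
            for day in config.plasma_days:
                matrix = cohort.matrix("plasma_" + day)
                sub = MetaboliteMatrix(
                    compartment=matrix.compartment,
                    data=matrix.data.loc[matrix.data.index.intersection(breed_ids)],
                    units=matrix.units,
                )
                key = (f"plasma_{day}", breed, endpoint)
                candidates[key] = screen_matrix(
                    sub,
                    outcomes.loc[sub.data.index],
                    covariates.loc[sub.data.index],
                    endpoint=endpoint,
                    alpha=config.alpha,
                    method=config.adjust_method,
                    outlier_threshold=config.outlier_threshold,
                )
                rocs[key] = _roc_block(
                    sub,
                    outcomes.loc[sub.data.index],
                    endpoint=endpoint,
                    config=config,
                    seed_offset=1000,
                )
                plasma_selected[day] = [r.metabolite for r in rocs[key] if r.selected]

            plasma_matrices = {
                day: cohort.matrix("plasma_" + day) for day in config.plasma_days
            }
            modes = [AGGREGATE]
            if len(breed_ids) >= config.stratify_min_n:
                modes.append(STRATIFIED)
            for mode in modes:
                try:
                    scored = score_all_pairs(
                        cohort.cm,
                        plasma_matrices,
                        outcomes.loc[breed_ids],
                        stages=cohort.stages(),
                        mode=mode,
                        endpoint=endpoint,
                        cm_candidates=cm_selected,
                        plasma_candidates=plasma_selected,
                        sample_filter=breed_ids,
                    )
                except (InsufficientDataError, UndefinedTestError) as exc:
                    log.append(f"pairs {breed}/{endpoint}/{mode}: {exc}")
                    scored = []
                pairs[(breed, endpoint, mode)] = scored
                if not scored:
                    log.append(f"pairs {breed}/{endpoint}/{mode}: no scorable pairs")

    bundle = DiscoveryBundle(
        cohort=cohort,
        candidates=candidates,
        roc=rocs,
        pairs=pairs,
        log=log,
        config_hash=emio.config_hash(config),
    )
    if outdir is not None:
        _write_discovery(bundle, config, Path(outdir))
    return bundle


def _write_discovery(bundle: DiscoveryBundle, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cand_frames = []
    for (compartment, block, endpoint), results in bundle.candidates.items():
        t = candidates_table(results)
        t.insert(1, "block", block)
        cand_frames.append(t)
    if cand_frames:
        pd.concat(cand_frames, ignore_index=True).to_csv(
            outdir / "candidates.tsv", sep="\t", index=False
        )
    roc_frames = []
    for (compartment, block, endpoint), results in bundle.roc.items():
        t = roc_table(results)
        t.insert(1, "compartment", compartment)
        t.insert(2, "block", block)
        roc_frames.append(t)
    if roc_frames:
        pd.concat(roc_frames, ignore_index=True).to_csv(
            outdir / "biomarkers.tsv", sep="\t", index=False
        )
    pair_frames = []
    for (breed, endpoint, mode), results in bundle.pairs.items():
        t = pairs_table(results)
        t.insert(0, "breed", breed)
        pair_frames.append(t)
    if pair_frames:
        pd.concat(pair_frames, ignore_index=True).to_csv(
            outdir / "pairs.tsv", sep="\t", index=False
        )
    emio.write_cohort(bundle.cohort, outdir / "cohort")
    emio.write_manifest(outdir / "manifest.json", config.cohort.seed, config)
    (outdir / "run.log").write_text("\n".join(bundle.log) + "\n")


def select_validation_pairs(
    bundle: DiscoveryBundle,
    *,
    breed: str = "Holstein",
    endpoint: str = "birth",
    n_top: int = 6,
) -> list[PairF1Result]:
    """Best discovery pairs (unique metabolite combinations) for validation.

    Determinable (non-ND) pairs are preferred; if every scored pair is ND
    (common in aggregate mode, where OR-combination mostly adds false
    positives), the top pairs by F1 are taken regardless.
    """
    pool: list[PairF1Result] = []
    for mode in (STRATIFIED, AGGREGATE):
        pool.extend(bundle.pairs.get((breed, endpoint, mode), []))
    seen: set[tuple[str, str]] = set()
    selected = []
    for nd_ok in (False, True):
        for pair in sorted(pool, key=lambda r: (r.nd, -r.f1, r.p)):
            key = (pair.cm_metabolite, pair.plasma_metabolite)
            if key in seen or (pair.nd and not nd_ok):
                continue
            seen.add(key)
            selected.append(pair)
            if len(selected) >= n_top:
                return selected
    return selected


def run_validation(
    config: RunConfig,
    bundle: DiscoveryBundle,
    outdir: str | Path | None = None,
    *,
    endpoint: str = "birth",
    plasma_day: str = "d0",
    n_top: int = 6,
    range_policy: str = REFIT,
) -> ValidationReport:
    """Validate discovery-selected pairs on an independent Holstein cohort.

    Day-0 plasma is the default validation compartment (recipients can then
    be selected a week before transfer). An empty selected-pair list yields
    an empty report with a warning.
    """
    selected = select_validation_pairs(bundle, endpoint=endpoint, n_top=n_top)
    validation = generate_validation_cohort(
        config.cohort,
        tuple(config.cohort.effect_table),
        n_et=config.validation_n,
    )
    if not selected:
        logger.warning("run_validation: empty selected-pair list")
        report = ValidationReport(
            table=pd.DataFrame(),
            n=config.validation_n,
            breed="Holstein",
            plasma_day=plasma_day,
            log=["no pairs selected from discovery"],
        )
    else:
        report = validate_pairs(
            selected,
            validation,
            endpoint=endpoint,
            plasma_day=plasma_day,
            range_policy=range_policy,
        )
    report.log.append(f"discovery_config_hash: {bundle.config_hash}")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.table.to_csv(outdir / "validation.tsv", sep="\t", index=False)
        if not report.table.empty:
            report.to_wide().to_csv(outdir / "validation_wide.tsv", sep="\t", index=False)
        (outdir / "validation.log").write_text("\n".join(report.log) + "\n")
        emio.write_manifest(outdir / "validation_manifest.json", config.cohort.seed, config)
    return report


# ---------------------------------------------------------------------------
# Benchmark: null calibration / power / selection inflation
# ---------------------------------------------------------------------------


def _call_matrix(data: pd.DataFrame, pregnant: np.ndarray) -> np.ndarray:
    """Pregnant-range membership calls for every metabolite of a matrix."""
    vals = data.to_numpy(dtype=float)
    lo = vals[pregnant].min(axis=0)
    hi = vals[pregnant].max(axis=0)
    return (vals >= lo) & (vals <= hi)


def pair_stat_matrices(
    cm_calls: np.ndarray, plasma_calls: np.ndarray, pregnant: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised F1 and chi-square p for every CM x plasma pair.

    OR-combined calls are counted through the complement identity
    (a OR b is false iff both are false), giving all pairwise confusion
    tables from two matrix products.
    """
    preg = pregnant.astype(bool)
    n_preg, n_open = int(preg.sum()), int((~preg).sum())
    not_cm = (~cm_calls).astype(float)
    not_pl = (~plasma_calls).astype(float)
    tp = n_preg - not_cm[preg].T @ not_pl[preg]
    fp = n_open - not_cm[~preg].T @ not_pl[~preg]
    fn = n_preg - tp
    tn = n_open - fp
    f1 = 2 * tp / (2 * tp + fp + fn)

    n = n_preg + n_open
    r1, r2 = tp + fp, fn + tn
    c1, c2 = float(n_preg), float(n_open)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = np.abs(tp - r1 * c1 / n) - 0.5
        var = r1 * r2 * c1 * c2 / n**3
        chi2 = np.where(var > 0, np.maximum(num, 0.0) ** 2 / var, np.nan)
    p = sps.chi2.sf(chi2, df=1)
    return f1, p


def run_benchmark(
    config: RunConfig,
    *,
    scenario: str = "null",
    n_replicates: int = 100,
    endpoint: str = "birth",
    plasma_day: str = "d0",
    planted: tuple[str, str, float] | None = None,
    seed: int = 0,
) -> dict:
    """Characterise the procedure by simulation.

    ``scenario="null"`` reports the per-metabolite univariate rejection rate
    at alpha, the family-wise error after Bonferroni, and the selection
    inflation of the pair search (distribution of the maximum pair F1 and the
    frequency of a best-pair chi-square p < alpha across all pairs — expected
    to sit far above the nominal level, which is the point of reporting it).
    ``scenario="planted"`` plants an effect pair and reports detection and
    top-rank frequencies with binomial confidence intervals.
    """
    if n_replicates < 50:
        logger.warning("run_benchmark: %d replicates is low", n_replicates)
    base = config.cohort
    if scenario == "planted":
        cm_met, pl_met, log2fc = planted or ("CM_M01", "PL_M01", 2.0)
        effects = (
            Effect(cm_met, "CM", endpoint, log2fc),
            Effect(pl_met, "plasma_" + plasma_day, endpoint, log2fc),
        )
        base = replace(base, effect_table=effects)
    elif scenario == "null":
        base = replace(base, effect_table=())
    else:
        raise ConfigurationError(f"scenario: unknown value {scenario!r}")

    alpha = config.alpha
    reject = 0
    tests = 0
    fwer_hits = 0
    best_p_hits = 0
    max_f1s = []
    top_rank_hits = 0
    detect_hits = 0
    usable = 0
    from .screen import adjust_pvalues, choose_test  # local to avoid cycle noise
    from scipy.stats import f_oneway, kruskal

    for rep in range(n_replicates):
        rep_seed = (seed * 100003 + rep * 7919 + base.seed) % 2**31
        cohort = generate_cohort(replace(base, seed=rep_seed))
        outcomes = cohort.outcomes(endpoint).to_numpy()
        if outcomes.sum() < 2 or (~outcomes).sum() < 2:
            continue
        usable += 1
        cm_vals = cohort.cm.data.to_numpy(dtype=float)
        pl = cohort.matrix("plasma_" + plasma_day)
        pl_vals = pl.data.reindex(cohort.cm.data.index).to_numpy(dtype=float)
        pl_ok = np.isfinite(pl_vals).all(axis=1)

        if scenario == "null":
            pvals = []
            for j in range(cm_vals.shape[1]):
                v = cm_vals[:, j]
                test = choose_test(v, outcomes)
                if test == "anova":
                    p = f_oneway(v[~outcomes], v[outcomes]).pvalue
                else:
                    p = kruskal(v[~outcomes], v[outcomes]).pvalue
                pvals.append(float(p))
            pvals = np.asarray(pvals)
            reject += int((pvals < alpha).sum())
            tests += pvals.size
            fwer_hits += int((adjust_pvalues(pvals, "bonferroni") < alpha).any())

            cm_calls = _call_matrix(cohort.cm.data, outcomes)
            pl_calls = _call_matrix(
                pd.DataFrame(pl_vals[pl_ok], columns=pl.metabolite_names),
                outcomes[pl_ok],
            )
            f1, p = pair_stat_matrices(
                cm_calls[pl_ok], pl_calls, outcomes[pl_ok]
            )
            max_f1s.append(float(np.nanmax(f1)))
            finite_p = p[np.isfinite(p)]
            best_p_hits += int(finite_p.size > 0 and finite_p.min() < alpha)
        else:
            cm_idx = cohort.cm.metabolite_names.index(cm_met)
            pl_idx = pl.metabolite_names.index(pl_met)
            roc_cm = evaluate_metabolite(
                cm_vals[:, cm_idx], outcomes, compute_ci=False,
                auc_threshold=config.auc_threshold, alpha=alpha,
            )
            roc_pl = evaluate_metabolite(
                pl_vals[pl_ok, pl_idx], outcomes[pl_ok], compute_ci=False,
                auc_threshold=config.auc_threshold, alpha=alpha,
            )
            detect_hits += int(roc_cm.selected and roc_pl.selected)
            cm_calls = _call_matrix(cohort.cm.data, outcomes)
            pl_calls = _call_matrix(
                pd.DataFrame(pl_vals[pl_ok], columns=pl.metabolite_names),
                outcomes[pl_ok],
            )
            f1, p = pair_stat_matrices(cm_calls[pl_ok], pl_calls, outcomes[pl_ok])
            rank = np.lexsort((p.ravel(), -f1.ravel()))
            best_flat = rank[0]
            top_rank_hits += int(
                best_flat == cm_idx * f1.shape[1] + pl_idx
            )

    summary: dict = {"scenario": scenario, "n_replicates": usable, "seed": seed}
    if scenario == "null":
        rate = reject / tests if tests else float("nan")
        summary.update(
            {
                "per_metabolite_rejection_rate": rate,
                "n_tests": tests,
                "fwer_bonferroni": fwer_hits / usable if usable else float("nan"),
                "best_pair_p_lt_alpha_rate": best_p_hits / usable if usable else float("nan"),
                "max_pair_f1_median": float(np.median(max_f1s)) if max_f1s else float("nan"),
                "max_pair_f1_q90": float(np.quantile(max_f1s, 0.9)) if max_f1s else float("nan"),
            }
        )
    else:
        lo, hi = _binom_ci(top_rank_hits, usable)
        summary.update(
            {
                "planted_pair": planted,
                "top_rank_rate": top_rank_hits / usable if usable else float("nan"),
                "top_rank_ci95": (lo, hi),
                "both_members_selected_rate": detect_hits / usable if usable else float("nan"),
            }
        )
    return summary


def _binom_ci(k: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    res = sps.binomtest(k, n)
    ci = res.proportion_ci(confidence_level=0.95)
    return (float(ci.low), float(ci.high))
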