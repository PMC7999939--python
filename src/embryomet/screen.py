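"""Univariate candidate-metabolite screening.

Each metabolite is tested for an open-vs-pregnant concentration difference at
one pregnancy endpoint. A Shapiro-Wilk normality gate (per group, alpha 0.05)
routes the comparison to one-way ANOVA when both groups look normal and to
the Kruskal-Wallis rank test otherwise. Multiplicity is controlled across the
metabolite family (Bonferroni by default, Benjamini-Hochberg optionally); a
metabolite is flagged as a biomarker candidate when both its raw and adjusted
p-values fall below alpha. Fixed-effect checks (bull breed, Day-6 embryonic
stage) reuse the same test applied to those factors, reported per factor.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CandidateResult, MetaboliteMatrix
from .errors import (
    ConfigurationError,
    InsufficientDataError,
    InsufficientVarianceError,
    UndefinedFoldChangeError,
)

logger = logging.getLogger(__name__)

MIN_GROUP_N = 3


def remove_outliers(
    values: np.ndarray | pd.Series,
    threshold_fold: float = 100.0,
    sample_ids: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Drop gross single-sample outliers.

    A value is removed when it exceeds ``threshold_fold`` times the mean of
    the remaining values (evaluated simultaneously for all samples, so two
    mutually-supporting extremes each below the threshold survive). Removals
    are returned, never silent.
    """
    if threshold_fold <= 1:
        raise ConfigurationError("threshold_fold: must be > 1")
    if isinstance(values, pd.Series):
        if sample_ids is None:
            sample_ids = [str(i) for i in values.index]
        arr = values.to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(arr.size)]
    finite = np.isfinite(arr)
    keep = np.ones(arr.size, dtype=bool)
    total = np.nansum(arr)
    n_finite = finite.sum()
    for i in np.flatnonzero(finite):
        if n_finite < 2:
            break
        mean_others = (total - arr[i]) / (n_finite - 1)
        if mean_others > 0 and arr[i] > threshold_fold * mean_others:
            keep[i] = False
    removed = [sample_ids[i] for i in np.flatnonzero(~keep)]
    if removed:
        logger.info("remove_outliers: removed %s (>%sx mean)", removed, threshold_fold)
    return arr[keep], removed


def fold_change(open_values, pregnant_values) -> float:
    """log2 of the ratio of group means, open over pregnant.

    Positive when the open group's mean concentration is higher.
    """
    mo = float(np.nanmean(np.asarray(open_values, dtype=float)))
    mp = float(np.nanmean(np.asarray(pregnant_values, dtype=float)))
    if mo <= 0 or mp <= 0:
        raise UndefinedFoldChangeError(
            f"fold change undefined for non-positive group mean ({mo:g}, {mp:g})"
        )
    return math.log2(mo / mp)


def _split(values: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(open, pregnant) values; groups truthy = pregnant."""
    groups = np.asarray(groups, dtype=bool)
    values = np.asarray(values, dtype=float)
    return values[~groups], values[groups]


def choose_test(values, groups, alpha: float = 0.05) -> str:
    """Normality gate: "anova" iff Shapiro-Wilk is non-significant in both groups.

    Within-group residuals are the group values centred on their group mean;
    Shapiro-Wilk is location/scale invariant so the test is applied to the
    raw group values directly.
    """
    open_vals, preg_vals = _split(values, groups)
    open_vals = open_vals[np.isfinite(open_vals)]
    preg_vals = preg_vals[np.isfinite(preg_vals)]
    for name, grp in (("open", open_vals), ("pregnant", preg_vals)):
        if grp.size < MIN_GROUP_N:
            raise InsufficientDataError(
                f"group {name!r} has {grp.size} < {MIN_GROUP_N} observations"
            )
    if np.ptp(np.concatenate([open_vals, preg_vals])) == 0:
        raise InsufficientVarianceError("metabolite is constant across all samples")
    for grp in (open_vals, preg_vals):
        if np.ptp(grp) == 0:
            return "kruskal_wallis"  # degenerate within a group: not normal
        if stats.shapiro(grp).pvalue < alpha:
            return "kruskal_wallis"
    return "anova"


def _group_test(values: np.ndarray, labels: np.ndarray, test: str) -> float:
    """p-value comparing ``values`` across the levels of ``labels``."""
    levels = pd.unique(labels)
    samples = [values[labels == lev] for lev in levels]
    samples = [s[np.isfinite(s)] for s in samples]
    if len(samples) < 2 or any(s.size < MIN_GROUP_N for s in samples):
        return float("nan")
    if np.ptp(np.concatenate(samples)) == 0:
        return float("nan")
    if test == "anova":
        return float(stats.f_oneway(*samples).pvalue)
    return float(stats.kruskal(*samples).pvalue)


def test_metabolite(
    values,
    groups,
    covariates: Mapping[str, Sequence] | None = None,
    *,
    alpha: float = 0.05,
    outlier_threshold: float | None = 100.0,
    metabolite: str = "",
    compartment: str = "",
    endpoint: str = "",
    sample_ids: Sequence[str] | None = None,
) -> CandidateResult:
    """Univariate open-vs-pregnant test for one metabolite.

    Missing values are dropped pairwise; gross outliers (``outlier_threshold``
    times the mean of the other samples) are removed first and recorded. The
    family-level ``p_adjusted`` and ``candidate_flag`` are provisional here
    (single-metabolite family); :func:`screen_matrix` overwrites them.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=bool)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(values.size)]
    cov = {k: np.asarray(v) for k, v in (covariates or {}).items()}

    finite = np.isfinite(values)
    removed: list[str] = []
    if outlier_threshold is not None:
        _, removed = remove_outliers(
            values, threshold_fold=outlier_threshold, sample_ids=list(sample_ids)
        )
        keep_ids = set(sample_ids) - set(removed)
        finite &= np.array([sid in keep_ids for sid in sample_ids])

    vals = values[finite]
    grp = groups[finite]
    test = choose_test(vals, grp, alpha=alpha)
    open_vals, preg_vals = _split(vals, grp)
    if test == "anova":
        p = float(stats.f_oneway(open_vals, preg_vals).pvalue)
    else:
        p = float(stats.kruskal(open_vals, preg_vals).pvalue)

    p_bull = p_stage = float("nan")
    if cov:
        if "bull_breed" in cov:
            p_bull = _group_test(vals, cov["bull_breed"][finite], test)
        if "day6_stage" in cov:
            p_stage = _group_test(vals, cov["day6_stage"][finite], test)

    return CandidateResult(
        metabolite=metabolite,
        compartment=compartment,
        endpoint=endpoint,
        test_used=test,
        p_value=p,
        p_adjusted=p,
        mean_open=float(np.mean(open_vals)),
        se_open=float(stats.sem(open_vals)),
        mean_pregnant=float(np.mean(preg_vals)),
        se_pregnant=float(stats.sem(preg_vals)),
        fch=fold_change(open_vals, preg_vals),
        p_bull_breed=p_bull,
        p_day6_stage=p_stage,
        candidate_flag=bool(p < alpha),
        n_open=int(open_vals.size),
        n_pregnant=int(preg_vals.size),
        outliers_removed=removed,
    )


def adjust_pvalues(p_values, method: str = "bonferroni") -> np.ndarray:
    """Multiplicity-adjusted p-values (Bonferroni or Benjamini-Hochberg)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigurationError("p_values: entries must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ConfigurationError(f"method: unknown adjustment {method!r}")


def screen_matrix(
    matrix: MetaboliteMatrix,
    outcomes: pd.Series,
    covariates: pd.DataFrame | None = None,
    *,
    endpoint: str = "",
    alpha: float = 0.05,
    method: str = "bonferroni",
    outlier_threshold: float | None = 100.0,
) -> list[CandidateResult]:
    """Screen every metabolite of a matrix at one endpoint.

    Returns one :class:`CandidateResult` per testable metabolite, with
    family-level adjusted p-values and candidate flags
    (flag = raw p < alpha AND adjusted p < alpha). Metabolites that are
    all-missing, constant, or leave a group below 3 observations are skipped
    with a logged warning.
    """
    idx = matrix.data.index.intersection(outcomes.index)
    data = matrix.data.loc[idx]
    grp = outcomes.loc[idx].astype(bool).to_numpy()
    cov = None
    if covariates is not None:
        cov_frame = covariates.loc[idx]
        cov = {c: cov_frame[c].to_numpy() for c in cov_frame.columns}

    results: list[CandidateResult] = []
    for name in data.columns:
        try:
            res = test_metabolite(
                data[name].to_numpy(dtype=float),
                grp,
                covariates=cov,
                alpha=alpha,
                outlier_threshold=outlier_threshold,
                metabolite=name,
                compartment=matrix.compartment,
                endpoint=endpoint,
                sample_ids=[str(s) for s in idx],
            )
        except InsufficientDataError as exc:
            logger.warning("screen: skipped %s (%s)", name, exc)
            continue
        results.append(res)

    if results:
        adjusted = adjust_pvalues([r.p_value for r in results], method=method)
        for r, padj in zip(results, adjusted):
            r.p_adjusted = float(padj)
            r.candidate_flag = bool(r.p_value < alpha and padj < alpha)
    return results


def candidates_table(results: Sequence[CandidateResult]) -> pd.DataFrame:
    """Candidate-table layout: one row per metabolite x endpoint."""
    return pd.DataFrame(
        {
            "metabolite": [r.metabolite for r in results],
            "compartment": [r.compartment for r in results],
            "endpoint": [r.endpoint for r in results],
            "test": [r.test_used for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "open_mean_se": [f"{r.mean_open:,.0f} ± {r.se_open:,.0f}" for r in results],
            "pregnant_mean_se": [
                f"{r.mean_pregnant:,.0f} ± {r.se_pregnant:,.0f}" for r in results
            ],
            "fch": [r.fch for r in results],
            "p_bull_breed": [r.p_bull_breed for r in results],
            "p_day6_stage": [r.p_day6_stage for r in results],
            "n_open": [r.n_open for r in results],
            "n_pregnant": [r.n_pregnant for r in results],
            "candidate": [r.candidate_flag for r in results],
            "outliers_removed": [";".join(r.outliers_removed) for r in results],
        }
    )
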