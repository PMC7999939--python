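"""Boolean pregnant-range calls and paired F1 scoring.

This is the combined embryo/recipient biomarker procedure: for each
metabolite, a sample is called "true" when its concentration falls inside the
inclusive [min, max] range spanned by the pregnant group. Calls from one
culture-medium metabolite and one plasma metabolite are then combined with a
logical OR (the stated truth table: F*F=F, T*F=T, F*T=T, T*T=T), the combined
calls are tallied against the pregnancy outcome, and the pair is scored by
F1 = 2TP / (2TP + FP + FN) with pregnancy as the positive class.

Significance comes from a stratified 2x2 chi-square in the Cochran form of
the Mantel-Haenszel test with a 0.5 continuity correction; for a single
stratum this reduces exactly to the Yates-corrected chi-square. In stratified
mode the strata are the Day-6 embryonic stages (blastocyst/morula), with
pregnant ranges re-derived within each stratum; F1 is computed from the
pooled confusion counts and the chi-square across strata.

A pair whose combined correct-call count falls below the better of its two
members alone is reported "ND" (not determined).
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (
    BooleanCallVector,
    ConfusionCounts,
    MetaboliteMatrix,
    PairF1Result,
)
from .errors import (
    InsufficientDataError,
    PairingError,
    UndefinedTestError,
)

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding used for printed F1 values."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Calls
# ---------------------------------------------------------------------------


def pregnant_range(values: pd.Series, labels: pd.Series) -> tuple[float, float]:
    """Inclusive [min, max] of the pregnant group's concentrations."""
    vals = values.loc[labels.index.intersection(values.index)]
    preg = vals[labels.reindex(vals.index).astype(bool)]
    preg = preg[np.isfinite(preg.to_numpy(dtype=float))]
    if preg.size < 2:
        raise InsufficientDataError(
            f"pregnant range needs >= 2 pregnant values, got {preg.size}"
        )
    return float(preg.min()), float(preg.max())


def boolean_calls(
    values: pd.Series,
    rng: tuple[float, float],
    *,
    metabolite: str = "",
    compartment: str = "",
) -> BooleanCallVector:
    """Per-sample inclusive-range membership (1/0; NaN where value missing)."""
    lo, hi = rng
    arr = values.to_numpy(dtype=float)
    calls = np.where((arr >= lo) & (arr <= hi), 1.0, 0.0)
    calls = np.where(np.isfinite(arr), calls, np.nan)
    return BooleanCallVector(
        metabolite=metabolite,
        compartment=compartment,
        range_low=lo,
        range_high=hi,
        calls=pd.Series(calls, index=values.index),
    )


def combine_or(calls_cm: pd.Series, calls_plasma: pd.Series) -> pd.Series:
    """Element-wise disjunction of two call vectors on their shared samples.

    Samples are inner-joined on id; a missing call on either side leaves the
    combined call missing (the sample is excluded from pair scoring).
    """
    idx = calls_cm.index.intersection(calls_plasma.index)
    if len(idx) == 0:
        raise PairingError("call vectors share no samples")
    dropped = len(calls_cm.index.symmetric_difference(calls_plasma.index))
    if dropped:
        logger.info("combine_or: %d unmatched sample(s) dropped", dropped)
    a = calls_cm.loc[idx].to_numpy(dtype=float)
    b = calls_plasma.loc[idx].to_numpy(dtype=float)
    combined = np.where(np.isnan(a) | np.isnan(b), np.nan, ((a > 0) | (b > 0)).astype(float))
    return pd.Series(combined, index=idx)


def confusion(combined_calls: pd.Series, outcomes: pd.Series) -> ConfusionCounts:
    """Tally calls against the pregnancy outcome (positive class = pregnant)."""
    idx = combined_calls.index.intersection(outcomes.index)
    calls = combined_calls.loc[idx].to_numpy(dtype=float)
    preg = outcomes.loc[idx].astype(bool).to_numpy()
    ok = ~np.isnan(calls)
    calls = calls[ok] > 0
    preg = preg[ok]
    return ConfusionCounts(
        tp=int((calls & preg).sum()),
        fp=int((calls & ~preg).sum()),
        fn=int((~calls & preg).sum()),
        tn=int((~calls & ~preg).sum()),
    )


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


def f1_score(conf: ConfusionCounts) -> float:
    """F1 = 2TP / (2TP + FP + FN), the harmonic mean of precision and recall."""
    denom = 2 * conf.tp + conf.fp + conf.fn
    if denom == 0:
        raise UndefinedTestError("F1 undefined: tp = fp = fn = 0")
    return 2.0 * conf.tp / denom


def mh_chi_square(
    per_stratum: Sequence[ConfusionCounts], *, continuity: bool = True
) -> tuple[float, float]:
    """Stratified 2x2 chi-square (Cochran-Mantel-Haenszel family).

    chi2 = (|sum_i (a_i - E[a_i])| - 1/2)^2 / sum_i Var(a_i) with a_i the
    true-positive cell, E and Var from the stratum margins. The Cochran
    variance r1*r2*c1*c2 / n^3 is used, so a single stratum reduces exactly
    to the Yates-corrected 2x2 chi-square (without continuity, to Pearson's).
    Strata with a zero margin contribute nothing and are logged.
    """
    num = 0.0
    var = 0.0
    used = 0
    for i, s in enumerate(per_stratum):
        n = s.total
        r1 = s.tp + s.fp  # called true
        r2 = s.fn + s.tn
        c1 = s.tp + s.fn  # pregnant
        c2 = s.fp + s.tn
        if n < 2 or min(r1, r2, c1, c2) == 0:
            logger.info("mh_chi_square: stratum %d degenerate, skipped", i)
            continue
        num += s.tp - r1 * c1 / n
        var += r1 * r2 * c1 * c2 / n**3
        used += 1
    if used == 0 or var == 0:
        raise UndefinedTestError("all strata degenerate for the stratified test")
    d = abs(num) - (0.5 if continuity else 0.0)
    chi2 = max(d, 0.0) ** 2 / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def nd_rule(pair_true_count: int, single_true_counts: Iterable[int]) -> bool:
    """Not-determined flag: the pair identifies fewer correct calls than the
    better of its member metabolites alone."""
    singles = list(single_true_counts)
    return bool(singles) and pair_true_count < max(singles)


# ---------------------------------------------------------------------------
# Pair scoring
# ---------------------------------------------------------------------------

AGGREGATE = "aggregate"
STRATIFIED = "stratified_b_m"


def _strata(
    index: pd.Index, stages: pd.Series | None, mode: str
) -> list[tuple[str, pd.Index]]:
    if mode == AGGREGATE:
        return [("all", index)]
    if mode != STRATIFIED:
        raise PairingError(f"unknown mode {mode!r}")
    if stages is None:
        raise InsufficientDataError("stratified mode requires Day-6 stage labels")
    stages = stages.reindex(index)
    return [
        (str(stage), index[(stages == stage).to_numpy()])
        for stage in pd.unique(stages.dropna())
    ]


def _solo_true_count(
    values: pd.Series,
    outcomes: pd.Series,
    strata: list[tuple[str, pd.Index]],
) -> int:
    """Correct-call count of one metabolite alone under the same stratification."""
    total = ConfusionCounts(0, 0, 0, 0)
    for _, idx in strata:
        rng = pregnant_range(values.loc[idx], outcomes.loc[idx])
        calls = boolean_calls(values.loc[idx], rng)
        total = total + confusion(calls.calls, outcomes.loc[idx])
    return total.true_count


def score_pair(
    cm_values: pd.Series,
    plasma_values: pd.Series,
    outcomes: pd.Series,
    *,
    stages: pd.Series | None = None,
    mode: str = AGGREGATE,
    cm_metabolite: str = "",
    plasma_metabolite: str = "",
    plasma_day: str = "d0",
    endpoint: str = "",
    continuity: bool = True,
) -> PairF1Result:
    """Score one CM x plasma metabolite pair.

    Aggregate mode derives pregnant ranges, calls and the confusion table on
    the pooled cohort (single-stratum chi-square). Stratified mode repeats
    the derivation within each Day-6 stage; F1 comes from the pooled
    confusion counts and the p-value from the chi-square across strata.
    """
    idx = cm_values.index.intersection(plasma_values.index).intersection(outcomes.index)
    if len(idx) == 0:
        raise PairingError("pair shares no samples with the outcome table")
    strata = _strata(idx, stages, mode)

    per_stratum: list[ConfusionCounts] = []
    ranges: dict[str, dict[str, tuple[float, float]]] = {}
    for name, sidx in strata:
        out_s = outcomes.loc[sidx]
        cm_rng = pregnant_range(cm_values.loc[sidx], out_s)
        pl_rng = pregnant_range(plasma_values.loc[sidx], out_s)
        ranges[name] = {"cm": cm_rng, "plasma": pl_rng}
        cm_calls = boolean_calls(cm_values.loc[sidx], cm_rng)
        pl_calls = boolean_calls(plasma_values.loc[sidx], pl_rng)
        combined = combine_or(cm_calls.calls, pl_calls.calls)
        per_stratum.append(confusion(combined, out_s))

    pooled = per_stratum[0]
    for s in per_stratum[1:]:
        pooled = pooled + s
    f1 = f1_score(pooled)
    try:
        chi2, p = mh_chi_square(per_stratum, continuity=continuity)
    except UndefinedTestError:
        # e.g. every sample called true: F1 is still defined but the 2x2 has a
        # zero margin, so no significance can be attached.
        logger.info(
            "score_pair: %s x %s has a degenerate 2x2; p undefined",
            cm_metabolite,
            plasma_metabolite,
        )
        chi2, p = float("nan"), float("nan")

    solo_cm = _solo_true_count(cm_values.loc[idx], outcomes.loc[idx], strata)
    solo_pl = _solo_true_count(plasma_values.loc[idx], outcomes.loc[idx], strata)
    nd = nd_rule(pooled.true_count, (solo_cm, solo_pl))

    return PairF1Result(
        cm_metabolite=cm_metabolite,
        plasma_metabolite=plasma_metabolite,
        plasma_day=plasma_day,
        endpoint=endpoint,
        mode=mode,
        confusion=pooled,
        per_stratum=per_stratum,
        true_count=pooled.true_count,
        n=pooled.total,
        f1=f1,
        chi2=chi2,
        p=p,
        nd=nd,
        ranges=ranges,
        single_true_counts=(solo_cm, solo_pl),
    )


def score_all_pairs(
    cm_matrix: MetaboliteMatrix,
    plasma_matrices: Mapping[str, MetaboliteMatrix],
    outcomes: pd.Series,
    *,
    stages: pd.Series | None = None,
    mode: str = AGGREGATE,
    endpoint: str = "",
    cm_candidates: Sequence[str] | None = None,
    plasma_candidates: Mapping[str, Sequence[str]] | None = None,
    sample_filter: pd.Index | None = None,
    continuity: bool = True,
) -> list[PairF1Result]:
    """Score the Cartesian product of candidate CM x plasma metabolites.

    ``plasma_matrices`` maps plasma day ("d0"/"d7") to its matrix; candidate
    lists default to every metabolite. Results are sorted by F1 descending
    then p ascending (the ND flag does not affect the ranking, only the
    report). Pairs that cannot be scored (too few pregnant values in a
    stratum) are skipped with a log entry.
    """
    cm_names = list(cm_candidates) if cm_candidates is not None else cm_matrix.metabolite_names
    if not cm_names:
        logger.warning("score_all_pairs: empty CM candidate set")
    results: list[PairF1Result] = []
    for day, matrix in plasma_matrices.items():
        if plasma_candidates is not None:
            pl_names = list(plasma_candidates.get(day, []))
        else:
            pl_names = matrix.metabolite_names
        if not pl_names:
            logger.warning("score_all_pairs: empty plasma candidate set for %s", day)
        for cm_name in cm_names:
            cm_vals = cm_matrix.metabolite(cm_name)
            if sample_filter is not None:
                cm_vals = cm_vals.loc[cm_vals.index.intersection(sample_filter)]
            for pl_name in pl_names:
                pl_vals = matrix.metabolite(pl_name)
                if sample_filter is not None:
                    pl_vals = pl_vals.loc[pl_vals.index.intersection(sample_filter)]
                try:
                    res = score_pair(
                        cm_vals,
                        pl_vals,
                        outcomes,
                        stages=stages,
                        mode=mode,
                        cm_metabolite=cm_name,
                        plasma_metabolite=pl_name,
                        plasma_day=day,
                        endpoint=endpoint,
                        continuity=continuity,
                    )
                except (InsufficientDataError, UndefinedTestError) as exc:
                    logger.info(
                        "score_all_pairs: skipped %s x %s (%s)", cm_name, pl_name, exc
                    )
                    continue
                results.append(res)
    results.sort(key=lambda r: (-r.f1, r.p))
    return results


def pairs_table(results: Sequence[PairF1Result]) -> pd.DataFrame:
    """Pair-report layout; F1 and p are withheld (blank) for ND pairs."""
    rows = []
    for r in results:
        rows.append(
            {
                "cm_metabolite": r.cm_metabolite,
                "plasma_metabolite": r.plasma_metabolite,
                "plasma_day": r.plasma_day,
                "endpoint": r.endpoint,
                "mode": r.mode,
                "true_count": f"{r.true_count}/{r.n}",
                "f1": "" if r.nd else f"{round_half_up(r.f1, 3):.3f}",
                "p": "" if r.nd else f"{r.p:.3g}",
                "nd": "ND" if r.nd else "",
            }
        )
    return pd.DataFrame(rows)
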