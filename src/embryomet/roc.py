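"""Single-biomarker ROC evaluation.

AUC is computed through the Mann-Whitney rank formulation (ties count one
half), with the orientation auto-detected per metabolite so the reported AUC
is always >= 0.5: "pregnant_high" when pregnant samples carry the higher
concentrations, "pregnant_low" otherwise. The operating cutoff is the
threshold closest (Euclidean distance in ROC space) to the perfect-classifier
corner (sensitivity 1, specificity 1), with ties broken by maximal Youden J
and then by the lower threshold. Confidence intervals come from a stratified
percentile bootstrap. A metabolite is selected as a discovery biomarker when
AUC exceeds 0.650 and a Welch t-test falls below the reporting threshold.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats

from .datatypes import RocResult
from .errors import DegenerateLabelsError, InsufficientDataError

logger = logging.getLogger(__name__)

AUC_THRESHOLD = 0.650

PREGNANT_HIGH = "pregnant_high"
PREGNANT_LOW = "pregnant_low"


def _check(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise DegenerateLabelsError("values and labels differ in length")
    finite = np.isfinite(values)
    values, labels = values[finite], labels[finite]
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("both outcome classes must be present")
    if n_pos < 2 or n_neg < 2:
        raise InsufficientDataError("need >= 2 samples per class")
    return values, labels


def auc(values, labels) -> tuple[float, str]:
    """Oriented AUC for pregnancy (positive class) via Mann-Whitney ranks.

    Returns ``(auc, orientation)`` with auc >= 0.5. Equivalent to
    U / (n_pos * n_neg) with tied between-class pairs counted one half.
    """
    values, labels = _check(values, labels)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(values)
    u_pos = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    raw = u_pos / (n_pos * n_neg)  # P(pregnant value > open value) + 0.5 ties
    if raw >= 0.5:
        return float(raw), PREGNANT_HIGH
    return float(1.0 - raw), PREGNANT_LOW


def _oriented_auc(values: np.ndarray, labels: np.ndarray, orientation: str) -> float:
    """AUC in a fixed orientation (may fall below 0.5; used by the bootstrap)."""
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(values)
    raw = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(raw) if orientation == PREGNANT_HIGH else float(1.0 - raw)


def bootstrap_ci(
    values, labels, n_boot: int = 1000, seed: int = 0, orientation: str | None = None
) -> tuple[float, float]:
    """Stratified percentile bootstrap interval (2.5/97.5) for the AUC.

    Resampling is within class, so every resample keeps both classes; the
    orientation is fixed from the full sample. Reproducible by ``seed``.
    """
    values, labels = _check(values, labels)
    if n_boot < 100:
        logger.warning("bootstrap_ci: n_boot=%d < 100 gives unstable intervals", n_boot)
    if orientation is None:
        _, orientation = auc(values, labels)
    rng = np.random.default_rng(seed)
    pos = values[labels]
    neg = values[~labels]
    n_pos, n_neg = pos.size, neg.size
    samples = np.concatenate(
        [
            pos[rng.integers(0, n_pos, size=(n_boot, n_pos))],
            neg[rng.integers(0, n_neg, size=(n_boot, n_neg))],
        ],
        axis=1,
    )
    ranks = stats.rankdata(samples, axis=1)
    raw = (ranks[:, :n_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    boot = raw if orientation == PREGNANT_HIGH else 1.0 - raw
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return float(lo), float(hi)


def _rates(values, labels, cutoff, orientation):
    """(sens, spec) of the pregnant-call rule at one threshold."""
    if orientation == PREGNANT_HIGH:
        called = values >= cutoff
    else:
        called = values <= cutoff
    sens = called[labels].mean() if labels.any() else 0.0
    spec = (~called[~labels]).mean() if (~labels).any() else 0.0
    return float(sens), float(spec)


def candidate_cutoffs(values: np.ndarray, orientation: str) -> np.ndarray:
    """Midpoints of adjacent distinct sorted values, plus -inf/+inf."""
    distinct = np.unique(values[np.isfinite(values)])
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def optimal_cutoff(values, labels, orientation: str) -> tuple[float, float, float]:
    """Closest-to-corner operating point.

    Among all candidate thresholds, minimise the Euclidean distance to the
    perfect-classification corner (sens 1, spec 1); break ties by maximal
    Youden J (sens + spec - 1), then by the lower threshold.
    """
    values, labels = _check(values, labels)
    best = None
    for cut in candidate_cutoffs(values, orientation):
        sens, spec = _rates(values, labels, cut, orientation)
        dist = math.hypot(1.0 - sens, 1.0 - spec)
        key = (round(dist, 12), -round(sens + spec, 12), cut)
        if best is None or key < best[0]:
            best = (key, cut, sens, spec)
    _, cut, sens, spec = best
    return float(cut), sens, spec


def class_counts(
    values, labels, cutoff: float, orientation: str
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Per-class correct counts at a cutoff: (open k/n, pregnant m/p)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    finite = np.isfinite(values)
    values, labels = values[finite], labels[finite]
    if orientation == PREGNANT_HIGH:
        called = values >= cutoff
    else:
        called = values <= cutoff
    n_open = int((~labels).sum())
    n_preg = int(labels.sum())
    correct_open = int((~called[~labels]).sum())
    correct_preg = int(called[labels].sum())
    return (correct_open, n_open), (correct_preg, n_preg)


def format_counts(counts: tuple[int, int]) -> str:
    """'correct/total' string as printed in biomarker tables, e.g. '13/17'."""
    return f"{counts[0]}/{counts[1]}"


def evaluate_metabolite(
    values,
    labels,
    *,
    metabolite: str = "",
    endpoint: str = "",
    n_boot: int = 1000,
    seed: int = 0,
    auc_threshold: float = AUC_THRESHOLD,
    alpha: float = 0.05,
    equal_var: bool = False,
    compute_ci: bool = True,
) -> RocResult:
    """Full single-biomarker evaluation of one metabolite.

    The discovery t-test is Welch's by default (``equal_var=True`` pools
    variances). ``selected`` marks AUC > ``auc_threshold`` with t-test
    p < ``alpha``. The percentile interval is clipped to contain the point
    estimate so 0 <= ci_low <= auc <= ci_high <= 1 always holds.
    """
    vals, labs = _check(values, labels)
    a, orientation = auc(vals, labs)
    cut, sens, spec = optimal_cutoff(vals, labs, orientation)
    correct_open, correct_preg = class_counts(vals, labs, cut, orientation)
    p_t = float(stats.ttest_ind(vals[~labs], vals[labs], equal_var=equal_var).pvalue)
    if compute_ci:
        lo, hi = bootstrap_ci(vals, labs, n_boot=n_boot, seed=seed, orientation=orientation)
        lo, hi = min(lo, a), max(hi, a)
    else:
        lo = hi = float("nan")
    return RocResult(
        metabolite=metabolite,
        endpoint=endpoint,
        auc=a,
        ci_low=lo,
        ci_high=hi,
        orientation=orientation,
        cutoff=cut,
        sens=sens,
        spec=spec,
        correct_open=correct_open,
        correct_pregnant=correct_preg,
        p_ttest=p_t,
        selected=bool(a > auc_threshold and p_t < alpha),
    )
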