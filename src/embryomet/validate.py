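"""Independent-cohort validation of selected metabolite pairs.

Pairs selected on the discovery cohort are re-scored on an independent cohort
(typically targeted, absolute-quantification data). Two range policies exist:

* ``refit_in_validation`` (default) — pregnant ranges are re-derived within
  the validation cohort. Discovery used dimensionless internal-standard
  ratios while targeted validation reports absolute concentrations, so
  numeric cutoffs cannot transfer across units; refitting is the only
  unit-coherent policy and is invariant to rescaling of the validation data.
* ``frozen_from_discovery`` — the numeric discovery ranges are applied
  verbatim; this is refused with :class:`UnitMismatchError` when the two
  cohorts carry different measurement units.

Each pair is reported in both aggregate and Day-6-stage-stratified modes with
the not-determined (ND) rule applied per mode independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import Cohort, ConfusionCounts, PairF1Result
from .errors import InsufficientDataError, UndefinedTestError, UnitMismatchError
from .pairs import (
    AGGREGATE,
    STRATIFIED,
    boolean_calls,
    combine_or,
    confusion,
    f1_score,
    mh_chi_square,
    round_half_up,
    score_pair,
)

logger = logging.getLogger(__name__)

REFIT = "refit_in_validation"
FROZEN = "frozen_from_discovery"


@dataclass
class ValidationReport:
    """Validation results: one row per pair per mode."""

    table: pd.DataFrame
    n: int
    breed: str
    plasma_day: str
    log: list[str] = field(default_factory=list)

    def to_wide(self) -> pd.DataFrame:
        """With/without Day-6-stage column blocks (ND rows blank F1/p)."""
        t = self.table
        blocks = []
        for mode, label in ((STRATIFIED, "with_day6_stage"), (AGGREGATE, "without_day6_stage")):
            sub = t[t["mode"] == mode].set_index(["cm_metabolite", "plasma_metabolite"])
            sub = sub[["true_count", "f1", "p", "nd"]]
            sub.columns = [f"{label}:{c}" for c in sub.columns]
            blocks.append(sub)
        return pd.concat(blocks, axis=1).reset_index()


def below_lod_fraction(values: pd.Series, lod: float) -> float:
    arr = values.to_numpy(dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return 1.0
    return float((arr < lod).mean())


def _frozen_score(
    cm_values: pd.Series,
    plasma_values: pd.Series,
    outcomes: pd.Series,
    stages: pd.Series | None,
    mode: str,
    ranges: Mapping[str, Mapping[str, tuple[float, float]]],
) -> tuple[ConfusionCounts, list[ConfusionCounts]]:
    """Apply stored discovery ranges verbatim (per stratum in stratified mode)."""
    idx = cm_values.index.intersection(plasma_values.index).intersection(outcomes.index)
    if mode == AGGREGATE:
        strata = [("all", idx)]
    else:
        st = stages.reindex(idx)
        strata = [(str(s), idx[(st == s).to_numpy()]) for s in pd.unique(st.dropna())]
    per_stratum = []
    for name, sidx in strata:
        rng = ranges.get(name) or ranges.get("all")
        if rng is None:
            raise InsufficientDataError(f"no frozen range stored for stratum {name!r}")
        cm_calls = boolean_calls(cm_values.loc[sidx], tuple(rng["cm"]))
        pl_calls = boolean_calls(plasma_values.loc[sidx], tuple(rng["plasma"]))
        per_stratum.append(confusion(combine_or(cm_calls.calls, pl_calls.calls), outcomes.loc[sidx]))
    pooled = per_stratum[0]
    for s in per_stratum[1:]:
        pooled = pooled + s
    return pooled, per_stratum


def validate_pairs(
    selected_pairs: Sequence[PairF1Result],
    validation_cohort: Cohort,
    *,
    endpoint: str = "birth",
    plasma_day: str = "d0",
    range_policy: str = REFIT,
    discovery_units: str = "is_ratio",
    modes: Sequence[str] = (STRATIFIED, AGGREGATE),
    lod: float | None = None,
    lod_max_fraction: float = 0.5,
    continuity: bool = True,
) -> ValidationReport:
    """Re-score selected pairs on an independent cohort.

    Returns a :class:`ValidationReport` with one row per pair and mode. Pairs
    whose metabolites are absent from the validation panel are flagged
    ``not_measured``; metabolites with more than ``lod_max_fraction`` of
    values below ``lod`` are excluded as below the detection limit.
    """
    if range_policy not in (REFIT, FROZEN):
        raise UnitMismatchError(f"unknown range_policy {range_policy!r}")
    plasma = validation_cohort.matrix("plasma_" + plasma_day)
    cm = validation_cohort.cm
    if range_policy == FROZEN and (
        cm.units != discovery_units or plasma.units != discovery_units
    ):
        raise UnitMismatchError(
            "frozen_from_discovery requires identical units: discovery "
            f"{discovery_units!r} vs validation ({cm.units!r}, {plasma.units!r})"
        )
    outcomes = validation_cohort.outcomes(endpoint)
    stages = validation_cohort.stages()
    log: list[str] = list(validation_cohort.log)

    rows = []
    seen: set[tuple[str, str]] = set()
    for pair in selected_pairs:
        key = (pair.cm_metabolite, pair.plasma_metabolite)
        if key in seen:
            continue
        seen.add(key)
        row_base = {
            "cm_metabolite": pair.cm_metabolite,
            "plasma_metabolite": pair.plasma_metabolite,
            "plasma_day": plasma_day,
            "endpoint": endpoint,
            "true_count": "",
            "f1": "",
            "p": "",
            "nd": "",
            "flag": "",
        }
        missing = [
            m
            for m, panel in (
                (pair.cm_metabolite, cm.metabolite_names),
                (pair.plasma_metabolite, plasma.metabolite_names),
            )
            if m not in panel
        ]
        if missing:
            log.append(f"not measured in validation panel: {', '.join(missing)}")
            for mode in modes:
                rows.append({**row_base, "mode": mode, "flag": "not_measured"})
            continue
        cm_vals = cm.metabolite(pair.cm_metabolite)
        pl_vals = plasma.metabolite(pair.plasma_metabolite)
        if lod is not None:
            excluded = [
                m
                for m, v in ((pair.cm_metabolite, cm_vals), (pair.plasma_metabolite, pl_vals))
                if below_lod_fraction(v, lod) > lod_max_fraction
            ]
            if excluded:
                log.append(f"below LOD in validation: {', '.join(excluded)}")
                for mode in modes:
                    rows.append({**row_base, "mode": mode, "flag": "below_lod"})
                continue
        for mode in modes:
            try:
                if range_policy == REFIT:
                    res = score_pair(
                        cm_vals,
                        pl_vals,
                        outcomes,
                        stages=stages,
                        mode=mode,
                        cm_metabolite=pair.cm_metabolite,
                        plasma_metabolite=pair.plasma_metabolite,
                        plasma_day=plasma_day,
                        endpoint=endpoint,
                        continuity=continuity,
                    )
                    pooled, per_stratum = res.confusion, res.per_stratum
                    f1, chi2, p, nd = res.f1, res.chi2, res.p, res.nd
                else:
                    pooled, per_stratum = _frozen_score(
                        cm_vals, pl_vals, outcomes, stages, mode, pair.ranges
                    )
                    f1 = f1_score(pooled)
                    chi2, p = mh_chi_square(per_stratum, continuity=continuity)
                    # Singles under frozen policy are not re-derivable from the
                    # stored pair ranges; the ND rule is applied on refit only.
                    nd = False
            except (InsufficientDataError, UndefinedTestError) as exc:
                log.append(
                    f"{pair.cm_metabolite} x {pair.plasma_metabolite} [{mode}]: {exc}"
                )
                rows.append({**row_base, "mode": mode, "flag": "degenerate"})
                continue
            rows.append(
                {
                    **row_base,
                    "mode": mode,
                    "true_count": f"{pooled.true_count}/{pooled.total}",
                    "f1": "" if nd else f"{round_half_up(f1, 3):.3f}",
                    "p": "" if nd else f"{p:.3g}",
                    "nd": "ND" if nd else "",
                    "flag": "",
                }
            )
    table = pd.DataFrame(rows)
    return ValidationReport(
        table=table,
        n=len(outcomes),
        breed="Holstein",
        plasma_day=plasma_day,
        log=log,
    )
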