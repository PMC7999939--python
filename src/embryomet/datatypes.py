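"""Core domain containers.

One embryo transfer (ET) is the sample unit: it links one spent culture-medium
(CM) sample from a single-embryo 24 h culture to the recipient heifer's Day-0
and Day-7 plasma samples, and to the nested pregnancy outcomes diagnosed at
gestational Day-40, Day-62 and birth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

BREEDS = ("AV", "Holstein", "cross")
BULL_BREEDS = ("AV", "Holstein")
STAGES = ("morula", "early_blastocyst")
ENDPOINTS = ("d40", "d62", "birth")
COMPARTMENTS = ("CM", "plasma_d0", "plasma_d7")
PLASMA_DAYS = ("d0", "d7")
UNITS = ("is_ratio", "absolute")


@dataclass(frozen=True)
class ETRecord:
    """One embryo transfer and its gestational trajectory.

    Outcomes are nested: a birth implies pregnancy at Day-62 which implies
    pregnancy at Day-40. Construction enforces this monotonicity.
    """

    et_id: str
    breed: str
    day6_stage: str
    bull_breed: str
    pregnant_d40: bool
    pregnant_d62: bool
    birth: bool

    def __post_init__(self) -> None:
        if self.breed not in BREEDS:
            raise ConfigurationError(f"breed: unknown value {self.breed!r}")
        if self.day6_stage not in STAGES:
            raise ConfigurationError(f"day6_stage: unknown value {self.day6_stage!r}")
        if self.bull_breed not in BULL_BREEDS:
            raise ConfigurationError(f"bull_breed: unknown value {self.bull_breed!r}")
        if self.birth and not self.pregnant_d62:
            raise ConfigurationError("outcomes: birth requires pregnant_d62")
        if self.pregnant_d62 and not self.pregnant_d40:
            raise ConfigurationError("outcomes: pregnant_d62 requires pregnant_d40")

    def outcome(self, endpoint: str) -> bool:
        """Pregnancy status at ``endpoint`` (one of d40, d62, birth)."""
        if endpoint == "d40":
            return self.pregnant_d40
        if endpoint == "d62":
            return self.pregnant_d62
        if endpoint == "birth":
            return self.birth
        raise ConfigurationError(f"endpoint: unknown value {endpoint!r}")


def records_frame(records: Sequence[ETRecord]) -> pd.DataFrame:
    """Tabulate ET records (index: et_id)."""
    return pd.DataFrame(
        {
            "breed": [r.breed for r in records],
            "day6_stage": [r.day6_stage for r in records],
            "bull_breed": [r.bull_breed for r in records],
            "pregnant_d40": [r.pregnant_d40 for r in records],
            "pregnant_d62": [r.pregnant_d62 for r in records],
            "birth": [r.birth for r in records],
        },
        index=pd.Index([r.et_id for r in records], name="et_id"),
    )


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites concentration table for one compartment.

    ``data`` rows are samples (index = ET ids), columns are metabolite names.
    Values are non-negative concentrations — dimensionless internal-standard
    response ratios in discovery data, absolute concentrations in targeted
    validation data. NaN marks a missing measurement.
    """

    compartment: str
    data: pd.DataFrame
    units: str = "is_ratio"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ConfigurationError(f"compartment: unknown value {self.compartment!r}")
        if self.units not in UNITS:
            raise ConfigurationError(f"units: unknown value {self.units!r}")
        if self.data.index.has_duplicates:
            raise ConfigurationError("sample_ids: duplicates present")
        if self.data.columns.has_duplicates:
            raise ConfigurationError("metabolite_names: duplicates present")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ConfigurationError("values: negative concentration present")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def metabolite(self, name: str) -> pd.Series:
        return self.data[name]


@dataclass(frozen=True)
class Effect:
    """A planted group difference: open minus pregnant, on the log2 scale.

    ``log2fc`` > 0 means open recipients/embryos show the higher
    concentration, matching the open/pregnant fold-change convention of the
    candidate tables. ``breeds`` optionally restricts the effect to recipient
    breeds (None = all).
    """

    metabolite: str
    compartment: str
    endpoint: str
    log2fc: float
    breeds: tuple[str, ...] | None = None


@dataclass(frozen=True)
class NoiseModel:
    """Per-metabolite lognormal concentration model.

    Baseline log-locations are drawn once per metabolite panel from
    Normal(log_mean, log_mean_sd); sample-level noise is additive Gaussian on
    the natural-log scale with standard deviation ``log_sigma``.
    """

    log_mean: float = 6.0
    log_mean_sd: float = 1.0
    log_sigma: float = 0.5

    def validate(self) -> None:
        if self.log_mean_sd < 0:
            raise ConfigurationError("noise_model.log_mean_sd: must be >= 0")
        if self.log_sigma <= 0:
            raise ConfigurationError("noise_model.log_sigma: must be > 0")


@dataclass(frozen=True)
class EndpointRates:
    """Markov chain over nested endpoints: D40 -> D62 -> birth."""

    p_d40: float = 0.61
    p_d62_given_d40: float = 0.95
    p_birth_given_d62: float = 0.90

    def validate(self) -> None:
        for name in ("p_d40", "p_d62_given_d40", "p_birth_given_d62"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"endpoint_rates.{name}: {v} outside [0, 1]")


def _default_breed_counts() -> dict[str, int]:
    return {"AV": 13, "Holstein": 17, "cross": 6}


@dataclass
class CohortConfig:
    """Design of a simulated embryo-transfer cohort.

    Defaults mirror the discovery-study structure: 36 ETs (13 Asturiana de
    los Valles, 17 Holstein, 6 crossbred recipients), 37 CM metabolites,
    71 plasma metabolites measured on Day-0 and Day-7, one uncollected Day-0
    plasma sample, and nested pregnancy outcomes at Day-40/Day-62/birth.
    """

    n_et: int = 36
    breed_counts: Mapping[str, int] = field(default_factory=_default_breed_counts)
    n_cm_metabolites: int = 37
    n_plasma_metabolites: int = 71
    stage_probs: Mapping[str, float] = field(
        default_factory=lambda: {"morula": 0.5, "early_blastocyst": 0.5}
    )
    endpoint_rates: EndpointRates = field(default_factory=EndpointRates)
    effect_table: Sequence[Effect] = field(default_factory=tuple)
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    breed_day0_effects: Mapping[str, float] = field(default_factory=dict)
    missing_day0: int = 1
    correlation_rank: int = 0
    correlation_strength: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_et <= 0:
            raise ConfigurationError("n_et: must be positive")
        for name, n in (
            ("n_cm_metabolites", self.n_cm_metabolites),
            ("n_plasma_metabolites", self.n_plasma_metabolites),
        ):
            if n <= 0:
                raise ConfigurationError(f"{name}: must be positive")
        for breed, count in self.breed_counts.items():
            if breed not in BREEDS:
                raise ConfigurationError(f"breed_counts: unknown breed {breed!r}")
            if count < 0:
                raise ConfigurationError(f"breed_counts[{breed}]: negative count")
        if sum(self.breed_counts.values()) != self.n_et:
            raise ConfigurationError(
                f"breed_counts: sum {sum(self.breed_counts.values())} != n_et {self.n_et}"
            )
        total_stage = 0.0
        for stage, p in self.stage_probs.items():
            if stage not in STAGES:
                raise ConfigurationError(f"stage_probs: unknown stage {stage!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"stage_probs[{stage}]: {p} outside [0, 1]")
            total_stage += p
        if not math.isclose(total_stage, 1.0, abs_tol=1e-9):
            raise ConfigurationError("stage_probs: probabilities must sum to 1")
        self.endpoint_rates.validate()
        self.noise_model.validate()
        if self.missing_day0 < 0 or self.missing_day0 >= self.n_et:
            raise ConfigurationError("missing_day0: must be in [0, n_et)")
        if self.correlation_rank < 0:
            raise ConfigurationError("correlation_rank: must be >= 0")
        if self.correlation_strength < 0:
            raise ConfigurationError("correlation_strength: must be >= 0")
        for eff in self.effect_table:
            if eff.compartment not in COMPARTMENTS:
                raise ConfigurationError(
                    f"effect_table: unknown compartment {eff.compartment!r}"
                )
            if eff.endpoint not in ENDPOINTS:
                raise ConfigurationError(
                    f"effect_table: unknown endpoint {eff.endpoint!r}"
                )


@dataclass
class Cohort:
    """A generated cohort: ET records plus one matrix per compartment."""

    records: list[ETRecord]
    cm: MetaboliteMatrix
    plasma_d0: MetaboliteMatrix
    plasma_d7: MetaboliteMatrix
    log: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter((self.records, self.cm, self.plasma_d0, self.plasma_d7))

    def outcomes(self, endpoint: str) -> pd.Series:
        frame = records_frame(self.records)
        col = {"d40": "pregnant_d40", "d62": "pregnant_d62", "birth": "birth"}[endpoint]
        return frame[col]

    def stages(self) -> pd.Series:
        return records_frame(self.records)["day6_stage"]

    def breeds(self) -> pd.Series:
        return records_frame(self.records)["breed"]

    def matrix(self, compartment: str) -> MetaboliteMatrix:
        return {
            "CM": self.cm,
            "plasma_d0": self.plasma_d0,
            "plasma_d7": self.plasma_d7,
        }[compartment]


# ---------------------------------------------------------------------------
# Result records
# ---------------------------------------------------------------------------


@dataclass
class CandidateResult:
    """Univariate screening verdict for one metabolite at one endpoint."""

    metabolite: str
    compartment: str
    endpoint: str
    test_used: str  # "anova" | "kruskal_wallis"
    p_value: float
    p_adjusted: float
    mean_open: float
    se_open: float
    mean_pregnant: float
    se_pregnant: float
    fch: float
    p_bull_breed: float
    p_day6_stage: float
    candidate_flag: bool
    n_open: int
    n_pregnant: int
    outliers_removed: list[str] = field(default_factory=list)


@dataclass
class RocResult:
    """Single-biomarker discovery result for one metabolite."""

    metabolite: str
    endpoint: str
    auc: float
    ci_low: float
    ci_high: float
    orientation: str  # "pregnant_high" | "pregnant_low"
    cutoff: float
    sens: float
    spec: float
    correct_open: tuple[int, int]
    correct_pregnant: tuple[int, int]
    p_ttest: float
    selected: bool


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with pregnancy as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: negative count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def true_count(self) -> int:
        """Correct calls: true positives + true negatives."""
        return self.tp + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


@dataclass
class BooleanCallVector:
    """Pregnant-range membership calls for one metabolite.

    ``calls`` is a float Series: 1.0 = within the pregnant range, 0.0 =
    outside, NaN = measurement missing (sample excluded from pair scoring).
    """

    metabolite: str
    compartment: str
    range_low: float
    range_high: float
    calls: pd.Series

    @property
    def n_true(self) -> int:
        return int(np.nansum(self.calls.to_numpy(dtype=float)))


@dataclass
class PairF1Result:
    """F1 evaluation of one CM x plasma metabolite pair at one endpoint."""

    cm_metabolite: str
    plasma_metabolite: str
    plasma_day: str
    endpoint: str
    mode: str  # "aggregate" | "stratified_b_m"
    confusion: ConfusionCounts
    per_stratum: list[ConfusionCounts]
    true_count: int
    n: int
    f1: float
    chi2: float
    p: float
    nd: bool
    ranges: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    single_true_counts: tuple[int, int] = (0, 0)
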