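"""Synthetic embryo-transfer cohort generator.

The generator reproduces the structure of a single-embryo-transfer
metabolomics study: each ET contributes one spent culture-medium (CM) sample
and Day-0/Day-7 recipient plasma samples, plus nested pregnancy outcomes at
Day-40, Day-62 and birth. Concentrations follow a per-metabolite lognormal
model; planted group effects act as symmetric shifts on the log scale, so a
configured open/pregnant log2 fold change is recovered in expectation as the
difference of group means of log2 concentrations.

Randomness is organised as named independent substreams off one root seed
(records, each matrix, missingness), so e.g. enlarging the plasma panel does
not perturb the generated outcomes.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    Cohort,
    CohortConfig,
    Effect,
    ETRecord,
    MetaboliteMatrix,
    records_frame,
)

_LN2 = math.log(2.0)

CM_PREFIX = "CM_M"
PLASMA_PREFIX = "PL_M"


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named substream of the root seed."""
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _generate_records(config: CohortConfig, namespace: str) -> list[ETRecord]:
    rng = _stream(config.seed, namespace + "records")
    n = config.n_et

    breeds = np.repeat(
        list(config.breed_counts.keys()), list(config.breed_counts.values())
    )
    breeds = breeds[rng.permutation(n)]

    p_morula = config.stage_probs.get("morula", 0.5)
    stages = np.where(rng.random(n) < p_morula, "morula", "early_blastocyst")
    bulls = rng.choice(["AV", "Holstein"], size=n)

    rates = config.endpoint_rates
    d40 = rng.random(n) < rates.p_d40
    d62 = d40 & (rng.random(n) < rates.p_d62_given_d40)
    birth = d62 & (rng.random(n) < rates.p_birth_given_d62)

    prefix = "VET" if namespace else "ET"
    return [
        ETRecord(
            et_id=f"{prefix}{i + 1:02d}",
            breed=str(breeds[i]),
            day6_stage=str(stages[i]),
            bull_breed=str(bulls[i]),
            pregnant_d40=bool(d40[i]),
            pregnant_d62=bool(d62[i]),
            birth=bool(birth[i]),
        )
        for i in range(n)
    ]


def _panel_baselines(config: CohortConfig, panel: str, n_met: int) -> np.ndarray:
    """Per-metabolite log-scale locations, shared across plasma days."""
    rng = _stream(config.seed, f"panel:{panel}")
    nm = config.noise_model
    return rng.normal(nm.log_mean, nm.log_mean_sd, size=n_met)


def _effect_shift(
    config: CohortConfig,
    compartment: str,
    names: Sequence[str],
    frame: pd.DataFrame,
) -> np.ndarray:
    """Log-scale shift matrix (samples x metabolites) implied by the config.

    An effect of ``log2fc`` adds +log2fc*ln2/2 for open and -log2fc*ln2/2 for
    pregnant samples at the effect's endpoint, optionally restricted by
    recipient breed, so the expected open-pregnant difference of log2
    concentrations equals log2fc.
    """
    n = len(frame)
    shift = np.zeros((n, len(names)))
    col = {"d40": "pregnant_d40", "d62": "pregnant_d62", "birth": "birth"}
    name_idx = {m: j for j, m in enumerate(names)}
    for eff in config.effect_table:
        if eff.compartment != compartment or eff.metabolite not in name_idx:
            continue
        j = name_idx[eff.metabolite]
        pregnant = frame[col[eff.endpoint]].to_numpy(dtype=bool)
        sign = np.where(pregnant, -0.5, 0.5) * eff.log2fc * _LN2
        if eff.breeds is not None:
            mask = frame["breed"].isin(eff.breeds).to_numpy()
            sign = np.where(mask, sign, 0.0)
        shift[:, j] += sign
    if compartment == "plasma_d0" and config.breed_day0_effects:
        # Recipient-breed separation confined to Day-0 plasma: AV up,
        # Holstein down, crossbreds unshifted.
        breed = frame["breed"].to_numpy()
        direction = np.where(breed == "AV", 0.5, np.where(breed == "Holstein", -0.5, 0.0))
        for met, fc in config.breed_day0_effects.items():
            if met in name_idx:
                shift[:, name_idx[met]] += direction * fc * _LN2
    return shift


def _generate_matrix(
    config: CohortConfig,
    records: Sequence[ETRecord],
    compartment: str,
    names: list[str],
    baselines: np.ndarray,
    namespace: str,
) -> MetaboliteMatrix:
    rng = _stream(config.seed, f"{namespace}matrix:{compartment}")
    frame = records_frame(records)
    n, m = len(records), len(names)
    log_vals = baselines[None, :] + rng.normal(
        0.0, config.noise_model.log_sigma, size=(n, m)
    )
    if config.correlation_rank > 0 and config.correlation_strength > 0:
        # Optional low-rank shared variation among metabolites (uncalibrated).
        k = config.correlation_rank
        loadings = _stream(config.seed, f"loadings:{compartment}").normal(
            0.0, 1.0, size=(m, k)
        )
        factors = rng.normal(0.0, 1.0, size=(n, k))
        log_vals += config.correlation_strength * factors @ loadings.T
    log_vals += _effect_shift(config, compartment, names, frame)
    data = pd.DataFrame(np.exp(log_vals), index=frame.index.copy(), columns=names)
    return MetaboliteMatrix(compartment=compartment, data=data)


def generate_cohort(config: CohortConfig, _namespace: str = "") -> Cohort:
    """Generate a discovery-style cohort.

    Returns a :class:`Cohort` whose matrices have shapes
    (n_et x n_cm_metabolites) for CM and (n_et x n_plasma_metabolites) for
    plasma, with ``missing_day0`` Day-0 plasma rows dropped entirely (the
    default of 1 mirrors one uncollected Day-0 sample). Reproducible given
    ``config.seed``; outcome nesting holds for every record by construction.
    """
    config.validate()
    records = _generate_records(config, _namespace)

    cm_names = [f"{CM_PREFIX}{j + 1:02d}" for j in range(config.n_cm_metabolites)]
    pl_names = [f"{PLASMA_PREFIX}{j + 1:02d}" for j in range(config.n_plasma_metabolites)]
    cm_base = _panel_baselines(config, "cm", config.n_cm_metabolites)
    pl_base = _panel_baselines(config, "plasma", config.n_plasma_metabolites)

    cm = _generate_matrix(config, records, "CM", cm_names, cm_base, _namespace)
    d0 = _generate_matrix(config, records, "plasma_d0", pl_names, pl_base, _namespace)
    d7 = _generate_matrix(config, records, "plasma_d7", pl_names, pl_base, _namespace)

    log: list[str] = []
    if config.missing_day0 > 0:
        rng = _stream(config.seed, _namespace + "missing_day0")
        drop_idx = rng.choice(config.n_et, size=config.missing_day0, replace=False)
        dropped = [records[i].et_id for i in sorted(drop_idx)]
        d0 = MetaboliteMatrix(
            compartment="plasma_d0",
            data=d0.data.drop(index=dropped),
            units=d0.units,
        )
        log.append(
            f"missing_day0: dropped {len(dropped)} Day-0 plasma sample(s): "
            + ", ".join(dropped)
        )
    return Cohort(records=records, cm=cm, plasma_d0=d0, plasma_d7=d7, log=log)


def generate_validation_cohort(
    config: CohortConfig | None = None,
    discovery_effects: Sequence[Effect] | None = None,
    *,
    n_et: int = 19,
    absolute_scale: float = 0.25,
) -> Cohort:
    """Generate an independent Holstein validation cohort (default N = 19).

    Draws from a separate seed substream so validation data are independent
    of the discovery cohort generated from the same config, while keeping the
    same effect structure (``discovery_effects`` overrides the config's
    effect table). Matrices carry absolute units: targeted quantification is
    emulated by a fixed calibration rescaling of the lognormal model, which
    changes the numeric scale but no distributional shape.
    """
    base = config if config is not None else CohortConfig()
    effects = tuple(discovery_effects) if discovery_effects is not None else tuple(
        base.effect_table
    )
    val_config = replace(
        base,
        n_et=n_et,
        breed_counts={"Holstein": n_et},
        effect_table=effects,
        breed_day0_effects={},
        missing_day0=0,
    )
    cohort = generate_cohort(val_config, _namespace="validation:")
    for matrix in (cohort.cm, cohort.plasma_d0, cohort.plasma_d7):
        matrix.data = matrix.data * absolute_scale
        matrix.units = "absolute"
    cohort.log.append(
        f"validation cohort: n={n_et} Holstein, absolute units "
        f"(calibration scale {absolute_scale})"
    )
    return cohort
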