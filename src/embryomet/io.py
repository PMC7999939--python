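"""Tab-separated input/output and run manifests.

Matrices are written samples-as-rows with a header row of metabolite names
and empty cells for missing values; sample metadata is one row per ET. A run
manifest records the seed and a SHA-256 hash of the canonicalised config so
outputs are traceable to the exact configuration that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .datatypes import (
    Cohort,
    CohortConfig,
    Effect,
    EndpointRates,
    ETRecord,
    MetaboliteMatrix,
    NoiseModel,
    records_frame,
)
from .errors import ConfigurationError


def write_matrix(matrix: MetaboliteMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", na_rep="", index_label="sample_id")


def read_matrix(
    path: str | Path, compartment: str, units: str = "is_ratio"
) -> MetaboliteMatrix:
    data = pd.read_csv(path, sep="\t", index_col="sample_id")
    return MetaboliteMatrix(compartment=compartment, data=data, units=units)


def write_metadata(records: Sequence[ETRecord], path: str | Path) -> None:
    records_frame(records).to_csv(path, sep="\t", index_label="et_id")


def read_metadata(path: str | Path) -> list[ETRecord]:
    frame = pd.read_csv(path, sep="\t", index_col="et_id")
    return [
        ETRecord(
            et_id=str(et_id),
            breed=row["breed"],
            day6_stage=row["day6_stage"],
            bull_breed=row["bull_breed"],
            pregnant_d40=bool(row["pregnant_d40"]),
            pregnant_d62=bool(row["pregnant_d62"]),
            birth=bool(row["birth"]),
        )
        for et_id, row in frame.iterrows()
    ]


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_metadata(cohort.records, outdir / "metadata.tsv")
    write_matrix(cohort.cm, outdir / "cm.tsv")
    write_matrix(cohort.plasma_d0, outdir / "plasma_d0.tsv")
    write_matrix(cohort.plasma_d7, outdir / "plasma_d7.tsv")
    (outdir / "exclusions.log").write_text("\n".join(cohort.log) + "\n")


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def config_to_dict(config: CohortConfig) -> dict:
    return _to_jsonable(config)


def config_hash(config: Any) -> str:
    """SHA-256 of the canonical JSON form of a config dataclass."""
    payload = json.dumps(_to_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode("utf8")).hexdigest()


def write_manifest(path: str | Path, seed: int, config: Any) -> None:
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": _to_jsonable(config),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def load_cohort_config(path: str | Path) -> CohortConfig:
    """Read a cohort config from a YAML or JSON document."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path}: expected a mapping")
    if "endpoint_rates" in raw:
        raw["endpoint_rates"] = EndpointRates(**raw["endpoint_rates"])
    if "noise_model" in raw:
        raw["noise_model"] = NoiseModel(**raw["noise_model"])
    if "effect_table" in raw:
        raw["effect_table"] = tuple(
            Effect(**{**e, "breeds": tuple(e["breeds"]) if e.get("breeds") else None})
            for e in raw["effect_table"]
        )
    try:
        config = CohortConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(f"config file {path}: {exc}") from exc
    config.validate()
    return config
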