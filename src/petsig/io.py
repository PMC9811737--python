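"""File formats: cohort TSV, curve CSV, model/fit JSON, YAML config.

Conventions: survival times are months (`time_months`), kinetic times are
minutes (`time_min`) — the column names enforce the unit split.  Every
generated artifact may carry a JSON sidecar with its generating config.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CohortTable, SchemaError, TimeActivityCurve, REQUIRED_COLUMNS
from .simulate import CLINICAL_COLUMNS

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_curve",
    "write_curve",
    "write_json",
    "read_yaml_config",
]

#: Columns never interpreted as genes when reading a cohort table.
RESERVED_COLUMNS = set(REQUIRED_COLUMNS) | set(CLINICAL_COLUMNS)


def write_cohort(cohort: CohortTable, path: str | Path, sidecar: dict | None = None) -> Path:
    """Cohort as TSV (patient_id, time_months, event, clinical..., genes...)
    plus an optional JSON sidecar with the generating config."""
    path = Path(path)
    cols = (
        list(REQUIRED_COLUMNS)
        + [c for c in cohort.clinical_cols]
        + [g for g in cohort.gene_cols]
    )
    cohort.data[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")
    if sidecar is not None:
        write_json(sidecar, path.with_suffix(path.suffix + ".json"))
    return path


def read_cohort(path: str | Path, clinical_cols: tuple[str, ...] | None = None) -> CohortTable:
    """Read a cohort TSV/CSV; genes are all columns outside the reserved
    clinical/outcome set."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    if clinical_cols is None:
        clinical_cols = tuple(c for c in CLINICAL_COLUMNS if c in df.columns)
    reserved = set(REQUIRED_COLUMNS) | set(clinical_cols)
    genes = tuple(c for c in df.columns if c not in reserved)
    for g in genes:
        if not np.issubdtype(df[g].dtype, np.number):
            raise SchemaError(f"{path.name}: non-numeric expression column {g!r}")
    n_missing = int(df[list(genes)].isna().sum().sum()) if genes else 0
    if n_missing:
        raise SchemaError(f"{path.name}: {n_missing} missing expression value(s)")
    return CohortTable(data=df, gene_cols=genes, clinical_cols=tuple(clinical_cols))


def write_curve(curve: TimeActivityCurve, path: str | Path) -> Path:
    """Curve as CSV (time_min, activity_fraction) + JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"time_min": curve.time, "activity_fraction": curve.activity}).to_csv(
        path, index=False, float_format="%.12g"
    )
    write_json(curve.meta, path.with_suffix(path.suffix + ".json"))
    return path


def read_curve(path: str | Path) -> TimeActivityCurve:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_min", "activity_fraction"):
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return TimeActivityCurve(
        time=df["time_min"].to_numpy(float),
        activity=df["activity_fraction"].to_numpy(float),
        meta=meta,
    )


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n")
    return path


def read_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg
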