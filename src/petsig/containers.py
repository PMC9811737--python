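"""Core in-memory containers shared across the pipeline.

A cohort is a patient-by-gene table of z-scored expression values carrying
progression-free survival (PFS) outcome columns and optional clinical
covariates.  A time-activity curve is a minute-sampled record of the fraction
of administered radiotracer dose retained by a cell culture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

#: Columns every cohort table must carry.
REQUIRED_COLUMNS = ("patient_id", "time_months", "event")


class SchemaError(ValueError):
    """A table does not conform to the expected cohort/curve schema."""


@dataclass
class CohortTable:
    """Patient cohort: survival outcome plus z-scored gene expression.

    Parameters
    ----------
    data
        One row per patient.  Must contain ``patient_id`` (unique),
        ``time_months`` (PFS time), ``event`` (1 = progression observed,
        0 = censored), any clinical covariate columns, and one numeric
        column per gene.
    gene_cols
        Names of the gene expression columns.
    clinical_cols
        Names of the clinical covariate columns (may be empty).
    """

    data: pd.DataFrame
    gene_cols: tuple[str, ...]
    clinical_cols: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.gene_cols = tuple(self.gene_cols)
        self.clinical_cols = tuple(self.clinical_cols)
        for col in REQUIRED_COLUMNS:
            if col not in self.data.columns:
                raise SchemaError(f"cohort table missing required column {col!r}")
        if self.data["patient_id"].duplicated().any():
            dup = self.data["patient_id"][self.data["patient_id"].duplicated()].iloc[0]
            raise SchemaError(f"duplicate patient_id {dup!r}")
        missing = [g for g in self.gene_cols if g not in self.data.columns]
        if missing:
            raise SchemaError(f"gene columns absent from table: {missing}")
        expr = self.data[list(self.gene_cols)]
        if not all(np.issubdtype(dt, np.number) for dt in expr.dtypes):
            bad = [c for c, dt in expr.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise SchemaError(f"non-numeric expression column(s): {bad}")
        if (self.data["time_months"] < 0).any():
            raise SchemaError("negative survival times")
        if not self.data["event"].isin((0, 1)).all():
            raise SchemaError("event indicator must be 0/1")

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return self.data["time_months"].to_numpy(float)

    @property
    def events(self) -> np.ndarray:
        return self.data["event"].to_numpy(int)

    @property
    def event_rate(self) -> float:
        return float(self.data["event"].mean())

    @property
    def expression(self) -> pd.DataFrame:
        """Patients x genes z-score matrix."""
        return self.data[list(self.gene_cols)]

    def columns_matrix(self, features: list[str] | tuple[str, ...]) -> np.ndarray:
        """Design matrix for an arbitrary mix of gene and clinical columns."""
        missing = [f for f in features if f not in self.data.columns]
        if missing:
            raise SchemaError(f"feature column(s) absent from cohort: {missing}")
        return self.data[list(features)].to_numpy(float)


@dataclass
class TimeActivityCurve:
    """Minute-sampled radiotracer retention as a fraction of administered dose."""

    time: np.ndarray  # minutes, strictly increasing
    activity: np.ndarray  # fraction of administered dose, in [0, 1]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.activity = np.asarray(self.activity, float)
        if self.time.shape != self.activity.shape:
            raise SchemaError("time and activity must have identical shape")
        if self.time.ndim != 1 or len(self.time) < 2:
            raise SchemaError("curve needs at least two samples")
        if not np.all(np.diff(self.time) > 0):
            raise SchemaError("time must be strictly increasing")
        if np.any(self.activity < 0) or np.any(self.activity > 1):
            raise SchemaError("activity must lie in [0, 1] (fraction of dose)")

    def __len__(self) -> int:
        return len(self.time)
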