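"""Case-control cohort container shared by the simulator, I/O and tests."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = ["Cohort"]


@dataclass
class Cohort:
    """Individuals with disease status and adjustment covariates.

    Parameters
    ----------
    ids : ndarray of str
        Sample identifiers, aligned with every other per-individual array.
    status : ndarray of 0/1
        1 for cases, 0 for controls.
    covariates : DataFrame
        One column per adjustment covariate (sex, age, principal
        components, batch indicators, ...).  May be empty (no columns).
    dataset : str
        Label of the originating dataset (used in per-dataset results and
        for the genomic-control intercept lookup).
    age_at_onset : ndarray of float, optional
        Age at diagnosis in years for cases; NaN for controls / unknown.
    """

    ids: np.ndarray
    status: np.ndarray
    covariates: pd.DataFrame
    dataset: str = "cohort"
    age_at_onset: Optional[np.ndarray] = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.status = np.asarray(self.status, dtype=np.int8)
        n = len(self.ids)
        if len(self.status) != n or len(self.covariates) not in (0, n):
            raise InputError("cohort arrays are not aligned")
        if len(self.covariates) == 0 and self.covariates.shape[1] == 0:
            self.covariates = pd.DataFrame(index=range(n))
        if not np.isin(self.status, (0, 1)).all():
            raise InputError("status must be coded 0/1")
        if self.age_at_onset is not None and len(self.age_at_onset) != n:
            raise InputError("age_at_onset is not aligned with the cohort")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return self.n - self.n_cases

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, status_col: str = "status",
                       id_col: str = "iid",
                       covariate_cols: Optional[list[str]] = None,
                       dataset: str = "cohort",
                       onset_col: Optional[str] = None) -> "Cohort":
        """Build a cohort from a phenotype/covariate table."""
        for col in [status_col, id_col] + (covariate_cols or []):
            if col not in df.columns:
                raise InputError(f"phenotype table lacks column {col!r}")
        onset = None
        if onset_col is not None:
            if onset_col not in df.columns:
                raise InputError(f"phenotype table lacks column {onset_col!r}")
            onset = df[onset_col].to_numpy(dtype=float)
        cov = df[covariate_cols] if covariate_cols else df[[]]
        return cls(ids=df[id_col].to_numpy(), status=df[status_col].to_numpy(),
                   covariates=cov.reset_index(drop=True), dataset=dataset,
                   age_at_onset=onset)
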