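"""Shared in-memory containers and covariate coding.

The pipeline moves two objects around: a gene x sample expression matrix
(log-intensity scale, with a per-sample platform label) and a per-sample
clinical table with right-censored disease-specific survival. The
expression matrix is a thin wrapper over a pandas DataFrame; the clinical
table *is* a pandas DataFrame with a validated schema.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class LungsigError(Exception):
    """Base error for all user-facing failures in this package."""


CLINICAL_COLUMNS = [
    "age",
    "gender",
    "stage",
    "grade",
    "smoking",
    "histology",
    "treatment",
    "radiotherapy",
    "tumor_size_cm",
    "followup_months",
    "dss_event",
]

#: AJCC stage label -> ordinal code used in Cox design matrices.
STAGE_CODES = {
    "I": 1, "IA": 1, "IB": 1,
    "II": 2, "IIA": 2, "IIB": 2,
    "III": 3, "IIIA": 3, "IIIB": 3,
    "IV": 4,
}

SMOKING_LEVELS = ("never", "former", "current", "unknown")


@dataclass
class ExpressionMatrix:
    """Gene x sample log-intensity matrix with per-sample platform labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene (or probe) identifier, columns by sample id.
        Duplicate gene ids are permitted only before probe collapse.
    platform : pandas.Series, optional
        Platform label per sample. Defaults to a single platform "P0".
    """

    values: pd.DataFrame
    platform: pd.Series = field(default=None)

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()]
            raise LungsigError(f"duplicate sample ids: {list(dups[:5])}")
        if self.platform is None:
            self.platform = pd.Series("P0", index=self.values.columns)
        else:
            self.platform = pd.Series(self.platform).reindex(self.values.columns)
            if self.platform.isna().any():
                missing = self.platform.index[self.platform.isna()]
                raise LungsigError(
                    f"samples without a platform label: {list(missing[:5])}"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes].copy(), self.platform.copy())

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(samples)].copy(),
            self.platform.loc[list(samples)].copy(),
        )


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Validate the clinical table schema; returns the table unchanged.

    Required: unique sample-id index, ``followup_months >= 0``,
    ``dss_event`` in {0, 1}, stage labels from the AJCC vocabulary.
    """
    if clinical.index.duplicated().any():
        raise LungsigError("duplicate sample ids in clinical table")
    missing = [c for c in ("followup_months", "dss_event") if c not in clinical.columns]
    if missing:
        raise LungsigError(f"clinical table missing columns: {missing}")
    if (clinical["followup_months"] < 0).any():
        raise LungsigError("negative followup_months")
    if not clinical["dss_event"].isin([0, 1]).all():
        raise LungsigError("dss_event must be 0/1")
    if "stage" in clinical.columns:
        bad = set(clinical["stage"].dropna().unique()) - set(STAGE_CODES)
        if bad:
            raise LungsigError(f"unknown AJCC stage labels: {sorted(bad)}")
    return clinical


def design_matrix(
    clinical: pd.DataFrame,
    covariates,
    risk_group: pd.Series | None = None,
) -> pd.DataFrame:
    """Numeric Cox design matrix for the requested clinical covariates.

    Coding: age continuous (years); gender male=1; stage ordinal (I..IV as
    1..4); grade ordinal 1-3 with unknown imputed to the cohort median;
    smoking categorical with "never" as reference and "unknown" as its own
    level; histology categorical with adenocarcinoma as reference;
    treatment ACT=1; radiotherapy 0/1. ``risk_group`` (0/1 per sample)
    appends a ``risk_group`` column.
    """
    cols: dict[str, np.ndarray] = {}
    n = len(clinical)
    for name in covariates:
        if name == "age":
            cols["age"] = clinical["age"].astype(float).to_numpy()
        elif name == "gender":
            cols["gender_male"] = (
                clinical["gender"].astype(str).str.lower().eq("male").astype(float).to_numpy()
            )
        elif name == "stage":
            cols["stage_ord"] = (
                clinical["stage"].map(STAGE_CODES).astype(float).to_numpy()
            )
        elif name == "grade":
            g = pd.to_numeric(clinical["grade"], errors="coerce")
            g = g.fillna(g.median() if g.notna().any() else 2.0)
            cols["grade_ord"] = g.astype(float).to_numpy()
        elif name == "smoking":
            s = clinical["smoking"].astype(str).str.lower()
            for level in ("former", "current", "unknown"):
                cols[f"smoking_{level}"] = s.eq(level).astype(float).to_numpy()
        elif name == "histology":
            h = clinical["histology"].astype(str).str.lower()
            for level in sorted(set(h.unique()) - {"adenocarcinoma"}):
                cols[f"histology_{level}"] = h.eq(level).astype(float).to_numpy()
        elif name == "treatment":
            cols["treatment_act"] = (
                clinical["treatment"].astype(str).str.upper().eq("ACT").astype(float).to_numpy()
            )
        elif name == "radiotherapy":
            cols["radiotherapy"] = clinical["radiotherapy"].astype(float).to_numpy()
        elif name == "tumor_size_gt3":
            cols["tumor_size_gt3"] = (
                (clinical["tumor_size_cm"].astype(float) > 3.0).astype(float).to_numpy()
            )
        else:
            raise LungsigError(f"unknown covariate: {name!r}")
    Z = pd.DataFrame(cols, index=clinical.index) if cols else pd.DataFrame(index=clinical.index)
    if risk_group is not None:
        rg = pd.Series(risk_group).reindex(clinical.index)
        if rg.isna().any():
            missing_ids = list(rg.index[rg.isna()][:5])
            raise LungsigError(f"risk group missing for samples: {missing_ids}")
        Z = Z.assign(risk_group=rg.astype(float).to_numpy())
    if len(Z) != n:
        raise LungsigError("design matrix / clinical table length mismatch")
    return Z


def child_seed(seed: int, name: str) -> int:
    """Derive a named, reproducible substream seed (< 2**31) from a master seed."""
    entropy = np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    return int(entropy.generate_state(1)[0] % (2**31))
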