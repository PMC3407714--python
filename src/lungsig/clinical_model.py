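"""Comparator "clinical algorithm": age + dichotomized tumor size.

The benchmark against which genomic prognostic signatures are judged: a
Cox regression on age at diagnosis and tumor size dichotomized at 3 cm
(3.0 cm inclusive in the small group), trained on stage I patients, with
the risk score thresholded at a percentile of the training scores to
mirror the genomic signature's class balance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .containers import LungsigError
from .signature import RiskPrediction
from .survstats import censor_at


@dataclass
class ClinicalComparator:
    """Cox risk score on (age, size > 3 cm) with a percentile threshold."""

    coef_age: float
    coef_size: float
    threshold: float
    threshold_percentile: float
    size_degenerate: bool = False

    def score(self, age: float, size_cm: float) -> float:
        if age is None or size_cm is None or not np.isfinite(age) or not np.isfinite(size_cm):
            raise LungsigError("age and tumor size are required")
        return float(self.coef_age * age + self.coef_size * (size_cm > 3.0))

    def to_json(self) -> str:
        return json.dumps(
            {
                "coef_age": self.coef_age,
                "coef_size": self.coef_size,
                "threshold": self.threshold,
                "threshold_percentile": self.threshold_percentile,
                "size_degenerate": self.size_degenerate,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClinicalComparator":
        return cls(**json.loads(text))


def train_clinical(
    clinical: pd.DataFrame,
    threshold_percentile: float = 60.0,
    censor_horizon: float = 60.0,
) -> ClinicalComparator:
    """Fit the comparator on a (caller-filtered, typically stage I) cohort.

    If tumor size does not vary across the 3 cm boundary the size term is
    inestimable; the model degrades to age-only with a warning.
    """
    cl = censor_at(clinical, censor_horizon)
    if cl["dss_event"].sum() == 0:
        raise LungsigError("clinical comparator requires at least one event")
    df = pd.DataFrame(
        {
            "followup_months": cl["followup_months"].astype(float),
            "dss_event": cl["dss_event"].astype(int),
            "age": cl["age"].astype(float),
            "size_gt3": (cl["tumor_size_cm"].astype(float) > 3.0).astype(float),
        }
    )
    size_degenerate = df["size_gt3"].nunique() < 2
    cols = ["age"] if size_degenerate else ["age", "size_gt3"]
    if size_degenerate:
        warnings.warn(
            "tumor size does not vary across 3 cm; clinical comparator degrades to age only"
        )
    cph = CoxPHFitter()
    cph.fit(df[["followup_months", "dss_event"] + cols], "followup_months", "dss_event")
    coef_age = float(cph.params_["age"])
    coef_size = 0.0 if size_degenerate else float(cph.params_["size_gt3"])
    scores = coef_age * df["age"].to_numpy() + coef_size * df["size_gt3"].to_numpy()
    threshold = float(np.percentile(scores, threshold_percentile, method="linear"))
    return ClinicalComparator(
        coef_age=coef_age,
        coef_size=coef_size,
        threshold=threshold,
        threshold_percentile=float(threshold_percentile),
        size_degenerate=size_degenerate,
    )


def classify_clinical(model: ClinicalComparator, age: float, size_cm: float) -> RiskPrediction:
    """High-risk iff score strictly exceeds the threshold (ties go low-risk)."""
    s = model.score(age, size_cm)
    label = "high-risk" if s > model.threshold else "low-risk"
    return RiskPrediction(index=s, class_label=label, coverage=1.0)


def classify_clinical_cohort(model: ClinicalComparator, clinical: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for sid, row in clinical.iterrows():
        pred = classify_clinical(model, float(row["age"]), float(row["tumor_size_cm"]))
        rows.append((sid, pred.index, pred.class_label, pred.coverage, ""))
    return pd.DataFrame(
        rows, columns=["sample_id", "index", "class", "coverage", "error"]
    ).set_index("sample_id")
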