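"""Cross-validated multivariate Cox gene selection.

Each candidate gene is tested in its own proportional-hazards model
containing the gene *plus* the clinical covariates jointly, so that
selected genes are associated with outcome independently of age, stage,
grade, gender and smoking history. Selection is a consensus over
stratified cross-validation rounds: in each round the per-gene model is
refitted on the training portion, and a gene is recorded when its Wald
p-value clears the significance threshold; genes significant in at least
``min_rounds`` rounds make the signature. The fold-consensus rule is the
false-discovery control mechanism — no explicit multiple-testing
correction is applied on top of it.

The same machinery, with the stage-1 risk group appended to the
covariates and a shorter censoring horizon, selects treatment-response
genes conditional on prognosis (stage 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._cox import cox_fit_per_gene
from .containers import ExpressionMatrix, LungsigError, design_matrix
from .survstats import censor_at

DEFAULT_COVARIATES = ("age", "gender", "stage", "grade", "smoking")


@dataclass
class SelectionConfig:
    """Knobs of the consensus selector.

    ``censor_horizon`` is in months: 60 for prognosis, 36 for treatment
    response. ``min_rounds`` is the number of cross-validation rounds in
    which a gene must reach ``p_threshold`` to be selected.
    """

    p_threshold: float = 0.001
    n_folds: int = 10
    min_rounds: int = 2
    covariates: tuple = DEFAULT_COVARIATES
    censor_horizon: float = 60.0
    seed: int = 0

    def validate(self, n_samples: int):
        if not (0.0 < self.p_threshold <= 1.0):
            raise LungsigError("invalid SelectionConfig.p_threshold")
        if not (2 <= self.n_folds <= n_samples):
            raise LungsigError("invalid SelectionConfig.n_folds")
        if not (1 <= self.min_rounds <= self.n_folds):
            raise LungsigError("invalid SelectionConfig.min_rounds")
        return self


@dataclass
class SelectionResult:
    """Outcome of consensus gene selection."""

    selected_gene_ids: list
    per_gene_fold_counts: dict
    per_gene_final_p: dict
    n_nonconvergent: int = 0
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        genes = list(self.per_gene_fold_counts)
        return pd.DataFrame(
            {
                "gene_id": genes,
                "fold_count": [self.per_gene_fold_counts[g] for g in genes],
                "final_p": [self.per_gene_final_p.get(g, np.nan) for g in genes],
                "selected": [g in set(self.selected_gene_ids) for g in genes],
            }
        ).set_index("gene_id")


def fit_cox_gene(
    gene_values,
    clinical: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    censor_horizon: float = 60.0,
    risk_group: pd.Series | None = None,
):
    """Cox model of one gene plus covariates; returns (coefficient, wald_p).

    Survival is censored at the horizon before fitting. A zero-variance
    or non-convergent gene returns ``(nan, nan)`` rather than raising.
    """
    cl = censor_at(clinical, censor_horizon)
    if cl["dss_event"].sum() == 0:
        raise LungsigError("no events after censoring at horizon")
    Z = design_matrix(cl, covariates, risk_group=risk_group)
    g = np.asarray(gene_values, dtype=float)[None, :]
    beta, p, conv = cox_fit_per_gene(
        g, Z.to_numpy(), cl["followup_months"].to_numpy(), cl["dss_event"].to_numpy()
    )
    if not conv[0]:
        return float("nan"), float("nan")
    return float(beta[0]), float(p[0])


def _stratified_folds(event: np.ndarray, n_folds: int, seed: int):
    """Event-stratified fold assignment; every training portion keeps events."""
    if event.sum() < n_folds and event.sum() < 2:
        raise LungsigError("too few events to form event-bearing folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    for train_idx, _test_idx in skf.split(np.zeros(len(event)), event):
        if event[train_idx].sum() == 0:
            raise LungsigError("fold with zero events; cannot stratify")
        folds.append(train_idx)
    return folds


def cv_select_genes(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    config: SelectionConfig,
    risk_group: pd.Series | None = None,
) -> SelectionResult:
    """Consensus gene selection over stratified cross-validation rounds.

    In each of ``n_folds`` rounds, every gene is refitted (gene + covariates)
    on that round's training portion; a gene scores the round when its
    Wald p-value is below ``p_threshold``. Genes scoring at least
    ``min_rounds`` rounds are selected (ordered as in the input matrix).
    Deterministic under (data, config, seed).
    """
    config.validate(len(clinical))
    samples = list(expr.values.columns)
    if set(samples) != set(clinical.index):
        raise LungsigError("expression and clinical tables cover different samples")
    cl = censor_at(clinical.loc[samples], config.censor_horizon)
    time = cl["followup_months"].to_numpy(dtype=float)
    event = cl["dss_event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise LungsigError("no events after censoring at horizon")
    rg = None
    if risk_group is not None:
        rg = pd.Series(risk_group).reindex(cl.index)
        if rg.isna().any():
            missing = list(rg.index[rg.isna()][:5])
            raise LungsigError(f"prognosis risk group missing for samples: {missing}")
    Z = design_matrix(cl, config.covariates, risk_group=rg).to_numpy()
    G = expr.values.to_numpy(dtype=float)
    genes = list(expr.values.index)

    counts = np.zeros(len(genes), dtype=int)
    any_nonconv = np.zeros(len(genes), dtype=bool)
    for train_idx in _stratified_folds(event, config.n_folds, config.seed):
        _, pvals, conv = cox_fit_per_gene(
            G[:, train_idx], Z[train_idx], time[train_idx], event[train_idx]
        )
        counts += ((pvals < config.p_threshold) & conv).astype(int)
        any_nonconv |= ~conv

    _, final_p, final_conv = cox_fit_per_gene(G, Z, time, event)
    selected = [
        g
        for i, g in enumerate(genes)
        if counts[i] >= config.min_rounds and final_conv[i]
    ]
    return SelectionResult(
        selected_gene_ids=selected,
        per_gene_fold_counts={g: int(counts[i]) for i, g in enumerate(genes)},
        per_gene_final_p={g: float(final_p[i]) for i, g in enumerate(genes)},
        n_nonconvergent=int((~final_conv).sum()),
        config=asdict(config) | {"covariates": list(config.covariates)},
    )


def select_response_genes(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    prognosis_calls: pd.Series,
    config: SelectionConfig,
) -> SelectionResult:
    """Stage-2 selection: genes tied to outcome *given* the prognosis call.

    All samples must be ACT-treated (the stage-2 training setting), and
    ``prognosis_calls`` — 0/1 risk classes from a frozen stage-1 model —
    joins the covariates, so purely prognostic genes are conditioned away.
    """
    if not clinical["treatment"].astype(str).str.upper().eq("ACT").all():
        raise LungsigError("stage-2 selection requires an all-ACT-treated cohort")
    calls = pd.Series(prognosis_calls).reindex(clinical.index)
    if calls.isna().any():
        missing = list(calls.index[calls.isna()][:5])
        raise LungsigError(f"prognosis_calls missing for samples: {missing}")
    return cv_select_genes(expr, clinical, config, risk_group=calls.astype(float))
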