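"""End-to-end study orchestration: train, validate, benefit analysis.

These functions are the library surface behind the command-line
interface: each consumes in-memory objects and returns (model, report)
pairs, with all file handling left to :mod:`lungsig.io` / the CLI.

Order of operations for training mirrors the study design: genes are
selected on median-centered log intensities; only after selection are
the selected genes percent-rank stabilized and the principal-component
index trained on them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import survstats
from .containers import ExpressionMatrix, LungsigError, design_matrix
from .preprocess import fit_ecdf, median_center, percent_rank_matrix
from .select import SelectionConfig, cv_select_genes, select_response_genes
from .signature import SignatureModel, classify_cohort, risk_groups, train_signature

STAGE2_COVARIATES = ("age", "stage", "gender", "smoking")


def _cv_risk_group_table(
    expr_sel: ExpressionMatrix,
    clinical: pd.DataFrame,
    k: int,
    threshold_percentile: float,
    config: SelectionConfig,
) -> dict:
    """Cross-validated training risk-group Cox table.

    Fold-wise: the signature is retrained on each training portion (gene
    list fixed to the full-data selection) and applied to the held-out
    samples; the assembled out-of-fold calls are tested in a
    covariate-adjusted Cox model.
    """
    from .select import _stratified_folds

    samples = np.array(expr_sel.values.columns)
    event = clinical.loc[samples, "dss_event"].to_numpy(dtype=int)
    calls = pd.Series(np.nan, index=samples)
    for train_idx in _stratified_folds(event, config.n_folds, config.seed):
        held = np.setdiff1d(np.arange(len(samples)), train_idx)
        tr_expr = expr_sel.subset_samples(samples[train_idx])
        ref = fit_ecdf(tr_expr)
        pr = percent_rank_matrix(ref, tr_expr)
        try:
            m = train_signature(
                pr, clinical.loc[samples[train_idx]], k=k,
                threshold_percentile=threshold_percentile,
                censor_horizon=config.censor_horizon,
            )
        except LungsigError:
            continue
        preds = classify_cohort(m, expr_sel.subset_samples(samples[held]))
        calls.loc[samples[held]] = (preds["class"] == m.label_above).astype(float).to_numpy()
    ok = calls.notna()
    cl = survstats.censor_at(clinical.loc[samples[ok.to_numpy()]], config.censor_horizon)
    Z = design_matrix(cl, ("age", "gender", "stage"))
    df = pd.concat([cl[["followup_months", "dss_event"]], Z], axis=1)
    df["risk_group"] = calls[ok].to_numpy()
    try:
        summ = survstats.cox_multivariate(
            df, "followup_months", "dss_event", "risk_group",
            covariate_cols=list(Z.columns),
        )
        return {"cv_risk_group_cox": summ.to_jsonable(), "n_crossvalidated": int(ok.sum())}
    except LungsigError as err:
        return {"cv_risk_group_cox": None, "error": str(err), "n_crossvalidated": int(ok.sum())}


def train_prognostic(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    selection: SelectionConfig | None = None,
    threshold_percentile: float = 60.0,
    k: int = 1,
    allow_treated: bool = False,
):
    """Stage 1: select prognostic genes and train the prognostic index.

    The training cohort must be adjuvant-therapy naive (no ACT, no
    radiotherapy) unless ``allow_treated`` is set.
    """
    selection = selection or SelectionConfig(censor_horizon=60.0)
    treated = clinical["treatment"].astype(str).str.upper().eq("ACT") | (
        clinical.get("radiotherapy", 0) == 1
    )
    if treated.any() and not allow_treated:
        raise LungsigError(
            f"{int(treated.sum())} treated samples in the prognostic training cohort; "
            "pass allow_treated=True (--allow-treated) to override"
        )
    centered = median_center(expr)
    sel = cv_select_genes(centered, clinical, selection)
    if not sel.selected_gene_ids:
        counts = sorted(sel.per_gene_fold_counts.values(), reverse=True)[:5]
        raise LungsigError(
            "gene selection produced zero genes "
            f"(best fold counts: {counts}, threshold p<{selection.p_threshold}, "
            f"min_rounds={selection.min_rounds})"
        )
    expr_sel = centered.subset_genes(sel.selected_gene_ids)
    ref = fit_ecdf(expr_sel)
    pr = percent_rank_matrix(ref, expr_sel)
    model = train_signature(
        pr, clinical, k=k, threshold_percentile=threshold_percentile,
        censor_horizon=selection.censor_horizon,
        label_above="high-risk", label_below="low-risk",
    )
    report = {
        "n_selected_genes": len(sel.selected_gene_ids),
        "selection_config": sel.config,
        "threshold_percentile": model.threshold_percentile,
        "n_training_samples": len(clinical),
    }
    report.update(
        _cv_risk_group_table(expr_sel, clinical, k, threshold_percentile, selection)
    )
    return model, sel, report


def train_predictive(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    prognostic_model: SignatureModel,
    selection: SelectionConfig | None = None,
    threshold_percentile: float = 50.0,
    k: int = 2,
):
    """Stage 2: select ACT-response genes conditional on the prognosis call.

    All training samples must be ACT-treated. The prognosis risk group,
    computed with the frozen stage-1 model, joins the Cox covariates, and
    the predictive index is a two-component classifier thresholded at the
    median of the training indices.
    """
    if not clinical["treatment"].astype(str).str.upper().eq("ACT").all():
        raise LungsigError("stage-2 training requires an all-ACT-treated cohort")
    selection = selection or SelectionConfig(
        covariates=STAGE2_COVARIATES, censor_horizon=36.0
    )
    centered = median_center(expr)
    prog_preds = classify_cohort(prognostic_model, centered, rank_mode="within")
    bad = prog_preds["error"] != ""
    if bad.any():
        raise LungsigError(
            f"prognosis calls unavailable for samples: {list(prog_preds.index[bad][:5])}"
        )
    calls = risk_groups(prog_preds, prognostic_model)
    sel = select_response_genes(centered, clinical, calls, selection)
    if not sel.selected_gene_ids:
        raise LungsigError("stage-2 gene selection produced zero genes")
    expr_sel = centered.subset_genes(sel.selected_gene_ids)
    ref = fit_ecdf(expr_sel)
    pr = percent_rank_matrix(ref, expr_sel)
    model = train_signature(
        pr, clinical, k=k, threshold_percentile=threshold_percentile,
        censor_horizon=selection.censor_horizon,
        label_above="ACT-non-responder", label_below="ACT-responder",
        adjustment=prog_preds["index"],  # decouple component weights from prognosis
    )
    report = {
        "n_selected_genes": len(sel.selected_gene_ids),
        "selection_config": sel.config,
        "threshold_percentile": model.threshold_percentile,
        "n_training_samples": len(clinical),
    }
    return model, sel, report


def score_cohort(
    model: SignatureModel,
    expr: ExpressionMatrix,
    min_coverage=0.5,
    rank_mode: str = "within",
):
    """Median-center a cohort within its platforms, then classify it.

    Cohort-level scoring defaults to within-cohort percent-ranking (the
    multi-platform validation convention); pass ``rank_mode="model"`` for
    the frozen-reference deployment convention.
    """
    return classify_cohort(
        model, median_center(expr), min_coverage=min_coverage, rank_mode=rank_mode
    )


def validate_cohort(
    model: SignatureModel,
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    censor_horizon: float = 60.0,
    roc_event_horizons=(60.0, 24.0),
    roc_min_followup: float = 12.0,
    roc_late_exclusion: float = 36.0,
    adjust_covariates=("age", "gender", "stage", "radiotherapy"),
) -> dict:
    """Apply a trained signature to an independent cohort and evaluate it.

    Produces per-sample predictions plus Kaplan–Meier curves, the
    high-vs-low log-rank test, covariate-adjusted Cox HR for the risk
    group, and time-thresholded ROC AUCs under the stated exclusion
    rules. Overlap between training and validation sample ids triggers a
    loud warning (naming the samples) rather than an error.
    """
    overlap = sorted(set(model.training_sample_ids) & set(expr.values.columns))
    if overlap:
        warnings.warn(
            f"{len(overlap)} validation samples overlap the training series: "
            f"{overlap[:10]}{'...' if len(overlap) > 10 else ''}"
        )
    preds = score_cohort(model, expr)
    scored = preds[preds["error"] == ""]
    if scored.empty:
        raise LungsigError("no scorable samples in validation cohort")
    cl = survstats.censor_at(clinical.loc[scored.index], censor_horizon)
    group = (scored["class"] == model.label_above).astype(int)

    report: dict = {
        "n_scored": int(len(scored)),
        "n_unscored": int((preds["error"] != "").sum()),
        "mean_coverage": float(scored["coverage"].mean()),
        "class_counts": scored["class"].value_counts().to_dict(),
        "overlap_samples": overlap,
    }
    if group.nunique() == 2 and cl["dss_event"].sum() > 0:
        chi2, p = survstats.logrank(cl["followup_months"], cl["dss_event"], group)
        report["logrank"] = {"chi2": chi2, "p": p}
        km = {
            label: survstats.km_estimate(g["followup_months"], g["dss_event"])
            for label, g in cl.groupby(scored["class"])
        }
        report["km_curves"] = {
            k: v.to_dict(orient="list") for k, v in km.items()
        }
        Z = design_matrix(cl, adjust_covariates)
        df = pd.concat([cl[["followup_months", "dss_event"]], Z], axis=1)
        df["risk_group"] = group.to_numpy(dtype=float)
        try:
            summ = survstats.cox_multivariate(
                df, "followup_months", "dss_event", "risk_group",
                covariate_cols=list(Z.columns),
            )
            report["adjusted_cox"] = summ.to_jsonable()
        except LungsigError as err:
            report["adjusted_cox"] = {"error": str(err)}
    rocs = {}
    for horizon in roc_event_horizons:
        labels, included = survstats.dss_outcome_labels(
            cl, horizon, roc_min_followup, roc_late_exclusion
        )
        lab = labels[included]
        sc = scored.loc[lab.index, "index"]
        if lab.nunique() == 2:
            auc, lo, hi, p = survstats.roc_auc(sc.to_numpy(), lab.to_numpy())
            rocs[f"{int(horizon)}m"] = {
                "auc": auc, "ci_low": lo, "ci_high": hi, "p_vs_0.5": p,
                "n": int(included.sum()),
            }
    report["roc"] = rocs
    return report, preds


def benefit_analysis(
    model: SignatureModel,
    expr: ExpressionMatrix,
    clinical_rct: pd.DataFrame,
    censor_horizon: float = 36.0,
    covariates=("age", "gender", "stage", "histology"),
):
    """Per-predicted-class ACT-vs-OBS analysis on a randomized cohort."""
    preds = score_cohort(model, expr)
    scored = preds[preds["error"] == ""]
    if scored.empty:
        raise LungsigError("no scorable samples in RCT cohort")
    res = survstats.treatment_benefit(
        clinical_rct.loc[scored.index],
        scored["class"],
        covariates=covariates,
        censor_horizon=censor_horizon,
    )
    report = {
        cls: summary.to_jsonable() for cls, summary in res.items()
    }
    report["class_counts"] = scored["class"].value_counts().to_dict()
    return report, preds, res


def selection_config_from_dict(d: dict) -> SelectionConfig:
    cfg = SelectionConfig()
    for key, value in (d or {}).items():
        if not hasattr(cfg, key):
            raise LungsigError(f"unknown selection config field: {key!r}")
        if key == "covariates":
            value = tuple(value)
        setattr(cfg, key, value)
    return cfg
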