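"""Principal-component risk/response index over percent-ranked genes.

A signature is: the selected gene list, frozen per-gene training ECDFs,
the per-gene percent-rank means, the top-k principal-component loadings
of the mean-centered percent-rank matrix (k=1 for the prognostic index,
k=2 for the treatment-response index), a survival-supervised combination
of the component scores, an orientation sign chosen so that a higher
index means higher hazard, and a percentile threshold on the oriented
training indices that dichotomizes patients. New samples are scorable
even when the assay covers only part of the gene list: missing genes'
loadings are dropped and the projection is rescaled per component by the
ratio of full to available loading norms, keeping the index scale
comparable across coverage levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._cox import cox_fit
from .containers import ExpressionMatrix, LungsigError
from .preprocess import EcdfReference, _percent_rank_sorted
from .survstats import censor_at


@dataclass
class SignatureModel:
    """A trained principal-component survival signature."""

    gene_ids: list
    ecdf_ref: EcdfReference
    gene_means: np.ndarray  # per-gene percent-rank mean in training
    loadings: np.ndarray  # genes x k, orthonormal columns
    combination_weights: np.ndarray  # per component
    orientation: int  # +1 / -1 so that higher index => higher hazard
    threshold: float
    threshold_percentile: float
    label_above: str = "high-risk"
    label_below: str = "low-risk"
    percent_rank_mode: str = "percentrank"
    quantile_convention: str = "linear"  # numpy 'linear' (type-7) quantile
    training_sample_ids: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "gene_ids": list(self.gene_ids),
                "ecdf_ref": self.ecdf_ref.to_jsonable(),
                "gene_means": np.asarray(self.gene_means).tolist(),
                "loadings": np.asarray(self.loadings).tolist(),
                "combination_weights": np.asarray(self.combination_weights).tolist(),
                "orientation": int(self.orientation),
                "threshold": float(self.threshold),
                "threshold_percentile": float(self.threshold_percentile),
                "label_above": self.label_above,
                "label_below": self.label_below,
                "percent_rank_mode": self.percent_rank_mode,
                "quantile_convention": self.quantile_convention,
                "training_sample_ids": list(self.training_sample_ids),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        o = json.loads(text)
        return cls(
            gene_ids=o["gene_ids"],
            ecdf_ref=EcdfReference.from_jsonable(o["ecdf_ref"]),
            gene_means=np.asarray(o["gene_means"], dtype=float),
            loadings=np.asarray(o["loadings"], dtype=float),
            combination_weights=np.asarray(o["combination_weights"], dtype=float),
            orientation=int(o["orientation"]),
            threshold=float(o["threshold"]),
            threshold_percentile=float(o["threshold_percentile"]),
            label_above=o["label_above"],
            label_below=o["label_below"],
            percent_rank_mode=o["percent_rank_mode"],
            quantile_convention=o["quantile_convention"],
            training_sample_ids=o.get("training_sample_ids", []),
        )


@dataclass
class RiskPrediction:
    """Continuous index, discrete class, and gene coverage at scoring time."""

    index: float
    class_label: str
    coverage: float


def train_signature(
    expr_percentrank: ExpressionMatrix,
    clinical: pd.DataFrame,
    k: int = 1,
    threshold_percentile: float = 60.0,
    ecdf_ref: EcdfReference | None = None,
    label_above: str = "high-risk",
    label_below: str = "low-risk",
    censor_horizon: float = 60.0,
    adjustment: pd.Series | None = None,
    combination: str = "sign",
) -> SignatureModel:
    """Train the principal-component index on a percent-ranked gene matrix.

    ``expr_percentrank`` holds the selected genes only, already percent-rank
    transformed (values in [0,1]). Loadings are the top-k right singular
    vectors of the mean-centered matrix. For k=1 the single component is
    the index; for k=2 the two component scores are combined with their
    joint Cox coefficients on the training survival (censored at
    ``censor_horizon``). The orientation sign is flipped if needed so a
    higher index implies higher hazard, and the classification threshold
    is the stated percentile (linear-interpolation quantile) of the
    oriented training indices.

    ``adjustment`` (per-sample, aligned to the training samples) is an
    optional nuisance score — typically the stage-1 prognostic index when
    training the treatment-response signature — included as a covariate
    in the component-weighting and orientation Cox fits but not in the
    index itself, so component weights reflect outcome association
    *independent of* the adjustment.
    """
    if k not in (1, 2):
        raise LungsigError("component count k must be 1 or 2")
    V = expr_percentrank.values
    if V.isna().any().any():
        raise LungsigError("training percent-rank matrix must be complete")
    n = V.shape[1]
    if n < k + 1:
        raise LungsigError("need at least k+1 training samples")
    genes = list(V.index)
    M = V.to_numpy(dtype=float).T  # samples x genes
    means = M.mean(axis=0)
    C = M - means
    if np.allclose(C, 0.0):
        raise LungsigError("all-constant percent-rank matrix")
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    if int(np.sum(s > s[0] * 1e-12)) < k:
        raise LungsigError(f"matrix rank below requested k={k}")
    loadings = Vt[:k].T  # genes x k
    # deterministic sign: largest-|.| entry of each loading positive
    for j in range(k):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    scores = C @ loadings  # samples x k

    cl = censor_at(clinical.loc[list(V.columns)], censor_horizon)
    time = cl["followup_months"].to_numpy(dtype=float)
    event = cl["dss_event"].to_numpy(dtype=int)
    adj = None
    if adjustment is not None:
        adj = pd.Series(adjustment).reindex(V.columns).to_numpy(dtype=float)[:, None]
        if not np.isfinite(adj).all():
            raise LungsigError("adjustment score missing for some training samples")
    if k == 1:
        weights = np.array([1.0])
    else:
        design = scores if adj is None else np.column_stack([scores, adj])
        fit = cox_fit(design, time, event)
        if not fit.converged:
            raise LungsigError("component-combination Cox fit did not converge")
        if combination == "cox":
            weights = fit.coef[:k].copy()
        elif combination == "sign":
            # survival-determined signs on the natural PCA score scale: the
            # Cox *magnitudes* overfit badly at typical stage-2 sample sizes
            # (the selected genes' in-sample outcome association is inflated),
            # whereas the component variances are stable
            weights = np.where(fit.coef[:k] < 0, -1.0, 1.0)
        else:
            raise LungsigError("combination must be 'sign' or 'cox'")
    raw_index = scores @ weights
    odesign = raw_index[:, None] if adj is None else np.column_stack([raw_index, adj])
    orient_fit = cox_fit(odesign, time, event)
    orientation = -1 if orient_fit.coef[0] < 0 else 1
    index = orientation * raw_index
    threshold = float(np.percentile(index, threshold_percentile, method="linear"))
    if ecdf_ref is None:
        ecdf_ref = EcdfReference({g: np.sort(V.loc[g].to_numpy(dtype=float)) for g in genes})
    ref = EcdfReference({g: ecdf_ref.references[g] for g in genes})
    return SignatureModel(
        gene_ids=genes,
        ecdf_ref=ref,
        gene_means=means,
        loadings=loadings,
        combination_weights=weights,
        orientation=orientation,
        threshold=threshold,
        threshold_percentile=float(threshold_percentile),
        label_above=label_above,
        label_below=label_below,
        training_sample_ids=list(V.columns),
    )


def _project_partial(model: SignatureModel, pr: np.ndarray, available: np.ndarray):
    """Project a (possibly incomplete) centered percent-rank vector.

    Missing genes' loadings are dropped; each component is rescaled by
    ||full loading|| / ||available loading||. At full coverage this equals
    the full projection exactly.
    """
    centered = pr - model.gene_means
    comps = np.zeros(model.k)
    for j in range(model.k):
        col = model.loadings[:, j]
        avail_col = col[available]
        norm_avail = np.linalg.norm(avail_col)
        if norm_avail == 0:
            continue
        scale = np.linalg.norm(col) / norm_avail
        comps[j] = float(centered[available] @ avail_col) * scale
    return comps


def compute_index(
    model: SignatureModel, sample_expr, min_coverage: float = 0.5
) -> RiskPrediction:
    """Score one sample from a {gene: log-intensity} mapping.

    Available signature genes are percent-ranked against the frozen
    training reference, centered by the training means, projected onto
    the (coverage-rescaled) loadings, combined, oriented and thresholded.
    An index exactly at the threshold takes the below-threshold class.
    """
    genes = model.gene_ids
    pr = np.full(len(genes), np.nan)
    for i, g in enumerate(genes):
        v = sample_expr.get(g) if hasattr(sample_expr, "get") else None
        if v is not None and np.isfinite(v):
            pr[i] = _percent_rank_sorted(
                model.ecdf_ref.references[g], float(v), model.percent_rank_mode
            )
    available = np.isfinite(pr)
    coverage = float(available.mean())
    if coverage < min_coverage:
        missing = [g for g, ok in zip(genes, available) if not ok]
        raise LungsigError(
            f"coverage {coverage:.2f} below minimum {min_coverage:.2f}; "
            f"missing genes: {missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    pr_filled = np.where(available, pr, model.gene_means)  # centered to 0 below
    comps = _project_partial(model, pr_filled, available)
    index = float(model.orientation * (comps @ model.combination_weights))
    label = model.label_above if index > model.threshold else model.label_below
    return RiskPrediction(index=index, class_label=label, coverage=coverage)


def classify_cohort(
    model: SignatureModel,
    expr: ExpressionMatrix,
    min_coverage: float = 0.5,
    rank_mode: str = "model",
) -> pd.DataFrame:
    """Score every sample of a cohort; per-sample failures are isolated.

    ``rank_mode="model"`` percent-ranks each gene against the frozen
    training reference (the single-sample deployment convention);
    ``rank_mode="within"`` ranks each gene against the cohort itself,
    which immunizes the index against cohort-level location shifts and is
    the convention for multi-platform validation series.

    Returns a DataFrame indexed by sample id with columns ``index``,
    ``class``, ``coverage`` and ``error`` (empty string when scored).
    """
    genes = model.gene_ids
    sub = expr.values.reindex(genes)
    arr = sub.to_numpy(dtype=float)
    if rank_mode == "within":
        refs = {}
        for i, g in enumerate(genes):
            vals = arr[i][np.isfinite(arr[i])]
            if vals.size >= 2:
                refs[g] = np.sort(vals)
            elif g in model.ecdf_ref.references:
                refs[g] = model.ecdf_ref.references[g]
    elif rank_mode == "model":
        refs = model.ecdf_ref.references
    else:
        raise LungsigError("rank_mode must be 'model' or 'within'")
    pr = np.full(arr.shape, np.nan)
    for i, g in enumerate(genes):
        if g not in refs:
            continue
        r = refs[g]
        for j in range(arr.shape[1]):
            if np.isfinite(arr[i, j]):
                pr[i, j] = _percent_rank_sorted(r, float(arr[i, j]), model.percent_rank_mode)
    rows = []
    for j, sid in enumerate(expr.values.columns):
        col = pr[:, j]
        available = np.isfinite(col)
        coverage = float(available.mean()) if len(col) else 0.0
        if coverage < min_coverage:
            missing = [g for g, ok in zip(genes, available) if not ok]
            rows.append((sid, np.nan, "", np.nan,
                         f"coverage {coverage:.2f} below minimum {min_coverage:.2f}; "
                         f"missing genes: {missing[:10]}{'...' if len(missing) > 10 else ''}"))
            continue
        filled = np.where(available, col, model.gene_means)
        comps = _project_partial(model, filled, available)
        index = float(model.orientation * (comps @ model.combination_weights))
        label = model.label_above if index > model.threshold else model.label_below
        rows.append((sid, index, label, coverage, ""))
    return pd.DataFrame(
        rows, columns=["sample_id", "index", "class", "coverage", "error"]
    ).set_index("sample_id")


def risk_groups(predictions: pd.DataFrame, model: SignatureModel) -> pd.Series:
    """0/1 risk-group coding (1 = above-threshold class) from predictions."""
    return (predictions["class"] == model.label_above).astype(float)
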