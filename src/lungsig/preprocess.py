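"""Expression preprocessing: median centering, probe collapse, percent-rank.

The chain mirrors common multi-platform microarray practice: log
intensities are median-centered within each platform, redundant probes
are collapsed to the probe with the highest mean intensity, and — for
the genes that enter a signature — values are stabilized by conversion
to percent-ranks against a frozen training reference, which makes the
index comparable across array generations.

Two percent-rank conventions exist in common software: the interpolated
"PERCENTRANK" convention (rank scaled by n-1, linear interpolation
between order statistics, primary here) and the empirical-CDF convention
(k/n). Both are provided; see :func:`percent_rank`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, LungsigError


def median_center(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene at zero median, independently within each platform.

    Missing values are excluded from medians and left missing. Idempotent.
    """
    values = expr.values.copy()
    for plat, samples in expr.platform.groupby(expr.platform).groups.items():
        cols = list(samples)
        if len(cols) == 0:
            raise LungsigError(f"platform {plat!r} has zero samples")
        block = values[cols]
        values[cols] = block.sub(block.median(axis=1, skipna=True), axis=0)
    return ExpressionMatrix(values, expr.platform.copy())


def collapse_probes(expr: ExpressionMatrix, probe_to_gene: dict) -> ExpressionMatrix:
    """Collapse probes to one row per gene, keeping the max-mean probe.

    ``probe_to_gene`` maps probe id -> gene id; unmapped probes are
    dropped. For each gene the retained row is the probe with the highest
    mean intensity across all samples; ties keep the probe earliest in
    input order.
    """
    if not probe_to_gene:
        raise LungsigError("empty probe-to-gene mapping")
    means = expr.values.mean(axis=1, skipna=True).to_numpy()
    best: dict[str, int] = {}  # gene -> row position
    probes = list(expr.values.index)
    for pos, probe in enumerate(probes):
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        if gene not in best or means[pos] > means[best[gene]]:
            best[gene] = pos
    if not best:
        raise LungsigError("no probes map to any gene")
    positions = list(best.values())
    out = expr.values.iloc[positions].copy()
    out.index = pd.Index(list(best.keys()), name="gene_id")
    return ExpressionMatrix(out, expr.platform.copy())


@dataclass
class EcdfReference:
    """Per-gene sorted reference values from a training cohort."""

    references: dict = field(default_factory=dict)  # gene -> sorted np.ndarray

    @property
    def gene_ids(self):
        return list(self.references)

    def to_jsonable(self):
        return {g: np.asarray(v).tolist() for g, v in self.references.items()}

    @classmethod
    def from_jsonable(cls, obj):
        return cls({g: np.asarray(v, dtype=float) for g, v in obj.items()})


def fit_ecdf(expr: ExpressionMatrix) -> EcdfReference:
    """Freeze each gene's sorted training values as a percent-rank reference."""
    if expr.values.shape[1] < 2:
        raise LungsigError("ECDF reference requires at least 2 samples")
    refs = {}
    for gene, row in expr.values.iterrows():
        vals = row.to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise LungsigError(f"gene {gene!r} has all-missing values")
        refs[gene] = np.sort(vals)
    return EcdfReference(refs)


def _percent_rank_sorted(ref: np.ndarray, value: float, mode: str) -> float:
    n = ref.size
    if mode == "ecdf":
        return float(np.searchsorted(ref, value, side="right")) / n
    if n == 1:
        return 0.0 if value < ref[0] else 1.0 if value > ref[0] else 0.5
    if value <= ref[0]:
        return 0.0
    if value >= ref[-1]:
        return 1.0
    i = int(np.searchsorted(ref, value, side="left"))
    if ref[i] == value:
        return i / (n - 1)
    lo, hi = ref[i - 1], ref[i]
    frac = (value - lo) / (hi - lo)
    return (i - 1 + frac) / (n - 1)


def percent_rank(ref: EcdfReference, gene_id, value: float, mode: str = "percentrank") -> float:
    """Percent-rank of ``value`` within a gene's frozen training reference.

    ``mode="percentrank"`` (default): count of reference values strictly
    below, linearly interpolated between order statistics, scaled by
    ``n-1`` — the minimum maps to 0, the maximum to 1, and values outside
    the reference range clamp to 0/1. ``mode="ecdf"``: right-continuous
    empirical CDF (k/n).
    """
    if gene_id not in ref.references:
        raise LungsigError(f"unknown gene id: {gene_id!r}")
    if not np.isfinite(value):
        return np.nan
    return _percent_rank_sorted(ref.references[gene_id], float(value), mode)


def percent_rank_matrix(
    ref: EcdfReference, expr: ExpressionMatrix, mode: str = "percentrank"
) -> ExpressionMatrix:
    """Percent-rank every available gene of ``expr`` against ``ref``.

    Genes absent from the reference are dropped; missing entries stay
    missing (handled downstream by partial scoring).
    """
    genes = [g for g in expr.values.index if g in ref.references]
    if not genes:
        raise LungsigError("no genes in common with the ECDF reference")
    out = np.full((len(genes), expr.values.shape[1]), np.nan)
    for i, g in enumerate(genes):
        r = ref.references[g]
        row = expr.values.loc[g].to_numpy(dtype=float)
        for j, v in enumerate(row):
            if np.isfinite(v):
                out[i, j] = _percent_rank_sorted(r, float(v), mode)
    return ExpressionMatrix(
        pd.DataFrame(out, index=pd.Index(genes), columns=expr.values.columns),
        expr.platform.copy(),
    )
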