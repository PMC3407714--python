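"""Plain-text file formats: expression TSV, clinical TSV, model/report JSON.

Expression matrices are genes-as-rows TSV with a header row of sample
ids and an optional second header row ``#platform`` carrying per-sample
platform labels. Clinical tables are TSV with the documented schema.
Models, truth objects and reports are JSON. All formats are diffable
text so pipeline reruns can be compared byte for byte.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, LungsigError, validate_clinical


def write_expression(expr: ExpressionMatrix, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(map(str, expr.values.columns)) + "\n")
        fh.write("#platform\t" + "\t".join(map(str, expr.platform.to_numpy())) + "\n")
        for gene, row in expr.values.iterrows():
            vals = "\t".join("" if not np.isfinite(v) else format(v, "g") for v in row.to_numpy(dtype=float))
            fh.write(f"{gene}\t{vals}\n")


def read_expression(path) -> ExpressionMatrix:
    path = Path(path)
    if not path.exists():
        raise LungsigError(f"expression file not found: {path}")
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[1:]
        pos = fh.tell()
        second = fh.readline().rstrip("\n").split("\t")
        platform = None
        if second and second[0] == "#platform":
            platform = pd.Series(second[1:], index=samples)
        else:
            fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", header=None, index_col=0, na_values=[""])
    df.index.name = "gene_id"
    df.columns = samples
    return ExpressionMatrix(df.astype(float), platform)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample_id")


def read_clinical(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise LungsigError(f"clinical file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return validate_clinical(df)


def write_predictions(predictions: pd.DataFrame, path) -> None:
    predictions.to_csv(path, sep="\t", index_label="sample_id", float_format="%.6g")


def read_probe_map(path) -> dict:
    """Two-column TSV (probe_id, gene_id) -> mapping dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe_id", "gene_id"])
    return dict(zip(df["probe_id"].astype(str), df["gene_id"].astype(str)))


def write_selection(result, path) -> None:
    result.to_frame().to_csv(path, sep="\t", float_format="%.6g")
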