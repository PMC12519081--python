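"""Reading and writing the package's standard file formats.

Numeric matrices travel as CSV/TSV with a header row of variable names and
one sample per row; expression matrices additionally as MatrixMarket (MTX)
triplets with gene/cell sidecar lists; variable annotations and sample
labels as two-column TSV; results as JSON records and TSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .data import DataMatrix, ExpressionMatrix
from .exceptions import ValidationError
from .gaussian import InfoValue

__all__ = [
    "read_data_matrix", "write_data_matrix",
    "read_annotations", "read_labels",
    "read_expression_mtx", "read_expression_table",
    "write_info_records", "write_json",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_data_matrix(path: str | Path,
                     annotations: str | Path | None = None,
                     labels: str | Path | None = None) -> DataMatrix:
    """Load a samples x variables CSV/TSV (header = variable names)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    non_numeric = [c for c in df.columns
                   if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValidationError(
            f"non-numeric column(s) in {path.name}: {non_numeric}"
        )
    ann = read_annotations(annotations) if annotations else None
    lab = read_labels(labels) if labels else None
    return DataMatrix.from_dataframe(df, variable_annotations=ann,
                                     sample_labels=lab)


def write_data_matrix(data: DataMatrix, path: str | Path) -> None:
    path = Path(path)
    data.to_dataframe().to_csv(path, sep=_sep_for(path), index=False)


def read_annotations(path: str | Path) -> dict[str, str]:
    """Two-column TSV/CSV: variable, category."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise ValidationError(f"{path.name} must have two columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_labels(path: str | Path) -> list[str]:
    """One label per row; single-column file or (sample, label) table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    col = df.columns[-1]
    return df[col].astype(str).tolist()


def read_expression_table(path: str | Path,
                          labels: str | Path | None = None
                          ) -> ExpressionMatrix:
    """Cells x genes CSV/TSV with a gene-name header."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    lab = read_labels(labels) if labels else None
    return ExpressionMatrix(df.to_numpy(dtype=float), list(df.columns),
                            cell_labels=lab, processing_state="raw")


def read_expression_mtx(matrix: str | Path, genes: str | Path,
                        cells: str | Path | None = None,
                        labels: str | Path | None = None
                        ) -> ExpressionMatrix:
    """MatrixMarket triplet: cells x genes matrix + gene list (+ cell list)."""
    mat = spio.mmread(str(matrix))
    if sparse.issparse(mat):
        mat = mat.toarray()
    gene_names = Path(genes).read_text().split()
    if len(gene_names) != mat.shape[1]:
        if len(gene_names) == mat.shape[0]:  # genes x cells orientation
            mat = mat.T
        else:
            raise ValidationError(
                f"{len(gene_names)} genes do not match matrix shape {mat.shape}"
            )
    lab = read_labels(labels) if labels else None
    return ExpressionMatrix(np.asarray(mat, dtype=float), gene_names,
                            cell_labels=lab, processing_state="raw")


def write_info_records(values: Sequence[InfoValue], path: str | Path) -> None:
    """JSON list of {measure, subset, value_nats, ...} records."""
    Path(path).write_text(
        json.dumps([v.to_record() for v in values], indent=2) + "\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")
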