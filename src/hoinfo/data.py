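"""Sample-by-variable data containers.

`DataMatrix` is the universal numeric input of the analysis modules: rows are
samples (models, cells), columns are named variables (biophysical parameters,
log-expression of genes, e-features). `ExpressionMatrix` wraps raw or
processed cells x genes expression with ground-truth cell labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["DataMatrix", "ExpressionMatrix", "LabeledDataset"]


def _check_names(names: Sequence[str], n_cols: int) -> list[str]:
    names = [str(n) for n in names]
    if len(names) != n_cols:
        raise ValidationError(
            f"{len(names)} variable names for {n_cols} columns"
        )
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate variable names: {dup}")
    return names


@dataclass
class DataMatrix:
    """A validated samples x variables numeric matrix.

    Parameters
    ----------
    values
        2-D float array, one sample per row. Must be finite.
    variable_names
        Unique column names, aligned with ``values``.
    variable_annotations
        Optional ``variable -> category`` mapping (compartment, channel
        family, ...). Unannotated variables are allowed.
    sample_labels
        Optional per-sample string labels (cell type, source cell).
    """

    values: np.ndarray
    variable_names: list[str]
    variable_annotations: dict[str, str] | None = None
    sample_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D samples x variables array")
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise ValidationError(
                f"need at least 2 samples and 1 variable, got {n} x {p}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain missing or non-finite entries")
        self.variable_names = _check_names(self.variable_names, p)
        if self.sample_labels is not None:
            self.sample_labels = [str(s) for s in self.sample_labels]
            if len(self.sample_labels) != n:
                raise ValidationError(
                    f"{len(self.sample_labels)} sample labels for {n} samples"
                )
        if self.variable_annotations is not None:
            unknown = set(self.variable_annotations) - set(self.variable_names)
            if unknown:
                raise ValidationError(f"annotations for unknown variables: {sorted(unknown)}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.variable_names.index(name)]

    def select_variables(self, names: Sequence[str]) -> "DataMatrix":
        idx = [self.variable_names.index(n) for n in names]
        ann = None
        if self.variable_annotations is not None:
            ann = {n: self.variable_annotations[n] for n in names
                   if n in self.variable_annotations}
        return DataMatrix(self.values[:, idx], list(names), ann, self.sample_labels)

    def select_samples(self, idx: Sequence[int]) -> "DataMatrix":
        idx = np.asarray(idx, dtype=int)
        labels = None
        if self.sample_labels is not None:
            labels = [self.sample_labels[i] for i in idx]
        return DataMatrix(self.values[idx], list(self.variable_names),
                          self.variable_annotations, labels)

    def with_column(self, name: str, values: np.ndarray) -> "DataMatrix":
        """Return a copy with an extra named column (e.g. a target e-feature)."""
        values = np.asarray(values, dtype=float).reshape(-1)
        if values.shape[0] != self.n_samples:
            raise ValidationError(
                f"new column has {values.shape[0]} entries for {self.n_samples} samples"
            )
        return DataMatrix(
            np.column_stack([self.values, values]),
            list(self.variable_names) + [name],
            self.variable_annotations,
            self.sample_labels,
        )

    # -- conversions -------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "DataMatrix":
        return cls(df.to_numpy(dtype=float), list(df.columns), **kw)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.variable_names)


_STATES = ("raw", "log", "standardized")


@dataclass
class ExpressionMatrix:
    """Cells x genes expression with optional ground-truth cell-type labels.

    ``processing_state`` records where the matrix sits in the
    raw -> log -> standardized pipeline so transforms are never applied twice.
    """

    values: np.ndarray
    gene_names: list[str]
    cell_labels: list[str] | None = None
    processing_state: str = "raw"
    processing_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression must be a 2-D cells x genes array")
        if self.processing_state not in _STATES:
            raise ValidationError(f"unknown processing state {self.processing_state!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression contains non-finite entries")
        if self.processing_state == "raw" and np.any(self.values < 0):
            raise ValidationError("raw expression must be nonnegative")
        self.gene_names = _check_names(self.gene_names, self.values.shape[1])
        if self.cell_labels is not None:
            self.cell_labels = [str(c) for c in self.cell_labels]
            if len(self.cell_labels) != self.values.shape[0]:
                raise ValidationError(
                    f"{len(self.cell_labels)} cell labels for "
                    f"{self.values.shape[0]} cells"
                )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise ValidationError(f"genes not present in matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def evolve(self, **kw) -> "ExpressionMatrix":
        return replace(self, **kw)


@dataclass
class LabeledDataset:
    """A generated dataset together with its ground-truth structure.

    ``truth`` records whatever the generator planted — cluster assignments,
    constraint weights, informative gene panels, feature-map parents — plus
    the full generator configuration, so tests can score recovery.
    """

    data: DataMatrix | ExpressionMatrix
    truth: Mapping[str, object]
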