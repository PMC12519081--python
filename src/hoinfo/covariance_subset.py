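"""High-covariance subset selection via PCA reconstruction error.

Samples whose parameter vectors are best reconstructed from the top few
principal components are the ones lying closest to the dominant covariance
structure of the ensemble. Ranking samples by residual L2 error and keeping
the lowest-error ones therefore selects a high-covariance sub-ensemble —
the manipulation that flips a synergy-rich population toward redundancy
without touching the model structure itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .data import DataMatrix
from .exceptions import ValidationError

__all__ = ["PcaModel", "SubsetSelection", "fit_pca",
           "reconstruction_residuals", "select_high_covariance"]


@dataclass
class PcaModel:
    components: np.ndarray  # (n_components, n_vars), orthonormal rows
    explained_variance_ratio: np.ndarray
    center: np.ndarray
    scale: np.ndarray | None  # per-variable sd when standardized, else None
    variable_names: list[str]

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def cumulative_explained_variance(self) -> float:
        return float(self.explained_variance_ratio.sum())


@dataclass
class SubsetSelection:
    indices: np.ndarray  # selected sample indices, original order
    residuals: np.ndarray  # per-sample residual L2 norm, all samples
    n_components: int
    n_keep: int

    @property
    def threshold(self) -> float:
        return float(self.residuals[self.indices].max())


def fit_pca(data: DataMatrix, n_components: int = 5,
            standardize: bool = True) -> PcaModel:
    """Centered (and by default z-scored) PCA of the ensemble.

    Standardization matters because biophysical parameters span different
    scales; disable it for data already on a common scale.
    """
    if n_components > min(data.n_samples - 1, data.n_variables):
        raise ValidationError(
            f"n_components {n_components} exceeds "
            f"min(n_samples - 1, n_vars) = "
            f"{min(data.n_samples - 1, data.n_variables)}"
        )
    x = data.values
    center = x.mean(axis=0)
    scale = None
    if standardize:
        scale = x.std(axis=0, ddof=1)
        if np.any(scale == 0):
            bad = [data.variable_names[i] for i in np.flatnonzero(scale == 0)]
            raise ValidationError(f"zero-variance column(s): {bad}")
        x = (x - center) / scale
    else:
        x = x - center
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(x)
    return PcaModel(pca.components_, pca.explained_variance_ratio_,
                    center, scale, list(data.variable_names))


def reconstruction_residuals(data: DataMatrix, model: PcaModel) -> np.ndarray:
    """Per-sample L2 norm of (sample - PCA reconstruction).

    Computed in the standardized space when the model was fitted with
    standardization, for consistency with the fitted components.
    """
    if list(data.variable_names) != model.variable_names:
        raise ValidationError("data variables do not match the fitted model")
    x = data.values - model.center
    if model.scale is not None:
        x = x / model.scale
    proj = x @ model.components.T
    recon = proj @ model.components
    return np.linalg.norm(x - recon, axis=1)


def select_high_covariance(data: DataMatrix, n_components: int = 5,
                           n_keep: int = 1000,
                           standardize: bool = True) -> SubsetSelection:
    """Keep the ``n_keep`` samples with lowest PCA reconstruction error.

    Ties break by original sample order (stable sort). The returned indices
    are sorted, so ``data.select_samples(sel.indices)`` preserves row order.
    """
    if n_keep > data.n_samples:
        raise ValidationError(
            f"n_keep {n_keep} exceeds {data.n_samples} samples"
        )
    model = fit_pca(data, n_components=n_components, standardize=standardize)
    residuals = reconstruction_residuals(data, model)
    order = np.argsort(residuals, kind="stable")
    indices = np.sort(order[:n_keep])
    return SubsetSelection(indices, residuals, n_components, n_keep)
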