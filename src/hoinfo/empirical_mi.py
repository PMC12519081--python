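"""Histogram-based pairwise mutual information with permutation significance.

MI between two numeric vectors is the plug-in MI of their 2-D equal-width
histogram, in nats. Significance is assessed by shuffling the second variable
(default 1,000 permutations) against a null distribution, p-values are
corrected with Benjamini-Hochberg FDR, and a pair is called significant only
if it passes FDR *and* a minimum effect-size threshold (default MI > 0.1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data import DataMatrix
from .exceptions import ValidationError

__all__ = [
    "BinningScheme",
    "MIMatrix",
    "histogram_mi",
    "permutation_test_mi",
    "bh_fdr",
    "significant_pair_map",
]


@dataclass
class BinningScheme:
    """Equal-width binning with a fixed number of bins per variable."""

    n_bins: int = 10
    strategy: str = "equal_width"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")
        if self.strategy != "equal_width":
            raise ValidationError(f"unknown binning strategy {self.strategy!r}")

    def edges(self, x: np.ndarray) -> np.ndarray:
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:  # constant vector: degenerate single-cell histogram
            hi = lo + 1.0
        return np.linspace(lo, hi, self.n_bins + 1)

    def codes(self, x: np.ndarray) -> np.ndarray:
        """Bin index per observation, in 0..n_bins-1 (right edge inclusive)."""
        edges = self.edges(x)
        c = np.searchsorted(edges, x, side="right") - 1
        return np.clip(c, 0, self.n_bins - 1)


def mi_from_codes(cx: np.ndarray, cy: np.ndarray, n_bins: int) -> float:
    """Plug-in MI (nats) of two pre-binned integer code vectors.

    This is the hot path of permutation testing: one ``bincount`` on the
    combined code instead of a fresh 2-D histogram per shuffle.
    """
    n = cx.shape[0]
    joint = np.bincount(cx * n_bins + cy, minlength=n_bins * n_bins).astype(float)
    joint = joint.reshape(n_bins, n_bins) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def _validate_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape[0] != y.shape[0]:
        raise ValidationError("x and y must have equal length")
    if x.shape[0] < 10:
        raise ValidationError("need at least 10 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    return x, y


def histogram_mi(x: np.ndarray, y: np.ndarray,
                 bins: BinningScheme | int = 10) -> float:
    """Histogram plug-in MI between two vectors, in nats.

    A constant vector yields MI 0 with a warning (not an error): its
    histogram occupies a single cell.
    """
    x, y = _validate_pair(x, y)
    if isinstance(bins, int):
        bins = BinningScheme(bins)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input vector: MI is 0 by construction",
                      stacklevel=2)
    return mi_from_codes(bins.codes(x), bins.codes(y), bins.n_bins)


def permutation_test_mi(x: np.ndarray, y: np.ndarray, n_perm: int = 1000,
                        seed: int | np.random.Generator = 0,
                        bins: BinningScheme | int = 10) -> float:
    """Permutation p-value for MI(x, y), shuffling y.

    p = (1 + #{MI_perm >= MI_obs}) / (1 + n_perm); the add-one form keeps
    p strictly positive and attains 1/(n_perm+1) at best.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    x, y = _validate_pair(x, y)
    if isinstance(bins, int):
        bins = BinningScheme(bins)
    rng = np.random.default_rng(seed)
    cx, cy = bins.codes(x), bins.codes(y)
    obs = mi_from_codes(cx, cy, bins.n_bins)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(cy)
        if mi_from_codes(cx, perm, bins.n_bins) >= obs:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def bh_fdr(p_values: np.ndarray, alpha: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR. Returns (rejected mask, q-values)."""
    p = np.asarray(p_values, dtype=float).reshape(-1)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    rejected, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return rejected, q


@dataclass
class MIMatrix:
    """Pairwise MI with permutation p-values, BH q-values and the
    conjunctive significance mask (q <= alpha AND mi > mi_threshold)."""

    mi: pd.DataFrame
    p_values: pd.DataFrame
    q_values: pd.DataFrame
    significant: pd.DataFrame
    n_permutations: int
    alpha: float
    mi_threshold: float
    symmetric: bool

    @property
    def n_significant_pairs(self) -> int:
        m = self.significant.to_numpy()
        total = int(m.sum())
        return total // 2 if self.symmetric else total

    @property
    def variables_in_significant_pairs(self) -> list[str]:
        """Variables (rows) participating in at least one significant pair."""
        mask = self.significant.to_numpy().any(axis=1)
        return [v for v, keep in zip(self.significant.index, mask) if keep]

    def to_long(self) -> pd.DataFrame:
        rows = []
        cols = list(self.significant.columns)
        for i, a in enumerate(self.significant.index):
            for j, b in enumerate(cols):
                if self.symmetric and j <= i:
                    continue
                rows.append({
                    "var_a": a, "var_b": b,
                    "mi_nats": self.mi.iat[i, j],
                    "p": self.p_values.iat[i, j],
                    "q": self.q_values.iat[i, j],
                    "significant": bool(self.significant.iat[i, j]),
                })
        return pd.DataFrame(rows)


def significant_pair_map(data: DataMatrix, features: DataMatrix | None = None,
                         alpha: float = 0.05, mi_threshold: float = 0.1,
                         n_perm: int = 1000, seed: int = 0,
                         bins: BinningScheme | int = 10) -> MIMatrix:
    """Test all unordered variable pairs (or all variable x feature pairs).

    With ``features`` given, a rectangular variable-by-feature map is
    produced; otherwise the symmetric within-matrix pair map.
    """
    if isinstance(bins, int):
        bins = BinningScheme(bins)
    rng = np.random.default_rng(seed)
    row_names = list(data.variable_names)
    codes_rows = [bins.codes(data.column(v)) for v in row_names]

    if features is None:
        col_names = row_names
        pairs = list(itertools.combinations(range(len(row_names)), 2))
        codes_cols = codes_rows
    else:
        if features.n_samples != data.n_samples:
            raise ValidationError(
                f"feature matrix has {features.n_samples} samples, "
                f"data has {data.n_samples}"
            )
        col_names = list(features.variable_names)
        codes_cols = [bins.codes(features.column(v)) for v in col_names]
        pairs = list(itertools.product(range(len(row_names)),
                                       range(len(col_names))))

    shape = (len(row_names), len(col_names))
    mi = np.zeros(shape)
    pv = np.ones(shape)
    for i, j in pairs:
        cx, cy = codes_rows[i], codes_cols[j]
        obs = mi_from_codes(cx, cy, bins.n_bins)
        exceed = 0
        for _ in range(n_perm):
            if mi_from_codes(cx, rng.permutation(cy), bins.n_bins) >= obs:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
        mi[i, j] = obs
        pv[i, j] = p
        if features is None:
            mi[j, i] = obs
            pv[j, i] = p

    flat_p = np.array([pv[i, j] for i, j in pairs])
    rejected, flat_q = bh_fdr(flat_p, alpha=alpha)
    qv = np.ones(shape)
    sig = np.zeros(shape, dtype=bool)
    for (i, j), q, rej in zip(pairs, flat_q, rejected):
        s = bool(rej and mi[i, j] > mi_threshold)
        qv[i, j] = q
        sig[i, j] = s
        if features is None:
            qv[j, i] = q
            sig[j, i] = s

    as_df = lambda m: pd.DataFrame(m, index=row_names, columns=col_names)
    return MIMatrix(as_df(mi), as_df(pv), as_df(qv), as_df(sig),
                    n_permutations=n_perm, alpha=alpha,
                    mi_threshold=mi_threshold, symmetric=features is None)
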