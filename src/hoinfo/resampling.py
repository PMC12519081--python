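"""Resampling inference for higher-order trajectories.

Bootstrap bands quantify how the per-order O-info / RSI trajectories vary
under subsampling of rows (models or cells); column-shuffle surrogates
destroy every cross-variable dependence while preserving marginals exactly,
giving the null band trajectories are compared against; absolute
area-under-curve summaries condense a trajectory into a synergy area
(negative part) and a redundancy area (positive part) for group comparison
with a rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataMatrix
from .exceptions import GuardError, ValidationError
from .tuple_scan import InfoCurve, ScanConfig, scan

__all__ = [
    "BootstrapBand",
    "SurrogateBand",
    "AucSummary",
    "GuardResult",
    "bootstrap_band",
    "column_shuffle",
    "shuffle_surrogates",
    "oinfo_auc",
    "compare_groups",
    "dataset_guard",
]


@dataclass
class GuardResult:
    passed: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.passed


def dataset_guard(data: DataMatrix, min_samples: int = 100,
                  imbalance_ratio: float = 0.1) -> GuardResult:
    """Exclusion rules against resampling artifacts.

    Fails datasets with fewer than ``min_samples`` rows, or — when sample
    labels are present — with a smallest class fraction below
    ``imbalance_ratio`` (strong class imbalance).
    """
    if data.n_samples < min_samples:
        return GuardResult(False, f"only {data.n_samples} samples "
                                  f"(minimum {min_samples})")
    if data.sample_labels is not None:
        counts = pd.Series(data.sample_labels).value_counts()
        frac = counts.min() / counts.sum()
        if frac < imbalance_ratio:
            return GuardResult(
                False,
                f"smallest class fraction {frac:.3f} below {imbalance_ratio} "
                f"(class {counts.idxmin()!r})",
            )
    return GuardResult(True)


@dataclass
class BootstrapBand:
    """Percentile bootstrap band of a per-order trajectory statistic."""

    orders: list[int]
    mean: np.ndarray
    sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    replicate_curves: dict[str, np.ndarray]  # statistic -> (n_reps, n_orders)
    statistic: str
    n_reps: int
    sample_size: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"order": self.orders, "mean": self.mean,
                             "sd": self.sd, "ci_low": self.ci_low,
                             "ci_high": self.ci_high})


def bootstrap_band(data: DataMatrix, scan_config: ScanConfig,
                   n_reps: int = 50, sample_size: int | None = None,
                   seed: int = 0, statistic: str = "mean",
                   guard: bool = True) -> BootstrapBand:
    """Bootstrap the per-order trajectory by subsampling rows.

    Each of ``n_reps`` replicates draws ``sample_size`` rows *without*
    replacement, re-estimates the covariance and re-evaluates the same tuple
    list (drawn once from the full data), so band width reflects sampling of
    rows, not of tuples. The 95% band is the 2.5/97.5 percentile of the
    chosen per-order statistic across replicates.
    """
    if guard:
        g = dataset_guard(data)
        if not g:
            raise GuardError(g.reason)
    if sample_size is None:
        sample_size = min(1000, data.n_samples)
    if sample_size > data.n_samples:
        raise ValidationError(
            f"sample_size {sample_size} exceeds {data.n_samples} samples"
        )
    if n_reps < 2:
        raise ValidationError("need at least 2 bootstrap replicates")
    base = scan(data, scan_config)
    tuple_lists = {k: base.per_order[k].tuples for k in base.orders}
    rng = np.random.default_rng(seed)
    stats_tracked = ("mean", "min", "max")
    curves = {s: np.empty((n_reps, len(base.orders))) for s in stats_tracked}
    for r in range(n_reps):
        rows = rng.choice(data.n_samples, size=sample_size, replace=False)
        rep = scan(data.select_samples(rows), scan_config,
                   tuple_lists=tuple_lists)
        for s in stats_tracked:
            curves[s][r] = rep.statistic(s)
    if statistic not in curves:
        raise ValidationError(f"unknown statistic {statistic!r}")
    mat = curves[statistic]
    return BootstrapBand(
        orders=base.orders,
        mean=mat.mean(axis=0),
        sd=mat.std(axis=0, ddof=1),
        ci_low=np.percentile(mat, 2.5, axis=0),
        ci_high=np.percentile(mat, 97.5, axis=0),
        replicate_curves=curves,
        statistic=statistic, n_reps=n_reps, sample_size=sample_size, seed=seed,
    )


def column_shuffle(data: DataMatrix, rng: np.random.Generator) -> DataMatrix:
    """One surrogate: independently permute every column, destroying all
    cross-column dependence while preserving each marginal exactly."""
    shuffled = np.column_stack([rng.permutation(data.values[:, j])
                                for j in range(data.n_variables)])
    return DataMatrix(shuffled, list(data.variable_names),
                      data.variable_annotations, data.sample_labels)


@dataclass
class SurrogateBand:
    """Extrema of per-order values over column-shuffled surrogates."""

    orders: list[int]
    max_positive: np.ndarray
    min_negative: np.ndarray
    per_surrogate_max: np.ndarray  # (n_surrogates, n_orders)
    per_surrogate_min: np.ndarray
    n_surrogates: int
    seed: int


def shuffle_surrogates(data: DataMatrix, scan_config: ScanConfig,
                       n_surrogates: int = 100, seed: int = 0) -> SurrogateBand:
    """Null band from column-wise shuffled surrogates.

    Each surrogate permutes every column independently, destroying all
    cross-column dependence while keeping each marginal's multiset of values
    exactly; the recorded band is the per-order max and min across
    surrogates (the dashed lines of the trajectory figures).
    """
    if n_surrogates < 1:
        raise ValidationError("need at least 1 surrogate")
    rng = np.random.default_rng(seed)
    maxes = np.empty((n_surrogates, len(scan_config.orders)))
    mins = np.empty_like(maxes)
    for s in range(n_surrogates):
        curve = scan(column_shuffle(data, rng), scan_config)
        maxes[s] = curve.statistic("max")
        mins[s] = curve.statistic("min")
    return SurrogateBand(
        orders=sorted(scan_config.orders),
        max_positive=maxes.max(axis=0),
        min_negative=mins.min(axis=0),
        per_surrogate_max=maxes,
        per_surrogate_min=mins,
        n_surrogates=n_surrogates, seed=seed,
    )


@dataclass
class AucSummary:
    """Absolute areas of the negative (synergy) and positive (redundancy)
    parts of a per-order trajectory."""

    synergy_auc: float
    redundancy_auc: float
    order_range: tuple[int, int]


def _split_auc(orders: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    pos = np.clip(values, 0.0, None)
    neg = np.clip(values, None, 0.0)
    if orders.size < 2:
        return 0.0, 0.0
    return (float(abs(np.trapezoid(neg, orders))),
            float(np.trapezoid(pos, orders)))


def oinfo_auc(curve: InfoCurve | tuple[Sequence[int], Sequence[float]],
              statistic: str | None = None) -> AucSummary:
    """Trapezoidal AUC of a trajectory, split by sign.

    By default the synergy area integrates the per-order *minimum* curve's
    negative part and the redundancy area the per-order *maximum* curve's
    positive part (the extrema capture the strongest interactions at each
    order). Passing ``statistic`` integrates that single summary curve
    instead. A raw ``(orders, values)`` pair is also accepted.
    """
    if isinstance(curve, InfoCurve):
        orders = np.asarray(curve.orders, dtype=float)
        if statistic is None:
            syn, _ = _split_auc(orders, curve.statistic("min"))
            _, red = _split_auc(orders, curve.statistic("max"))
        else:
            syn, red = _split_auc(orders, curve.statistic(statistic))
    else:
        orders, values = curve
        orders = np.asarray(orders, dtype=float)
        values = np.asarray(values, dtype=float)
        if orders.shape != values.shape:
            raise ValidationError("orders and values must align")
        syn, red = _split_auc(orders, values)
    lo, hi = (int(orders[0]), int(orders[-1])) if orders.size else (0, 0)
    return AucSummary(syn, red, (lo, hi))


def compare_groups(auc_group_a: Sequence[float],
                   auc_group_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U (rank-sum) p-value between two AUC groups.

    Uses the exact U distribution when both groups are small and tie-free,
    the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(auc_group_a, dtype=float)
    b = np.asarray(auc_group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and max(a.size, b.size) <= 25) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)
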