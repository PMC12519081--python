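"""Tuple scans: evaluate O-info / RSI across variable combinations per order.

At each tuple order k the scan enumerates all C(N, k) combinations when that
count fits the budget and otherwise draws distinct combinations uniformly at
random under the seed. Downstream summaries extract extrema curves,
top-fraction frequency maps (which variables dominate the most synergistic
or redundant tuples), minimal synergistic sets, and stabilization points of
per-order trajectories.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import DataMatrix
from .exceptions import SingularCovarianceError, ValidationError
from .gaussian import (CovarianceModel, estimate_covariance, oinfo_from_sigma,
                       rsi_from_sigma)

__all__ = [
    "ScanConfig",
    "OrderResult",
    "InfoCurve",
    "FrequencyMap",
    "MinimalSet",
    "scan",
    "top_fraction_frequency",
    "minimal_synergistic_set",
    "detect_stabilization",
]


@dataclass
class ScanConfig:
    """What to scan: which orders, how many tuples per order, which measure."""

    orders: Sequence[int]
    budget: int = 20_000
    seed: int = 0
    measure: str = "oinfo"  # oinfo | rsi
    target: str | None = None
    convention: str = "results"  # RSI sign convention

    def __post_init__(self) -> None:
        self.orders = sorted(int(k) for k in self.orders)
        if not self.orders:
            raise ValidationError("orders must be non-empty")
        if self.budget < 1:
            raise ValidationError("budget must be >= 1")
        if self.measure not in ("oinfo", "rsi"):
            raise ValidationError(f"unknown measure {self.measure!r}")
        min_order = 3 if self.measure == "oinfo" else 1
        if self.orders[0] < min_order:
            raise ValidationError(
                f"minimum order for {self.measure} is {min_order}"
            )
        if self.measure == "rsi" and self.target is None:
            raise ValidationError("rsi scans require a target variable")


@dataclass
class OrderResult:
    order: int
    tuples: list[tuple[str, ...]]
    values: np.ndarray
    exhaustive: bool
    n_skipped: int = 0

    @property
    def n_evaluated(self) -> int:
        return len(self.tuples)


@dataclass
class InfoCurve:
    """Per-order (tuple, value) collections with summary statistics."""

    measure: str
    per_order: dict[int, OrderResult]
    target: str | None = None
    convention: str | None = None
    skipped_total: int = 0

    @property
    def orders(self) -> list[int]:
        return sorted(self.per_order)

    def statistic(self, stat: str) -> np.ndarray:
        """Per-order summary (min | max | mean | sd), aligned with .orders."""
        fns = {"min": np.min, "max": np.max, "mean": np.mean,
               "sd": lambda v: np.std(v, ddof=1) if len(v) > 1 else 0.0}
        if stat not in fns:
            raise ValidationError(f"unknown statistic {stat!r}")
        return np.array([fns[stat](self.per_order[k].values)
                         for k in self.orders])

    def summary(self) -> pd.DataFrame:
        rows = []
        for k in self.orders:
            res = self.per_order[k]
            rows.append({
                "order": k, "min": float(np.min(res.values)),
                "max": float(np.max(res.values)),
                "mean": float(np.mean(res.values)),
                "sd": float(np.std(res.values, ddof=1)) if len(res.values) > 1 else 0.0,
                "n": res.n_evaluated, "exhaustive": res.exhaustive,
                "skipped": res.n_skipped,
            })
        return pd.DataFrame(rows)


def _draw_tuples(n_vars: int, order: int, budget: int,
                 rng: np.random.Generator) -> tuple[list[tuple[int, ...]], bool]:
    total = math.comb(n_vars, order)
    if total <= budget:
        return list(itertools.combinations(range(n_vars), order)), True
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    # distinct-combination rejection sampling; collisions are vanishingly
    # rare when budget << C(n, k)
    while len(out) < budget:
        t = tuple(sorted(rng.choice(n_vars, size=order, replace=False).tolist()))
        if t not in seen:
            seen.add(t)
            out.append(t)
    return out, False


def scan(cov_or_data: CovarianceModel | DataMatrix, config: ScanConfig,
         tuple_lists: dict[int, list[tuple[str, ...]]] | None = None
         ) -> InfoCurve:
    """Evaluate the configured measure over tuples at each order.

    ``tuple_lists`` pins the tuples to evaluate (used by bootstrap replicates
    so band width reflects row sampling, not tuple sampling). Singular
    subsets are skipped and tallied, not fatal.
    """
    if isinstance(cov_or_data, DataMatrix):
        cov = estimate_covariance(cov_or_data)
    else:
        cov = cov_or_data
    names = list(cov.variable_names)
    if config.measure == "rsi":
        if config.target not in names:
            raise ValidationError(f"target {config.target!r} not in variables")
        names = [n for n in names if n != config.target]
        idx_target = cov.indices([config.target])[0]
    n_vars = len(names)
    if config.orders[-1] > n_vars:
        raise ValidationError(
            f"max order {config.orders[-1]} exceeds {n_vars} available variables"
        )
    name_idx = cov.indices(names)
    rng = np.random.default_rng(config.seed)
    sigma = cov.sigma

    per_order: dict[int, OrderResult] = {}
    skipped_total = 0
    for order in config.orders:
        if tuple_lists is not None:
            tuples_named = tuple_lists[order]
            idx_tuples = [[names.index(v) for v in t] for t in tuples_named]
            exhaustive = False
        else:
            idx_tuples, exhaustive = _draw_tuples(n_vars, order, config.budget, rng)
            tuples_named = [tuple(names[i] for i in t) for t in idx_tuples]
        values, kept_tuples = [], []
        n_skipped = 0
        for t, named in zip(idx_tuples, tuples_named):
            cols = name_idx[list(t)]
            try:
                if config.measure == "oinfo":
                    v = oinfo_from_sigma(sigma[np.ix_(cols, cols)])
                else:
                    full = np.append(cols, idx_target)
                    v = rsi_from_sigma(sigma[np.ix_(full, full)])
                    if config.convention == "results":
                        v = -v
            except SingularCovarianceError:
                n_skipped += 1
                continue
            values.append(v)
            kept_tuples.append(tuple(named))
        if not kept_tuples:
            raise SingularCovarianceError(
                f"every tuple at order {order} had a singular covariance"
            )
        per_order[order] = OrderResult(order, kept_tuples, np.array(values),
                                       exhaustive and n_skipped == 0, n_skipped)
        skipped_total += n_skipped
    return InfoCurve(config.measure, per_order, target=config.target,
                     convention=config.convention if config.measure == "rsi" else None,
                     skipped_total=skipped_total)


@dataclass
class FrequencyMap:
    """Variable x order normalized appearance frequency in extreme tuples."""

    frequencies: pd.DataFrame  # variables x orders, each in [0, 1]
    fraction: float
    side: str
    n_selected: dict[int, int] = field(default_factory=dict)

    def mean_frequency(self) -> pd.Series:
        """Average frequency of each variable across orders (a contribution
        score; high for variables that dominate extreme tuples)."""
        return self.frequencies.mean(axis=1).sort_values(ascending=False)


def top_fraction_frequency(curve: InfoCurve, fraction: float = 0.05,
                           side: str = "min") -> FrequencyMap:
    """How often each variable appears in the top-``fraction`` extreme tuples.

    ``side='min'`` selects the lowest values (most synergistic under the
    results convention), ``side='max'`` the highest (most redundant). The
    count per order is ceil(fraction * n_evaluated), minimum 1; frequencies
    are normalized by that count, so a variable present in every selected
    tuple scores 1.
    """
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must be in (0, 1]")
    if side not in ("min", "max"):
        raise ValidationError(f"side must be 'min' or 'max', got {side!r}")
    variables = sorted({v for res in curve.per_order.values()
                        for t in res.tuples for v in t})
    var_idx = {v: i for i, v in enumerate(variables)}
    freq = np.zeros((len(variables), len(curve.orders)))
    n_selected: dict[int, int] = {}
    for j, order in enumerate(curve.orders):
        res = curve.per_order[order]
        n_sel = max(1, math.ceil(fraction * res.n_evaluated))
        order_ix = np.argsort(res.values, kind="stable")
        chosen = order_ix[:n_sel] if side == "min" else order_ix[::-1][:n_sel]
        for t_i in chosen:
            for v in res.tuples[t_i]:
                freq[var_idx[v], j] += 1
        freq[:, j] /= n_sel
        n_selected[order] = n_sel
    df = pd.DataFrame(freq, index=variables, columns=curve.orders)
    return FrequencyMap(df, fraction, side, n_selected)


@dataclass
class MinimalSet:
    order: int
    tuple: tuple[str, ...]
    value_nats: float
    tolerance: float


def minimal_synergistic_set(curve: InfoCurve, tolerance: float | None = None,
                            side: str = "min") -> MinimalSet:
    """Smallest order whose extremum reaches the global extremum's plateau.

    The global extremum is taken across all scanned orders; the returned
    order is the smallest one whose own extremum lies within ``tolerance``
    of it (default 1% of the global extremum's magnitude). The returned
    tuple is the extremal tuple of that order; exact ties break to the
    lexicographically first tuple.
    """
    if not curve.per_order:
        raise ValidationError("empty curve")
    orders = curve.orders
    if orders != list(range(orders[0], orders[-1] + 1)):
        raise ValidationError("curve must cover contiguous orders")
    sign = 1.0 if side == "min" else -1.0
    per_order_ext = {k: sign * np.min(sign * curve.per_order[k].values)
                     for k in orders}
    global_ext = min(sign * v for v in per_order_ext.values()) * sign
    if tolerance is None:
        tolerance = 0.01 * abs(global_ext)
    for k in orders:
        if sign * (per_order_ext[k] - global_ext) <= tolerance:
            res = curve.per_order[k]
            target_val = per_order_ext[k]
            best = min((t for t, v in zip(res.tuples, res.values)
                        if v == target_val))
            return MinimalSet(k, best, float(target_val), float(tolerance))
    raise AssertionError("unreachable: global extremum not found in any order")


def detect_stabilization(series: Sequence[float],
                         rule: str = "min_d2") -> int:
    """Index of the stabilization point of a per-order trajectory.

    Computes discrete second differences d2[i] = s[i+1] - 2 s[i] + s[i-1]
    over interior indices and, under the default rule, returns the index of
    the minimum second difference (steepest concavity), marking the
    transition from rapid decay to plateau. Ties resolve to the first
    interior index. ``rule='max_abs_d2'`` selects the knee of largest
    curvature magnitude instead.
    """
    s = np.asarray(series, dtype=float)
    if s.ndim != 1 or s.shape[0] < 3:
        raise ValidationError("series must be 1-D with at least 3 points")
    d2 = s[2:] - 2 * s[1:-1] + s[:-2]  # d2[i-1] belongs to interior index i
    if rule == "min_d2":
        return int(np.argmin(d2)) + 1
    if rule == "max_abs_d2":
        return int(np.argmax(np.abs(d2))) + 1
    raise ValidationError(f"unknown stabilization rule {rule!r}")
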