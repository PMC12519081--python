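"""Closed-form Gaussian information measures on covariance matrices.

Under a multivariate Gaussian model every entropy is a log-determinant, so
mutual information, total correlation (TC), dual total correlation (DTC),
O-information and the redundancy-synergy index (RSI) all reduce to ratios of
determinants of the covariance matrix and its principal minors:

    h(X)   = 1/2 ln((2 pi e)^k |Sigma|)
    TC     = sum_i h(X_i) - h(X)            = 1/2 ln(prod sigma_i^2 / |Sigma|)
    DTC    = h(X) - sum_i h(X_i | X_{-i})   = 1/2 ln(prod |Sigma_{-i}| / |Sigma|^(k-1))
    O(X)   = TC - DTC                       = 1/2 ln(|Sigma|^(k-2) prod sigma_i^2 / prod |Sigma_{-i}|)
    RSI    = I(S;Y) - sum_i I(X_i;Y)

All values are in nats. Positive O-info means net redundancy among the
variables, negative means net synergy. For RSI two sign conventions coexist
in the literature: the determinant fraction above ("printed", positive for a
synergistic Y = X1 + X2 + noise construction) and its negation ("results",
where negative values mean synergy, consistent with O-info's sign). Both are
available; the default is ``results``.

Singular minors (duplicated / perfectly collinear variables) raise
:class:`~hoinfo.exceptions.SingularCovarianceError` instead of returning NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import DataMatrix
from .exceptions import SingularCovarianceError, ValidationError

__all__ = [
    "CovarianceModel",
    "InfoValue",
    "estimate_covariance",
    "gaussian_entropy",
    "gaussian_mi",
    "total_correlation",
    "dual_total_correlation",
    "o_info",
    "conditional_covariance",
    "conditional_variance",
    "rsi",
]

_LN_2PIE = math.log(2.0 * math.pi * math.e)


@dataclass
class InfoValue:
    """A single information measurement: what was measured, on which subset."""

    measure: str  # entropy | mi | tc | dtc | oinfo | rsi
    value: float  # nats
    subset: tuple[str, ...]
    target: str | None = None
    convention: str | None = None  # printed | results (RSI only)

    def to_record(self) -> dict:
        rec = {"measure": self.measure, "subset": list(self.subset),
               "value_nats": self.value}
        if self.target is not None:
            rec["target"] = self.target
        if self.convention is not None:
            rec["convention"] = self.convention
        return rec


@dataclass
class CovarianceModel:
    """A validated covariance matrix with named variables.

    The substrate of every closed-form measure. ``ridge`` records the amount
    actually added to the diagonal at estimation time (0 unless requested).
    """

    sigma: np.ndarray
    variable_names: list[str]
    n_samples: int
    ridge: float = 0.0

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        p = self.sigma.shape[0]
        if self.sigma.shape != (p, p):
            raise ValidationError("sigma must be square")
        if len(self.variable_names) != p:
            raise ValidationError("variable_names must match sigma's size")
        self.variable_names = [str(n) for n in self.variable_names]
        if len(set(self.variable_names)) != p:
            raise ValidationError("variable names must be unique")
        scale = max(np.abs(self.sigma).max(), 1.0)
        if not np.allclose(self.sigma, self.sigma.T, rtol=0, atol=1e-12 * scale):
            raise ValidationError("sigma is not symmetric")
        self.sigma = 0.5 * (self.sigma + self.sigma.T)
        if np.any(np.diag(self.sigma) <= 0):
            bad = [self.variable_names[i] for i in
                   np.flatnonzero(np.diag(self.sigma) <= 0)]
            raise ValidationError(f"non-positive variance for: {bad}")
        self._index = {n: i for i, n in enumerate(self.variable_names)}

    def indices(self, names: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._index[n] for n in names], dtype=int)
        except KeyError as err:
            raise ValidationError(f"unknown variable {err.args[0]!r}") from None

    def submatrix(self, names: Sequence[str]) -> np.ndarray:
        idx = self.indices(names)
        return self.sigma[np.ix_(idx, idx)]

    def variance(self, name: str) -> float:
        return float(self.sigma[self._index[name], self._index[name]])


def _logdet(sigma: np.ndarray, what: str = "covariance") -> float:
    """Stable log-determinant with positive-definiteness check."""
    sigma = np.atleast_2d(sigma)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise SingularCovarianceError(
            f"{what} submatrix is not positive definite"
        ) from None
    return 2.0 * float(np.sum(np.log(np.diag(chol))))


def estimate_covariance(data: DataMatrix, ridge: float = 0.0) -> CovarianceModel:
    """Unbiased (n-1 denominator) sample covariance of a `DataMatrix`.

    With ``ridge > 0`` an amount ``ridge * trace(Sigma)/n_vars`` is added to
    every diagonal entry, an opt-in regularization for near-singular
    empirical covariances. Default is no ridge.
    """
    if ridge < 0:
        raise ValidationError("ridge must be nonnegative")
    if data.n_samples < 3:
        raise ValidationError("covariance estimation needs at least 3 samples")
    sigma = np.atleast_2d(np.cov(data.values, rowvar=False, ddof=1))
    var = np.diag(sigma)
    if np.any(var <= 0):
        bad = [data.variable_names[i] for i in np.flatnonzero(var <= 0)]
        raise ValidationError(f"zero-variance column(s): {bad}")
    added = 0.0
    if ridge > 0:
        added = ridge * float(np.trace(sigma)) / data.n_variables
        sigma = sigma + added * np.eye(data.n_variables)
    return CovarianceModel(sigma, list(data.variable_names), data.n_samples,
                           ridge=added)


def gaussian_entropy(cov: CovarianceModel, subset: Sequence[str]) -> float:
    """Differential entropy 1/2 ln((2 pi e)^k |Sigma_subset|), in nats."""
    if len(subset) == 0:
        raise ValidationError("subset must be non-empty")
    sub = cov.submatrix(subset)
    return 0.5 * (len(subset) * _LN_2PIE + _logdet(sub))


def gaussian_mi(cov: CovarianceModel, a: str, b: str) -> float:
    """Pairwise Gaussian MI, -1/2 ln(1 - rho^2) nats; always >= 0."""
    if a == b:
        raise ValidationError("gaussian_mi requires two distinct variables")
    sub = cov.submatrix([a, b])
    rho2 = sub[0, 1] ** 2 / (sub[0, 0] * sub[1, 1])
    if rho2 >= 1.0:
        raise SingularCovarianceError(
            f"|correlation| of {a!r} and {b!r} is >= 1"
        )
    return -0.5 * math.log1p(-rho2)


def _tc_from_sigma(sub: np.ndarray) -> float:
    logvars = np.log(np.diag(sub))
    return 0.5 * (float(logvars.sum()) - _logdet(sub))


def _dtc_from_sigma(sub: np.ndarray, names: Sequence[str] | None = None) -> float:
    k = sub.shape[0]
    ld = _logdet(sub)
    minors = 0.0
    for i in range(k):
        keep = [j for j in range(k) if j != i]
        try:
            minors += _logdet(sub[np.ix_(keep, keep)])
        except SingularCovarianceError:
            name = names[i] if names is not None else str(i)
            raise SingularCovarianceError(
                f"minor omitting variable {name!r} is singular"
            ) from None
    return 0.5 * (minors - (k - 1) * ld)


def total_correlation(cov: CovarianceModel, subset: Sequence[str]) -> float:
    """TC = sum of marginal entropies minus joint entropy; >= 0."""
    if len(subset) < 2:
        raise ValidationError("total correlation needs at least 2 variables")
    return _tc_from_sigma(cov.submatrix(subset))


def dual_total_correlation(cov: CovarianceModel, subset: Sequence[str]) -> float:
    """DTC = joint entropy minus sum of conditional entropies; >= 0."""
    if len(subset) < 2:
        raise ValidationError("dual total correlation needs at least 2 variables")
    return _dtc_from_sigma(cov.submatrix(subset), subset)


def oinfo_from_sigma(sub: np.ndarray) -> float:
    """O-information of a raw covariance submatrix (fast path for scans).

    O(X) = 1/2 ln(|Sigma|^(k-2) * prod sigma_i^2 / prod |Sigma_{-i}|).
    """
    k = sub.shape[0]
    ld = _logdet(sub)
    logvars = float(np.sum(np.log(np.diag(sub))))
    minors = 0.0
    for i in range(k):
        keep = [j for j in range(k) if j != i]
        minors += _logdet(sub[np.ix_(keep, keep)], what="leave-one-out")
    return 0.5 * ((k - 2) * ld + logvars - minors)


def o_info(cov: CovarianceModel, subset: Sequence[str]) -> InfoValue:
    """O-information of a variable subset (k >= 3), in nats.

    Positive values indicate net redundancy, negative net synergy. Equal to
    TC - DTC; invariant to variable order and per-variable rescaling.
    """
    if len(subset) < 3:
        raise ValidationError("o_info requires a subset of at least 3 variables")
    value = oinfo_from_sigma(cov.submatrix(subset))
    return InfoValue("oinfo", value, tuple(subset))


def conditional_covariance(cov: CovarianceModel, subset: Sequence[str],
                           target: str) -> CovarianceModel:
    """Schur complement Sigma_S|Y = Sigma_S - s_SY s_YY^-1 s_YS."""
    if target in subset:
        raise ValidationError("target must not be part of the subset")
    s_yy = cov.variance(target)
    if s_yy <= 0:
        raise ValidationError(f"target {target!r} has non-positive variance")
    idx_s = cov.indices(subset)
    idx_y = cov.indices([target])[0]
    sigma_s = cov.sigma[np.ix_(idx_s, idx_s)]
    s_sy = cov.sigma[idx_s, idx_y]
    cond = sigma_s - np.outer(s_sy, s_sy) / s_yy
    cond = 0.5 * (cond + cond.T)
    return CovarianceModel(cond, list(subset), cov.n_samples, ridge=cov.ridge)


def conditional_variance(cov: CovarianceModel, x: str, target: str) -> float:
    """sigma_x|Y^2 = sigma_x^2 (1 - rho^2); never exceeds the marginal."""
    sub = cov.submatrix([x, target])
    if sub[1, 1] <= 0:
        raise ValidationError(f"target {target!r} has non-positive variance")
    return float(sub[0, 0] - sub[0, 1] ** 2 / sub[1, 1])


def rsi_from_sigma(sub: np.ndarray) -> float:
    """RSI (printed convention) from the covariance of [S..., Y] with the
    target in the LAST row/column; fast path for scans."""
    k = sub.shape[0] - 1
    sigma_s = sub[:k, :k]
    s_sy = sub[:k, k]
    s_yy = sub[k, k]
    if s_yy <= 0:
        raise SingularCovarianceError("target variance is not positive")
    cond = sigma_s - np.outer(s_sy, s_sy) / s_yy
    i_joint = 0.5 * (_logdet(sigma_s) - _logdet(cond, what="conditional"))
    i_single = 0.0
    for i in range(k):
        cv = sigma_s[i, i] - s_sy[i] ** 2 / s_yy
        if cv <= 0:
            raise SingularCovarianceError(
                "predictor is deterministically related to the target"
            )
        i_single += 0.5 * (math.log(sigma_s[i, i]) - math.log(cv))
    return i_joint - i_single


def rsi(cov: CovarianceModel, predictors: Sequence[str], target: str,
        convention: str = "results") -> InfoValue:
    """Redundancy-synergy index of a predictor set S for a target Y.

    ``printed`` returns I(S;Y) - sum_i I(X_i;Y) (the determinant fraction,
    positive for the synergistic Y = X1 + X2 + noise construction);
    ``results`` returns its negation, so negative values indicate synergy —
    the same sign language as O-info. Default ``results``.
    """
    if convention not in ("printed", "results"):
        raise ValidationError(f"unknown RSI convention {convention!r}")
    if len(predictors) < 1:
        raise ValidationError("rsi needs at least one predictor")
    if target in predictors:
        raise ValidationError("target must not be among the predictors")
    sub = cov.submatrix(list(predictors) + [target])
    value = rsi_from_sigma(sub)
    if convention == "results":
        value = -value
    return InfoValue("rsi", value, tuple(predictors), target=target,
                     convention=convention)
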