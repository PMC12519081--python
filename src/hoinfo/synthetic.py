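"""Seeded generators for the statistical structures the analysis probes.

Each generator emulates one structure observed in neuronal parameter
ensembles or single-cell expression data:

- ``gen_independent``: the null — iid standard normal columns.
- ``gen_redundant``: latent-factor coexpression, X = L Z + E. Shared factors
  make variables covary, producing net redundancy (positive O-info).
- ``gen_synergistic``: a population conditioned on a shared phenotype,
  sampled exactly from the Gaussian conditional on w.X = y0 + eta. The
  constraint carves a degenerate manifold with anti-correlated variables,
  producing net synergy (negative O-info).
- ``gen_cluster_mixture``: a mixture of tight clusters whose centers lie on
  a constraint manifold — the setting where *how you sample* (one model per
  cluster vs. many models from few clusters) flips the synergy/redundancy
  balance.
- ``gen_feature_map``: target e-features as functions of a few parameters
  (a 2-variable weighted sum for an RMP-like feature; a many-variable
  product mix for an ISI-like feature).
- ``gen_counts``: zero-inflated log-normal count matrices with a planted
  subtype-informative gene panel, for the clustering ARI-null analyses.

Every generator takes a mandatory seed, is bit-reproducible, and records
its full configuration in the returned ``LabeledDataset.truth``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .data import DataMatrix, ExpressionMatrix, LabeledDataset
from .exceptions import ValidationError

__all__ = [
    "gen_independent",
    "gen_redundant",
    "gen_synergistic",
    "constraint_covariance",
    "conditioned_covariance",
    "tau_for_equicorrelation",
    "gen_cluster_mixture",
    "gen_feature_map",
    "gen_counts",
]


def _names(p: int, prefix: str = "x") -> list[str]:
    width = max(2, len(str(p)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(p)]


def gen_independent(n: int, p: int, seed: int) -> LabeledDataset:
    """iid standard normal columns: no dependence at any order."""
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n, p))
    truth = {"kind": "independent", "n_samples": n, "n_variables": p,
             "seed": seed}
    return LabeledDataset(DataMatrix(values, _names(p)), truth)


def gen_redundant(n: int, p: int = 3, seed: int = 0,
                  loadings: np.ndarray | float = 1.0,
                  noise_sd: float = 1.0) -> LabeledDataset:
    """Latent-factor model X = L Z + E with iid standard normal factors.

    ``loadings`` may be a scalar (one shared factor, uniform loading), a
    length-p vector (one factor), or a (p, q) matrix (q factors). With a
    single unit-loading factor and unit noise the population covariance of
    any triple is the equicorrelated matrix diag 2 / off-diag 1, whose
    O-info is 1/2 ln(32/27) ~ +0.085 nats.
    """
    rng = np.random.default_rng(seed)
    load = np.asarray(loadings, dtype=float)
    if load.ndim == 0:
        load = np.full((p, 1), float(load))
    elif load.ndim == 1:
        if load.shape[0] != p:
            raise ValidationError("loadings vector must have length p")
        load = load[:, None]
    if load.shape[0] != p:
        raise ValidationError("loadings must have p rows")
    if not np.all(np.isfinite(load)):
        raise ValidationError("loadings must be finite")
    q = load.shape[1]
    z = rng.standard_normal((n, q))
    x = z @ load.T + noise_sd * rng.standard_normal((n, p))
    truth = {"kind": "latent_factor", "n_samples": n, "n_variables": p,
             "seed": seed, "loadings": load.tolist(), "noise_sd": noise_sd,
             "population_covariance": (load @ load.T
                                       + noise_sd ** 2 * np.eye(p)).tolist()}
    return LabeledDataset(DataMatrix(x, _names(p)), truth)


def constraint_covariance(p: int, weights: np.ndarray, tau: float,
                          base_var: float = 1.0) -> np.ndarray:
    """Population covariance of N(0, base_var I_p) given w.X = y0 + eta.

    The Schur complement base_var (I - v v^T / (v.v + tau^2/base_var)) with
    v = weights; independent of y0.
    """
    w = np.asarray(weights, dtype=float)
    denom = base_var * float(w @ w) + tau ** 2
    if denom <= 0:
        raise ValidationError("degenerate constraint (zero weights, zero tau)")
    return base_var * (np.eye(p) - base_var * np.outer(w, w) / denom)


def tau_for_equicorrelation(rho: float, k: int) -> float:
    """Constraint noise sd giving pairwise correlation ``rho`` among k
    exchangeable unit-weight constrained variables (rho must be negative,
    above the positive-definiteness floor -1/(k-1))."""
    if not (-1.0 / (k - 1) < rho < 0):
        raise ValidationError(
            f"rho must lie in (-1/{k - 1}, 0) for a k={k} sum constraint"
        )
    tau2 = -1.0 / rho - (k - 1)
    return float(np.sqrt(tau2))


def conditioned_covariance(base_sigma: np.ndarray, weights: np.ndarray,
                           tau: float) -> np.ndarray:
    """Population covariance of N(0, base_sigma) given W.X = y + eta.

    ``weights`` is (p,) for a single constraint or (p, m) for m soft
    constraints, each observed with independent noise sd ``tau``:
    Sigma* = Sigma - Sigma W (W' Sigma W + tau^2 I)^-1 W' Sigma.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim == 1:
        w = w[:, None]
    s_w = base_sigma @ w
    m = w.T @ base_sigma @ w + tau ** 2 * np.eye(w.shape[1])
    if np.linalg.matrix_rank(m) < w.shape[1]:
        raise ValidationError("degenerate constraint (zero weights, zero tau)")
    sig = base_sigma - s_w @ np.linalg.solve(m, s_w.T)
    return 0.5 * (sig + sig.T)


def gen_synergistic(n: int, p: int = 3, seed: int = 0,
                    weights: Sequence[float] | np.ndarray | None = None,
                    y0: float = 0.0, tau: float = 0.5,
                    constrained: Sequence[int] | None = None,
                    n_background: int = 0,
                    base_loadings: np.ndarray | None = None
                    ) -> LabeledDataset:
    """Gaussian population conditioned exactly on a shared phenotype.

    Samples X ~ N(0, Sigma_base) conditioned on w.X = y0 + eta with
    eta ~ N(0, tau^2), via the closed-form conditional Gaussian (no
    accept-reject). The conditioning induces negative correlations along
    the constraint directions and net synergy.

    ``weights`` may be a length-k vector (one constraint) or a (k, m)
    matrix (an m-dimensional phenotype). ``constrained`` restricts the
    constraint to a subset of the p variables (the planted synergistic
    tuple); ``n_background`` appends that many extra iid standard normal
    columns. ``base_loadings`` (p x q) adds latent-factor structure
    L L' + I to the *base* covariance before conditioning — a population
    with both coregulation (redundancy-leaning spectrum) and a shared
    phenotype (synergy), the setting of the high-covariance subset
    experiment.
    """
    rng = np.random.default_rng(seed)
    if constrained is None:
        constrained = list(range(p))
    constrained = list(constrained)
    k = len(constrained)
    if weights is None:
        weights = np.ones(k)
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != k:
        raise ValidationError("weights must match the constrained subset")
    if np.allclose(w, 0) and tau == 0:
        raise ValidationError("degenerate constraint")

    if base_loadings is not None:
        load = np.asarray(base_loadings, dtype=float)
        if load.shape[0] != k:
            raise ValidationError(
                "base_loadings must have one row per constrained variable")
        base = load @ load.T + np.eye(k)
    else:
        base = np.eye(k)
    cov_c = conditioned_covariance(base, w, tau)
    w2 = w[:, None] if w.ndim == 1 else w
    m_mat = w2.T @ base @ w2 + tau ** 2 * np.eye(w2.shape[1])
    mean_c = (base @ w2 @ np.linalg.solve(m_mat, np.full(w2.shape[1], y0)))
    chol = np.linalg.cholesky(cov_c + 1e-12 * np.eye(k))
    x = rng.standard_normal((n, p))
    x[:, constrained] = mean_c + rng.standard_normal((n, k)) @ chol.T
    if n_background > 0:
        x = np.column_stack([x, rng.standard_normal((n, n_background))])
    names = _names(p + n_background)
    truth = {"kind": "constraint", "n_samples": n,
             "n_variables": p + n_background, "seed": seed,
             "weights": w.tolist(), "y0": y0, "tau": tau,
             "constrained": [names[i] for i in constrained],
             "has_base_loadings": base_loadings is not None,
             "population_covariance_constrained": cov_c.tolist()}
    return LabeledDataset(DataMatrix(x, names), truth)


def gen_cluster_mixture(n: int, p: int = 10, n_clusters: int = 72,
                        seed: int = 0, mode: str = "pooled",
                        center_structure: str = "constraint",
                        center_scale: float = 1.0, within_sd: float = 0.05,
                        tau: float = 0.3,
                        clusters_used: int = 2) -> LabeledDataset:
    """Mixture of tight Gaussian clusters on a constraint manifold.

    Cluster centers emulate per-cell optimization targets: with
    ``center_structure='constraint'`` they are drawn from the
    constraint-conditioned distribution (all cells share one phenotype), so
    the *between-cluster* structure is synergy-rich; within-cluster scatter
    is tight and isotropic, like repeated solutions around one optimum.

    Sampling modes:
      - ``pooled``: n draws with uniformly random cluster assignment;
      - ``unique``: one draw per cluster (n forced to n_clusters) — spans
        the manifold, inheriting its synergy;
      - ``oversampled``: n draws split evenly over ``clusters_used``
        clusters — dominated by the few-cluster separation, a shared
        discrete factor that reads as redundancy.
    """
    rng = np.random.default_rng(seed)
    if n_clusters < 1:
        raise ValidationError("need at least one cluster")
    if mode not in ("pooled", "unique", "oversampled"):
        raise ValidationError(f"unknown sampling mode {mode!r}")
    if center_structure == "constraint":
        cov_c = constraint_covariance(p, np.ones(p), tau)
        chol = np.linalg.cholesky(cov_c + 1e-12 * np.eye(p))
        centers = center_scale * rng.standard_normal((n_clusters, p)) @ chol.T
    elif center_structure == "gaussian":
        centers = center_scale * rng.standard_normal((n_clusters, p))
    else:
        raise ValidationError(f"unknown center structure {center_structure!r}")

    if mode == "unique":
        assign = np.arange(n_clusters)
    elif mode == "oversampled":
        if clusters_used > n_clusters:
            raise ValidationError("clusters_used exceeds n_clusters")
        chosen = rng.choice(n_clusters, size=clusters_used, replace=False)
        assign = np.repeat(chosen, int(np.ceil(n / clusters_used)))[:n]
    else:
        assign = rng.integers(0, n_clusters, size=n)
    x = centers[assign] + within_sd * rng.standard_normal((len(assign), p))
    names = _names(p)
    truth = {"kind": "cluster_mixture", "n_samples": len(assign),
             "n_variables": p, "seed": seed, "mode": mode,
             "n_clusters": n_clusters, "center_structure": center_structure,
             "center_scale": center_scale, "within_sd": within_sd,
             "tau": tau, "cluster_assignments": assign.tolist()}
    data = DataMatrix(x, names, sample_labels=[f"c{a}" for a in assign])
    return LabeledDataset(data, truth)


def gen_feature_map(params: DataMatrix, kind: str = "weighted_sum",
                    seed: int = 0, variables: Sequence[str] | None = None,
                    weights: Sequence[float] | None = None,
                    noise_sd: float = 0.5, offset: float = 1.0,
                    name: str = "Y") -> LabeledDataset:
    """Map parameters to a target e-feature and append it as a column.

    ``weighted_sum`` (RMP-like): Y = sum w_i X_i + noise over 2 variables by
    default — a compact synergistic pair, like the conductance pair that
    sets the resting potential.

    ``pairwise_products`` (ISI-like): Y = sum over disjoint pairs of
    (X_i + offset)(X_j + offset) + noise over ~10 variables — a distributed
    nonlinear mix. The positive operating-point offset mirrors
    conductance-like positive parameters and keeps the map visible to
    covariance-based measures.
    """
    rng = np.random.default_rng(seed)
    if variables is None:
        n_default = 2 if kind == "weighted_sum" else 10
        variables = params.variable_names[:n_default]
    variables = list(variables)
    missing = [v for v in variables if v not in params.variable_names]
    if missing:
        raise ValidationError(f"unknown variables: {missing}")
    x = np.column_stack([params.column(v) for v in variables])
    if kind == "weighted_sum":
        if weights is None:
            weights = np.ones(len(variables))
        w = np.asarray(weights, dtype=float)
        y = x @ w
    elif kind == "pairwise_products":
        if len(variables) < 2:
            raise ValidationError("pairwise_products needs >= 2 variables")
        shifted = x + offset
        pairs = [(i, i + 1) for i in range(0, len(variables) - 1, 2)]
        y = sum(shifted[:, i] * shifted[:, j] for i, j in pairs)
    else:
        raise ValidationError(f"unknown feature map kind {kind!r}")
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(params.n_samples)
    truth = {"kind": f"feature_map:{kind}", "seed": seed,
             "parents": variables, "noise_sd": noise_sd, "target": name}
    if kind == "weighted_sum":
        truth["weights"] = np.asarray(weights, dtype=float).tolist()
    else:
        truth["offset"] = offset
    return LabeledDataset(params.with_column(name, y), truth)


def gen_counts(n_cells: int, n_genes: int, n_subtypes: int = 2,
               seed: int = 0, panel_size: int = 150,
               zero_inflation: float = 0.3, log_mean: float = 1.0,
               log_sd: float = 0.5, shift_sd: float = 1.0,
               panel_factor_sd: float = 0.0) -> LabeledDataset:
    """Zero-inflated log-normal counts with a planted informative panel.

    counts = Bernoulli(1 - zero_inflation) * round(LogNormal(mu + shift, s)).
    The first ``panel_size`` genes carry per-subtype shifts drawn from
    N(0, shift_sd^2) in log space (the informative panel); background genes
    carry none. ``panel_factor_sd`` optionally adds a per-cell latent factor
    to the panel genes' log-means, planting coexpression (redundancy) on top
    of the subtype structure.
    """
    rng = np.random.default_rng(seed)
    if not (0 <= zero_inflation <= 1):
        raise ValidationError("zero_inflation must be a probability")
    if panel_size > n_genes:
        raise ValidationError("panel_size exceeds n_genes")
    subtype = rng.integers(0, n_subtypes, size=n_cells)
    shifts = np.zeros((n_subtypes, n_genes))
    shifts[:, :panel_size] = rng.normal(0.0, shift_sd,
                                        size=(n_subtypes, panel_size))
    log_mu = log_mean + shifts[subtype]
    if panel_factor_sd > 0:
        factor = rng.standard_normal(n_cells)
        log_mu[:, :panel_size] += panel_factor_sd * factor[:, None]
    raw = np.round(np.exp(rng.normal(log_mu, log_sd)))
    detected = rng.random((n_cells, n_genes)) >= zero_inflation
    counts = raw * detected
    genes = _names(n_genes, prefix="g")
    labels = [f"type{t}" for t in subtype]
    em = ExpressionMatrix(counts, genes, cell_labels=labels,
                          processing_state="raw")
    truth = {"kind": "counts", "n_cells": n_cells, "n_genes": n_genes,
             "n_subtypes": n_subtypes, "seed": seed,
             "panel_genes": genes[:panel_size],
             "zero_inflation": zero_inflation, "log_mean": log_mean,
             "log_sd": log_sd, "shift_sd": shift_sd,
             "panel_factor_sd": panel_factor_sd,
             "subtype": subtype.tolist()}
    return LabeledDataset(em, truth)
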