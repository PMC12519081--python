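"""End-to-end desk-scale experiment recipes.

Each recipe wires the synthetic generators to the analysis modules to
reproduce one figure-level result structurally: the sign of higher-order
interactions against surrogate nulls, the sampling-structure flip between
unique and oversampled cluster draws, the synergy-to-redundancy shift of a
high-covariance subset, minimal synergistic sets of target features, and
the gene-panel ARI null.

The ensemble *structure* of each recipe (factor loadings, constraint
weights) is fixed by an internal structure seed so that the experiment is
one well-defined study; the caller's ``seed`` drives sampling only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import ClusterConfig, GenePanel, ari_null, preprocess
from .covariance_subset import select_high_covariance
from .data import DataMatrix, LabeledDataset
from .resampling import compare_groups, oinfo_auc, shuffle_surrogates
from .tuple_scan import ScanConfig, minimal_synergistic_set, scan
from . import synthetic

__all__ = [
    "constrained_factor_ensemble",
    "high_covariance_flip",
    "HighCovarianceFlip",
    "sampling_structure_experiment",
    "SamplingStructureResult",
    "sign_recovery",
    "minimal_set_recovery",
    "gene_panel_ari_experiment",
]

# fixed structure of the coregulated-but-constrained ensemble: 3 weak latent
# factors (coexpression) + a 2-dimensional shared phenotype (constraint)
_STRUCTURE_SEED = 0
_P, _Q, _M = 12, 3, 2
_FACTOR_SD, _TAU = 0.5, 0.4


def constrained_factor_ensemble(n: int, seed: int) -> LabeledDataset:
    """Sample the canonical synergy-dominated ensemble with weak factor
    structure: latent factors give it a dominant principal subspace, the
    two soft phenotype constraints give it net synergy."""
    srng = np.random.default_rng(_STRUCTURE_SEED)
    loadings = srng.normal(0.0, _FACTOR_SD, size=(_P, _Q))
    weights = srng.normal(0.0, 1.0, size=(_P, _M))
    weights /= np.linalg.norm(weights, axis=0)
    return synthetic.gen_synergistic(n, p=_P, seed=seed, weights=weights,
                                     tau=_TAU, base_loadings=loadings)


def _mean_auc_dominance(data: DataMatrix, config: ScanConfig) -> tuple[float, float]:
    """(synergy_auc, redundancy_auc) of the per-order *mean* trajectory."""
    curve = scan(data, config)
    auc = oinfo_auc((np.asarray(curve.orders, dtype=float),
                     curve.statistic("mean")))
    return auc.synergy_auc, auc.redundancy_auc


@dataclass
class HighCovarianceFlip:
    """AUCs of the mean O-info trajectory for the full ensemble, its
    high-covariance subset, and an equal-size random subset."""

    full: tuple[float, float]  # (synergy_auc, redundancy_auc)
    subset: tuple[float, float]
    random: tuple[float, float]

    @property
    def full_synergy_dominated(self) -> bool:
        return self.full[0] > self.full[1]

    @property
    def subset_redundancy_dominated(self) -> bool:
        return self.subset[1] > self.subset[0]

    @property
    def random_synergy_dominated(self) -> bool:
        return self.random[0] > self.random[1]


def high_covariance_flip(seed: int, n: int = 10_000, n_keep: int = 1000,
                         n_components: int = 5, budget: int = 150
                         ) -> HighCovarianceFlip:
    """Select the high-covariance subset of a synergy-rich ensemble and
    compare O-info dominance against an equal-size random subset."""
    ds = constrained_factor_ensemble(n, seed)
    config = ScanConfig(orders=range(3, 10), budget=budget, seed=seed)
    full = _mean_auc_dominance(ds.data, config)
    sel = select_high_covariance(ds.data, n_components=n_components,
                                 n_keep=n_keep)
    subset = _mean_auc_dominance(ds.data.select_samples(sel.indices), config)
    rng = np.random.default_rng(seed + 1)
    rand_idx = np.sort(rng.choice(n, size=n_keep, replace=False))
    random = _mean_auc_dominance(ds.data.select_samples(rand_idx), config)
    return HighCovarianceFlip(full, subset, random)


@dataclass
class SamplingStructureResult:
    """Per-replicate AUC dominance for unique vs. oversampled draws from
    the same cluster mixture, plus the rank-sum p-value between them."""

    unique_dominance: np.ndarray  # synergy_auc - redundancy_auc, per draw
    oversampled_dominance: np.ndarray
    p_value: float


def sampling_structure_experiment(seed: int, n_replicates: int = 20,
                                  n_clusters: int = 72, p: int = 10
                                  ) -> SamplingStructureResult:
    """Unique (one model per cluster) vs. oversampled (two clusters, many
    models each) draws from one mixture: does sampling structure alone flip
    synergy-AUC vs redundancy-AUC dominance?"""
    uni = np.empty(n_replicates)
    over = np.empty(n_replicates)
    for r in range(n_replicates):
        u = synthetic.gen_cluster_mixture(
            n_clusters, p=p, n_clusters=n_clusters, seed=seed + 2 * r,
            mode="unique")
        o = synthetic.gen_cluster_mixture(
            n_clusters, p=p, n_clusters=n_clusters, seed=seed + 2 * r + 1,
            mode="oversampled")
        config = ScanConfig(orders=range(3, 9), budget=120, seed=seed + r)
        au = oinfo_auc(scan(u.data, config))
        ao = oinfo_auc(scan(o.data, config))
        uni[r] = au.synergy_auc - au.redundancy_auc
        over[r] = ao.synergy_auc - ao.redundancy_auc
    return SamplingStructureResult(uni, over, compare_groups(uni, over))


def sign_recovery(seed: int, n: int = 800, p: int = 8,
                  n_surrogates: int = 20) -> dict[str, bool]:
    """One seed of the sign-recovery check: constraint ensembles must drop
    below the surrogate band (synergy), latent-factor ensembles must rise
    above it (redundancy), at every order."""
    config = ScanConfig(orders=range(3, 7), budget=300, seed=seed)
    syn = synthetic.gen_synergistic(n, p=p, seed=seed, tau=0.5)
    syn_curve = scan(syn.data, config)
    syn_band = shuffle_surrogates(syn.data, config,
                                  n_surrogates=n_surrogates, seed=seed)
    red = synthetic.gen_redundant(n, p=p, seed=seed)
    red_curve = scan(red.data, config)
    red_band = shuffle_surrogates(red.data, config,
                                  n_surrogates=n_surrogates, seed=seed)
    return {
        "synergy_below_band": bool(np.all(
            syn_curve.statistic("min") < syn_band.min_negative)),
        "redundancy_above_band": bool(np.all(
            red_curve.statistic("max") > red_band.max_positive)),
    }


def minimal_set_recovery(seed: int, n: int = 3000) -> dict[str, object]:
    """Minimal synergistic sets of two planted feature maps: a compact
    2-parameter weighted sum (RMP-like) and a distributed ~10-parameter
    product mix (ISI-like)."""
    params = synthetic.gen_independent(n, 10, seed=seed).data
    rmp = synthetic.gen_feature_map(params, "weighted_sum", seed=seed)
    config = ScanConfig(orders=range(1, 5), budget=800, seed=seed,
                        measure="rsi", target="Y")
    rmp_set = minimal_synergistic_set(scan(rmp.data, config))

    params2 = synthetic.gen_independent(n, 12, seed=seed + 1).data
    isi = synthetic.gen_feature_map(params2, "pairwise_products",
                                    seed=seed + 1, noise_sd=1.0)
    isi_set = minimal_synergistic_set(scan(isi.data, config))
    return {
        "rmp_order": rmp_set.order,
        "rmp_tuple": rmp_set.tuple,
        "rmp_parents": tuple(rmp.truth["parents"]),
        "isi_order": isi_set.order,
    }


def gene_panel_ari_experiment(seed: int, n_cells: int = 300,
                              n_genes: int = 2000, panel_size: int = 150,
                              n_draws: int = 500):
    """Planted-informative gene panel vs. matched-size random panels:
    generate zero-inflated counts with a subtype-informative panel,
    preprocess, and rank the panel's clustering ARI against the null."""
    ds = synthetic.gen_counts(n_cells, n_genes, n_subtypes=2, seed=seed,
                              panel_size=panel_size)
    em = preprocess(ds.data)
    panel_genes = [g for g in ds.truth["panel_genes"] if g in em.gene_names]
    focal = GenePanel(panel_genes, source="ion_channel")
    return ari_null(em, None, focal, panel_size=len(panel_genes),
                    n_draws=n_draws, seed=seed,
                    cluster_config=ClusterConfig(seed=seed))
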