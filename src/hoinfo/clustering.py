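"""Gene-panel clustering and the random-panel ARI null.

Does a designated gene panel (e.g. ion-channel genes) recover ground-truth
cell types better than random panels of matched size? Cells are clustered on
a panel's expression via PCA -> kNN graph -> Leiden community detection, the
partition is scored against known cell types with the adjusted Rand index,
and the focal panel's ARI is ranked against a null distribution of ARIs from
randomly drawn panels of the same size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg as la
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .data import DataMatrix, ExpressionMatrix
from .empirical_mi import bh_fdr
from .exceptions import GuardError, ValidationError
from .resampling import dataset_guard

__all__ = [
    "GenePanel",
    "ClusterConfig",
    "AriNull",
    "preprocess",
    "filter_nonzero_median",
    "identify_degs",
    "cluster_cells",
    "adjusted_rand_index",
    "ari_null",
]


@dataclass
class GenePanel:
    genes: list[str]
    source: str = "custom"  # ion_channel | deg | random | custom
    draw_seed: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene panel contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)


def preprocess(em: ExpressionMatrix) -> ExpressionMatrix:
    """log(1 + x) then per-gene z-scoring; drops zero-variance genes.

    Refuses already-processed input so transforms are never stacked.
    """
    if em.processing_state != "raw":
        raise ValidationError(
            f"preprocess expects raw counts, got state {em.processing_state!r}"
        )
    logged = np.log1p(em.values)
    sd = logged.std(axis=0, ddof=0)
    keep = sd > 0
    if not np.all(keep):
        dropped = [g for g, k in zip(em.gene_names, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} zero-variance gene(s)",
                      stacklevel=2)
        logged = logged[:, keep]
        sd = sd[keep]
    if logged.shape[1] == 0:
        raise ValidationError("no genes left after dropping zero-variance ones")
    z = (logged - logged.mean(axis=0)) / sd
    genes = [g for g, k in zip(em.gene_names, keep) if k]
    return em.evolve(values=z, gene_names=genes,
                     processing_state="standardized",
                     processing_log=em.processing_log + ["log1p", "zscore"])


def filter_nonzero_median(em: ExpressionMatrix, groups: list[str]
                          ) -> GenePanel:
    """Genes with nonzero median raw expression in every named group."""
    if em.cell_labels is None:
        raise ValidationError("cell labels are required")
    labels = np.asarray(em.cell_labels)
    known = set(labels)
    for g in groups:
        if g not in known:
            raise ValidationError(f"unknown group label {g!r}")
    keep = np.ones(em.n_genes, dtype=bool)
    for g in groups:
        med = np.median(em.values[labels == g], axis=0)
        keep &= med > 0
    genes = [name for name, k in zip(em.gene_names, keep) if k]
    return GenePanel(genes, source="custom")


def identify_degs(em: ExpressionMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """One-vs-rest rank-sum differential expression, BH-corrected per class.

    Returns the union of significant genes ranked by best adjusted p across
    classes; columns: gene, best_class, p, q. Classes with fewer than 3
    cells are skipped with a warning.
    """
    if em.cell_labels is None:
        raise ValidationError("cell labels are required")
    labels = np.asarray(em.cell_labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    best_q = np.full(em.n_genes, np.inf)
    best_p = np.full(em.n_genes, np.inf)
    best_class = np.array([""] * em.n_genes, dtype=object)
    for cls in classes:
        mask = labels == cls
        if mask.sum() < 3:
            warnings.warn(f"class {cls!r} has fewer than 3 cells; skipped",
                          stacklevel=2)
            continue
        in_cls = em.values[mask]
        rest = em.values[~mask]
        p = np.empty(em.n_genes)
        for j in range(em.n_genes):
            a, b = in_cls[:, j], rest[:, j]
            if np.ptp(np.concatenate([a, b])) == 0:
                p[j] = 1.0
            else:
                p[j] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        _, q = bh_fdr(np.clip(p, np.nextafter(0, 1), 1.0), alpha=alpha)
        better = q < best_q
        best_q[better] = q[better]
        best_p[better] = p[better]
        best_class[better] = cls
    table = pd.DataFrame({
        "gene": em.gene_names,
        "best_class": best_class,
        "p": best_p,
        "q": best_q,
    })
    table = table[table["q"] <= alpha].sort_values(
        ["q", "p", "gene"], kind="stable").reset_index(drop=True)
    return table


@dataclass
class ClusterConfig:
    """PCA -> kNN -> Leiden hyperparameters (all logged with results)."""

    n_pcs: int = 50
    n_neighbors: int = 15
    resolution: float = 1.0
    seed: int = 0


def cluster_cells(em: ExpressionMatrix, panel: GenePanel,
                  config: ClusterConfig | None = None) -> np.ndarray:
    """Cluster cells on a gene panel: PCA, kNN graph, Leiden communities.

    Deterministic under a fixed config seed. Returns integer cluster labels.
    """
    if config is None:
        config = ClusterConfig()
    if len(panel) < 2:
        raise ValidationError("panel must contain at least 2 genes")
    if em.processing_state == "raw":
        raise ValidationError("cluster_cells expects preprocessed expression")
    x = em.values[:, em.gene_index(panel.genes)]
    n_pcs = min(config.n_pcs, x.shape[1], x.shape[0] - 1)
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(x)
    k = min(config.n_neighbors, em.n_cells - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, neighbor_idx = nn.kneighbors(pcs)
    edges = {(min(i, j), max(i, j))
             for i, row in enumerate(neighbor_idx) for j in row if i != j}
    graph = ig.Graph(n=em.n_cells, edges=sorted(edges))
    part = la.find_partition(
        graph, la.RBConfigurationVertexPartition,
        resolution_parameter=config.resolution, seed=config.seed,
    )
    return np.asarray(part.membership, dtype=int)


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected partition agreement; 1 for identical partitions
    (up to relabeling), ~0 for independent ones."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError("partitions must have equal length")
    return float(adjusted_rand_score(a, b))


@dataclass
class AriNull:
    """Focal-panel ARI against a matched-size random-panel null."""

    focal_ari: float
    null_aris: np.ndarray
    percentile: float  # focal's percentile within the null, in [0, 100]
    n_draws: int
    panel_size: int
    pool: str
    seed: int
    cluster_config: ClusterConfig = field(default_factory=ClusterConfig)

    @property
    def null_mean(self) -> float:
        return float(self.null_aris.mean())

    @property
    def ratio(self) -> float:
        """focal ARI / mean null ARI (guarding a zero mean)."""
        m = self.null_mean
        return float("inf") if m <= 0 else self.focal_ari / m


def ari_null(em: ExpressionMatrix, truth: list[str] | np.ndarray | None,
             focal_panel: GenePanel, panel_size: int | None = None,
             n_draws: int = 500, pool: str | list[str] = "all",
             seed: int = 0, cluster_config: ClusterConfig | None = None,
             guard: bool = True) -> AriNull:
    """Rank a focal panel's clustering ARI against random panels.

    ``pool`` is the gene universe random panels are drawn from: ``"all"``
    genes, or an explicit gene list (e.g. DEGs). Each random panel is
    clustered with exactly the same configuration as the focal panel.
    """
    if truth is None:
        truth = em.cell_labels
    if truth is None:
        raise ValidationError("ground-truth labels are required")
    truth = np.asarray(truth)
    if truth.shape[0] != em.n_cells:
        raise ValidationError("truth labels must match cell count")
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    if panel_size is None:
        panel_size = len(focal_panel)
    if cluster_config is None:
        cluster_config = ClusterConfig()
    if guard:
        probe = DataMatrix(np.zeros((em.n_cells, 2)), ["_a", "_b"],
                           sample_labels=list(map(str, truth)))
        g = dataset_guard(probe)
        if not g:
            raise GuardError(g.reason)

    if pool == "all":
        pool_genes = list(em.gene_names)
        pool_name = "all"
    else:
        pool_genes = list(pool)
        em.gene_index(pool_genes)  # validates presence
        pool_name = "custom"
    if len(pool_genes) < panel_size:
        raise ValidationError(
            f"pool of {len(pool_genes)} genes smaller than panel size "
            f"{panel_size}"
        )

    focal = adjusted_rand_index(
        truth, cluster_cells(em, focal_panel, cluster_config))
    rng = np.random.default_rng(seed)
    null = np.empty(n_draws)
    for d in range(n_draws):
        draw = rng.choice(len(pool_genes), size=panel_size, replace=False)
        panel = GenePanel([pool_genes[i] for i in draw], source="random")
        null[d] = adjusted_rand_index(
            truth, cluster_cells(em, panel, cluster_config))
    pct = float(stats.percentileofscore(null, focal, kind="mean"))
    return AriNull(focal, null, pct, n_draws, panel_size, pool_name, seed,
                   cluster_config)
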