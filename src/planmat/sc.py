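"""Single-cell expression analytics used to locate the cellular source of the
extracellular matrix: CP10K normalization, binned-control module scores,
cluster-specificity AUC, and matrisome-gene-restricted reclustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .types import CellAnnotation, ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


def normalize_cp10k(matrix: ExpressionMatrix, log_transform: bool = True) -> ExpressionMatrix:
    """Scale each cell's counts to a total of 10,000 (counts per 10K), with an
    optional ln(1 + x) transform. All-zero cells stay all-zero (warned).
    Zero pattern is conserved. Populates ``matrix.norm`` in place and returns
    the matrix."""
    counts = sparse.csc_matrix(matrix.counts, dtype=np.float64)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    zero_cells = int((totals == 0).sum())
    if zero_cells:
        logger.warning("%d all-zero cells left unnormalized", zero_cells)
    scale = np.divide(1e4, totals, out=np.zeros_like(totals), where=totals > 0)
    norm = counts.multiply(sparse.csr_matrix(scale[None, :])).tocsr()
    if log_transform:
        norm = norm.log1p()
    matrix.norm = norm
    matrix.state = "log_cp10k" if log_transform else "cp10k"
    return matrix


def _require_norm(matrix: ExpressionMatrix) -> sparse.csr_matrix:
    if matrix.norm is None:
        raise ValueError("matrix is not normalized; call normalize_cp10k first")
    return sparse.csr_matrix(matrix.norm)


@dataclass
class ModuleScoreResult:
    scores: np.ndarray            # per cell
    set_name: str
    n_bins: int
    n_ctrl: int
    seed: int
    control_pool: list[int] = field(default_factory=list)  # gene indices with multiplicity


def module_score(
    matrix: ExpressionMatrix,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Expression-matched module score of a gene set per cell.

    The score is the mean normalized expression of the set genes minus the
    mean over a control pool of expression-matched genes: genes are cut into
    ``n_bins`` equal-frequency bins by their mean expression over all cells,
    and for every set gene ``n_ctrl`` controls are drawn from its bin
    (without replacement, or with replacement when the bin is smaller than
    ``n_ctrl``). This normalizes each set's average by genes of similar
    overall expression, so the score is centred near zero for an unremarkable
    set. Deterministic given ``seed``; invariant to gene and cell order.
    """
    norm = _require_norm(matrix)
    members = sorted(gene_set.members & set(matrix.gene_ids))
    dropped = gene_set.members - set(members)
    if dropped:
        logger.info("%s: %d set genes absent from matrix", gene_set.name, len(dropped))
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the matrix")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")

    gene_means = np.asarray(norm.mean(axis=1)).ravel()
    genes_arr = np.asarray(matrix.gene_ids)
    # equal-frequency bins; ties in mean expression break by gene id so the
    # binning (and hence the score) is invariant to input gene order
    sort_idx = np.lexsort((genes_arr, gene_means))
    ranks = np.empty(len(genes_arr), dtype=float)
    ranks[sort_idx] = np.arange(1, len(genes_arr) + 1)
    bin_of = np.ceil(ranks / (len(genes_arr) / n_bins)).clip(max=n_bins).astype(int)
    bins = pd.Series(bin_of, index=matrix.gene_ids)

    rng = np.random.default_rng(seed)
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    bin_members: dict[int, np.ndarray] = {
        b: np.sort(genes_arr[bin_of == b]) for b in range(1, n_bins + 1)
    }
    pool: list[int] = []
    for g in members:
        cands = bin_members[int(bins[g])]
        if len(cands) <= n_ctrl:
            if len(cands) == n_ctrl:
                chosen = cands
            else:
                chosen = rng.choice(cands, size=n_ctrl, replace=True)
        else:
            chosen = rng.choice(cands, size=n_ctrl, replace=False)
        pool.extend(gene_pos[c] for c in chosen)

    set_idx = np.array([gene_pos[g] for g in members])
    set_mean = np.asarray(norm[set_idx, :].mean(axis=0)).ravel()
    pool_idx = np.array(pool)
    ctrl_mean = np.asarray(norm[pool_idx, :].mean(axis=0)).ravel()
    return ModuleScoreResult(
        scores=set_mean - ctrl_mean,
        set_name=gene_set.name,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
        control_pool=pool,
    )


@dataclass
class AUCResult:
    auc: dict[str, float]          # label -> AUC
    best_cluster: str
    tie_broken: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": list(self.auc), "auc": list(self.auc.values())}
        ).sort_values("auc", ascending=False, ignore_index=True)


def cluster_auc(values: np.ndarray, labels: np.ndarray) -> AUCResult:
    """Per-label AUC of a per-cell statistic for separating that label's cells
    from all others (0.5 = chance, 1.0 = perfect). Computed as the normalized
    Mann-Whitney U with mid-rank tie handling."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and labels differ in length")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two distinct labels")
    ranks = stats.rankdata(values)  # midranks
    n = len(values)
    out: dict[str, float] = {}
    for lab in uniq:
        mask = labels == lab
        n1 = int(mask.sum())
        n0 = n - n1
        u = ranks[mask].sum() - n1 * (n1 + 1) / 2
        out[str(lab)] = float(u / (n1 * n0))
    best_auc = max(out.values())
    winners = sorted(k for k, v in out.items() if v == best_auc)
    return AUCResult(auc=out, best_cluster=winners[0], tie_broken=len(winners) > 1)


@dataclass
class ReclusterResult:
    cell_ids: list[str]
    cluster_labels: np.ndarray
    embedding: Optional[np.ndarray]          # cells x 2 tSNE, or None
    pca_components: np.ndarray               # n_pcs_total x genes loadings
    pca_gene_ids: list[str]
    cell_pcs: np.ndarray                     # cells x n_pcs_total
    composition: pd.DataFrame                # new cluster x reference label counts


def recluster_matrisome(
    matrix: ExpressionMatrix,
    hc_genes: GeneSet,
    annotation: Optional[CellAnnotation] = None,
    n_pcs_total: int = 20,
    n_pcs_use: int = 6,
    perplexity: float = 40.0,
    seed: int = 0,
    graph_k: int = 30,
    resolution: float = 1.0,
    compute_embedding: bool = True,
) -> ReclusterResult:
    """Cluster and embed cells using only high-confidence matrisome genes.

    The matrix is restricted to ``hc_genes``, genes are z-scored (clipped at
    +/-10), PCA retains ``n_pcs_total`` components, and both the
    shared-nearest-neighbor modularity clustering and the tSNE embedding run
    on the top ``n_pcs_use`` components (tSNE perplexity ``perplexity``).
    Cells that express none of the restricted genes still receive labels.
    """
    norm = _require_norm(matrix)
    genes = sorted(hc_genes.members & set(matrix.gene_ids))
    if len(genes) < n_pcs_total:
        raise ValueError(
            f"only {len(genes)} of the {len(hc_genes.members)} restricted genes are "
            f"in the matrix; need at least n_pcs_total={n_pcs_total}"
        )
    idx = matrix.gene_index(genes)
    sub = norm[idx, :].toarray().astype(np.float64).T  # cells x genes
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = np.clip((sub - mu) / sd, -10, 10)

    pca = PCA(n_components=n_pcs_total, svd_solver="full", random_state=seed)
    pcs = pca.fit_transform(z)
    use = pcs[:, :n_pcs_use]

    labels = _snn_cluster(use, k=graph_k, resolution=resolution, seed=seed)

    embedding = None
    if compute_embedding:
        embedding = TSNE(
            n_components=2,
            perplexity=min(perplexity, (len(labels) - 1) / 3),
            random_state=seed,
            init="pca",
        ).fit_transform(use)

    if annotation is not None:
        ref = annotation.labels_for(matrix.cell_ids)
        comp = composition_report(labels.astype(str), ref)
    else:
        comp = pd.DataFrame()

    return ReclusterResult(
        cell_ids=list(matrix.cell_ids),
        cluster_labels=labels,
        embedding=embedding,
        pca_components=pca.components_,
        pca_gene_ids=genes,
        cell_pcs=pcs,
        composition=comp,
    )


def _snn_cluster(x: np.ndarray, k: int, resolution: float, seed: int) -> np.ndarray:
    """Shared-nearest-neighbor graph + modularity community detection."""
    n = x.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(x)
    knn = nn.kneighbors_graph(x, mode="connectivity")
    # SNN weight = Jaccard overlap of k-NN sets
    shared = (knn @ knn.T).tocoo()
    rows, cols, vals = shared.row, shared.col, shared.data
    keep = rows < cols
    rows, cols, vals = rows[keep], cols[keep], vals[keep]
    jac = vals / (2 * k - vals)
    mask = jac > 1.0 / 15  # prune weak edges, as SNN clustering tools do
    edges = list(zip(rows[mask].tolist(), cols[mask].tolist()))
    g = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=jac[mask].tolist(),
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.array(part.membership)


def composition_report(new_labels: np.ndarray, reference_labels: np.ndarray) -> pd.DataFrame:
    """Contingency of new clusters vs reference cell-type labels with per-row
    recovery (fraction of each reference type captured) and contamination
    (fraction of the cluster that is not its majority reference type)."""
    new_labels = np.asarray(new_labels)
    reference_labels = np.asarray(reference_labels)
    if new_labels.shape != reference_labels.shape:
        raise ValueError("label vectors differ in length")
    tab = pd.crosstab(
        pd.Series(new_labels, name="cluster"),
        pd.Series(reference_labels, name="reference"),
    )
    out = tab.copy()
    out["size"] = tab.sum(axis=1)
    ref_totals = tab.sum(axis=0)
    for ref in tab.columns:
        out[f"recovery_{ref}"] = tab[ref] / ref_totals[ref]
    majority = tab.idxmax(axis=1)
    out["majority_reference"] = majority
    out["contamination"] = [
        1.0 - tab.loc[cl, majority[cl]] / out.loc[cl, "size"] for cl in tab.index
    ]
    return out


def best_cluster_for(composition: pd.DataFrame, reference_type: str) -> pd.Series:
    """Row of the cluster that captures the largest share of ``reference_type``."""
    col = f"recovery_{reference_type}"
    if col not in composition.columns:
        raise ValueError(f"reference type {reference_type!r} not in composition table")
    return composition.loc[composition[col].idxmax()]
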