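"""Marker ranking and weighted preranked gene-set enrichment analysis.

Genes are ranked by average log fold change between a cell group and all
other cells, filtered by a detection threshold, and gene sets are scored with
the weighted Kolmogorov-Smirnov-like running-sum statistic (weight exponent
``p``, default 1.0). Significance comes from a gene-set-permutation null:
random same-size sets drawn from the ranked universe, with the normalized
enrichment score (NES) scaling the observed ES by the mean magnitude of
same-sign null scores, and Benjamini-Hochberg adjustment across the set
collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from statsmodels.stats.multitest import multipletests

from .types import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


def avg_log_fc(matrix: ExpressionMatrix, in_cells, out_cells) -> dict[str, float]:
    """Per-gene average log fold change between two cell groups.

    For log-normalized expression x, logFC = ln(mean(e^x - 1) + 1) over the
    in-group minus the same over the out-group — i.e. the log ratio of
    pseudocounted mean de-logged expression, the convention of the standard
    single-cell marker test.
    """
    if matrix.norm is None:
        raise ValueError("matrix is not normalized")
    in_cells, out_cells = list(in_cells), list(out_cells)
    if not in_cells or not out_cells:
        raise ValueError("both cell groups must be non-empty")
    if set(in_cells) & set(out_cells):
        raise ValueError("cell groups overlap")
    pos = {c: i for i, c in enumerate(matrix.cell_ids)}
    ii = np.array([pos[c] for c in in_cells])
    oo = np.array([pos[c] for c in out_cells])
    norm = sparse.csr_matrix(matrix.norm)
    mean_in = np.asarray(norm[:, ii].expm1().mean(axis=1)).ravel()
    mean_out = np.asarray(norm[:, oo].expm1().mean(axis=1)).ravel()
    lfc = np.log1p(mean_in) - np.log1p(mean_out)
    return dict(zip(matrix.gene_ids, lfc))


def expression_filter(
    matrix: ExpressionMatrix, min_frac: float = 0.01, min_level: float = 0.5
) -> list[str]:
    """Genes whose normalized expression exceeds ``min_level`` in strictly
    more than ``min_frac`` of cells."""
    if matrix.norm is None:
        raise ValueError("matrix is not normalized")
    norm = sparse.csr_matrix(matrix.norm)
    frac = np.asarray((norm > min_level).mean(axis=1)).ravel()
    return [g for g, f in zip(matrix.gene_ids, frac) if f > min_frac]


@dataclass
class RankedList:
    """Genes in descending order of a ranking statistic (average logFC).

    Ties in the statistic break by gene id so the order is reproducible.
    """

    genes: np.ndarray
    stats: np.ndarray

    @classmethod
    def from_dict(cls, stat_by_gene: dict[str, float]) -> "RankedList":
        items = sorted(stat_by_gene.items(), key=lambda kv: (-kv[1], kv[0]))
        genes = np.array([g for g, _ in items])
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate genes in ranking")
        return cls(genes=genes, stats=np.array([s for _, s in items], dtype=float))

    def __len__(self) -> int:
        return len(self.genes)


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, p: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted running-sum enrichment score of a gene set in a ranking.

    Walking the ranking top to bottom, the running sum rises by
    ``|r_i|^p / sum over hits of |r_j|^p`` at a set gene and falls by
    ``1 / (N - N_hits)`` at a non-set gene; ES is the extremum of largest
    magnitude (positive extremum preferred on exact magnitude ties). The
    leading edge is the set genes at or before a positive extremum, or at and
    after a negative one.

    Returns ``(ES, running_sum, leading_edge)``.
    """
    hit_mask = np.isin(ranked.genes, list(gene_set.members))
    n, nh = len(ranked), int(hit_mask.sum())
    if nh == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the ranking")
    if nh == n:
        raise ValueError("gene set covers the entire ranking")
    w = np.abs(ranked.stats) ** p
    wsum = w[hit_mask].sum()
    if wsum == 0:  # degenerate all-zero hit statistics: equal weights
        inc = hit_mask / nh
    else:
        inc = np.where(hit_mask, w / wsum, 0.0)
    dec = np.where(hit_mask, 0.0, 1.0 / (n - nh))
    running = np.cumsum(inc - dec)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es, i_ext, positive = float(running[i_max]), i_max, True
    else:
        es, i_ext, positive = float(running[i_min]), i_min, False
    if positive:
        leading = ranked.genes[: i_ext + 1][hit_mask[: i_ext + 1]]
    else:
        leading = ranked.genes[i_ext:][hit_mask[i_ext:]]
    return es, running, list(leading)


def _null_es(
    ranked: RankedList, set_size: int, p: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES values of ``n_perm`` random gene sets of ``set_size``, vectorized.

    Uses the fact that the running sum only attains its extrema at hit
    positions (just after a hit) or just before a hit (minimum candidate), so
    each permutation's ES is computable from its sorted hit positions alone.
    """
    n = len(ranked)
    w = np.abs(ranked.stats) ** p
    # sample hit positions without replacement per permutation
    pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :set_size]
    pos.sort(axis=1)
    wh = w[pos]  # n_perm x k weights at hits
    wsum = wh.sum(axis=1, keepdims=True)
    safe = np.where(wsum == 0, 1.0, wsum)
    inc = np.where(wsum == 0, 1.0 / set_size, wh / safe)
    cum_inc = np.cumsum(inc, axis=1)
    dec = 1.0 / (n - set_size)
    # misses before the j-th hit (0-based hit index j): pos[:, j] - j
    misses_before = pos - np.arange(set_size)[None, :]
    at_hit = cum_inc - misses_before * dec            # value just after hit j
    before_hit = cum_inc - inc - misses_before * dec  # value just before hit j
    # also the trailing tail after the last hit only decreases; min there is
    # at the very end: total = 1 - (n - k) * dec * ... = 0 at the end exactly
    maxima = at_hit.max(axis=1)
    minima = np.minimum(before_hit.min(axis=1), 0.0)
    return np.where(maxima >= -minima, maxima, minima)


@dataclass
class GseaResult:
    name: str
    es: float
    nes: float
    pval: float
    padj: float
    size: int
    leading_edge: list[str]


def gsea_preranked(
    ranked: RankedList,
    sets: list[GeneSet],
    p: float = 1.0,
    n_perm: int = 10000,
    seed: int = 0,
) -> list[GseaResult]:
    """Preranked GSEA over a collection of gene sets.

    Null distributions are built per set size from ``n_perm`` random same-size
    gene sets drawn from the ranked universe (seeded). For an observed ES,
    pval = (1 + #{same-sign null at least as extreme}) / (1 + #{same-sign
    null}), NES = ES / mean |same-sign null ES|, and padj is Benjamini-
    Hochberg across the sets analyzed in this call.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is very small; p-values will be coarse", n_perm)
    rng = np.random.default_rng(seed)
    universe = set(ranked.genes)
    observed: list[tuple[GeneSet, float, list[str], int]] = []
    for gs in sets:
        inter = gs.members & universe
        if not inter:
            logger.info("set %s empty after intersection; skipped", gs.name)
            continue
        es, _, le = enrichment_score(ranked, GeneSet(gs.name, frozenset(inter)), p=p)
        observed.append((gs, es, le, len(inter)))

    null_by_size: dict[int, np.ndarray] = {}
    results: list[GseaResult] = []
    pvals: list[float] = []
    for gs, es, le, size in observed:
        if size not in null_by_size:
            null_by_size[size] = _null_es(ranked, size, p, n_perm, rng)
        null = null_by_size[size]
        same_sign = null >= 0 if es >= 0 else null < 0
        n_sign = int(same_sign.sum())
        extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        pval = (1 + extreme) / (1 + n_sign)
        mean_mag = np.abs(null[same_sign]).mean() if n_sign else np.nan
        nes = es / mean_mag if n_sign and mean_mag > 0 else 0.0
        results.append(GseaResult(gs.name, es, float(nes), float(pval), 1.0, size, le))
        pvals.append(pval)
    if pvals:
        padj = multipletests(pvals, method="fdr_bh")[1]
        for r, q in zip(results, padj):
            r.padj = float(max(q, r.pval))
    return results
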