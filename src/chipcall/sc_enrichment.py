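"""Wilcoxon-AUC gene ranking and preranked GSEA for single-cell comparisons.

Per cluster, each gene is scored by the Wilcoxon rank-sum AUC between two
cell groups (e.g. cells from high-CHIP-burden vs. CHIP-negative samples):
auc = U / (n1 * n2), the probability that a random group-1 cell expresses
the gene higher than a random group-2 cell, ties counted half. The
preranked metric is the centered AUC (auc - 0.5), which is antisymmetric
under swapping the groups, so enrichment can be read two-sidedly.

Pathway enrichment then follows the classical weighted Kolmogorov–Smirnov
construction: walking the ranked list, in-set genes push a running sum up
by |score|^w normalized by the in-set total, out-of-set genes pull it down
by 1/(N - K); the enrichment score (ES) is the extremum, and the leading
edge is the in-set genes up to (positive ES) or after (negative ES) that
extremum. Significance comes from a gene-label permutation null preserving
set size; NES normalizes by the mean |null ES| of matching sign, and
p-values are Benjamini–Hochberg adjusted across the sets tested in one
call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .burden_stats import bh_adjust
from .io import GeneSet

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Cells-by-genes expression with cluster / sample / group labels.

    ``counts`` may be raw or library-size-normalized; only the within-gene
    rank order across cells matters to the AUC.
    """

    counts: np.ndarray  # (n_cells, n_genes)
    genes: list[str]
    cell_cluster: np.ndarray
    cell_sample: np.ndarray
    cell_group: np.ndarray

    def __post_init__(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.genes) != n_genes:
            raise ValueError("gene names do not match matrix width")
        for name in ("cell_cluster", "cell_sample", "cell_group"):
            labels = getattr(self, name)
            if len(labels) != n_cells:
                raise ValueError(f"{name} does not match matrix height")


@dataclass(frozen=True)
class RankedGene:
    gene: str
    auc: float
    u_statistic: float
    p_value: float
    rank_score: float  # auc - 0.5, the preranked metric


@dataclass
class RankedGeneList:
    """Genes sorted by rank_score descending (ties broken by gene name)."""

    entries: list[RankedGene]

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([e.rank_score for e in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    es: float
    nes: float
    p_perm: float
    padj: float
    leading_edge: tuple[str, ...]
    n_overlap: int
    p_floored: bool = False
    skipped_reason: str | None = None


def wilcoxon_auc(
    values_group1: Sequence[float], values_group2: Sequence[float]
) -> tuple[float, float, float]:
    """Rank-sum AUC, U statistic and two-sided p for two samples.

    U uses midranks for ties, so auc = U/(n1*n2) equals the win fraction
    with ties counted half. The p-value is the Mann-Whitney two-sided test
    (exact for small tie-free samples, tie-corrected normal approximation
    with continuity correction otherwise).
    """
    x = np.asarray(values_group1, dtype=float)
    y = np.asarray(values_group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)
    auc = u / (x.size * y.size)
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        p = 1.0  # all observations tied: no evidence either way
    else:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return auc, u, p


def rank_genes(
    expr: ExpressionMatrix,
    cluster: str,
    group_a: str,
    group_b: str,
    min_frac: float = 0.05,
) -> RankedGeneList | None:
    """AUC-rank all genes between two cell groups within one cluster.

    Genes detected (count > 0) in fewer than ``min_frac`` of cells in both
    groups are dropped. Returns None (with a warning) when the cluster
    lacks cells from either group, so per-cluster sweeps can skip cleanly.
    """
    in_cluster = expr.cell_cluster == cluster
    mask_a = in_cluster & (expr.cell_group == group_a)
    mask_b = in_cluster & (expr.cell_group == group_b)
    if not mask_a.any() or not mask_b.any():
        logger.warning(
            "cluster %r lacks cells for %r vs %r; skipped", cluster, group_a, group_b
        )
        return None
    a = np.asarray(expr.counts[mask_a])
    b = np.asarray(expr.counts[mask_b])
    frac_a = (a > 0).mean(axis=0)
    frac_b = (b > 0).mean(axis=0)
    keep = (frac_a >= min_frac) | (frac_b >= min_frac)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d genes below detection fraction %.2f", n_dropped, min_frac)
    entries = []
    for j in np.flatnonzero(keep):
        auc, u, p = wilcoxon_auc(a[:, j], b[:, j])
        entries.append(RankedGene(expr.genes[j], auc, u, p, auc - 0.5))
    entries.sort(key=lambda e: (-e.rank_score, e.gene))
    return RankedGeneList(entries)


def gsea_es(
    ranked: RankedGeneList | Sequence[str],
    gene_set: Sequence[str],
    weight_exponent: float = 1.0,
    scores: np.ndarray | None = None,
) -> tuple[float, np.ndarray, tuple[str, ...]]:
    """Weighted KS enrichment score, running sum and leading edge.

    Accepts either a RankedGeneList or a plain gene list plus ``scores``.
    """
    if isinstance(ranked, RankedGeneList):
        genes = ranked.genes
        scores = ranked.scores
    else:
        genes = list(ranked)
        if scores is None:
            raise ValueError("scores required with a plain gene list")
        scores = np.asarray(scores, dtype=float)
    in_set = np.isin(genes, list(gene_set))
    es, running, extremum_idx = _es_from_mask(scores, in_set, weight_exponent)
    set_idx = np.flatnonzero(in_set)
    if es > 0:
        leading = [genes[i] for i in set_idx if i <= extremum_idx]
    elif es < 0:
        leading = [genes[i] for i in set_idx if i >= extremum_idx]
    else:
        leading = []
    return es, running, tuple(leading)


def _es_from_mask(
    scores: np.ndarray, in_set: np.ndarray, weight_exponent: float
) -> tuple[float, np.ndarray, int]:
    n = scores.size
    k = int(in_set.sum())
    if k == 0 or k == n:
        return 0.0, np.zeros(n), 0
    weights = np.abs(scores) ** weight_exponent
    in_total = weights[in_set].sum()
    steps = np.where(in_set, 0.0, -1.0 / (n - k))
    if in_total > 0:
        steps = np.where(in_set, weights / in_total, steps)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        return float(running[i_max]), running, i_max
    return float(running[i_min]), running, i_min


def gsea_permutation(
    ranked: RankedGeneList,
    gene_sets: Sequence[GeneSet],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    weight_exponent: float = 1.0,
    min_set_size: int = 5,
) -> list[EnrichmentResult]:
    """Preranked GSEA over gene sets with a gene-label permutation null.

    For each set, the null draws ``n_perm`` random same-size gene subsets of
    the ranking. NES divides the observed ES by the mean |null ES| of the
    matching sign; p_perm = (1 + #{same-sign null at least as extreme}) /
    (1 + #same-sign null). Fully reproducible given the seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    genes = ranked.genes
    scores = ranked.scores
    n = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    results: list[EnrichmentResult] = []
    tested: list[int] = []
    pvals: list[float] = []
    for gs in gene_sets:
        overlap = [g for g in gs.genes if g in gene_index]
        n_dropped = len(gs.genes) - len(overlap)
        if n_dropped:
            logger.info("%s: %d genes absent from ranking", gs.name, n_dropped)
        if len(overlap) < min_set_size:
            results.append(
                EnrichmentResult(
                    pathway=gs.name,
                    es=np.nan,
                    nes=np.nan,
                    p_perm=np.nan,
                    padj=np.nan,
                    leading_edge=(),
                    n_overlap=len(overlap),
                    skipped_reason=f"overlap {len(overlap)} < min_set_size {min_set_size}",
                )
            )
            continue
        k = len(overlap)
        mask = np.zeros(n, dtype=bool)
        mask[[gene_index[g] for g in overlap]] = True
        es, _, leading = gsea_es(genes, overlap, weight_exponent, scores)
        null_es = np.empty(n_perm)
        for t in range(n_perm):
            perm_mask = np.zeros(n, dtype=bool)
            perm_mask[rng.choice(n, size=k, replace=False)] = True
            null_es[t], _, _ = _es_from_mask(scores, perm_mask, weight_exponent)
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same_sign.sum())
        floored = False
        if n_same == 0:
            p = 1.0 / (1.0 + n_perm)
            nes = np.nan
            floored = True
        else:
            extreme = np.abs(null_es[same_sign]) >= abs(es)
            p = (1.0 + int(extreme.sum())) / (1.0 + n_same)
            mean_null = np.abs(null_es[same_sign]).mean()
            nes = es / mean_null if mean_null > 0 else np.nan
        results.append(
            EnrichmentResult(
                pathway=gs.name,
                es=es,
                nes=nes,
                p_perm=p,
                padj=np.nan,  # filled below
                leading_edge=leading,
                n_overlap=k,
                p_floored=floored,
            )
        )
        tested.append(len(results) - 1)
        pvals.append(p)
    if pvals:
        adjusted = bh_adjust(pvals)
        for idx, padj in zip(tested, adjusted):
            r = results[idx]
            results[idx] = EnrichmentResult(
                pathway=r.pathway,
                es=r.es,
                nes=r.nes,
                p_perm=r.p_perm,
                padj=float(max(padj, r.p_perm)),
                leading_edge=r.leading_edge,
                n_overlap=r.n_overlap,
                p_floored=r.p_floored,
            )
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    if not df.empty:
        df["leading_edge"] = df["leading_edge"].map(lambda le: ",".join(le))
    return df
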