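"""Pre-ranked GSEA and single-sample GSEA (ssGSEA) statistics.

``gsea_preranked`` implements the weighted Kolmogorov–Smirnov running
sum on a ranked gene list: hit increments are proportional to
``|score|^weight_p`` and misses decrement uniformly; the enrichment
score (ES) is the maximum signed deviation. Significance comes from a
gene-label permutation null (set membership randomised over the fixed
ranking), with the normalised ES (NES) standardised by the mean |null
ES| of the same sign and BH correction across gene sets.

``ssgsea_score`` is the single-sample rank-weighted variant: within one
sample, genes are ranked by expression and the score is the summed gap
between the weighted in-set CDF and the uniform out-of-set CDF, with
weights ``rank^alpha``. It depends on a sample's expression only through
ranks, hence is invariant to monotone transforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "gsea_preranked", "ssgsea_score"]


@dataclass
class GeneSetCollection:
    """Named gene sets, optionally restricted to a data gene universe."""

    sets: Dict[str, List[str]]
    source: str = "<memory>"

    def restrict(
        self, genes: Iterable[str], min_size: int = 3, max_size: int = 5000
    ) -> "GeneSetCollection":
        universe = set(genes)
        kept = {}
        for name, members in self.sets.items():
            inter = [g for g in members if g in universe]
            if min_size <= len(inter) <= max_size:
                kept[name] = inter
            else:
                logger.info(
                    "gene set %s skipped: %d genes after intersection", name, len(inter)
                )
        return GeneSetCollection(kept, self.source)


def _running_es(
    order_scores: np.ndarray, hit_mask: np.ndarray, weight_p: float
) -> float:
    """ES of one gene-set membership pattern over a ranked score vector."""
    n = order_scores.size
    n_hits = int(hit_mask.sum())
    n_miss = n - n_hits
    if n_hits == 0 or n_miss == 0:
        return 0.0
    w = np.abs(order_scores) ** weight_p
    hit_w = np.where(hit_mask, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all-zero scores inside the set: fall back to uniform hits
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    running = np.cumsum(hit_w / total - (~hit_mask) / n_miss)
    return float(running[np.argmax(np.abs(running))])


def gsea_preranked(
    ranked: pd.Series,
    gene_sets: Mapping[str, Sequence[str]] | GeneSetCollection,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 3,
) -> pd.DataFrame:
    """Weighted-KS enrichment of each gene set on a pre-ranked list.

    ``ranked`` maps gene → score; genes are sorted by descending score
    (ties broken by symbol) internally. Returns a DataFrame with columns
    (set, size, ES, NES, p, adj_p). Sets intersecting the ranking in
    fewer than ``min_size`` genes are skipped with a log line.
    """
    if ranked.index.duplicated().any():
        raise ValueError("ranking contains duplicate genes")
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    if isinstance(gene_sets, GeneSetCollection):
        gene_sets = gene_sets.sets

    order = ranked.to_frame("score").assign(gene=ranked.index)
    order = order.sort_values(["score", "gene"], ascending=[False, True])
    genes = order["gene"].to_numpy()
    scores = order["score"].to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(genes)}
    n = genes.size
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in gene_sets.items():
        idx = [pos[g] for g in members if g in pos]
        if len(idx) < min_size:
            logger.info("gsea_preranked: set %s skipped (%d genes in ranking)", name, len(idx))
            continue
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        es = _running_es(scores, hit, weight_p)

        null = np.empty(n_perm)
        g = len(idx)
        for b in range(n_perm):
            perm_hit = np.zeros(n, dtype=bool)
            perm_hit[rng.choice(n, size=g, replace=False)] = True
            null[b] = _running_es(scores, perm_hit, weight_p)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same_sign.size == 0:
            p, nes = 1.0, 0.0
        else:
            p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + same_sign.size)
            nes = es / np.mean(np.abs(same_sign))
        rows.append({"set": name, "size": g, "ES": es, "NES": nes, "p": float(p)})

    table = pd.DataFrame(rows)
    if len(table):
        table["adj_p"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values(["p", "set"]).reset_index(drop=True)
    return table


def _ssgsea_one(expr: np.ndarray, genes: np.ndarray, members: set, alpha: float) -> float:
    """ssGSEA score of one sample: sum of (weighted hit CDF − miss CDF)."""
    n = expr.size
    ranks = stats.rankdata(expr, method="average")  # ascending: top gene = n
    desc = np.lexsort((genes, -ranks))  # descending rank, symbol tie-break
    in_set = np.fromiter((genes[i] in members for i in desc), bool, count=n)
    w = ranks[desc] ** alpha
    hit_w = np.where(in_set, w, 0.0)
    denom = hit_w.sum()
    n_miss = n - int(in_set.sum())
    if denom == 0 or n_miss == 0:
        return 0.0
    p_hit = np.cumsum(hit_w) / denom
    p_miss = np.cumsum(~in_set) / n_miss
    return float(np.sum(p_hit - p_miss))


def ssgsea_score(
    expression: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]] | GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
    min_size: int = 3,
) -> pd.DataFrame:
    """Samples × sets ssGSEA scores.

    ``expression`` is genes × samples. With ``normalize=True`` each set's
    scores are min–max scaled across samples (the common cross-sample
    normalisation); raw scores otherwise.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if isinstance(gene_sets, GeneSetCollection):
        gene_sets = gene_sets.sets
    genes = expression.index.to_numpy()
    usable = {}
    for name, members in gene_sets.items():
        inter = set(members) & set(genes)
        if len(inter) < min_size:
            logger.info("ssgsea_score: set %s skipped (%d genes present)", name, len(inter))
            continue
        usable[name] = inter

    out = pd.DataFrame(index=expression.columns, columns=list(usable), dtype=float)
    X = expression.to_numpy()
    for j, sample in enumerate(expression.columns):
        col = X[:, j]
        for name, members in usable.items():
            out.loc[sample, name] = _ssgsea_one(col, genes, members, alpha)
    if normalize:
        rng_span = out.max() - out.min()
        out = (out - out.min()) / rng_span.replace(0, np.nan)
        out = out.fillna(0.0)
    return out
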