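"""AUCell-style regulon activity scoring and group-specific regulon tests.

The regulon activity score (RAS) of a regulon in a cell is the area
under the recovery curve of the regulon's genes within the top fraction
of that cell's expression ranking, normalised by the maximal possible
area. Being rank-based, it is invariant to any monotone transform of a
cell's expression values. Group-specific regulons are found by one-way
ANOVA on RAS across cell groups with Benjamini–Hochberg correction.
"""

from __future__ import annotations

import logging
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ActivityMatrix, ExpressionMatrix, Regulon

logger = logging.getLogger(__name__)

__all__ = ["aucell_score", "score_all", "group_specific_regulons"]


def _rank_order(values: np.ndarray) -> np.ndarray:
    """Gene indices sorted by descending expression, stable in input order."""
    return np.argsort(-values, axis=0, kind="stable")


def _max_area(n_hits: int, k_top: int) -> float:
    """Area when all regulon genes occupy the very top ranks."""
    g = min(n_hits, k_top)
    return g * (g + 1) / 2 + (k_top - g) * g


def aucell_score(
    m: ExpressionMatrix, regulon: Regulon, top_frac: float = 0.05
) -> pd.Series:
    """Per-cell RAS for one regulon.

    For each cell, genes are ranked by descending expression (ties broken
    stably by input gene order); the recovery curve counts regulon genes
    within the top ``k`` ranks for ``k = 1..K`` with
    ``K = floor(top_frac * n_genes)``. RAS is the exact cumulative-sum
    area under this curve divided by the maximal achievable area, so it
    lies in [0, 1]. Regulon genes absent from the matrix are ignored; an
    empty intersection yields NaN for every cell.
    """
    if not 0 < top_frac < 1:
        raise ValueError(f"top_frac must lie in (0, 1), got {top_frac}")
    members = set(regulon.targets) & set(m.genes)
    if len(members) < len(regulon.targets):
        logger.info(
            "aucell_score(%s): %d/%d targets present",
            regulon.tf, len(members), len(regulon.targets),
        )
    if not members:
        logger.warning("aucell_score(%s): no target in matrix; RAS = NaN", regulon.tf)
        return pd.Series(np.nan, index=m.cells, name=regulon.tf)

    X = m.values.to_numpy()
    k_top = int(np.floor(top_frac * m.n_genes))
    if k_top < 1:
        raise ValueError("top_frac * n_genes < 1: no ranks to recover into")
    order = _rank_order(X)  # genes x cells, row k = gene index at rank k+1
    is_member = np.asarray(m.genes.isin(members))
    hits = is_member[order[:k_top, :]]  # K x cells
    area = np.cumsum(hits, axis=0).sum(axis=0)
    ras = area / _max_area(len(members), k_top)
    return pd.Series(np.clip(ras, 0.0, 1.0), index=m.cells, name=regulon.tf)


def score_all(
    m: ExpressionMatrix, regulons: Sequence[Regulon], top_frac: float = 0.05
) -> ActivityMatrix:
    """RAS for every regulon; one argsort of the matrix is shared."""
    if not 0 < top_frac < 1:
        raise ValueError(f"top_frac must lie in (0, 1), got {top_frac}")
    X = m.values.to_numpy()
    k_top = int(np.floor(top_frac * m.n_genes))
    if k_top < 1:
        raise ValueError("top_frac * n_genes < 1: no ranks to recover into")
    order = _rank_order(X)[:k_top, :]
    gene_pos = {g: i for i, g in enumerate(m.genes)}
    rows = {}
    for reg in regulons:
        members = [gene_pos[t] for t in reg.targets if t in gene_pos]
        if not members:
            logger.warning("score_all(%s): no target in matrix; RAS = NaN", reg.tf)
            rows[reg.tf] = np.full(m.n_cells, np.nan)
            continue
        is_member = np.zeros(m.n_genes, dtype=bool)
        is_member[members] = True
        hits = is_member[order]
        area = np.cumsum(hits, axis=0).sum(axis=0)
        rows[reg.tf] = np.clip(area / _max_area(len(members), k_top), 0.0, 1.0)
    values = pd.DataFrame(rows, index=m.cells).T
    return ActivityMatrix(values, m.cell_meta.copy())


def group_specific_regulons(
    activity: ActivityMatrix,
    groups: pd.Series,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """One-way ANOVA per regulon across cell groups, BH-adjusted.

    Groups with fewer than ``min_group_size`` cells are excluded with a
    warning; fewer than two usable groups is an error. Returns a table
    (regulon, F, p, adj_p, one mean column per group) sorted by adj_p
    then descending F.
    """
    groups = groups.reindex(activity.cells)
    counts = groups.value_counts()
    usable = counts[counts >= min_group_size].index.tolist()
    skipped = counts[counts < min_group_size].index.tolist()
    if skipped:
        logger.warning("group_specific_regulons: groups too small, excluded: %s", skipped)
    if len(usable) < 2:
        raise ValueError(f"need >= 2 groups with >= {min_group_size} cells")

    masks = {g: (groups == g).to_numpy() for g in usable}
    rows = []
    for name, ras in activity.values.iterrows():
        vals = ras.to_numpy()
        samples = [vals[mask] for mask in masks.values()]
        if any(np.isnan(s).any() for s in samples):
            continue
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*samples)
            # numerically degenerate contrasts (identical groups) can yield
            # tiny negative F and NaN p
            if not np.isfinite(f_stat) or f_stat < 0:
                f_stat = 0.0
            if not np.isfinite(p):
                p = 1.0
        row = {"regulon": name, "F": float(f_stat), "p": float(p)}
        for g, mask in masks.items():
            row[f"mean_{g}"] = float(vals[mask].mean())
        rows.append(row)
    table = pd.DataFrame(rows)
    table["adj_p"] = multipletests(table["p"], method="fdr_bh")[1]
    cols = ["regulon", "F", "p", "adj_p"] + [f"mean_{g}" for g in usable]
    return (
        table[cols]
        .sort_values(["adj_p", "F"], ascending=[True, False])
        .reset_index(drop=True)
    )
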