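"""Differential expression, signature construction and consensus subtyping.

Differential expression between two groups uses the two-sided Wilcoxon
rank-sum test per gene with BH correction, and a log-fold-change taken
as the difference of group means of log-scale expression. The subtype
signature intersects a regulon's genes (targets plus the TF) with genes
passing the DE thresholds. Subtypes are then discovered by consensus
clustering: repeated k-means on sample/feature subsamples accumulate a
co-assignment frequency matrix per k, final labels come from
hierarchical clustering of 1−consensus, and k is selected by the largest
relative delta-area of the consensus CDF (overridable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .datatypes import Regulon, SurvivalCohort

logger = logging.getLogger(__name__)

__all__ = [
    "differential_expression",
    "build_signature",
    "ConsensusResult",
    "consensus_cluster",
    "compare_subtypes",
]


def differential_expression(
    values: pd.DataFrame,
    group_labels: pd.Series,
    group1: Optional[str] = None,
    group2: Optional[str] = None,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE table between two groups.

    ``values`` is genes × samples on a log scale; ``logFC`` is
    mean(group1) − mean(group2) of those values. Returns one row per
    gene with (gene, logFC, p, adj_p), BH-adjusted across genes.
    """
    group_labels = group_labels.reindex(values.columns)
    levels = [g for g in group_labels.dropna().unique()]
    if group1 is None or group2 is None:
        if len(levels) != 2:
            raise ValueError(f"need exactly 2 groups, found {levels}")
        group1, group2 = levels
    m1 = (group_labels == group1).to_numpy()
    m2 = (group_labels == group2).to_numpy()
    if m1.sum() < 3 or m2.sum() < 3:
        raise ValueError(f"both groups need >= 3 samples ({m1.sum()}, {m2.sum()})")

    X = values.to_numpy()
    a, b = X[:, m1], X[:, m2]
    logfc = a.mean(axis=1) - b.mean(axis=1)
    # vectorised two-sided Wilcoxon rank-sum (normal approximation with ties)
    stat, p = stats.ranksums(a, b, axis=1)
    degenerate = (np.ptp(a, axis=1) == 0) & (np.ptp(b, axis=1) == 0) & (
        a[:, 0] == b[:, 0]
    )
    p = np.where(degenerate, 1.0, p)
    table = pd.DataFrame(
        {"gene": values.index, "logFC": logfc, "p": p},
    )
    table["adj_p"] = multipletests(table["p"], method="fdr_bh")[1]
    return table.reset_index(drop=True)


def filter_de(
    de: pd.DataFrame,
    adj_p: float = 0.05,
    logfc: float = 1.0,
    positive_only: bool = False,
) -> pd.DataFrame:
    """Apply the DE thresholds (adj_p < cutoff, |logFC| > cutoff).

    ``positive_only`` restricts to up-regulated genes (logFC > cutoff)
    instead of the default two-sided magnitude rule.
    """
    fc = de["logFC"] if positive_only else de["logFC"].abs()
    return de[(de["adj_p"] < adj_p) & (fc > logfc)].reset_index(drop=True)


def build_signature(regulon: Regulon, de_filtered: pd.DataFrame) -> List[str]:
    """Intersect a regulon's genes (targets + TF) with DE-passing genes."""
    de_genes = set(de_filtered["gene"])
    sig = sorted(regulon.genes & de_genes)
    if not sig:
        raise ValueError(
            f"signature of {regulon.tf} is empty: no regulon gene passes the DE "
            "thresholds — consider reviewing adj_p/logFC cutoffs"
        )
    logger.info("build_signature(%s): %d genes", regulon.tf, len(sig))
    return sig


@dataclass
class ConsensusResult:
    """Consensus matrices per k, CDF-based model selection and labels."""

    consensus: Dict[int, pd.DataFrame]
    selected_k: int
    labels: pd.Series
    labels_per_k: Dict[int, pd.Series]
    cdf_area: Dict[int, float]
    delta_area: Dict[int, float]


def _consensus_for_k(
    X: np.ndarray,
    k: int,
    n_resamples: int,
    sample_frac: float,
    feature_frac: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = X.shape[0]
    co = np.zeros((n, n))
    cnt = np.zeros((n, n))
    m = max(k + 1, int(round(sample_frac * n)))
    f = max(1, int(round(feature_frac * X.shape[1])))
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        feats = rng.choice(X.shape[1], size=f, replace=False)
        km = KMeans(
            n_clusters=k,
            n_init=3,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(X[np.ix_(idx, feats)])
        lab = km.labels_
        same = lab[:, None] == lab[None, :]
        co[np.ix_(idx, idx)] += same
        cnt[np.ix_(idx, idx)] += 1.0
    with np.errstate(invalid="ignore"):
        cons = np.where(cnt > 0, co / np.maximum(cnt, 1), 0.0)
    np.fill_diagonal(cons, 1.0)
    return cons


def _cdf_area(cons: np.ndarray) -> float:
    """Area under the empirical CDF of off-diagonal consensus entries."""
    vals = cons[np.triu_indices_from(cons, k=1)]
    grid = np.linspace(0.0, 1.0, 101)
    cdf = np.searchsorted(np.sort(vals), grid, side="right") / vals.size
    return float(np.trapezoid(cdf, grid))


def consensus_cluster(
    expression: pd.DataFrame,
    k_range: Sequence[int] = (2, 3, 4, 5),
    n_resamples: int = 100,
    sample_frac: float = 0.8,
    feature_frac: float = 0.8,
    seed: int = 0,
    force_k: Optional[int] = None,
) -> ConsensusResult:
    """Consensus clustering of samples (rows = samples, columns = features).

    For each k, ``n_resamples`` random subsamples of samples (and 80% of
    features by default) are clustered with k-means; co-assignment
    frequencies among co-sampled pairs form the consensus matrix. Final
    labels per k come from average-linkage hierarchical clustering of
    1−consensus. k is selected by the largest relative delta-area of the
    consensus CDF — the area at k=2, then the relative gain for each
    larger k — unless ``force_k`` overrides it.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if not 0.5 < sample_frac <= 1.0:
        raise ValueError(f"sample_frac must lie in (0.5, 1], got {sample_frac}")
    n = expression.shape[0]
    k_range = sorted(set(int(k) for k in k_range))
    k_max = max(2, n // 3)
    usable = [k for k in k_range if 2 <= k <= k_max]
    if usable != k_range:
        logger.warning("consensus_cluster: k_range clipped to %s", usable)
    if not usable:
        raise ValueError("no usable k in k_range")

    rng = np.random.default_rng(seed)
    X = expression.to_numpy(dtype=float)
    consensus: Dict[int, pd.DataFrame] = {}
    labels_per_k: Dict[int, pd.Series] = {}
    area: Dict[int, float] = {}
    for k in usable:
        cons = _consensus_for_k(X, k, n_resamples, sample_frac, feature_frac, rng)
        consensus[k] = pd.DataFrame(cons, index=expression.index, columns=expression.index)
        dist = squareform(1.0 - cons, checks=False)
        Z = hierarchy.linkage(dist, method="average")
        labels_per_k[k] = pd.Series(
            hierarchy.fcluster(Z, t=k, criterion="maxclust"),
            index=expression.index,
            name="subtype",
        )
        area[k] = _cdf_area(cons)

    delta: Dict[int, float] = {}
    for i, k in enumerate(usable):
        if i == 0:
            delta[k] = area[k]
        else:
            prev = usable[i - 1]
            delta[k] = (area[k] - area[prev]) / area[prev] if area[prev] > 0 else 0.0
    selected = force_k if force_k is not None else max(delta, key=lambda k: (delta[k], -k))
    if selected not in labels_per_k:
        raise ValueError(f"force_k={selected} not in evaluated k_range {usable}")
    logger.info("consensus_cluster: selected k=%d (delta areas %s)",
                selected, {k: round(v, 4) for k, v in delta.items()})
    return ConsensusResult(
        consensus=consensus,
        selected_k=selected,
        labels=labels_per_k[selected],
        labels_per_k=labels_per_k,
        cdf_area=area,
        delta_area=delta,
    )


def km_table(time: pd.Series, event: pd.Series) -> pd.DataFrame:
    """Kaplan–Meier survival table (time, at-risk, survival probability)."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    tbl = kmf.survival_function_.reset_index()
    tbl.columns = ["time", "survival"]
    return tbl


def compare_subtypes(
    cohort: SurvivalCohort,
    labels: pd.Series,
    gene_set_scores: Optional[pd.DataFrame] = None,
) -> dict:
    """Survival and gene-set-score contrasts between subtypes.

    Returns a dict with per-subtype KM tables, the log-rank chi-square
    and p-value, and (when ``gene_set_scores`` — samples × sets — is
    given) a per-set two-sided Wilcoxon comparison with BH correction.
    Subtypes without events are still plotted; the log-rank test warns.
    """
    labels = labels.reindex(cohort.samples)
    if labels.nunique() < 2:
        raise ValueError("need >= 2 subtypes")
    events_per = cohort.event.groupby(labels).sum()
    if (events_per == 0).any():
        logger.warning("compare_subtypes: subtypes with zero events: %s",
                       list(events_per[events_per == 0].index))

    km = {
        str(sub): km_table(cohort.time[labels == sub], cohort.event[labels == sub])
        for sub in sorted(labels.unique())
    }
    lr = multivariate_logrank_test(cohort.time, labels, cohort.event)
    out = {
        "km": km,
        "logrank_stat": float(lr.test_statistic),
        "logrank_p": float(lr.p_value),
    }

    if gene_set_scores is not None:
        subs = sorted(labels.unique())
        g1 = labels == subs[0]
        g2 = labels == subs[1]
        rows = []
        for name in gene_set_scores.columns:
            s = gene_set_scores[name].reindex(cohort.samples)
            stat, p = stats.ranksums(s[g1.to_numpy()], s[g2.to_numpy()])
            rows.append(
                {
                    "set": name,
                    "mean_1": float(s[g1.to_numpy()].mean()),
                    "mean_2": float(s[g2.to_numpy()].mean()),
                    "p": float(p),
                }
            )
        tbl = pd.DataFrame(rows)
        tbl["adj_p"] = multipletests(tbl["p"], method="fdr_bh")[1]
        out["set_comparison"] = tbl
    return out
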