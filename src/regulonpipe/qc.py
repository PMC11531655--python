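"""Cell-level quality control, normalisation, HVG selection and annotation.

Filtering keeps cells with a detected-gene count inside a fixed window
and a ribosomal read fraction strictly below a cap (ribosomal genes are
recognised by the community RPS*/RPL* symbol prefix convention).
Normalisation is library-size scaling to a fixed total followed by
log1p; highly variable genes are ranked by a binned dispersion
statistic. Annotation assigns each cell the type whose marker genes have
the highest mean normalised expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix
from .synthetic import DEFAULT_MARKERS

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerTable",
    "filter_cells",
    "normalize_and_select_hvg",
    "annotate_cells",
]


@dataclass
class MarkerTable:
    """Ordered cell-type → marker-gene map; order breaks score ties."""

    markers: Dict[str, List[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MARKERS.items()}
    )

    def __post_init__(self) -> None:
        for ct, genes in self.markers.items():
            if not genes or any(not isinstance(g, str) or not g for g in genes):
                raise ValueError(f"cell type {ct!r} has an empty or invalid marker list")


def ribosomal_fraction(m: ExpressionMatrix) -> pd.Series:
    """Fraction of counts on RPS*/RPL*-prefixed genes, per cell."""
    is_ribo = m.genes.str.startswith(("RPS", "RPL"))
    total = m.values.sum(axis=0)
    ribo = m.values.loc[is_ribo].sum(axis=0) if is_ribo.any() else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = ribo / total.replace(0, np.nan)
    return pd.Series(frac, index=m.cells).fillna(0.0)


def filter_cells(
    m: ExpressionMatrix,
    min_genes: int = 200,
    max_genes: int = 7000,
    max_ribo_frac: float = 0.05,
) -> Tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove cells outside the detected-gene window or with high ribo load.

    A cell is kept when ``min_genes <= detected genes <= max_genes`` and
    its ribosomal fraction is strictly below ``max_ribo_frac``. Returns
    the filtered matrix and a per-cell QC table with the removal reason.
    Idempotent: a second pass removes nothing.
    """
    if min_genes > max_genes:
        raise ValueError(f"min_genes ({min_genes}) exceeds max_genes ({max_genes})")
    detected = (m.values > 0).sum(axis=0)
    ribo = ribosomal_fraction(m)
    low = detected < min_genes
    high = detected > max_genes
    ribo_bad = ribo >= max_ribo_frac
    keep = ~(low | high | ribo_bad)
    qc = pd.DataFrame(
        {
            "n_genes": detected,
            "ribo_frac": ribo,
            "removed_low": low,
            "removed_high": high,
            "removed_ribo": ribo_bad,
            "kept": keep,
        }
    )
    logger.info(
        "filter_cells: %d/%d kept (low=%d, high=%d, ribo=%d)",
        int(keep.sum()), m.n_cells, int(low.sum()), int(high.sum()), int(ribo_bad.sum()),
    )
    if not keep.any():
        raise ValueError("all cells removed by QC filters")
    return m.subset_cells(m.cells[keep]), qc


def lognormalize(m: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Library-size normalise each cell to ``target_sum`` counts, then log1p."""
    totals = m.values.sum(axis=0).replace(0, np.nan)
    norm = np.log1p(m.values / totals * target_sum).fillna(0.0)
    return ExpressionMatrix(norm, m.cell_meta.copy())


def hvg_dispersion(values: pd.DataFrame, n_bins: int = 20) -> pd.Series:
    """Variance/mean dispersion of log-normalised values, z-scored in mean bins.

    Genes are grouped into ``n_bins`` equal-frequency bins of mean
    expression; within each bin the dispersion is standardised, making
    the statistic comparable across the expression range. Deterministic
    given the input.
    """
    mean = values.mean(axis=1)
    var = values.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = var / mean
    disp = disp.replace([np.inf, -np.inf], np.nan).fillna(0.0)
    # equal-frequency bins on mean, at least ~5 genes per bin
    n_bins = max(1, min(n_bins, len(disp) // 5))
    try:
        bins = pd.qcut(mean.rank(method="first"), q=n_bins, labels=False, duplicates="drop")
    except ValueError:
        bins = pd.Series(0, index=mean.index)
    out = pd.Series(0.0, index=values.index)
    for b in np.unique(bins):
        idx = bins == b
        d = disp[idx]
        sd = d.std(ddof=1)
        # centred dispersion when the bin is degenerate (zero spread)
        out[idx] = (d - d.mean()) / sd if sd > 0 else d - d.mean()
    return out


def normalize_and_select_hvg(
    m: ExpressionMatrix, n_hvg: int = 2000, target_sum: float = 1e4
) -> ExpressionMatrix:
    """Log-normalise all genes, then restrict to the top-dispersion genes.

    Ties in the dispersion ranking are broken by gene symbol order so the
    selection is deterministic. ``n_hvg`` larger than the gene count is
    clamped with a warning.
    """
    if n_hvg > m.n_genes:
        logger.warning("n_hvg=%d exceeds n_genes=%d; clamping", n_hvg, m.n_genes)
        n_hvg = m.n_genes
    norm = lognormalize(m, target_sum=target_sum)
    disp = hvg_dispersion(norm.values)
    order = pd.DataFrame({"disp": disp, "gene": disp.index}).sort_values(
        ["disp", "gene"], ascending=[False, True]
    )
    chosen = order["gene"].head(n_hvg)
    # preserve original gene order within the selection
    selected = [g for g in norm.genes if g in set(chosen)]
    return norm.subset_genes(selected)


def annotate_cells(
    m: ExpressionMatrix, markers: MarkerTable | None = None
) -> pd.Series:
    """Label each cell by the cell type with the highest mean marker score.

    Expects log-normalised expression. Marker genes absent from the
    matrix are dropped with a log line; a type with no marker present is
    excluded. Ties go to the earlier type in the table's order.
    """
    markers = markers or MarkerTable()
    scores = {}
    for ct, genes in markers.markers.items():
        present = [g for g in genes if g in m.genes]
        missing = set(genes) - set(present)
        if missing:
            logger.info("annotate_cells: %s markers missing for %s", sorted(missing), ct)
        if present:
            scores[ct] = m.values.loc[present].mean(axis=0)
    if not scores:
        raise ValueError("no marker gene of any cell type present in the matrix")
    score_df = pd.DataFrame(scores)  # cells x types, column order = table order
    labels = score_df.idxmax(axis=1)  # idxmax takes the first max -> tie rule
    props = labels.value_counts(normalize=True)
    logger.info("annotate_cells proportions: %s", props.round(3).to_dict())
    return labels.rename("cell_type")
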