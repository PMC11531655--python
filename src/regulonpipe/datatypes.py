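"""Core in-memory containers shared across the pipeline.

The pipeline operates on three kinds of tabular objects:

* :class:`ExpressionMatrix` — a genes × cells (or genes × samples) matrix
  with per-cell metadata, the unit of all single-cell stages;
* :class:`Regulon` — a transcription factor together with its inferred
  target genes and per-edge importance weights;
* :class:`ActivityMatrix` — regulons × cells AUCell activity scores;
* :class:`SurvivalCohort` — samples × genes expression paired with
  right-censored survival outcomes and optional clinical covariates.

All containers are thin wrappers over :class:`pandas.DataFrame` so that
indexing, alignment and on-disk round trips stay in pandas idiom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "Regulon",
    "ActivityMatrix",
    "SurvivalCohort",
]


@dataclass
class ExpressionMatrix:
    """Genes × cells expression values plus per-cell metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per cell.
        Gene symbols must be unique (collapse duplicates upstream).
    cell_meta
        DataFrame indexed by cell ID, aligned with ``values.columns``.
        Typical columns: ``condition`` (WT|MUT), ``sample``, ``cell_type``.
    """

    values: pd.DataFrame
    cell_meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.values.columns)
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols in matrix: {list(dup[:5])}")
        if not self.values.columns.equals(self.cell_meta.index):
            self.cell_meta = self.cell_meta.reindex(self.values.columns)

    # -- basic geometry -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        cells = pd.Index(cells)
        return ExpressionMatrix(self.values[cells], self.cell_meta.loc[cells])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        genes = pd.Index(genes)
        return ExpressionMatrix(self.values.loc[genes], self.cell_meta)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.cell_meta.copy())


@dataclass(frozen=True)
class Regulon:
    """A transcription factor with its target set and importance weights.

    Targets are kept in descending-importance order; the TF itself is
    never a member of its own target set.
    """

    tf: str
    targets: tuple
    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise ValueError(f"regulon {self.tf} lists its own TF as a target")
        for t, w in self.weights.items():
            if w < 0:
                raise ValueError(f"negative importance for edge {self.tf}->{t}")

    @property
    def size(self) -> int:
        return len(self.targets)

    @property
    def genes(self) -> set:
        """Targets plus the TF itself (the signature-building convention)."""
        return set(self.targets) | {self.tf}


@dataclass
class ActivityMatrix:
    """Regulons × cells AUCell regulon-activity scores (RAS) in [0, 1]."""

    values: pd.DataFrame
    cell_meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.values.columns)
        finite = self.values.to_numpy()
        finite = finite[np.isfinite(finite)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("RAS values must lie in [0, 1]")

    @property
    def regulons(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns


@dataclass
class SurvivalCohort:
    """Samples × genes expression with right-censored survival outcomes.

    ``time`` is follow-up in months (> 0) and ``event`` is 1 for an
    observed death, 0 for censoring. ``covariates`` may carry clinical
    columns such as WHO grade or IDH status.
    """

    expression: pd.DataFrame  # samples x genes
    time: pd.Series
    event: pd.Series
    covariates: pd.DataFrame = None
    name: str = "cohort"

    def __post_init__(self) -> None:
        if not self.expression.index.is_unique:
            raise ValueError("sample IDs must be unique")
        self.time = self.time.reindex(self.expression.index)
        self.event = self.event.reindex(self.expression.index)
        if (self.time <= 0).any():
            raise ValueError("survival times must be strictly positive")
        if not self.event.isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=self.expression.index)

    @property
    def samples(self) -> pd.Index:
        return self.expression.index

    @property
    def genes(self) -> pd.Index:
        return self.expression.columns

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset_genes(self, genes: Sequence[str]) -> "SurvivalCohort":
        genes = [g for g in genes if g in self.expression.columns]
        return SurvivalCohort(
            self.expression[genes], self.time, self.event, self.covariates, self.name
        )
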