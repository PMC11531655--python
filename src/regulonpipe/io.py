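"""File readers and writers for the pipeline's exchange formats.

Expression travels as Matrix Market (matrix.mtx + features.tsv +
barcodes.tsv) or dense CSV; gene sets as GMT; regulons as JSON; survival
cohorts as an expression CSV plus clinical TSV. All writers emit
deterministic row/column order so repeated runs produce byte-identical
artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .datatypes import ExpressionMatrix, Regulon, SurvivalCohort

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_prior",
    "write_prior",
    "read_regulons",
    "write_regulons",
    "read_cohort",
    "write_cohort",
]


def _collapse_duplicate_genes(values: pd.DataFrame) -> pd.DataFrame:
    if values.index.is_unique:
        return values
    dup = values.index[values.index.duplicated()].unique()
    logger.warning("collapsing %d duplicate gene symbols by sum: %s",
                   len(dup), list(dup[:5]))
    return values.groupby(level=0, sort=False).sum()


def read_expression(path: str | Path, format: str = "auto") -> ExpressionMatrix:
    """Read a genes × cells matrix from an MTX bundle directory or CSV.

    ``format`` is ``mtx`` (a directory holding matrix.mtx, features.tsv,
    barcodes.tsv and optionally cell_meta.tsv), ``csv`` (genes in rows,
    cells in columns, first column = gene symbol) or ``auto`` (by path
    type). Duplicate gene symbols are collapsed by summation.
    """
    path = Path(path)
    if format == "auto":
        format = "mtx" if path.is_dir() else "csv"
    if format == "mtx":
        mtx_file = path / "matrix.mtx"
        feat_file = path / "features.tsv"
        bc_file = path / "barcodes.tsv"
        for f in (mtx_file, feat_file, bc_file):
            if not f.exists():
                raise FileNotFoundError(f"missing {f}")
        try:
            mat = scipy_io.mmread(mtx_file)
        except ValueError as err:
            raise ValueError(f"malformed MTX file {mtx_file}: {err}") from err
        genes = pd.read_csv(feat_file, sep="\t", header=None)[0].astype(str)
        cells = pd.read_csv(bc_file, sep="\t", header=None)[0].astype(str)
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"MTX dimensions {mat.shape} do not match features ({len(genes)}) "
                f"x barcodes ({len(cells)})"
            )
        values = pd.DataFrame(
            np.asarray(mat.todense() if sparse.issparse(mat) else mat),
            index=genes.to_numpy(),
            columns=cells.to_numpy(),
        )
        meta_file = path / "cell_meta.tsv"
        meta = (
            pd.read_csv(meta_file, sep="\t", index_col=0) if meta_file.exists() else None
        )
    elif format == "csv":
        try:
            values = pd.read_csv(path, index_col=0)
        except ValueError as err:
            raise ValueError(f"parse error in {path}: {err}") from err
        non_numeric = values.columns[values.dtypes == object]
        if len(non_numeric):
            bad = values[non_numeric[0]]
            line = int(np.argmax(pd.to_numeric(bad, errors="coerce").isna())) + 2
            raise ValueError(
                f"non-numeric value in column {non_numeric[0]!r} near line {line} of {path}"
            )
        meta = None
    else:
        raise ValueError(f"unknown format {format!r}")
    values = _collapse_duplicate_genes(values)
    return ExpressionMatrix(values, meta)


def write_expression(m: ExpressionMatrix, path: str | Path, format: str = "mtx") -> Path:
    """Write a matrix as an MTX bundle directory or a dense CSV file."""
    path = Path(path)
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        scipy_io.mmwrite(path / "matrix.mtx", sparse.csr_matrix(m.values.to_numpy()))
        pd.Series(m.genes).to_csv(path / "features.tsv", sep="\t", index=False, header=False)
        pd.Series(m.cells).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
        if len(m.cell_meta.columns):
            m.cell_meta.to_csv(path / "cell_meta.tsv", sep="\t")
    elif format == "csv":
        path.parent.mkdir(parents=True, exist_ok=True)
        m.values.to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_gmt(path: str | Path) -> Dict[str, List[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> ..."""
    sets: Dict[str, List[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs >= 3 tab-separated fields")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Dict[str, Sequence[str]], path: str | Path, description: str = "na") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
    return path


def read_prior(path: str | Path) -> pd.DataFrame:
    """Read a TF→candidate-target prior table (TSV with tf/target columns)."""
    prior = pd.read_csv(path, sep="\t")
    if not {"tf", "target"} <= set(prior.columns):
        raise ValueError(f"prior table {path} must have 'tf' and 'target' columns")
    return prior[["tf", "target"]]


def write_prior(prior: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    prior[["tf", "target"]].to_csv(path, sep="\t", index=False)
    return path


def write_regulons(regulons: Sequence[Regulon], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [
        {"tf": r.tf, "targets": list(r.targets), "weights": dict(r.weights)}
        for r in regulons
    ]
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_regulons(path: str | Path) -> List[Regulon]:
    payload = json.loads(Path(path).read_text())
    return [
        Regulon(tf=r["tf"], targets=tuple(r["targets"]), weights=r.get("weights", {}))
        for r in payload
    ]


def write_cohort(cohort: SurvivalCohort, expr_path: str | Path, clin_path: str | Path) -> None:
    """Write a cohort as expression CSV (samples × genes) + clinical TSV."""
    Path(expr_path).parent.mkdir(parents=True, exist_ok=True)
    cohort.expression.to_csv(expr_path)
    clin = pd.DataFrame({"time": cohort.time, "event": cohort.event})
    clin = pd.concat([clin, cohort.covariates], axis=1)
    clin.to_csv(clin_path, sep="\t")


def read_cohort(expr_path: str | Path, clin_path: str | Path, name: str = "cohort") -> SurvivalCohort:
    expr = pd.read_csv(expr_path, index_col=0)
    clin = pd.read_csv(clin_path, sep="\t", index_col=0)
    for col in ("time", "event"):
        if col not in clin.columns:
            raise ValueError(f"clinical table {clin_path} missing column {col!r}")
    covs = clin.drop(columns=["time", "event"])
    return SurvivalCohort(
        expression=expr,
        time=clin["time"],
        event=clin["event"].astype(int),
        covariates=covs if len(covs.columns) else None,
        name=name,
    )
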