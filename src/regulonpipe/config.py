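"""Structured pipeline configuration with range validation.

Every stage parameter lives on :class:`PipelineConfig`, validated before
any stage runs. Defaults follow the analysis conventions: QC window
200–7000 detected genes and ribosomal fraction < 5%, 2000 HVGs, minimum
regulon size 10, CSI dendrogram cut height 8, DE thresholds
adj_p < 0.05 and |logFC| > 1. Configs can be loaded from a YAML file and
selectively overridden (the CLI maps flags onto these fields).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Tuple

import yaml
from pydantic import BaseModel, Field, model_validator


class PipelineConfig(BaseModel):
    """All stage parameters for an end-to-end run."""

    # paths
    outdir: str = "regulonpipe_out"

    # QC
    min_genes: int = Field(200, ge=0)
    max_genes: int = Field(7000, ge=1)
    max_ribo_frac: float = Field(0.05, ge=0.0, le=1.0)
    n_hvg: int = Field(2000, ge=1)

    # meta-cells / GRN
    cells_per_metacell: int = Field(10, ge=1)
    n_pcs: int = Field(20, ge=2)
    grn_method: str = "forward"
    grn_n_estimators: int = Field(50, ge=10)
    min_regulon_size: int = Field(10, ge=1)

    # activity / CSI
    aucell_top_frac: float = Field(0.05, gt=0.0, lt=1.0)
    csi_delta: float = Field(0.05, ge=0.0, le=1.0)
    csi_cut_height: float = Field(8.0, gt=0.0)

    # DE / subtyping
    de_adj_p: float = Field(0.05, gt=0.0, le=1.0)
    de_logfc: float = Field(1.0, ge=0.0)
    consensus_k_min: int = Field(2, ge=2)
    consensus_k_max: int = Field(5, ge=2)
    consensus_resamples: int = Field(100, ge=50)
    consensus_sample_frac: float = Field(0.8, gt=0.5, lt=1.0)

    # prognosis
    cox_p: float = Field(0.05, gt=0.0, le=1.0)

    # seeds
    seed: int = Field(0, ge=0)
    sim_seed_sc: int = Field(1, ge=0)
    sim_seed_bulk: int = Field(2, ge=0)

    @model_validator(mode="after")
    def _cross_field(self) -> "PipelineConfig":
        if self.min_genes > self.max_genes:
            raise ValueError(
                f"min_genes ({self.min_genes}) must not exceed max_genes ({self.max_genes})"
            )
        if self.consensus_k_min > self.consensus_k_max:
            raise ValueError("consensus_k_min must not exceed consensus_k_max")
        if self.grn_method not in ("forward", "gbm", "spearman"):
            raise ValueError(f"grn_method must be forward|gbm|spearman, got {self.grn_method!r}")
        return self

    @property
    def consensus_k_range(self) -> Tuple[int, ...]:
        return tuple(range(self.consensus_k_min, self.consensus_k_max + 1))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def params(self) -> dict:
        """Stage parameters without the output path (for manifests/hashes)."""
        return self.model_dump(exclude={"outdir"})

    def config_hash(self) -> str:
        payload = json.dumps(self.params(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
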