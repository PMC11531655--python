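"""Synthetic single-cell and bulk-cohort generators with planted ground truth.

The single-cell generator emulates the structure the regulon pipeline
assumes in droplet scRNA-seq of glioma tissue from two conditions (IDH
wild-type vs mutant):

* negative-binomial counts with uniform Bernoulli dropout;
* cell types defined by elevated marker genes;
* transcription factors organised into co-active modules, each TF driving
  a disjoint target-gene regulon through a latent per-cell activity;
* one or more modules whose mean activity is shifted in the WT condition
  (the "differentially active module" phenomenon the analysis recovers).

The bulk generator emulates a survival cohort of wild-type patients:
expression of a planted signature differs between two latent subtypes and
drives an exponential hazard, with independent exponential censoring
calibrated to a target censoring fraction.

Every draw flows from one :class:`numpy.random.Generator` seeded from the
config, so a fixed config reproduces byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import ExpressionMatrix, SurvivalCohort

__all__ = [
    "SimConfig",
    "GroundTruth",
    "DEFAULT_CELL_TYPE_PROPS",
    "simulate_single_cell",
    "simulate_bulk_cohort",
    "make_gene_sets",
    "make_prior",
]

# Marker panel used both for planting cell types and for annotation.
DEFAULT_MARKERS: Dict[str, List[str]] = {
    "astrocyte": ["S100B", "AQP4", "GFAP"],
    "microglia": ["CSF1R", "CX3CR1", "P2RY12", "TMEM119"],
    "oligodendrocyte": ["OLIG1", "MAG", "OLIG2", "PLP1", "MOG", "MBP"],
    "epithelial": ["CD44", "CDH2"],
    "macrophage": ["AIF1", "CD163", "CD68"],
    "neuron": ["DCX", "MAP2", "STMN2"],
    "T cell": ["CD3D", "CD3E", "CD8A"],
    "endothelial": ["VWF", "CD34", "FLT1", "CLDN5"],
}

# Rough glioma-tissue composition: astrocytes dominate, followed by
# myeloid cells; lymphocytes and endothelium are rare.
DEFAULT_CELL_TYPE_PROPS: Dict[str, float] = {
    "astrocyte": 0.40,
    "microglia": 0.22,
    "oligodendrocyte": 0.12,
    "macrophage": 0.08,
    "epithelial": 0.05,
    "neuron": 0.05,
    "T cell": 0.04,
    "endothelial": 0.04,
}

_RIBO_GENES = [f"RPS{i}" for i in range(1, 6)] + [f"RPL{i}" for i in range(1, 6)]


class ConfigError(ValueError):
    """A SimConfig field violates its documented range."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Single-cell block
    -----------------
    n_cells : cells *per condition* (WT and MUT each get this many).
    n_genes : total genes, including TFs, targets, markers, ribosomal
        and background genes.
    n_tfs : number of transcription factors, each owning a regulon.
    targets_per_regulon : disjoint targets planted per TF.
    n_modules : number of co-active TF modules (a partition of the TFs).
    n_shifted_modules : leading modules whose WT mean activity is raised
        by ``activity_shift`` (MUT stays at 0).
    activity_shift : log-scale mean shift of module activity in WT.
    module_icc : intraclass correlation of TF activities within a module.
        Per-cell TF activity has unit total variance, split between a
        shared module latent (variance ``module_icc``) and TF-specific
        noise (variance ``1 - module_icc``).
    dropout_rate : uniform Bernoulli zeroing probability.
    nb_dispersion : NB dispersion θ (variance = μ + μ²/θ).

    Bulk block
    ----------
    n_samples : cohort size.
    n_signature_genes : planted prognostic/subtype genes.
    subtype_sep : mean shift (in noise SDs) of signature genes in subtype 1.
    beta : log-hazard coefficient per signature gene.
    censor_rate : target fraction of censored samples.
    baseline_hazard : hazard at the cohort-mean linear predictor
        (default anchors median survival near 24 months).
    """

    n_cells: int = 1500
    n_genes: int = 2000
    n_tfs: int = 50
    targets_per_regulon: int = 20
    n_modules: int = 4
    n_shifted_modules: int = 1
    activity_shift: float = 1.5
    module_icc: float = 0.5
    dropout_rate: float = 0.2
    nb_dispersion: float = 2.0
    marker_boost: float = 40.0
    n_samples: int = 200
    n_signature_genes: int = 10
    subtype_sep: float = 2.0
    beta: float = 1.0
    censor_rate: float = 0.3
    baseline_hazard: float = math.log(2) / 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "censor_rate", "module_icc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ConfigError(f"nb_dispersion must be positive, got {self.nb_dispersion}")
        n_markers = sum(len(v) for v in DEFAULT_MARKERS.values())
        reserved = self.n_tfs * (1 + self.targets_per_regulon) + n_markers + len(_RIBO_GENES)
        if reserved > self.n_genes:
            raise ConfigError(
                "n_genes too small: n_tfs*(1+targets_per_regulon)+markers+ribosomal "
                f"= {reserved} exceeds n_genes = {self.n_genes}"
            )
        if self.n_modules < 1 or self.n_modules > self.n_tfs:
            raise ConfigError(f"n_modules must lie in [1, n_tfs], got {self.n_modules}")
        if not 0 <= self.n_shifted_modules <= self.n_modules:
            raise ConfigError(
                f"n_shifted_modules must lie in [0, n_modules], got {self.n_shifted_modules}"
            )
        if self.n_signature_genes > self.n_tfs * self.targets_per_regulon:
            raise ConfigError("n_signature_genes exceeds the planted target pool")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset.

    ``regulons`` maps each TF to its disjoint targets; ``modules``
    partitions TFs into co-active modules; ``latent_activity`` stores the
    per-cell TF activity used to generate counts (TF × cell), enabling
    oracle checks that regenerate downstream quantities from the latents.
    """

    genes: List[str] = field(default_factory=list)
    regulons: Dict[str, List[str]] = field(default_factory=dict)
    edge_weights: Dict[Tuple[str, str], float] = field(default_factory=dict)
    modules: Dict[str, int] = field(default_factory=dict)
    module_means: Dict[int, Dict[str, float]] = field(default_factory=dict)
    cell_types: Optional[pd.Series] = None
    marker_genes: Dict[str, List[str]] = field(default_factory=dict)
    latent_activity: Optional[pd.DataFrame] = None
    subtype_labels: Optional[pd.Series] = None
    signature_genes: List[str] = field(default_factory=list)
    beta: Dict[str, float] = field(default_factory=dict)

    @property
    def shifted_modules(self) -> List[int]:
        return [
            m for m, means in self.module_means.items() if means["WT"] != means["MUT"]
        ]

    def to_json_dict(self) -> dict:
        return {
            "regulons": self.regulons,
            "edge_weights": {f"{tf}\t{t}": w for (tf, t), w in self.edge_weights.items()},
            "modules": self.modules,
            "module_means": {str(k): v for k, v in self.module_means.items()},
            "cell_types": None if self.cell_types is None else self.cell_types.to_dict(),
            "marker_genes": self.marker_genes,
            "subtype_labels": None
            if self.subtype_labels is None
            else self.subtype_labels.to_dict(),
            "signature_genes": self.signature_genes,
            "beta": self.beta,
        }


def _gene_names(config: SimConfig) -> Tuple[List[str], List[str], List[str]]:
    """Return (all genes, tf names, target names) in a fixed order."""
    tfs = [f"TF{i:03d}" for i in range(1, config.n_tfs + 1)]
    n_targets = config.n_tfs * config.targets_per_regulon
    targets = [f"TG{i:04d}" for i in range(1, n_targets + 1)]
    markers = [m for ms in DEFAULT_MARKERS.values() for m in ms]
    n_bg = config.n_genes - len(tfs) - len(targets) - len(markers) - len(_RIBO_GENES)
    background = [f"BG{i:04d}" for i in range(1, n_bg + 1)]
    genes = tfs + targets + markers + _RIBO_GENES + background
    return genes, tfs, targets


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB(mean=mu, dispersion=theta) via the gamma–Poisson mixture."""
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam)


def simulate_single_cell(config: SimConfig) -> Tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a two-condition scRNA-seq count matrix with planted regulons.

    Per cell, each module draws a shared latent ``L = mean(condition) + N(0,1)``;
    a TF's activity adds TF-specific noise, and both the TF's own transcript
    and its targets have NB mean ``baseline * exp(w * activity)``. Marker
    genes are elevated only in their own cell type. Counts are NB draws
    zeroed with probability ``dropout_rate``.
    """
    rng = np.random.default_rng(config.seed)
    genes, tfs, target_names = _gene_names(config)

    n_cells_total = 2 * config.n_cells
    cell_ids = [f"C{i:06d}" for i in range(1, n_cells_total + 1)]
    condition = np.array(["WT"] * config.n_cells + ["MUT"] * config.n_cells)

    # cell types drawn once, independent of condition
    types = list(DEFAULT_MARKERS)
    props = np.array([DEFAULT_CELL_TYPE_PROPS[t] for t in types])
    cell_type = rng.choice(types, size=n_cells_total, p=props / props.sum())
    sample = np.where(
        condition == "WT",
        [f"WT_s{1 + i % 3}" for i in range(n_cells_total)],
        [f"MUT_s{1 + i % 3}" for i in range(n_cells_total)],
    )

    # TF -> module as contiguous blocks so modules are near-equal in size
    modules = {tf: 1 + (i * config.n_modules) // config.n_tfs for i, tf in enumerate(tfs)}
    module_means = {
        m: {
            "WT": config.activity_shift if m <= config.n_shifted_modules else 0.0,
            "MUT": 0.0,
        }
        for m in range(1, config.n_modules + 1)
    }

    # TF activity = condition mean + shared module latent + TF noise; unit
    # total variance with intraclass correlation module_icc
    cond_is_wt = condition == "WT"
    lat_sd = math.sqrt(config.module_icc)
    noise_sd = math.sqrt(1.0 - config.module_icc)
    module_latent = np.empty((config.n_modules, n_cells_total))
    for m in range(1, config.n_modules + 1):
        mean = np.where(cond_is_wt, module_means[m]["WT"], module_means[m]["MUT"])
        module_latent[m - 1] = mean + lat_sd * rng.standard_normal(n_cells_total)
    tf_activity = np.empty((config.n_tfs, n_cells_total))
    for i, tf in enumerate(tfs):
        tf_activity[i] = module_latent[modules[tf] - 1] + noise_sd * rng.standard_normal(
            n_cells_total
        )

    # regulon map: disjoint target blocks; the TF transcript itself reads
    # out its activity with unit gain (the co-expression assumption)
    regulons: Dict[str, List[str]] = {}
    edge_weights: Dict[Tuple[str, str], float] = {}
    tf_weight = np.ones(config.n_tfs)
    for i, tf in enumerate(tfs):
        block = target_names[
            i * config.targets_per_regulon : (i + 1) * config.targets_per_regulon
        ]
        regulons[tf] = list(block)
        for t in block:
            edge_weights[(tf, t)] = float(rng.uniform(0.5, 1.5))

    baseline = rng.lognormal(mean=math.log(0.8), sigma=0.6, size=config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    # TFs are moderately expressed so their transcript is a usable
    # activity readout
    for tf in tfs:
        baseline[gene_index[tf]] = 2.0
    # background genes include a housekeeping-like heavy tail so library
    # size is dominated by constitutive expression, as in real cells
    bg_idx = [gene_index[g] for g in genes if g.startswith("BG")]
    baseline[bg_idx] = rng.lognormal(mean=math.log(2.0), sigma=1.0, size=len(bg_idx))
    # canonical markers are near-exclusive to their type: low shared
    # off-type baseline, strong in-type boost
    for ms in DEFAULT_MARKERS.values():
        for mgene in ms:
            baseline[gene_index[mgene]] = 0.25

    log_mu = np.tile(np.log(baseline)[:, None], (1, n_cells_total))
    for i, tf in enumerate(tfs):
        log_mu[gene_index[tf]] += tf_weight[i] * tf_activity[i]
        for t in regulons[tf]:
            log_mu[gene_index[t]] += edge_weights[(tf, t)] * tf_activity[i]
    for ct, ms in DEFAULT_MARKERS.items():
        mask = cell_type == ct
        for mgene in ms:
            log_mu[gene_index[mgene], mask] += math.log(config.marker_boost)

    mu = np.exp(np.clip(log_mu, -20, 12))
    counts = _nb_counts(rng, mu, config.nb_dispersion).astype(float)
    if config.dropout_rate > 0:
        keep = rng.random(counts.shape) >= config.dropout_rate
        counts *= keep

    values = pd.DataFrame(counts, index=genes, columns=cell_ids)
    cell_meta = pd.DataFrame(
        {"condition": condition, "sample": sample, "cell_type": cell_type},
        index=cell_ids,
    )
    truth = GroundTruth(
        genes=genes,
        regulons=regulons,
        edge_weights=edge_weights,
        modules=modules,
        module_means=module_means,
        cell_types=pd.Series(cell_type, index=cell_ids, name="cell_type"),
        marker_genes={k: list(v) for k, v in DEFAULT_MARKERS.items()},
        latent_activity=pd.DataFrame(tf_activity, index=tfs, columns=cell_ids),
    )
    return ExpressionMatrix(values, cell_meta), truth


def _censoring_rate_for_target(hazards: np.ndarray, target: float) -> float:
    """Solve for the exponential censoring rate giving the target fraction.

    With T_i ~ Exp(h_i) and C ~ Exp(c) independent, P(censored_i) =
    c / (c + h_i); the overall expected censoring fraction is the mean.
    """
    if target <= 0:
        return 0.0
    if target >= 1:
        return math.inf

    def frac(c: float) -> float:
        return float(np.mean(c / (c + hazards))) - target

    hi = float(np.max(hazards)) * target / (1 - target) + 1e-12
    while frac(hi) < 0:
        hi *= 2
    return float(optimize.brentq(frac, 1e-15, hi, xtol=1e-12, rtol=1e-10))


def simulate_bulk_cohort(
    config: SimConfig,
    truth: Optional[GroundTruth] = None,
    seed: Optional[int] = None,
    name: str = "cohort",
    signature_pool: Optional[List[str]] = None,
) -> Tuple[SurvivalCohort, GroundTruth]:
    """Simulate a bulk survival cohort with two planted subtypes.

    Expression is Gaussian on a log-like scale; planted signature genes
    are shifted by ``subtype_sep`` SDs in subtype 1. Survival times are
    exponential with hazard ``h0 * exp(lp - mean(lp))`` where ``lp`` is
    the planted linear predictor ``sum(beta * x_signature)``; censoring
    is independent exponential, its rate solved so the expected censored
    fraction equals ``censor_rate``.

    If ``truth`` from :func:`simulate_single_cell` is given, the cohort
    reuses the same gene universe and draws its signature genes from the
    targets of the shifted modules, tying the bulk stages to the
    single-cell regulon structure; otherwise a standalone gene space is
    generated. An explicit ``signature_pool`` narrows the pool the
    signature genes are drawn from (e.g. the targets of one analysis-
    selected regulon).
    """
    if config.n_samples < 40:
        raise ConfigError(f"n_samples must be >= 40, got {config.n_samples}")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    if truth is not None and truth.genes:
        genes = list(truth.genes)
        if signature_pool is not None:
            pool = [g for g in signature_pool if g in set(genes)]
        else:
            shifted = set(truth.shifted_modules) or set(truth.module_means)
            pool = [
                t
                for tf, targets in truth.regulons.items()
                if truth.modules[tf] in shifted
                for t in targets
            ]
        if len(pool) < config.n_signature_genes:
            raise ConfigError(
                f"signature pool ({len(pool)}) smaller than n_signature_genes "
                f"({config.n_signature_genes})"
            )
        sig = [str(g) for g in rng.choice(pool, size=config.n_signature_genes, replace=False)]
    else:
        genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
        pool = (
            [g for g in signature_pool if g in set(genes)]
            if signature_pool is not None
            else genes
        )
        if len(pool) < config.n_signature_genes:
            raise ConfigError(
                f"signature pool ({len(pool)}) smaller than n_signature_genes "
                f"({config.n_signature_genes})"
            )
        sig = [str(g) for g in rng.choice(pool, size=config.n_signature_genes, replace=False)]

    n = config.n_samples
    samples = [f"{name}_S{i:04d}" for i in range(1, n + 1)]
    subtype = np.array([1] * (n // 2) + [2] * (n - n // 2))
    subtype = subtype[rng.permutation(n)]

    expr = rng.standard_normal((n, len(genes)))
    expr_df = pd.DataFrame(expr, index=samples, columns=genes)
    sig_idx = [genes.index(g) for g in sig]
    expr_df.iloc[:, sig_idx] += config.subtype_sep * (subtype == 1)[:, None]

    lp = config.beta * expr_df[sig].to_numpy().sum(axis=1)
    lp = lp - lp.mean()
    hazards = config.baseline_hazard * np.exp(lp)
    times = rng.exponential(1.0 / hazards)

    c_rate = _censoring_rate_for_target(hazards, config.censor_rate)
    if c_rate == 0.0:
        event = np.ones(n, dtype=int)
    else:
        cens = rng.exponential(1.0 / c_rate, size=n)
        event = (times <= cens).astype(int)
        times = np.minimum(times, cens)
    times = np.maximum(times, 1e-6)

    grade = rng.choice(["II", "III", "IV"], size=n, p=[0.2, 0.3, 0.5])
    covariates = pd.DataFrame({"grade": grade, "idh_status": "WT"}, index=samples)

    cohort = SurvivalCohort(
        expression=expr_df,
        time=pd.Series(times, index=samples, name="time"),
        event=pd.Series(event, index=samples, name="event"),
        covariates=covariates,
        name=name,
    )
    bulk_truth = GroundTruth(
        genes=genes,
        subtype_labels=pd.Series(subtype, index=samples, name="subtype"),
        signature_genes=sig,
        beta={g: config.beta for g in sig},
    )
    if truth is not None:
        bulk_truth.regulons = truth.regulons
        bulk_truth.modules = truth.modules
        bulk_truth.module_means = truth.module_means
    return cohort, bulk_truth


def make_gene_sets(
    truth: GroundTruth,
    n_sets: int,
    set_size: int,
    overlap: float = 0.5,
    seed: int = 0,
) -> Dict[str, List[str]]:
    """Build gene sets overlapping the planted signature at a set fraction.

    Emulates curated collections (death pathways, immune features) whose
    member genes partially coincide with the condition-responsive genes.
    A fraction ``overlap`` of each set is drawn from the planted signature
    pool (capped at the pool size), the rest from the remaining genes.
    """
    if not truth.genes:
        raise ValueError("truth carries no gene universe")
    if set_size > len(truth.genes):
        raise ValueError(f"set_size {set_size} exceeds gene universe {len(truth.genes)}")
    if not 0.0 <= overlap <= 1.0:
        raise ValueError(f"overlap must lie in [0, 1], got {overlap}")
    rng = np.random.default_rng(seed)
    pool = list(truth.signature_genes)
    rest = [g for g in truth.genes if g not in set(pool)]
    sets: Dict[str, List[str]] = {}
    for i in range(1, n_sets + 1):
        k = min(len(pool), int(round(overlap * set_size)))
        chosen = [str(g) for g in rng.choice(pool, size=k, replace=False)] if k else []
        filler = [str(g) for g in rng.choice(rest, size=set_size - k, replace=False)]
        sets[f"SET{i:02d}"] = chosen + filler
    return sets


def make_prior(
    truth: GroundTruth,
    decoys_per_tf: int = 0,
    drop_frac: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a TF→candidate-target prior table from planted regulons.

    Stands in for a motif database: by default it covers exactly the
    planted pairs; ``decoys_per_tf`` adds random non-target candidates and
    ``drop_frac`` removes a fraction of true pairs, mimicking an imperfect
    motif scan. Returns a two-column DataFrame (tf, target).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for tf, targets in truth.regulons.items():
        kept = [t for t in targets if drop_frac == 0.0 or rng.random() >= drop_frac]
        rows.extend((tf, t) for t in kept)
        if decoys_per_tf:
            non_targets = [g for g in truth.genes if g not in set(targets) and g != tf]
            decoys = rng.choice(non_targets, size=decoys_per_tf, replace=False)
            rows.extend((tf, d) for d in decoys)
    return pd.DataFrame(rows, columns=["tf", "target"])
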