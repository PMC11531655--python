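"""Prognostic screening, the survival-model grid and risk evaluation.

The screening stage fits a univariate Cox proportional-hazards model per
gene (Newton iterations on the Efron partial likelihood, tolerance
1e-8) and keeps genes below a Wald p-value threshold. The model grid
crosses feature selectors (none, lasso-Cox, stepwise-Cox, RSF
permutation importance) with final risk models (random survival forest,
lasso/ridge/elastic-net Cox, stepwise Cox, componentwise gradient
boosting), drops redundant selector/model pairs, fits every combination
on the training cohort with a fixed seed and ranks them by mean
Harrell's C-index across the test cohorts. Harrell's C itself is
implemented directly from its pairwise definition. Risk stratification
splits cohorts at the median training score and reports Kaplan–Meier
tables, log-rank tests and IPCW time-dependent ROC AUCs at 1–5 years.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sksurv.ensemble import (
    ComponentwiseGradientBoostingSurvivalAnalysis,
    RandomSurvivalForest,
)
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .datatypes import SurvivalCohort
from .subtyping import km_table

logger = logging.getLogger(__name__)

__all__ = [
    "cox_screen",
    "build_input_geneset",
    "cindex",
    "RiskModel",
    "fit_model_grid",
    "stratify_and_evaluate",
    "SELECTORS",
    "FINAL_MODELS",
    "INVALID_PAIRS",
]


# ---------------------------------------------------------------------------
# univariate Cox (Efron ties, scalar Newton)
# ---------------------------------------------------------------------------

def _efron_groups(time: np.ndarray, event: np.ndarray):
    """Precompute risk-set boundaries for the Efron partial likelihood.

    Samples are sorted by descending time so the risk set of an event
    time is a prefix. Returns the sort order plus, per unique event
    time, the prefix end and the tied-event member indices.
    """
    order = np.argsort(-time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    groups = []
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j + 1 < n and t_sorted[j + 1] == t_sorted[i]:
            j += 1
        evt_idx = [k for k in range(i, j + 1) if e_sorted[k] == 1]
        if evt_idx:
            groups.append((j, np.array(evt_idx)))
        i = j + 1
    return order, groups


def univariate_cox(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> Tuple[float, float, float]:
    """Fit hazard ∝ exp(beta * x); return (beta, HR, Wald p).

    The covariate is standardised internally (HR is per SD). Raises on a
    constant covariate or failed convergence.
    """
    sd = x.std()
    if sd == 0:
        raise ValueError("constant covariate")
    z = (x - x.mean()) / sd
    order, groups = _efron_groups(time, event)
    zs = z[order]

    beta = 0.0
    for _ in range(max_iter):
        phi = np.exp(beta * zs)
        a = zs * phi
        b = zs * a
        cs_phi = np.cumsum(phi)
        cs_a = np.cumsum(a)
        cs_b = np.cumsum(b)
        grad = 0.0
        info = 0.0
        for end, evt in groups:
            d = len(evt)
            s_r, u_r, v_r = cs_phi[end], cs_a[end], cs_b[end]
            s_d, u_d, v_d = phi[evt].sum(), a[evt].sum(), b[evt].sum()
            grad += zs[evt].sum()
            frac = np.arange(d) / d
            denom = s_r - frac * s_d
            u = u_r - frac * u_d
            v = v_r - frac * v_d
            grad -= np.sum(u / denom)
            info += np.sum(v / denom - (u / denom) ** 2)
        if info <= 0:
            raise RuntimeError("non-positive information in Cox fit")
        step = grad / info
        beta += step
        if abs(step) < tol:
            se = 1.0 / math.sqrt(info)
            p = 2.0 * stats.norm.sf(abs(beta) / se)
            return beta, math.exp(beta), float(p)
    raise RuntimeError("univariate Cox did not converge")


def cox_screen(
    cohort: SurvivalCohort,
    genes: Optional[Sequence[str]] = None,
    p_thresh: float = 0.05,
) -> pd.DataFrame:
    """Univariate Cox per gene; keep genes with Wald p < ``p_thresh``.

    Returns (gene, beta, HR, p) for the retained genes, sorted by p.
    Constant or non-converging genes are skipped with a log line.
    """
    if cohort.n_events < 10:
        raise ValueError(f"need >= 10 events, cohort has {cohort.n_events}")
    genes = list(genes) if genes is not None else list(cohort.genes)
    t = cohort.time.to_numpy(dtype=float)
    e = cohort.event.to_numpy(dtype=int)
    rows = []
    for g in genes:
        if g not in cohort.expression.columns:
            continue
        x = cohort.expression[g].to_numpy(dtype=float)
        try:
            beta, hr, p = univariate_cox(x, t, e)
        except (ValueError, RuntimeError) as err:
            logger.info("cox_screen: %s skipped (%s)", g, err)
            continue
        if p < p_thresh:
            rows.append({"gene": g, "beta": beta, "HR": hr, "p": p})
    return pd.DataFrame(rows, columns=["gene", "beta", "HR", "p"]).sort_values(
        "p", ignore_index=True
    ) if rows else pd.DataFrame(columns=["gene", "beta", "HR", "p"])


def build_input_geneset(
    cox_genes: Sequence[str],
    de_genes: Sequence[str],
    subtype_genes: Sequence[str],
) -> List[str]:
    """Three-way intersection of prognostic, differential and subtype genes."""
    sets = [set(cox_genes), set(de_genes), set(subtype_genes)]
    if any(not s for s in sets):
        raise ValueError("all three gene lists must be non-empty")
    inter = sorted(sets[0] & sets[1] & sets[2])
    logger.info(
        "build_input_geneset: |cox|=%d |de|=%d |subtype|=%d -> |intersection|=%d",
        *(len(s) for s in sets), len(inter),
    )
    if not inter:
        raise ValueError("empty three-way intersection of gene lists")
    return inter


# ---------------------------------------------------------------------------
# Harrell's concordance index
# ---------------------------------------------------------------------------

def cindex(scores: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's C over comparable pairs.

    A pair is comparable when the earlier time carries an event;
    concordant when the shorter survivor has the higher risk score; score
    ties count 0.5. Undefined (raises) when no pair is comparable.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (len(scores) == len(time) == len(event)):
        raise ValueError("scores, time and event must have equal length")
    # comparable pairs: time_i < time_j and event_i == 1 (i the earlier)
    ti, tj = time[:, None], time[None, :]
    comparable = (ti < tj) & (event[:, None] == 1)
    si, sj = scores[:, None], scores[None, :]
    concordant = comparable & (si > sj)
    tied = comparable & (si == sj)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs: C-index undefined")
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


# ---------------------------------------------------------------------------
# the model grid
# ---------------------------------------------------------------------------

def _surv(cohort: SurvivalCohort, samples: Optional[pd.Index] = None):
    idx = cohort.samples if samples is None else samples
    return Surv.from_arrays(
        event=cohort.event.loc[idx].astype(bool).to_numpy(),
        time=cohort.time.loc[idx].to_numpy(dtype=float),
    )


@dataclass
class RiskModel:
    """A fitted risk model: higher score = worse expected survival."""

    algorithm: str
    features: List[str]
    scorer: Callable[[pd.DataFrame], np.ndarray]
    cindex_train: float = math.nan
    cindex_test: Dict[str, float] = field(default_factory=dict)
    train_median: float = math.nan

    def score(self, expression: pd.DataFrame) -> np.ndarray:
        return self.scorer(expression[self.features])


def _cv_folds(n: int, k: int, seed: int):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    return np.array_split(idx, k)


def _cv_pick(
    cohort: SurvivalCohort,
    features: List[str],
    fit_fn: Callable[[pd.DataFrame, np.ndarray], Callable],
    candidates: List,
    seed: int,
    k: int = 5,
) -> object:
    """Pick the candidate hyper-parameter with the best 5-fold CV C-index."""
    X = cohort.expression[features]
    folds = _cv_folds(len(X), k, seed)
    best, best_c = candidates[0], -np.inf
    for cand in candidates:
        cs = []
        for f in range(k):
            test_idx = X.index[folds[f]]
            train_idx = X.index.difference(test_idx, sort=False)
            try:
                predict = fit_fn(cand, X.loc[train_idx], _surv(cohort, train_idx))
                sc = predict(X.loc[test_idx])
                cs.append(
                    cindex(
                        sc,
                        cohort.time.loc[test_idx].to_numpy(),
                        cohort.event.loc[test_idx].to_numpy(),
                    )
                )
            except (ValueError, ArithmeticError):
                cs.append(0.0)
        mean_c = float(np.mean(cs))
        if mean_c > best_c:
            best, best_c = cand, mean_c
    return best


def _fit_coxnet(train: SurvivalCohort, features: List[str], l1_ratio: float, seed: int):
    """Coxnet with the penalty strength chosen by 5-fold CV on the train cohort."""
    X = train.expression[features]
    y = _surv(train)
    path = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, n_alphas=20, max_iter=50000)
    path.fit(X.to_numpy(), y)
    alphas = list(path.alphas_[:: max(1, len(path.alphas_) // 8)])

    def fit_one(alpha, Xtr, ytr):
        m = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=[alpha], max_iter=50000)
        m.fit(Xtr.to_numpy(), ytr)
        return lambda Xte: m.predict(Xte.to_numpy())

    alpha = _cv_pick(train, features, fit_one, alphas, seed)
    model = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=[alpha], max_iter=50000)
    model.fit(X.to_numpy(), y)
    return model, float(alpha)


def _stepwise_features(
    train: SurvivalCohort, features: List[str], max_features: int = 10
) -> List[str]:
    """Forward selection on the Cox partial likelihood by AIC."""
    df = train.expression[features].copy()
    df["time"] = train.time
    df["event"] = train.event
    selected: List[str] = []
    best_aic = np.inf
    while len(selected) < min(max_features, len(features)):
        best_gene, best_gene_aic = None, best_aic
        for g in features:
            if g in selected:
                continue
            cph = CoxPHFitter(penalizer=1e-4)
            try:
                cph.fit(
                    df[selected + [g, "time", "event"]],
                    duration_col="time",
                    event_col="event",
                )
            except Exception:
                continue
            aic = cph.AIC_partial_
            if aic < best_gene_aic - 1e-9:
                best_gene, best_gene_aic = g, aic
        if best_gene is None:
            break
        selected.append(best_gene)
        best_aic = best_gene_aic
    return selected or features[:1]


def _rsf_importance_features(
    train: SurvivalCohort,
    features: List[str],
    seed: int,
    n_trees: int = 100,
    n_repeats: int = 3,
    top: int = 10,
) -> List[str]:
    """Permutation importance of a small RSF, measured as C-index drop."""
    X = train.expression[features].to_numpy()
    y = _surv(train)
    rsf = RandomSurvivalForest(
        n_estimators=n_trees, min_samples_leaf=15, random_state=seed, n_jobs=1
    )
    rsf.fit(X, y)
    t = train.time.to_numpy()
    e = train.event.to_numpy()
    base = cindex(rsf.predict(X), t, e)
    rng = np.random.default_rng(seed)
    imp = np.zeros(len(features))
    for j in range(len(features)):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(X)), j]
            drops.append(base - cindex(rsf.predict(Xp), t, e))
        imp[j] = np.mean(drops)
    order = np.argsort(-imp, kind="stable")
    chosen = [features[j] for j in order[:top] if imp[j] > 0]
    return chosen if len(chosen) >= 2 else [features[j] for j in order[:2]]


SELECTORS = ("none", "lasso", "stepwise", "rsf_importance")
FINAL_MODELS = ("rsf", "lasso_cox", "ridge_cox", "enet_cox", "stepwise_cox", "coxboost")
# a selector paired with its own algorithm as the final model is redundant
INVALID_PAIRS = {
    ("lasso", "lasso_cox"),
    ("stepwise", "stepwise_cox"),
    ("rsf_importance", "rsf"),
}


def _run_selector(name: str, train: SurvivalCohort, features: List[str], seed: int) -> List[str]:
    if name == "none":
        return list(features)
    if name == "lasso":
        model, _ = _fit_coxnet(train, features, l1_ratio=1.0, seed=seed)
        coef = np.asarray(model.coef_).ravel()
        chosen = [f for f, c in zip(features, coef) if c != 0]
        if len(chosen) < 2:
            logger.warning("lasso selector kept < 2 features; falling back to all")
            return list(features)
        return chosen
    if name == "stepwise":
        return _stepwise_features(train, features)
    if name == "rsf_importance":
        return _rsf_importance_features(train, features, seed=seed)
    raise ValueError(f"unknown selector {name!r}")


def _fit_final(
    name: str, train: SurvivalCohort, features: List[str], seed: int
) -> Callable[[pd.DataFrame], np.ndarray]:
    X = train.expression[features]
    y = _surv(train)
    if name == "rsf":
        rsf = RandomSurvivalForest(
            n_estimators=500, min_samples_leaf=15, random_state=seed, n_jobs=1
        )
        rsf.fit(X.to_numpy(), y)
        return lambda Xn: rsf.predict(Xn.to_numpy())
    if name in ("lasso_cox", "enet_cox"):
        l1 = 1.0 if name == "lasso_cox" else 0.5
        model, _ = _fit_coxnet(train, features, l1_ratio=l1, seed=seed)
        return lambda Xn: model.predict(Xn.to_numpy())
    if name == "ridge_cox":
        def fit_one(alpha, Xtr, ytr):
            m = CoxPHSurvivalAnalysis(alpha=alpha)
            m.fit(Xtr.to_numpy(), ytr)
            return lambda Xte: m.predict(Xte.to_numpy())

        alpha = _cv_pick(train, features, fit_one, [0.1, 1.0, 10.0, 100.0], seed)
        model = CoxPHSurvivalAnalysis(alpha=alpha)
        model.fit(X.to_numpy(), y)
        return lambda Xn: model.predict(Xn.to_numpy())
    if name == "stepwise_cox":
        chosen = _stepwise_features(train, features)
        df = train.expression[chosen].copy()
        df["time"] = train.time
        df["event"] = train.event
        cph = CoxPHFitter(penalizer=1e-4)
        cph.fit(df, duration_col="time", event_col="event")
        return lambda Xn: cph.predict_partial_hazard(Xn[chosen]).to_numpy()
    if name == "coxboost":
        model = ComponentwiseGradientBoostingSurvivalAnalysis(
            n_estimators=200, learning_rate=0.2, random_state=seed
        )
        model.fit(X.to_numpy(), y)
        return lambda Xn: model.predict(Xn.to_numpy())
    raise ValueError(f"unknown final model {name!r}")


def fit_model_grid(
    train: SurvivalCohort,
    tests: Sequence[SurvivalCohort],
    geneset: Sequence[str],
    selectors: Sequence[str] = SELECTORS,
    final_models: Sequence[str] = FINAL_MODELS,
    seed: int = 0,
) -> Tuple[pd.DataFrame, RiskModel, Dict[str, RiskModel]]:
    """Fit every valid selector × model combination; rank by test C-index.

    The gene set is intersected with every cohort's genes (logged);
    cohorts with fewer than 10 events are excluded with a warning.
    Returns ``(leaderboard, best_model, all_models)`` where the
    leaderboard has one row per combination with per-cohort C-indices
    and their mean over test cohorts, sorted descending.
    """
    usable_tests = []
    for c in tests:
        if c.n_events < 10:
            logger.warning("fit_model_grid: cohort %s excluded (<10 events)", c.name)
        else:
            usable_tests.append(c)
    genes = set(geneset) & set(train.genes)
    for c in usable_tests:
        genes &= set(c.genes)
    features = sorted(genes)
    if len(features) < 2:
        raise ValueError("fewer than 2 grid genes shared by all cohorts")
    if len(features) < len(set(geneset)):
        logger.info(
            "fit_model_grid: gene set restricted from %d to %d shared genes",
            len(set(geneset)), len(features),
        )

    selector_cache: Dict[str, List[str]] = {}
    models: Dict[str, RiskModel] = {}
    rows = []
    for sel in selectors:
        for fin in final_models:
            if (sel, fin) in INVALID_PAIRS:
                continue
            combo = f"{sel}+{fin}"
            if sel not in selector_cache:
                selector_cache[sel] = _run_selector(sel, train, features, seed)
            feats = selector_cache[sel]
            scorer = _fit_final(fin, train, feats, seed)
            model = RiskModel(algorithm=combo, features=feats, scorer=scorer)
            train_scores = model.score(train.expression)
            model.cindex_train = cindex(
                train_scores, train.time.to_numpy(), train.event.to_numpy()
            )
            model.train_median = float(np.median(train_scores))
            for c in usable_tests:
                sc = model.score(c.expression)
                model.cindex_test[c.name] = cindex(
                    sc, c.time.to_numpy(), c.event.to_numpy()
                )
            models[combo] = model
            row = {
                "combination": combo,
                "n_features": len(feats),
                "cindex_train": model.cindex_train,
                **{f"cindex_{c.name}": model.cindex_test[c.name] for c in usable_tests},
            }
            row["cindex_test_mean"] = (
                float(np.mean(list(model.cindex_test.values())))
                if model.cindex_test
                else math.nan
            )
            rows.append(row)
            logger.info("grid %s: train C=%.3f test C=%.3f",
                        combo, model.cindex_train, row["cindex_test_mean"])
    leaderboard = pd.DataFrame(rows).sort_values(
        ["cindex_test_mean", "combination"], ascending=[False, True], ignore_index=True
    )
    best = models[leaderboard.iloc[0]["combination"]]
    return leaderboard, best, models


def stratify_and_evaluate(
    model: RiskModel,
    cohort: SurvivalCohort,
    horizons_months: Sequence[float] = (12, 24, 36, 48, 60),
) -> dict:
    """Median-split risk stratification plus time-dependent ROC AUCs.

    Groups are "high"/"low" risk by the *training* median score stored on
    the model (falls back to the cohort median if unset). Reports KM
    tables per group, the log-rank test, and cumulative/dynamic AUC with
    inverse-probability-of-censoring weights from the KM censoring curve
    at each horizon inside the cohort's follow-up range.
    """
    scores = model.score(cohort.expression)
    threshold = model.train_median
    if not np.isfinite(threshold):
        threshold = float(np.median(scores))
    high = scores > threshold
    out: dict = {
        "scores": pd.Series(scores, index=cohort.samples, name="risk_score"),
        "threshold": threshold,
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
    }
    if high.all() or (~high).all():
        logger.warning("stratify_and_evaluate: degenerate scores, single risk group")
        out["logrank_p"] = math.nan
        out["km"] = {}
    else:
        t, e = cohort.time.to_numpy(), cohort.event.to_numpy()
        lr = logrank_test(t[high], t[~high], e[high], e[~high])
        out["logrank_stat"] = float(lr.test_statistic)
        out["logrank_p"] = float(lr.p_value)
        out["km"] = {
            "high": km_table(cohort.time[high], cohort.event[high]),
            "low": km_table(cohort.time[~high], cohort.event[~high]),
        }

    t = cohort.time.to_numpy()
    lo, hi = t.min(), t.max()
    times = [h for h in horizons_months if lo < h < hi]
    if times:
        try:
            aucs, _ = cumulative_dynamic_auc(
                _surv(cohort), _surv(cohort), scores, np.array(times)
            )
            out["roc_auc"] = dict(zip([float(h) for h in times], map(float, aucs)))
        except ValueError as err:
            logger.warning("time-dependent AUC failed: %s", err)
            out["roc_auc"] = {}
    else:
        out["roc_auc"] = {}
    return out
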