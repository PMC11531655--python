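"""Cox screening, Harrell's C and the survival model grid."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from regulonpipe.datatypes import SurvivalCohort
from regulonpipe.prognosis import (
    INVALID_PAIRS,
    build_input_geneset,
    cindex,
    cox_screen,
    fit_model_grid,
    stratify_and_evaluate,
    univariate_cox,
)
from regulonpipe.synthetic import SimConfig, simulate_bulk_cohort


def brute_cindex(scores, time, event):
    conc = ties = comp = 0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                comp += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    ties += 1
    return (conc + 0.5 * ties) / comp


class TestCindex:
    def test_matches_exhaustive_enumeration_on_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = rng.integers(4, 12)
            scores = rng.integers(0, 5, n).astype(float)  # force some ties
            time = rng.integers(1, 10, n).astype(float)
            event = rng.integers(0, 2, n)
            if not ((event == 1) & (time < time.max())).any():
                continue
            try:
                want = brute_cindex(scores, time, event)
            except ZeroDivisionError:
                continue
            assert cindex(scores, time, event) == pytest.approx(want, abs=1e-12)

    def test_perfect_and_inverted_orderings(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, dtype=int)
        assert cindex(-t, t, e) == 1.0
        assert cindex(t, t, e) == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(14)
        t = rng.exponential(10, 2000)
        e = np.ones(2000, dtype=int)
        s = rng.normal(size=2000)
        assert cindex(s, t, e) == pytest.approx(0.5, abs=0.03)

    def test_five_sample_toy_with_censoring(self, toy_survival):
        c = toy_survival
        scores = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        # hand enumeration: comparable pairs from s0,s1,s3,s4 (events) with
        # later times; s2 censored at t=6 is only a later partner
        want = brute_cindex(scores, c.time.to_numpy(), c.event.to_numpy())
        assert cindex(scores, c.time.to_numpy(), c.event.to_numpy()) == want == 1.0

    def test_complement_identity_without_ties(self):
        rng = np.random.default_rng(15)
        s = rng.normal(size=50)
        t = rng.exponential(5, 50)
        e = rng.integers(0, 2, 50)
        e[np.argmin(t)] = 1
        assert cindex(s, t, e) + cindex(-s, t, e) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(16)
        s = rng.normal(size=40)
        t = rng.exponential(5, 40)
        e = np.ones(40, dtype=int)
        assert cindex(s, t, e) == cindex(np.exp(s), t, e)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            cindex(np.array([1.0, 2.0]), np.array([5.0, 5.0]), np.array([0, 0]))


class TestUnivariateCox:
    def test_matches_lifelines(self):
        rng = np.random.default_rng(17)
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(1 / (0.05 * np.exp(0.8 * x)))
        e = np.ones(n, dtype=int)
        beta, hr, p = univariate_cox(x, t, e)
        # same standardisation (population SD) as univariate_cox applies
        df = pd.DataFrame({"x": (x - x.mean()) / x.std(), "time": t, "event": e})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        # agreement to lifelines' own solver tolerance
        assert beta == pytest.approx(cph.params_["x"], rel=1e-4)
        assert p == pytest.approx(cph.summary.loc["x", "p"], rel=1e-3)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            univariate_cox(np.ones(20), np.arange(1.0, 21.0), np.ones(20, dtype=int))


class TestCoxScreen:
    def test_planted_gene_retained_with_strong_p(self):
        cfg = SimConfig(n_samples=300, beta=1.0, seed=19)
        cohort, truth = simulate_bulk_cohort(cfg)
        hits = cox_screen(cohort, truth.signature_genes, p_thresh=0.05)
        assert set(truth.signature_genes) <= set(hits["gene"])
        assert (hits["p"] < 1e-4).all()

    def test_null_retention_near_alpha(self):
        cfg = SimConfig(n_samples=200, beta=0.0, seed=20)
        cohort, _ = simulate_bulk_cohort(cfg)
        genes = list(cohort.genes[:500])
        hits = cox_screen(cohort, genes, p_thresh=0.05)
        assert 0.02 <= len(hits) / 500 <= 0.09

    def test_constant_gene_skipped(self, small_cohort):
        _, cohort, _ = small_cohort
        cohort = SurvivalCohort(
            cohort.expression.assign(CONST=1.0), cohort.time, cohort.event,
            cohort.covariates, cohort.name,
        )
        hits = cox_screen(cohort, ["CONST"], p_thresh=1.0)
        assert "CONST" not in set(hits["gene"])

    def test_too_few_events_rejected(self, toy_survival):
        with pytest.raises(ValueError, match="events"):
            cox_screen(toy_survival, ["g1"])


class TestBuildInputGeneset:
    def test_identical_lists(self):
        assert build_input_geneset(["a", "b"], ["b", "a"], ["a", "b"]) == ["a", "b"]

    def test_disjoint_lists_error(self):
        with pytest.raises(ValueError, match="intersection"):
            build_input_geneset(["a"], ["b"], ["c"])

    def test_empty_list_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            build_input_geneset([], ["a"], ["a"])


@pytest.fixture(scope="module")
def signal_cohorts():
    cfg = SimConfig(n_samples=250, beta=1.0, seed=30)
    train, truth = simulate_bulk_cohort(cfg, name="train")
    test1, _ = simulate_bulk_cohort(
        SimConfig(n_samples=120, beta=1.0, seed=31),
        name="test1", signature_pool=truth.signature_genes,
    )
    rng = np.random.default_rng(0)
    noise = [g for g in train.genes if g not in set(truth.signature_genes)]
    genes = truth.signature_genes + [str(g) for g in rng.choice(noise, 8, replace=False)]
    return train, test1, genes


class TestModelGrid:
    def test_leaderboard_covers_valid_combinations(self, signal_cohorts):
        train, test1, genes = signal_cohorts
        lb, best, models = fit_model_grid(
            train, [test1], genes,
            selectors=("none", "lasso"),
            final_models=("ridge_cox", "lasso_cox", "coxboost"),
            seed=0,
        )
        combos = set(lb["combination"])
        assert ("lasso", "lasso_cox") in INVALID_PAIRS
        assert "lasso+lasso_cox" not in combos
        assert len(combos) == 5
        assert lb["cindex_test_mean"].iloc[0] == lb["cindex_test_mean"].max()

    def test_strong_signal_recovered(self, signal_cohorts):
        train, test1, genes = signal_cohorts
        lb, best, _ = fit_model_grid(
            train, [test1], genes,
            selectors=("none",), final_models=("ridge_cox", "coxboost"),
            seed=0,
        )
        assert lb["cindex_test_mean"].max() >= 0.75

    def test_features_stay_inside_gene_set(self, signal_cohorts):
        train, test1, genes = signal_cohorts
        _, best, models = fit_model_grid(
            train, [test1], genes,
            selectors=("lasso", "stepwise"), final_models=("ridge_cox",),
            seed=0,
        )
        for model in models.values():
            assert set(model.features) <= set(genes)

    def test_deterministic_leaderboard(self, signal_cohorts):
        train, test1, genes = signal_cohorts
        kw = dict(selectors=("none",), final_models=("ridge_cox", "lasso_cox"), seed=0)
        lb1, _, _ = fit_model_grid(train, [test1], genes, **kw)
        lb2, _, _ = fit_model_grid(train, [test1], genes, **kw)
        pd.testing.assert_frame_equal(lb1, lb2)

    def test_low_event_cohort_excluded(self, signal_cohorts, toy_survival):
        train, test1, genes = signal_cohorts
        lb, _, _ = fit_model_grid(
            train, [toy_survival], genes,
            selectors=("none",), final_models=("ridge_cox",), seed=0,
        )
        assert "cindex_toy" not in lb.columns


class TestStratifyAndEvaluate:
    def test_median_split_and_oracle_auc(self, signal_cohorts):
        train, test1, genes = signal_cohorts
        _, best, _ = fit_model_grid(
            train, [test1], genes,
            selectors=("none",), final_models=("ridge_cox",), seed=0,
        )
        rep = stratify_and_evaluate(best, train)
        # distinct scores: median split within one of half
        assert abs(rep["n_high"] - rep["n_low"]) <= 1
        assert rep["logrank_p"] < 0.01
        assert all(v > 0.8 for v in rep["roc_auc"].values())
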