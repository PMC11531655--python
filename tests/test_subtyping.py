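"""Differential expression, signatures, consensus clustering, subtype contrast."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from regulonpipe.datatypes import Regulon, SurvivalCohort
from regulonpipe.subtyping import (
    build_signature,
    compare_subtypes,
    consensus_cluster,
    differential_expression,
    filter_de,
)


def _two_group_matrix(n_genes=50, n_per=20, seed=0, shift_genes=(), shift=3.0):
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(n_genes)]
    cols = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    X = rng.normal(0, 1, size=(n_genes, 2 * n_per))
    for g in shift_genes:
        X[genes.index(g), :n_per] += shift
    values = pd.DataFrame(X, index=genes, columns=cols)
    labels = pd.Series(["A"] * n_per + ["B"] * n_per, index=cols)
    return values, labels


class TestDifferentialExpression:
    def test_duplicated_groups_find_nothing(self):
        values, _ = _two_group_matrix()
        dup = pd.concat([values.iloc[:, :20], values.iloc[:, :20]], axis=1)
        dup.columns = [f"c{i}" for i in range(40)]
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=dup.columns)
        de = differential_expression(dup, labels)
        assert (de["p"] > 0.999).all()
        assert len(filter_de(de)) == 0

    def test_forced_gene_passes_thresholds(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(10)]
        cols = [f"c{i}" for i in range(40)]
        X = rng.normal(5, 0.1, size=(10, 40))
        X[0, :20] = rng.normal(8, 0.1, 20)
        X[0, 20:] = rng.normal(2, 0.1, 20)
        values = pd.DataFrame(X, index=genes, columns=cols)
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=cols)
        hits = filter_de(differential_expression(values, labels))
        assert "G0" in set(hits["gene"])

    def test_null_type_i_error_calibrated(self):
        values, labels = _two_group_matrix(n_genes=1000, n_per=25, seed=2)
        de = differential_expression(values, labels)
        frac = (de["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_logfc_is_mean_difference(self):
        values, labels = _two_group_matrix(seed=3)
        de = differential_expression(values, labels, "A", "B").set_index("gene")
        g = values.index[0]
        want = values.loc[g, labels == "A"].mean() - values.loc[g, labels == "B"].mean()
        assert de.loc[g, "logFC"] == pytest.approx(want)

    def test_degenerate_groups_rejected(self):
        values, _ = _two_group_matrix()
        labels = pd.Series(["A"] * 2 + ["B"] * 38, index=values.columns)
        with pytest.raises(ValueError, match="3 samples"):
            differential_expression(values, labels)

    def test_positive_only_flag(self):
        values, labels = _two_group_matrix(shift_genes=["G0"], shift=-3.0, seed=4)
        de = differential_expression(values, labels, "A", "B")
        assert "G0" in set(filter_de(de)["gene"])
        assert "G0" not in set(filter_de(de, positive_only=True)["gene"])


class TestBuildSignature:
    def test_regulon_subset_of_de_gives_full_signature(self):
        reg = Regulon(tf="TF1", targets=("A", "B"))
        de = pd.DataFrame({"gene": ["A", "B", "TF1", "C"]})
        assert set(build_signature(reg, de)) == {"A", "B", "TF1"}

    def test_disjoint_sets_error(self):
        reg = Regulon(tf="TF1", targets=("A",))
        de = pd.DataFrame({"gene": ["X", "Y"]})
        with pytest.raises(ValueError, match="empty"):
            build_signature(reg, de)


class TestConsensusCluster:
    def _planted(self, n=90, sep=4.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, size=(n, 12))
        lab = np.array([1] * (n // 2) + [2] * (n - n // 2))
        X[lab == 1, :6] += sep
        return pd.DataFrame(X, index=[f"s{i}" for i in range(n)]), lab

    def test_two_planted_subtypes_recovered(self):
        X, lab = self._planted()
        res = consensus_cluster(X, k_range=(2, 3, 4), n_resamples=60, seed=0)
        assert res.selected_k == 2
        assert adjusted_rand_score(lab, res.labels.to_numpy()) >= 0.9
        cons = res.consensus[2].to_numpy()
        off = cons[~np.eye(len(X), dtype=bool)]
        assert ((off < 0.1) | (off > 0.9)).mean() > 0.9  # near-binary

    def test_single_full_resample_gives_binary_entries(self):
        X, _ = self._planted(n=30)
        res = consensus_cluster(
            X, k_range=(2,), n_resamples=1, sample_frac=0.999, seed=0
        )
        vals = np.unique(res.consensus[2].to_numpy())
        assert set(np.round(vals, 12)) <= {0.0, 1.0}

    def test_sample_order_equivariance(self):
        X, _ = self._planted(n=40)
        res1 = consensus_cluster(X, k_range=(2,), n_resamples=40, seed=5)
        perm = list(reversed(X.index))
        res2 = consensus_cluster(X.loc[perm], k_range=(2,), n_resamples=40, seed=5)
        # same partition of samples up to label names
        ari = adjusted_rand_score(
            res1.labels.reindex(X.index).to_numpy(),
            res2.labels.reindex(X.index).to_numpy(),
        )
        assert ari == 1.0

    def test_consensus_entries_are_frequencies(self):
        X, _ = self._planted(n=40)
        res = consensus_cluster(X, k_range=(2, 3), n_resamples=30, seed=1)
        for cons in res.consensus.values():
            v = cons.to_numpy()
            assert v.min() >= 0 and v.max() <= 1
            np.testing.assert_allclose(v, v.T)

    def test_bad_sample_frac_rejected(self):
        X, _ = self._planted(n=30)
        with pytest.raises(ValueError, match="sample_frac"):
            consensus_cluster(X, n_resamples=10, sample_frac=0.3)

    def test_k_range_clipped(self):
        X, _ = self._planted(n=24)
        res = consensus_cluster(X, k_range=(2, 30), n_resamples=10, seed=0)
        assert max(res.consensus) <= max(2, len(X) // 3)


class TestCompareSubtypes:
    def _cohort_with_hr(self, hr=3.0, n=150, seed=0):
        rng = np.random.default_rng(seed)
        lab = pd.Series([1] * (n // 2) + [2] * (n - n // 2),
                        index=[f"s{i}" for i in range(n)])
        rate = np.where(lab == 1, hr, 1.0) * 0.05
        t = rng.exponential(1 / rate)
        cohort = SurvivalCohort(
            expression=pd.DataFrame({"g": rng.normal(size=n)}, index=lab.index),
            time=pd.Series(t, index=lab.index),
            event=pd.Series(1, index=lab.index),
        )
        return cohort, lab

    def test_identical_survival_gives_null_logrank(self):
        cohort, lab = self._cohort_with_hr(hr=1.0, seed=1)
        # duplicate data across the two groups for an exact null
        half = len(lab) // 2
        cohort.time.iloc[half:] = cohort.time.iloc[:half].to_numpy()
        cohort.event.iloc[half:] = cohort.event.iloc[:half].to_numpy()
        out = compare_subtypes(cohort, lab)
        assert out["logrank_p"] > 0.9

    def test_planted_hazard_ratio_detected(self):
        cohort, lab = self._cohort_with_hr(hr=3.0)
        out = compare_subtypes(cohort, lab)
        assert out["logrank_p"] < 0.01

    def test_logrank_matches_hand_computation_on_toy(self):
        """6 samples, no censoring: observed-vs-expected events by hand."""
        from lifelines.statistics import multivariate_logrank_test

        time = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=list("abcdef"))
        event = pd.Series([1, 1, 1, 1, 1, 1], index=list("abcdef"))
        lab = pd.Series([1, 2, 1, 2, 1, 2], index=list("abcdef"))
        # hand computation of the group-1 observed minus expected
        o_minus_e = 0.0
        var = 0.0
        at_risk = {"1": 3, "2": 3}
        for t in sorted(time):
            g = lab[time[time == t].index[0]]
            n1, n2 = at_risk["1"], at_risk["2"]
            n = n1 + n2
            e1 = n1 / n
            o_minus_e += (1.0 if g == 1 else 0.0) - e1
            if n > 1:
                var += n1 * n2 / n**2
            at_risk[str(g)] -= 1
        chi2 = o_minus_e**2 / var
        lr = multivariate_logrank_test(time, lab, event)
        cohort = SurvivalCohort(
            expression=pd.DataFrame(index=list("abcdef")),
            time=time, event=event,
        )
        out = compare_subtypes(cohort, lab)
        assert out["logrank_stat"] == pytest.approx(chi2, rel=1e-9)
        assert out["logrank_stat"] == pytest.approx(lr.test_statistic, rel=1e-12)

    def test_set_score_comparison_reported(self):
        cohort, lab = self._cohort_with_hr()
        rng = np.random.default_rng(7)
        scores = pd.DataFrame(
            {"S1": rng.normal(size=len(lab)) + (lab == 1) * 2.0,
             "S2": rng.normal(size=len(lab))},
            index=lab.index,
        )
        out = compare_subtypes(cohort, lab, scores)
        tbl = out["set_comparison"].set_index("set")
        assert tbl.loc["S1", "adj_p"] < 0.01
        assert tbl.loc["S2", "p"] > 0.001
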