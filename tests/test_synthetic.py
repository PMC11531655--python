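"""Generator contracts: determinism, noise model, planted structure."""

import numpy as np
import pandas as pd
import pytest

from regulonpipe.synthetic import (
    ConfigError,
    SimConfig,
    make_gene_sets,
    make_prior,
    simulate_bulk_cohort,
    simulate_single_cell,
)
from regulonpipe.prognosis import cindex

from conftest import small_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("dropout_rate", 1.5),
            ("censor_rate", -0.1),
            ("nb_dispersion", 0.0),
            ("module_icc", 2.0),
            ("n_modules", 0),
        ],
    )
    def test_invalid_field_names_the_field(self, field, value):
        with pytest.raises(ConfigError, match=field):
            small_config(**{field: value})

    def test_gene_budget_checked(self):
        with pytest.raises(ConfigError, match="n_genes too small"):
            SimConfig(n_genes=100, n_tfs=50, targets_per_regulon=20)


class TestSingleCell:
    def test_deterministic_given_seed(self):
        m1, t1 = simulate_single_cell(small_config())
        m2, t2 = simulate_single_cell(small_config())
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1.latent_activity, t2.latent_activity)

    def test_shapes_and_partition(self, small_sim):
        cfg, m, truth = small_sim
        assert m.values.shape == (cfg.n_genes, 2 * cfg.n_cells)
        # every planted target belongs to exactly one regulon
        all_targets = [t for ts in truth.regulons.values() for t in ts]
        assert len(all_targets) == len(set(all_targets))
        # modules partition TFs
        assert set(truth.modules) == set(truth.regulons)
        assert set(truth.modules.values()) == set(range(1, cfg.n_modules + 1))

    def test_dropout_one_gives_all_zero_matrix(self):
        m, _ = simulate_single_cell(small_config(dropout_rate=1.0))
        assert (m.values.to_numpy() == 0).all()

    def test_no_shift_balances_conditions(self):
        """With activity_shift=0 the latent activity means match across conditions."""
        cfg = small_config(activity_shift=0.0, n_cells=600)
        m, truth = simulate_single_cell(cfg)
        cond = m.cell_meta["condition"]
        la = truth.latent_activity
        gap = la.loc[:, (cond == "WT").to_numpy()].mean(axis=1) - la.loc[
            :, (cond == "MUT").to_numpy()
        ].mean(axis=1)
        assert np.abs(gap.mean()) < 0.1

    def test_overdispersion_without_dropout(self):
        """NB marginals: per-gene variance >= mean for expressed genes."""
        m, _ = simulate_single_cell(small_config(dropout_rate=0.0))
        mean = m.values.mean(axis=1)
        var = m.values.var(axis=1)
        expressed = mean > 0.5
        assert (var[expressed] >= mean[expressed]).mean() > 0.95

    def test_latent_shift_matches_pipeline_contrast(self):
        """Regenerated latent WT-MUT gap matches the planted shift (MC error)."""
        cfg = small_config(n_cells=800, activity_shift=1.5, seed=7)
        m, truth = simulate_single_cell(cfg)
        cond = (m.cell_meta["condition"] == "WT").to_numpy()
        shifted_tfs = [tf for tf, mod in truth.modules.items() if mod in truth.shifted_modules]
        la = truth.latent_activity.loc[shifted_tfs]
        gap = la.loc[:, cond].to_numpy().mean() - la.loc[:, ~cond].to_numpy().mean()
        assert gap == pytest.approx(1.5, abs=0.15)

    def test_monotone_in_activity_shift(self):
        """Raising the shift raises the downstream latent contrast."""
        gaps = []
        for shift in [0.5, 1.5, 3.0]:
            cfg = small_config(activity_shift=shift, n_cells=400)
            m, truth = simulate_single_cell(cfg)
            cond = (m.cell_meta["condition"] == "WT").to_numpy()
            shifted = [tf for tf, mod in truth.modules.items() if mod in truth.shifted_modules]
            la = truth.latent_activity.loc[shifted]
            gaps.append(la.loc[:, cond].to_numpy().mean() - la.loc[:, ~cond].to_numpy().mean())
        assert gaps[0] < gaps[1] < gaps[2]


class TestBulkCohort:
    def test_censor_rate_zero_means_all_events(self):
        cohort, _ = simulate_bulk_cohort(SimConfig(n_samples=80, censor_rate=0.0, seed=5))
        assert (cohort.event == 1).all()

    def test_censor_rate_targeted(self):
        cohort, _ = simulate_bulk_cohort(SimConfig(n_samples=2000, censor_rate=0.4, seed=5))
        assert 1 - cohort.event.mean() == pytest.approx(0.4, abs=0.05)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ConfigError, match="n_samples"):
            simulate_bulk_cohort(SimConfig(n_samples=10))

    def test_null_beta_gives_chance_concordance(self):
        cfg = SimConfig(n_samples=400, beta=0.0, seed=5)
        cohort, truth = simulate_bulk_cohort(cfg)
        score = cohort.expression[truth.signature_genes].sum(axis=1).to_numpy()
        c = cindex(score, cohort.time.to_numpy(), cohort.event.to_numpy())
        assert c == pytest.approx(0.5, abs=0.06)

    def test_true_predictor_concordance_matches_pair_enumeration(self):
        """All-pairs brute force over (time, event, lp) agrees with cindex."""
        cfg = SimConfig(n_samples=300, beta=1.0, seed=3)
        cohort, truth = simulate_bulk_cohort(cfg)
        lp = cohort.expression[truth.signature_genes].sum(axis=1).to_numpy()
        t = cohort.time.to_numpy()
        e = cohort.event.to_numpy()
        conc = ties = comp = 0
        for i in range(len(t)):
            for j in range(len(t)):
                if t[i] < t[j] and e[i] == 1:
                    comp += 1
                    if lp[i] > lp[j]:
                        conc += 1
                    elif lp[i] == lp[j]:
                        ties += 1
        brute = (conc + 0.5 * ties) / comp
        assert cindex(lp, t, e) == pytest.approx(brute, abs=1e-12)
        assert brute > 0.8  # strong planted signal

    def test_shared_signature_pool(self):
        cfg = SimConfig(n_samples=80, seed=5)
        _, t1 = simulate_bulk_cohort(cfg)
        _, t2 = simulate_bulk_cohort(cfg, seed=99, signature_pool=t1.signature_genes)
        assert set(t2.signature_genes) == set(t1.signature_genes)


class TestGeneSets:
    def test_gmt_shapes(self, small_cohort):
        _, _, truth = small_cohort
        sets = make_gene_sets(truth, n_sets=13, set_size=50, overlap=0.5, seed=0)
        assert len(sets) == 13
        assert all(len(genes) == 50 for genes in sets.values())

    def test_zero_overlap_avoids_signature(self, small_cohort):
        _, _, truth = small_cohort
        sets = make_gene_sets(truth, n_sets=5, set_size=30, overlap=0.0, seed=0)
        sig = set(truth.signature_genes)
        assert all(not (set(g) & sig) for g in sets.values())

    def test_high_overlap_scores_separate_subtypes(self):
        """ssGSEA scores differ by subtype for all sets at overlap 0.8."""
        from regulonpipe.enrichment import ssgsea_score

        cfg = SimConfig(n_samples=200, seed=21)
        cohort, truth = simulate_bulk_cohort(cfg)
        sets = make_gene_sets(truth, n_sets=13, set_size=50, overlap=0.8, seed=1)
        scores = ssgsea_score(cohort.expression.T, sets)
        lab = truth.subtype_labels
        diff = scores[lab == 1].mean() - scores[lab == 2].mean()
        assert (diff > 0).all()


class TestPrior:
    def test_prior_covers_truth(self, small_sim):
        _, _, truth = small_sim
        prior = make_prior(truth)
        pairs = set(zip(prior["tf"], prior["target"]))
        planted = set(truth.edge_weights)
        assert pairs == planted

    def test_decoys_extend_prior(self, small_sim):
        _, _, truth = small_sim
        prior = make_prior(truth, decoys_per_tf=5, seed=1)
        assert len(prior) == len(truth.edge_weights) + 5 * len(truth.regulons)
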