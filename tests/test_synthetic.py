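import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from sigreverse.io import ValidationError
from sigreverse.pipeline import truth_signature
from sigreverse.signature import permutation_t_test
from sigreverse.synthetic import (
    SimulationConfig, simulate_expression, simulate_rank_database,
    simulate_survival,
)


class TestConfigValidation:
    def test_planted_exceeding_genes_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(genes=10, planted_de=11)

    def test_strength_bounds(self):
        with pytest.raises(ValidationError):
            SimulationConfig(strength=1.5)

    def test_censoring_bounds(self):
        with pytest.raises(ValidationError):
            SimulationConfig(censoring_fraction=1.0)

    def test_nonpositive_hazard_ratio_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(hazard_ratio=0.0)


class TestExpressionGenerator:
    def test_bit_identical_given_seed(self):
        cfg = SimulationConfig(seed=9, genes=50, planted_de=5, samples_per_group=4)
        m1, t1 = simulate_expression(cfg)
        m2, t2 = simulate_expression(cfg)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1, t2)

    def test_truth_table_lists_planted_directions(self):
        cfg = SimulationConfig(seed=0, genes=40, planted_de=10, de_fraction_up=0.7)
        _, truth = simulate_expression(cfg)
        assert len(truth) == 10
        assert (truth["direction"] == "up").sum() == 7

    def test_strong_effects_dominate_t_ranking(self):
        """Planted genes at 3 SD land in the top 15 by |t| in >= 18/20 seeds."""
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, genes=100, planted_de=10,
                                   effect_size=3.0, samples_per_group=10)
            m, truth = simulate_expression(cfg)
            de = permutation_t_test(m, permutations=100, seed=seed + 500)
            top15 = set(de["t"].abs().nlargest(15).index)
            hits += set(truth["gene"]) <= top15
        assert hits >= 18


class TestRankDatabaseGenerator:
    def _cfg(self, **kw):
        base = dict(seed=3, genes=80, planted_de=20, instances=30, compounds=6,
                    antagonists=1, agonists=1, strength=1.0)
        base.update(kw)
        return SimulationConfig(**base)

    def test_every_column_is_a_valid_permutation(self):
        cfg = self._cfg()
        db, truth = simulate_rank_database(cfg, truth_signature(cfg))
        n = db.n_genes
        expected = np.arange(1, n + 1)
        for col in db.instances:
            assert np.array_equal(np.sort(db.ranks[col].to_numpy()), expected)
        assert set(truth["role"]) == {"antagonist", "agonist", "null"}

    def test_bit_identical_given_seed(self):
        cfg = self._cfg()
        db1, _ = simulate_rank_database(cfg, truth_signature(cfg))
        db2, _ = simulate_rank_database(cfg, truth_signature(cfg))
        pd.testing.assert_frame_equal(db1.ranks, db2.ranks)

    def test_full_strength_antagonist_displaces_tags_to_extremes(self):
        cfg = self._cfg()
        sig = truth_signature(cfg)
        db, _ = simulate_rank_database(cfg, sig)
        inst = db.instances_of("antagonist_1")[0]
        ranks = db.ranks[inst]
        up_ranks = ranks.loc[list(sig.up.genes)]
        down_ranks = ranks.loc[list(sig.down.genes)]
        n, t_up, t_dn = db.n_genes, len(up_ranks), len(down_ranks)
        # up tags occupy the very bottom, down tags the very top
        assert set(up_ranks) == set(range(n - t_up + 1, n + 1))
        assert set(down_ranks) == set(range(1, t_dn + 1))

    def test_agonist_mirrors_antagonist(self):
        cfg = self._cfg()
        sig = truth_signature(cfg)
        db, _ = simulate_rank_database(cfg, sig)
        inst = db.instances_of("agonist_1")[0]
        ranks = db.ranks[inst]
        assert set(ranks.loc[list(sig.up.genes)]) == set(range(1, len(sig.up) + 1))

    def test_zero_strength_indistinguishable_from_null(self):
        """At strength 0 the planted compound's tag ranks keep the uniform
        distribution of null instances (two-sample KS)."""
        cfg = self._cfg(strength=0.0, instances=60, compounds=6)
        sig = truth_signature(cfg)
        db, truth = simulate_rank_database(cfg, sig)
        tag_genes = list(sig.up.genes)
        planted = {c for c, r in zip(truth["compound"], truth["role"]) if r != "null"}
        planted_inst = db.metadata.index[db.metadata["compound"].isin(planted)]
        null_inst = db.metadata.index[~db.metadata["compound"].isin(planted)]
        a = db.ranks.loc[tag_genes, planted_inst].to_numpy().ravel()
        b = db.ranks.loc[tag_genes, null_inst].to_numpy().ravel()
        assert ks_2samp(a, b).pvalue > 0.01

    def test_signature_gene_missing_from_universe_rejected(self):
        from sigreverse.io import GeneSet
        from sigreverse.signature import GeneSignature

        cfg = self._cfg()
        sig = GeneSignature(up=GeneSet("u_UP", "", ("NOT_A_GENE",)),
                            down=GeneSet("d_DN", "", ("G01",)), fdr_threshold=0.05)
        with pytest.raises(ValidationError, match="missing from universe"):
            simulate_rank_database(cfg, sig)


class TestSurvivalGenerator:
    def test_bit_identical_given_seed(self):
        cfg = SimulationConfig(seed=5, cohort_size=60)
        c1, t1 = simulate_survival(cfg)
        c2, t2 = simulate_survival(cfg)
        pd.testing.assert_frame_equal(c1.table, c2.table)
        pd.testing.assert_frame_equal(t1, t2)

    def test_zero_censoring_gives_all_events(self):
        cfg = SimulationConfig(seed=1, cohort_size=50, censoring_fraction=0.0)
        cohort, _ = simulate_survival(cfg)
        assert (cohort.event == 1).all()

    def test_censoring_fraction_respected(self):
        cfg = SimulationConfig(seed=1, cohort_size=200, censoring_fraction=0.3)
        cohort, _ = simulate_survival(cfg)
        assert (cohort.event == 0).sum() == 60

    def test_high_biomarker_group_protective(self):
        """At hazard ratio 3 and n=300, mean+1SD dichotomization plus
        log-rank separates the strata (p <= 0.05) in >= 19/20 seeds, and the
        high group survives longer."""
        from sigreverse.survival import BiomarkerSurvival

        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, cohort_size=300, hazard_ratio=3.0)
            cohort, _ = simulate_survival(cfg)
            res = BiomarkerSurvival(cohort).fit()
            if res.logrank.p <= 0.05:
                hits += 1
        assert hits >= 19
        # direction: high-group median survival exceeds low-group
        high = res.curves["high"].step_function()
        low = res.curves["low"].step_function()
        t_mid = float(np.median(cohort.time))
        assert high(t_mid) > low(t_mid)

    def test_null_hazard_ratio_calibrated(self):
        """At hazard ratio 1 the log-rank rejection rate stays near alpha."""
        from sigreverse.survival import BiomarkerSurvival

        rejections = 0
        n_rep = 60
        for seed in range(n_rep):
            cfg = SimulationConfig(seed=seed + 10_000, cohort_size=150, hazard_ratio=1.0)
            cohort, _ = simulate_survival(cfg)
            res = BiomarkerSurvival(cohort).fit()
            rejections += res.logrank.p <= 0.05
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert rate <= 0.05 + 3 * se


def test_generated_artifacts_round_trip_through_io(tmp_path):
    from sigreverse.io import (
        read_expression_matrix, read_rank_database, read_survival_table,
        write_expression_matrix, write_rank_database, write_survival_table,
    )

    cfg = SimulationConfig(seed=2, genes=40, planted_de=8, instances=10,
                           compounds=5, cohort_size=30)
    matrix, _ = simulate_expression(cfg)
    write_expression_matrix(matrix, tmp_path / "e.tsv", tmp_path / "g.tsv")
    back = read_expression_matrix(tmp_path / "e.tsv", tmp_path / "g.tsv")
    pd.testing.assert_frame_equal(back.values, matrix.values)

    db, _ = simulate_rank_database(cfg, truth_signature(cfg))
    write_rank_database(db, tmp_path / "r.tsv", tmp_path / "m.tsv")
    dback = read_rank_database(tmp_path / "r.tsv", tmp_path / "m.tsv")
    pd.testing.assert_frame_equal(dback.ranks, db.ranks)
    pd.testing.assert_frame_equal(dback.metadata, db.metadata)

    cohort, _ = simulate_survival(cfg)
    write_survival_table(cohort, tmp_path / "s.tsv")
    sback = read_survival_table(tmp_path / "s.tsv")
    pd.testing.assert_frame_equal(sback.table, cohort.table)
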