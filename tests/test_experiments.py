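"""Evolution driver, mutation-effect screens and grid statistics."""

import numpy as np
import pandas as pd
import pytest

import kinforage as kf
from kinforage.arena import ArenaConfig
from kinforage.experiments import epistasis_z
from kinforage.fixtures import SHARE_SWITCH_GENE
from kinforage.relatedness import GroupComposition


@pytest.fixture(scope="module")
def short_cfg():
    return ArenaConfig(trial_duration=20.0)


class TestHamiltonThreshold:
    @pytest.mark.parametrize("r,ratio,expect", [
        (0.7492, 0.25, "altruism-favored"),
        (0.5, 0.5, "neutral"),
        (0.0, 0.01, "selfish-favored"),
    ])
    def test_sign_mapping(self, r, ratio, expect):
        assert kf.hamilton_threshold(r, ratio) == expect

    def test_validation(self):
        with pytest.raises(ValueError):
            kf.hamilton_threshold(1.5, 0.1)
        with pytest.raises(ValueError):
            kf.hamilton_threshold(0.5, -0.1)


class TestRunEvolution:
    def test_single_generation_log_and_initial_altruism(self, short_cfg):
        comp = GroupComposition((8,), m=60)
        log = kf.run_evolution(comp, 0.25, generations=1, seed=3,
                               cfg=short_cfg, trials=4)
        assert len(log.table) == 1
        # random controllers share or keep with equal probability
        assert log.table.mean_altruism.iloc[0] == pytest.approx(0.5, abs=0.12)
        assert log.final_population.shape == (60, 8, 33)

    def test_no_variation_from_single_founder_is_static(self, short_cfg):
        # clonal scheme seeded from one founder genome with mutation and
        # crossover off: the gene pool cannot change and the share
        # phenotype (always-share founder) stays at altruism 1 throughout
        comp = GroupComposition((8,), m=12)
        founder = kf.make_fixtures("always-share")[0]
        init = np.tile(founder, (12, 8, 1))
        log = kf.run_evolution(comp, 0.5, generations=3, seed=9, cfg=short_cfg,
                               trials=5, mutation_rate=0.0, crossover_rate=0.0,
                               initial_population=init)
        assert (log.final_population == founder).all()
        a = log.table.mean_altruism.dropna()
        assert len(a) > 0 and (a == 1.0).all()

    def test_reproducible_from_seed(self, short_cfg):
        comp = GroupComposition((7, 1), m=10)
        a = kf.run_evolution(comp, 0.25, 2, seed=21, cfg=short_cfg, trials=2)
        b = kf.run_evolution(comp, 0.25, 2, seed=21, cfg=short_cfg, trials=2)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert np.array_equal(a.final_population, b.final_population)

    def test_batch_matches_population_count(self, short_cfg):
        comps = [GroupComposition((8,), m=5), GroupComposition((1,) * 8, m=5)]
        logs = kf.run_evolution_batch(comps, [0.01, 1.0], 2, seed=4,
                                      cfg=short_cfg, trials=2)
        assert len(logs) == 2
        assert all(log.final_population.shape == (5, 8, 33) for log in logs)


class TestPleiotropyScreen:
    def test_share_switch_mutation_is_altruism_only(self, rng):
        # wall-seeker groups with the share circuit balanced at its
        # threshold: flipping gene 18's third bit flips the share sign
        # (altruism 1 -> 0) while leaving wheels nearly untouched.  A
        # small arena raises focal delivery counts enough for the
        # rank-sum test to resolve the altruism flip.
        cfg = ArenaConfig(side=25.0)
        pop = np.repeat(kf.make_fixtures("wall-seeker")[None], 6, axis=0)
        res = kf.pleiotropy_screen(
            pop, rng, trials=120, cfg=cfg,
            gene_indices=np.full(6, SHARE_SWITCH_GENE))
        t = res.table[~res.table["excluded"]]
        assert len(t) > 0
        # no mutation effect on foraging should ever be detected
        assert not t["sig_performance"].any()
        # wherever the focal delivered enough items for the test to have
        # power, the pure share-sign flip is detected as altruism-only
        enough = np.isfinite(res.alt_pre).sum(axis=1) >= 4
        powered = t[enough[~res.table["excluded"].to_numpy()]]
        assert len(powered) > 0
        assert (powered["classification"] == "altruism-only").all()
        assert (powered["alt_pre_mean"] > powered["alt_post_mean"]).all()

    def test_identical_pre_post_never_significant(self, short_cfg, rng):
        # flipping a gene and flipping it back is the identity; emulate a
        # no-op mutation by comparing a population against itself
        pop = np.repeat(kf.make_fixtures("wall-seeker")[None], 3, axis=0)
        res = kf.pleiotropy_screen(pop, rng, trials=30, cfg=short_cfg)
        t = res.table
        # bookkeeping: classes + excluded = sampled
        assert len(t) == 3
        counts = res.class_counts()
        assert sum(counts.values()) + res.n_excluded == 3

    def test_seed_reproducible(self, short_cfg):
        pop = np.repeat(kf.make_fixtures("wall-seeker")[None], 4, axis=0)
        a = kf.pleiotropy_screen(pop, np.random.default_rng(7), trials=20,
                                 cfg=short_cfg)
        b = kf.pleiotropy_screen(pop, np.random.default_rng(7), trials=20,
                                 cfg=short_cfg)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestEpistasisZ:
    def test_additive_fitness_gives_exact_zero(self, rng):
        # F(AB) - F(B) = F(A) - F(0) for any additive construction;
        # values on a dyadic grid keep the contrast exact in floating point
        for _ in range(20):
            f0, da, db = rng.integers(0, 20, 3) * 0.25
            means = np.array([f0, f0 + da, f0 + db, f0 + da + db])
            sds = rng.uniform(0.1, 1.0, 4)
            assert epistasis_z(means, sds, trials=100) == 0.0

    def test_multiplicative_interaction_detected(self):
        # B doubles fitness only when A is present
        means = np.array([2.0, 2.0, 2.0, 4.0])
        sds = np.full(4, 0.5)
        z = epistasis_z(means, sds, trials=100)
        assert abs(z) > 2

    def test_zero_variance_flagged(self):
        assert np.isnan(epistasis_z(np.array([1, 2, 3, 4.0]), np.zeros(4), 100))


class TestEpistasisScreen:
    def test_runs_and_bookkeeps(self, short_cfg, rng):
        pop = np.repeat(kf.make_fixtures("wall-seeker")[None], 4, axis=0)
        res = kf.epistasis_screen(pop, kf.make_payoff(0.25), rng,
                                  trials=25, cfg=short_cfg)
        t = res.table
        assert len(t) == 4
        assert (t["gene_a"] != t["gene_b"]).all()
        # z finite wherever some condition varies; flagged otherwise
        finite = np.isfinite(t["z"])
        assert (finite == ~t["flagged"]).all()


class TestWeakSelectionScreen:
    def _fake_screen(self, rows):
        table = pd.DataFrame(rows)
        return kf.MutationScreenResult(table=table, perf_pre=None, perf_post=None,
                                       alt_pre=None, alt_post=None)

    def test_relative_change_arithmetic(self):
        rows = [
            dict(perf_pre_mean=4.0, perf_post_mean=5.2,   # +30% -> flagged
                 alt_pre_mean=0.5, alt_post_mean=0.5, excluded=False),
            dict(perf_pre_mean=4.0, perf_post_mean=4.5,   # +12.5% -> not
                 alt_pre_mean=0.5, alt_post_mean=0.8, excluded=False),
            dict(perf_pre_mean=0.0, perf_post_mean=1.0,   # 0 -> >0: flagged
                 alt_pre_mean=np.nan, alt_post_mean=0.2, excluded=False),
            dict(perf_pre_mean=2.0, perf_post_mean=2.0,
                 alt_pre_mean=0.4, alt_post_mean=0.4, excluded=True),
        ]
        out = kf.weak_selection_screen(self._fake_screen(rows))
        assert out["performance_total"] == 3
        assert out["performance_count"] == 2
        assert out["performance_fraction"] == pytest.approx(2 / 3)
        # altruism: only rows with defined pre and post means count
        assert out["altruism_total"] == 2
        assert out["altruism_count"] == 1  # 0.5 -> 0.8 is +60%


class TestResultsStatistics:
    def _grid(self, altruism_fn):
        rows = []
        levels = [("r0", 0.0), ("r50", 0.5346), ("r100", 1.0)]
        ratios = [0.01, 0.5357, 1.0]
        for si, (scheme, r) in enumerate(levels):
            for ri, ratio in enumerate(ratios):
                for rep in range(4):
                    cls = {-1: "below", 0: "diagonal", 1: "above"}[int(np.sign(si - ri))]
                    rows.append(dict(scheme=scheme, ratio=ratio, r=r, replicate=rep,
                                     final_altruism=altruism_fn(r, ratio, rep),
                                     final_items=1.0, cell_class=cls))
        return pd.DataFrame(rows)

    def test_perfect_separation_gives_unit_correlations(self):
        # altruism = 1 iff r > c/b, 0 iff r < c/b, 0.5 on the diagonal
        def fn(r, ratio, rep):
            s = np.sign(r - ratio)
            base = {1: 0.9, 0: 0.5, -1: 0.1}[int(s)]
            return base + 0.02 * (r - ratio)  # monotone within branch
        stats = kf.results_statistics(self._grid(fn))
        assert stats["pearson"]["positive_branch"] == pytest.approx(1.0, abs=1e-6)
        assert stats["pearson"]["negative_branch"] == pytest.approx(1.0, abs=1e-6)

    def test_constant_diagonal_cannot_reject_half(self):
        stats = kf.results_statistics(self._grid(lambda r, x, rep: 0.5))
        for p in stats["diagonal_wilcoxon_p"].values():
            assert p == 1.0
        # zero variance everywhere -> F = 0 in every defined cell
        assert (stats["drift_F"]["F"].dropna() == 0).all()

    def test_diagonal_drift_excess_detected(self):
        def fn(r, ratio, rep):
            if abs(r - ratio) < 0.1:   # diagonal: drift spread
                return [0.1, 0.4, 0.6, 0.9][rep]
            return 0.9 if r > ratio else 0.1
        stats = kf.results_statistics(self._grid(fn))
        for p in stats["F_class_comparison_p"].values():
            assert p < 0.05
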