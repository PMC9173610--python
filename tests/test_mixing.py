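import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

from trophicmix.baselines import TDFSpec
from trophicmix.dataset import IsotopeSample
from trophicmix.mixing import (DietPosterior, DietSources, SourceSpec,
                               combine_posterior, dic, fit_mixing,
                               polygon_check, pool_sources)
from trophicmix.synthetic import TruthRecord, simulate_mixture_consumer

TDF0 = TDFSpec(0.0, 0.0, 0.0, 0.0)


def _samples(tid, c_vals, n_vals):
    return [IsotopeSample(tid, tid, "Decapoda", float(c), float(n))
            for c, n in zip(c_vals, n_vals)]


def _sources(*rows, tdf=TDF0):
    return DietSources(tuple(
        SourceSpec(sid, mc, sc, mn, sn, 10, tdf)
        for sid, mc, sc, mn, sn in rows))


class TestFitMixing:
    def test_pure_diet_concentrates(self, tiny_mcmc):
        sources = _sources(("A", -20.0, 0.05, 8.0, 0.05),
                           ("B", -13.0, 0.05, 15.0, 0.05))
        rng = np.random.default_rng(0)
        cons = _samples("X", -20.0 + 0.05 * rng.standard_normal(8),
                        8.0 + 0.05 * rng.standard_normal(8))
        post = fit_mixing(cons, sources, tiny_mcmc, seed=1)
        assert post.p_draws[:, 0].mean() > 0.95

    def test_two_source_one_tracer_closed_form(self, tiny_mcmc):
        """Sources identical in carbon: nitrogen alone fixes p linearly."""
        delta = TDFSpec(0.0, 0.0, 2.0, 0.0)
        sources = _sources(("A", -17.0, 0.05, 6.0, 0.05),
                           ("B", -17.0, 0.05, 14.0, 0.05), tdf=delta)
        p1_true = 0.7
        mN = p1_true * (6.0 + 2.0) + (1 - p1_true) * (14.0 + 2.0)
        rng = np.random.default_rng(2)
        cons = _samples("X", -17.0 + 0.05 * rng.standard_normal(10),
                        mN + 0.05 * rng.standard_normal(10))
        post = fit_mixing(cons, sources, tiny_mcmc, seed=3)
        closed = (np.mean([s.d15N for s in cons]) - 16.0) / (8.0 - 16.0)
        assert post.p_draws[:, 0].mean() == pytest.approx(closed, abs=0.02)

    def test_simplex_conservation(self, tiny_mcmc):
        sources = _sources(("A", -20, 0.3, 8, 0.3), ("B", -16, 0.3, 12, 0.3),
                           ("C", -12, 0.3, 9, 0.3))
        rng = np.random.default_rng(4)
        cons = _samples("X", -16.0 + 0.3 * rng.standard_normal(6),
                        10.0 + 0.3 * rng.standard_normal(6))
        post = fit_mixing(cons, sources, tiny_mcmc, seed=5)
        sums = post.p_draws.sum(axis=1)
        assert np.all(np.abs(sums - 1.0) < 1e-9)
        assert np.all(post.p_draws >= 0)
        assert np.all(post.resid_draws >= 1.0)

    def test_source_order_equivariance(self, tiny_mcmc):
        rows = [("A", -20.0, 0.3, 8.0, 0.3), ("B", -16.0, 0.3, 12.0, 0.3),
                ("C", -12.0, 0.3, 9.0, 0.3)]
        rng = np.random.default_rng(6)
        cons = _samples("X", -17.0 + 0.3 * rng.standard_normal(8),
                        10.0 + 0.3 * rng.standard_normal(8))
        a = fit_mixing(cons, _sources(*rows), tiny_mcmc, seed=7).summary()
        b = fit_mixing(cons, _sources(*rows[::-1]), tiny_mcmc, seed=7).summary()
        for sid in "ABC":
            ma = float(a.set_index("source").loc[sid, "mean"])
            mb = float(b.set_index("source").loc[sid, "mean"])
            assert ma == pytest.approx(mb, abs=0.03)

    def test_polygon_warning_attached(self, tiny_mcmc):
        sources = _sources(("A", -20, 0.2, 8, 0.2), ("B", -18, 0.2, 12, 0.2),
                           ("C", -16, 0.2, 9, 0.2))
        cons = _samples("X", np.full(5, -10.0), np.full(5, 25.0))
        post = fit_mixing(cons, sources, tiny_mcmc, seed=8)
        assert post.warnings


class TestPooling:
    def test_pooled_moments_match_concatenation(self):
        rng = np.random.default_rng(9)
        a = rng.normal(-15.7, 0.9, 21)
        b = rng.normal(-16.9, 0.7, 72)
        sa = SourceSpec("SBF", a.mean(), a.std(ddof=1), 14.6, 0.7, 21, TDF0)
        sb = SourceSpec("BIF", b.mean(), b.std(ddof=1), 13.2, 0.8, 72, TDF0)
        sc = SourceSpec("DFC", -17.3, 0.8, 15.2, 0.9, 82, TDF0)
        pooled = pool_sources(DietSources((sa, sb, sc)),
                              {"SBF-BIF": ["SBF", "BIF"]})
        merged = next(s for s in pooled.sources if s.source_id == "SBF-BIF")
        both = np.concatenate([a, b])
        assert merged.mean_dC == pytest.approx(both.mean(), abs=1e-9)
        assert merged.sd_dC == pytest.approx(both.std(ddof=1), abs=1e-9)
        assert merged.n == 93
        assert len(pooled) == 2  # DFC passes through

    def test_identity_merge_unchanged(self):
        src = _sources(("A", -20, 0.3, 8, 0.3), ("B", -16, 0.3, 12, 0.3))
        assert pool_sources(src, {}).sources == src.sources

    def test_equal_identical_sources_keep_moments(self):
        """Merging two identical sources keeps the mean; the SD carries the
        (N−1)-denominator concatenation factor √((2n−2)/(2n−1))."""
        src = _sources(("A", -20, 0.3, 8, 0.4), ("B", -20, 0.3, 8, 0.4),
                       ("C", -15, 0.3, 12, 0.3))
        pooled = pool_sources(src, {"AB": ["A", "B"]})
        merged = next(s for s in pooled.sources if s.source_id == "AB")
        assert merged.mean_dC == pytest.approx(-20.0)
        assert merged.mean_dN == pytest.approx(8.0)
        factor = np.sqrt(18 / 19)  # n = 10 each
        assert merged.sd_dN == pytest.approx(0.4 * factor, abs=1e-12)

    def test_overlapping_merge_rejected(self):
        src = _sources(("A", -20, 0.3, 8, 0.3), ("B", -16, 0.3, 12, 0.3),
                       ("C", -12, 0.3, 9, 0.3))
        with pytest.raises(ValueError):
            pool_sources(src, {"X": ["A", "B"], "Y": ["B", "C"]})


def _manual_posterior(p_chains):
    p_chains = np.asarray(p_chains, float)
    C, n, K = p_chains.shape
    return DietPosterior("X", tuple(f"S{k}" for k in range(K)), p_chains,
                         np.ones((C, n, 2)), np.full(C * n, 10.0), 10.0,
                         1.0, True, pd.DataFrame())


class TestCombinePosterior:
    def test_singleton_groups_unchanged(self):
        rng = np.random.default_rng(10)
        p = rng.dirichlet([1, 1, 1], size=(2, 50))
        post = _manual_posterior(p)
        comb = combine_posterior(post, {"S0": ["S0"], "S1": ["S1"],
                                        "S2": ["S2"]})
        np.testing.assert_allclose(comb.p_draws, post.p_draws)

    def test_all_in_one_group_is_unity(self):
        rng = np.random.default_rng(11)
        post = _manual_posterior(rng.dirichlet([1, 1, 1], size=(2, 50)))
        comb = combine_posterior(post, {"all": ["S0", "S1", "S2"]})
        np.testing.assert_allclose(comb.p_draws[:, 0], 1.0, atol=1e-12)

    def test_incomplete_partition_rejected(self):
        rng = np.random.default_rng(12)
        post = _manual_posterior(rng.dirichlet([1, 1, 1], size=(2, 50)))
        with pytest.raises(ValueError):
            combine_posterior(post, {"X": ["S0", "S1"]})


class TestDIC:
    def test_degenerate_posterior_has_zero_pd(self):
        post = _manual_posterior(np.full((2, 40, 3), 1.0 / 3))
        assert dic(post) == pytest.approx(10.0)  # pD = 0 ⇒ DIC = deviance

    def test_true_source_model_preferred(self, tiny_mcmc):
        """Dropping a source that feeds the consumer costs DIC."""
        sources3 = _sources(("A", -20, 0.3, 8, 0.3), ("B", -16, 0.3, 12, 0.3),
                            ("C", -12, 0.3, 9, 0.3))
        sources2 = DietSources(sources3.sources[:2])
        wins = 0
        for seed in range(3):
            truth = TruthRecord("M", 3.0, 0.5, n=30,
                                true_p={"A": 0.2, "B": 0.3, "C": 0.5})
            cons = simulate_mixture_consumer(truth, sources3, resid_sd=0.2,
                                             seed=seed)
            full = fit_mixing(cons, sources3, tiny_mcmc, seed=seed)
            dropped = fit_mixing(cons, sources2, tiny_mcmc, seed=seed)
            wins += dic(full) < dic(dropped)
        assert wins >= 2

    def test_irrelevant_source_does_not_win(self, tiny_mcmc):
        sources2 = _sources(("A", -20, 0.3, 8, 0.3), ("B", -16, 0.3, 12, 0.3))
        sources3 = DietSources(sources2.sources + (
            SourceSpec("far", -5.0, 0.3, 25.0, 0.3, 10, TDF0),))
        truth = TruthRecord("M", 3.0, 0.5, n=30, true_p={"A": 0.6, "B": 0.4})
        cons = simulate_mixture_consumer(truth, sources2, resid_sd=0.2, seed=3)
        base = fit_mixing(cons, sources2, tiny_mcmc, seed=3)
        bigger = fit_mixing(cons, sources3, tiny_mcmc, seed=3)
        assert dic(bigger) > dic(base) - 2.0  # no spurious improvement


def _lp_inside(point, vertices):
    """Oracle: point is a convex combination of vertices (LP feasibility)."""
    K = len(vertices)
    A_eq = np.vstack([np.asarray(vertices).T, np.ones(K)])
    b_eq = np.array([point[0], point[1], 1.0])
    res = linprog(np.zeros(K), A_eq=A_eq, b_eq=b_eq, bounds=[(0, None)] * K)
    return res.status == 0


class TestPolygonCheck:
    SRC = _sources(("A", -20, 0.2, 8, 0.2), ("B", -16, 0.2, 14, 0.2),
                   ("C", -12, 0.2, 9, 0.2))

    def test_centroid_inside(self):
        pts = self.SRC.corrected_means()
        assert polygon_check(tuple(pts.mean(axis=0)), self.SRC)

    def test_far_outside(self):
        assert not polygon_check((-30.0, 25.0), self.SRC)

    def test_vertex_counts_as_inside(self):
        pts = self.SRC.corrected_means()
        assert polygon_check(tuple(pts[0]), self.SRC)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_lp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = [(f"S{k}", rng.uniform(-22, -12), 0.2, rng.uniform(6, 16), 0.2)
                for k in range(4)]
        src = _sources(*rows)
        point = (rng.uniform(-23, -11), rng.uniform(5, 17))
        assert polygon_check(point, src) == _lp_inside(
            point, src.corrected_means())

    def test_two_source_interval_fallback(self):
        src = _sources(("A", -20, 0.2, 8, 0.2), ("B", -16, 0.2, 12, 0.2))
        assert polygon_check((-18.0, 10.0), src)
        assert not polygon_check((-10.0, 10.0), src)
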