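import numpy as np
import pandas as pd
import pytest

from trophicmix.baselines import TDFSpec, build_baseline_pair
from trophicmix.dataset import IsotopeSample
from trophicmix.tp_model import (TPModelSpec, TPPosterior, compare_to_reference,
                                 fit_tp, reconstitute_samples,
                                 reference_tl_from_diet, summarize_tp)


def _samples(tid, c_vals, n_vals, cls="Actinopterygii"):
    return [IsotopeSample(tid, tid, cls, float(c), float(n))
            for c, n in zip(c_vals, n_vals)]


def _tight_pair(rng, jitter=0.01):
    ben = _samples("BEN", -17.9 + jitter * rng.standard_normal(20),
                   10.1 + jitter * rng.standard_normal(20), "Baseline")
    pel = _samples("PEL", -20.4 + jitter * rng.standard_normal(20),
                   8.6 + jitter * rng.standard_normal(20), "Baseline")
    return build_baseline_pair(ben, pel, 2.0)


class TestFitTP:
    def test_one_step_consumer_lands_near_three(self, tiny_mcmc):
        """A consumer one exact TDF step above the benthic baseline."""
        rng = np.random.default_rng(0)
        pair = _tight_pair(rng)
        cons = _samples("X", -16.9 + 0.01 * rng.standard_normal(6),
                        13.5 + 0.01 * rng.standard_normal(6))
        spec = TPModelSpec(tdf=TDFSpec(1.0, 0.5, 3.4, 0.5), mcmc=tiny_mcmc,
                           fix_alpha=1.0)
        post = fit_tp(cons, pair, spec, seed=1)
        assert summarize_tp(post)[0] == pytest.approx(3.0, abs=0.15)

    def test_degenerate_limit_matches_closed_form(self, tiny_mcmc):
        """Tight data, fixed α, point TDFs: TP collapses to the algebra."""
        rng = np.random.default_rng(1)
        pair = _tight_pair(rng, jitter=0.005)
        alpha, tp_true = 0.3, 4.1
        mC = alpha * -17.9 + (1 - alpha) * -20.4 + 1.0 * (tp_true - 2)
        mN = alpha * 10.1 + (1 - alpha) * 8.6 + 3.4 * (tp_true - 2)
        cons = _samples("X", mC + 0.005 * rng.standard_normal(8),
                        mN + 0.005 * rng.standard_normal(8))
        spec = TPModelSpec(tdf=TDFSpec(1.0, 0.0, 3.4, 0.0), mcmc=tiny_mcmc,
                           fix_alpha=alpha)
        post = fit_tp(cons, pair, spec, seed=2)
        closed = 2 + (np.mean([s.d15N for s in cons])
                      - alpha * 10.1 - (1 - alpha) * 8.6) / 3.4
        assert summarize_tp(post)[0] == pytest.approx(closed, abs=0.01)

    def test_posterior_monotone_in_d15N(self, tiny_mcmc, flat_baselines):
        rng = np.random.default_rng(3)
        base_n = 13.0 + 0.3 * rng.standard_normal(6)
        c = -17.5 + 0.3 * rng.standard_normal(6)
        spec = TPModelSpec(tdf=TDFSpec(1.0, 0.5, 3.4, 0.5), mcmc=tiny_mcmc)
        lo = fit_tp(_samples("X", c, base_n), flat_baselines, spec, seed=4)
        hi = fit_tp(_samples("X", c, base_n + 1.0), flat_baselines, spec, seed=4)
        assert hi.mean_tp > lo.mean_tp

    def test_alpha_tracks_benthic_carbon(self, tiny_mcmc, flat_baselines):
        """A consumer at the benthic δ13C pulls α above one half."""
        rng = np.random.default_rng(5)
        cons = _samples("X", -17.4 + 0.2 * rng.standard_normal(7),
                        13.0 + 0.3 * rng.standard_normal(7))
        spec = TPModelSpec(tdf=TDFSpec(0.5, 0.13, 2.3, 0.18), mcmc=tiny_mcmc)
        post = fit_tp(cons, flat_baselines, spec, seed=6)
        assert post.alpha_draws.mean() > 0.5

    def test_chain_geometry(self, tiny_mcmc, flat_baselines):
        rng = np.random.default_rng(7)
        cons = _samples("X", -17.5 + 0.3 * rng.standard_normal(5),
                        13.5 + 0.3 * rng.standard_normal(5))
        spec = TPModelSpec(tdf=TDFSpec(1.0, 0.5, 3.4, 0.5), mcmc=tiny_mcmc)
        post = fit_tp(cons, flat_baselines, spec, seed=8)
        expect = (tiny_mcmc.iterations - tiny_mcmc.burn_in) // tiny_mcmc.thin
        assert post.tp_chains.shape == (tiny_mcmc.chains, expect)
        assert post.tp_draws.min() > 2.0 and post.tp_draws.max() < 10.0
        assert np.all(post.alpha_draws >= 0) and np.all(post.alpha_draws <= 1)

    def test_single_individual_rejected(self, tiny_mcmc, flat_baselines):
        spec = TPModelSpec(tdf=TDFSpec(1.0, 0.5, 3.4, 0.5), mcmc=tiny_mcmc)
        with pytest.raises(ValueError):
            fit_tp(_samples("X", [-17.0], [13.0]), flat_baselines, spec)


def _posterior_from_draws(draws):
    arr = np.atleast_2d(np.asarray(draws, float))
    return TPPosterior("X", arr, np.full_like(arr, 0.5), 2.0, 1.0, True,
                       pd.DataFrame())


class TestSummaries:
    def test_constant_draws(self):
        mean, ci = summarize_tp(_posterior_from_draws(np.full(100, 3.0)))
        assert mean == 3.0 and ci == (3.0, 3.0)

    def test_uniform_grid_quantiles(self):
        mean, (lo, hi) = summarize_tp(
            _posterior_from_draws(np.linspace(2, 4, 2001)))
        assert lo == pytest.approx(2.05, abs=1e-6)
        assert hi == pytest.approx(3.95, abs=1e-6)

    def test_reference_overlap_and_direction(self):
        post = _posterior_from_draws(np.linspace(3.9, 4.5, 500))
        cmp_ = compare_to_reference(post, 4.4, 0.2)
        assert cmp_.overlap and cmp_.direction == "below"

    def test_reference_disjoint(self):
        post = _posterior_from_draws(np.linspace(3.0, 3.4, 500))
        cmp_ = compare_to_reference(post, 4.4, 0.2)
        assert not cmp_.overlap and cmp_.direction == "below"

    def test_reference_inside_ci(self):
        post = _posterior_from_draws(np.linspace(3.9, 4.5, 500))
        assert compare_to_reference(post, 4.2, None).overlap


class TestReferenceTLFromDiet:
    def test_single_prey(self):
        assert reference_tl_from_diet([2.0]) == (3.0, 0.0)

    def test_two_prey_symmetry(self):
        mean, se = reference_tl_from_diet([2.0, 3.0], n_resample=40_000, seed=0)
        assert mean == pytest.approx(3.5, abs=0.01)
        assert se > 0

    def test_many_prey_expectation(self):
        mean, _ = reference_tl_from_diet([2.0, 2.5, 3.1], n_resample=60_000,
                                         seed=1)
        assert mean == pytest.approx(1 + np.mean([2.0, 2.5, 3.1]), abs=0.01)


class TestReconstitute:
    def test_moments_match_exactly(self):
        out = reconstitute_samples("X", "x", "Decapoda", -17.1, 0.8, 12.5, 0.5,
                                   9, seed=0)
        c = np.array([s.d13C for s in out])
        n = np.array([s.d15N for s in out])
        assert c.mean() == pytest.approx(-17.1, abs=1e-9)
        assert c.std(ddof=1) == pytest.approx(0.8, abs=1e-9)
        assert n.mean() == pytest.approx(12.5, abs=1e-9)
        assert n.std(ddof=1) == pytest.approx(0.5, abs=1e-9)

    def test_seeded_reproducibility(self):
        a = reconstitute_samples("X", "x", "Decapoda", -17.0, 0.5, 12.0, 0.5,
                                 5, seed=3)
        b = reconstitute_samples("X", "x", "Decapoda", -17.0, 0.5, 12.0, 0.5,
                                 5, seed=3)
        assert a == b
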