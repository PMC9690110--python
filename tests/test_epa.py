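import numpy as np
import pytest
from scipy.stats import chisquare, expon, kstest

from oracles import crp_partition_prob, crp_seating_probs
from tipclust.epa_baseline import (
    EPAParams,
    epa_conditional,
    run_crp_sampler,
    run_epa_sampler,
    sample_alpha_west,
)
from tipclust.gibbs_sampler import SamplerConfig
from tipclust.similarity import SimilarityMatrix


def _const_sim(n, c=0.5):
    v = np.full((n, n), c)
    np.fill_diagonal(v, 1.0)
    return SimilarityMatrix(v)


class TestEpaConditional:
    def test_crp_case_two_subjects(self):
        L = _const_sim(2)
        labels, probs = epa_conditional(
            2, np.array([1]), np.arange(2), L, EPAParams(alpha=1.0, delta=0.0)
        )
        assert probs == pytest.approx([0.5, 0.5])

    def test_reduces_to_crp_for_all_partials(self, rng):
        """delta = 0 with constant similarity reproduces size-proportional
        seating exactly, for every partial partition of n <= 6."""
        alpha = 1.3
        params = EPAParams(alpha=alpha, delta=0.0)
        for n in (3, 4, 5, 6):
            L = _const_sim(n, c=0.37)
            sigma = np.arange(n)
            for _ in range(20):
                i_pos = int(rng.integers(2, n + 1))
                partial = rng.integers(1, 4, size=i_pos - 1)
                partial[0] = 1
                labels, probs = epa_conditional(i_pos, partial, sigma, L, params)
                oracle = crp_seating_probs(partial, alpha)
                for lab, p in zip(labels, probs[:-1]):
                    assert p == pytest.approx(oracle[int(lab)], abs=1e-12)
                assert probs[-1] == pytest.approx(oracle["new"], abs=1e-12)

    def test_attraction_weighted_example(self):
        # two seated subjects share one cluster; similarity ratio is 1
        # for a single cluster, so P(join) = 2/3, P(new) = 1/3
        v = np.array([[1, 0.8, 0.2], [0.8, 1, 0.5], [0.2, 0.5, 1.0]])
        L = SimilarityMatrix(v)
        sigma = np.array([0, 1, 2])  # subject 2 arrives third
        labels, probs = epa_conditional(
            3, np.array([1, 1]), sigma, L, EPAParams(alpha=1.0, delta=0.0)
        )
        assert probs == pytest.approx([2 / 3, 1 / 3])

    def test_probabilities_sum_to_one(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 8))
            v = rng.uniform(0.05, 1, size=(n, n))
            v = 0.5 * (v + v.T)
            np.fill_diagonal(v, 1.0)
            params = EPAParams(alpha=float(rng.uniform(0.2, 3)),
                               delta=float(rng.uniform(0, 0.9)))
            sigma = rng.permutation(n)
            i_pos = int(rng.integers(2, n + 1))
            partial = rng.integers(1, 3, size=i_pos - 1)
            partial[0] = 1
            _, probs = epa_conditional(i_pos, partial, sigma, SimilarityMatrix(v), params)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(probs >= 0)

    def test_first_position_rejected(self):
        with pytest.raises(ValueError):
            epa_conditional(1, np.array([]), np.arange(3), _const_sim(3), EPAParams())


class TestSampleAlphaWest:
    def test_gamma_mean_monte_carlo(self):
        rng = np.random.default_rng(8)
        params = EPAParams(a=1.0, b=1.0)
        draws = np.array(
            [sample_alpha_west(3, 10, params, rng) for _ in range(100_000)]
        )
        rate = 1.0 + np.euler_gamma + np.log(10)
        mean = 3 / rate  # shape 3 / rate
        sd = np.sqrt(3) / rate
        assert abs(draws.mean() - mean) < 3 * sd / np.sqrt(draws.size)

    def test_seeded_reproducibility(self):
        a = sample_alpha_west(4, 20, EPAParams(), np.random.default_rng(5))
        b = sample_alpha_west(4, 20, EPAParams(), np.random.default_rng(5))
        assert a == b

    def test_single_cluster_is_exponential(self):
        rng = np.random.default_rng(17)
        params = EPAParams(a=1.0, b=1.0)
        draws = np.array(
            [sample_alpha_west(1, 50, params, rng) for _ in range(10_000)]
        )
        rate = 1.0 + np.euler_gamma + np.log(50)
        stat = kstest(draws, expon(scale=1 / rate).cdf)
        assert stat.pvalue > 0.01

    def test_invalid_shape(self):
        with pytest.raises(ValueError):
            sample_alpha_west(0, 10, EPAParams(a=1.0), np.random.default_rng(0))


class TestRunEpaSampler:
    def test_seeded_reproducibility(self, tiny_two_clusters):
        X, _ = tiny_two_clusters
        cfg = SamplerConfig(burn_in=5, samples=10, seed=4)
        a = run_epa_sampler(X=X, config=cfg)
        b = run_epa_sampler(X=X, config=cfg)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.K_trace, b.K_trace)

    def test_alpha_chain_stays_positive(self, tiny_two_clusters):
        X, _ = tiny_two_clusters
        rec = run_epa_sampler(X=X, config=SamplerConfig(burn_in=0, samples=30, seed=1))
        assert all(info["alpha"] > 0 for info in rec.log_info)

    def test_likelihood_free_chain_matches_crp_distribution(self):
        """With delta = 0, constant similarity, fixed alpha and no
        likelihood, each reseating sweep is an exact sequential CRP
        draw: partition frequencies over 10^4 sweeps match the CRP
        product-form probabilities (chi-squared, n = 4)."""
        n, alpha = 4, 1.0
        cfg = SamplerConfig(burn_in=0, samples=10_000, seed=12, use_likelihood=False)
        X = np.arange(n, dtype=float)[:, None]  # distances irrelevant
        rec = run_epa_sampler(
            X=X, config=cfg, params=EPAParams(alpha=alpha),
            constant_similarity=True, update_alpha=False,
        )
        # canonical form: labels in order of first appearance
        def canon(c):
            seen, out = {}, []
            for x in c:
                seen.setdefault(x, len(seen) + 1)
                out.append(seen[x])
            return tuple(out)

        from collections import Counter

        freq = Counter(canon(d) for d in rec.draws)
        parts = sorted(freq)
        expected = np.array([crp_partition_prob(np.array(p), alpha) for p in parts])
        assert expected.sum() == pytest.approx(1.0, abs=1e-9)
        observed = np.array([freq[p] for p in parts])
        stat = chisquare(observed, expected * observed.sum())
        assert stat.pvalue > 0.001

    def test_crp_sampler_equals_epa_with_constant_similarity(self, tiny_two_clusters):
        X, _ = tiny_two_clusters
        cfg = SamplerConfig(burn_in=2, samples=5, seed=9)
        a = run_crp_sampler(X=X, config=cfg)
        b = run_epa_sampler(X=X, config=cfg, constant_similarity=True)
        assert np.array_equal(a.draws, b.draws)

    def test_collapsed_scheme_recovers_two_clusters(self, tiny_two_clusters):
        X, labels = tiny_two_clusters
        from tipclust.consensus import posterior_similarity_from_draws, select_consensus
        from tipclust.simulation import adjusted_rand

        rec = run_epa_sampler(
            X=X, config=SamplerConfig(burn_in=30, samples=30, seed=2),
            scheme="collapsed",
        )
        Bbar = posterior_similarity_from_draws(rec.draws)
        cons = select_consensus(rec.draws, Bbar)
        assert adjusted_rand(cons.assignment, labels) == 1.0
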