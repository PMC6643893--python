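"""Gamete-ancestry chain, accumulated recombination, look-ahead objective."""

import numpy as np
import pytest

from looksel import (
    LookaheadParams,
    Population,
    accumulated_recomb,
    compute_gebv,
    estimate_flas,
    sample_terminal_gamete,
    transition_probability,
)
from looksel.lookahead import FlasEvaluator, sample_ancestry_paths

from conftest import make_spec, pop_from_haplotypes


class TestAccumulatedRecomb:
    def test_zero_recombination_gives_zero(self):
        assert np.allclose(accumulated_recomb(np.zeros(5), S=20, horizon=7), 0.0)

    def test_two_parents_give_zero(self):
        r = np.array([0.1, 0.4])
        assert np.allclose(accumulated_recomb(r, S=2, horizon=9), 0.0)

    def test_direct_evaluation(self):
        R = accumulated_recomb(np.array([0.1]), S=20, horizon=3)
        assert R[0] == pytest.approx(18 * (1 - 0.9**3) / 20, abs=1e-12)
        assert R[0] == pytest.approx(0.2439, abs=1e-6)

    def test_long_horizon_limit(self):
        R = accumulated_recomb(np.array([0.3]), S=20, horizon=10_000)
        assert R[0] == pytest.approx(18 / 20, abs=1e-9)

    def test_first_order_in_small_r_and_horizon(self):
        r, S, h = 1e-5, 20, 3
        R = accumulated_recomb(np.array([r]), S=S, horizon=h)
        assert R[0] == pytest.approx((S - 2) * h * r / S, rel=1e-3)


class TestTransitionKernel:
    def test_case_values(self):
        # S=4, r=0.2, R=0.3
        kw = dict(r_next=0.2, R_next=0.3, S=4)
        assert transition_probability(0, 0, 0, 0, **kw) == pytest.approx(0.448)
        assert transition_probability(0, 0, 0, 1, **kw) == pytest.approx(0.112)
        assert transition_probability(0, 0, 1, 0, **kw) == pytest.approx(0.07)
        assert transition_probability(0, 0, 2, 1, **kw) == pytest.approx(0.075)

    def test_no_recombination_freezes_state(self):
        for S in (2, 4):
            assert transition_probability(1, 1, 1, 1, 0.0, 0.0, S) == 1.0
            assert transition_probability(1, 1, 0, 1, 0.0, 0.0, S) == 0.0

    @pytest.mark.parametrize("S", [2, 4, 20])
    @pytest.mark.parametrize("R", [0.0, 0.2, 0.8])
    @pytest.mark.parametrize("r", [0.0, 0.1, 0.3, 0.5])
    def test_normalization_over_destination_states(self, r, R, S):
        total = sum(
            transition_probability(1, 0, i1, m1, r, R, S)
            for i1 in range(S)
            for m1 in range(2)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_cross_pair_case_impossible_with_two_parents(self):
        assert transition_probability(0, 0, 1, 0, 0.2, 0.0, 2) == pytest.approx(
            0.5 * 0.2
        )
        # no non-mate pair exists for S=2; requesting one would need R > 0,
        # which the two-parent chain cannot accumulate
        with pytest.raises(ValueError):
            transition_probability(0, 0, 2, 0, 0.2, 0.0, 2)


def exact_chain_distribution(S, r, R):
    """Enumerate the chain over all (2S)^L ancestry paths; independent oracle.

    Returns a dict mapping state-path tuples to exact probabilities, built
    by brute-force products of Eq-style case probabilities.
    """
    L = len(r) + 1
    states = [(i, m) for i in range(S) for m in range(2)]
    paths = {(): 1.0}
    for l in range(L):
        new = {}
        for path, p in paths.items():
            for st in states:
                if l == 0:
                    q = 1.0 / (2 * S)
                else:
                    i0, m0 = path[-1]
                    q = transition_probability(i0, m0, st[0], st[1], r[l - 1], R[l - 1], S)
                if p * q > 0:
                    new[path + (st,)] = p * q
        paths = new
    return paths


class TestAncestrySampling:
    def test_two_parent_no_recomb_gamete_uniform_over_haplotypes(self, rng):
        pop = pop_from_haplotypes(((1, 1), (1, 0)), ((0, 1), (0, 0)))
        spec = make_spec([1.0, 1.0], r=[0.0])
        counts = {}
        for _ in range(4000):
            g = sample_terminal_gamete(pop, spec.r, np.zeros(1), rng)
            counts[tuple(g.g)] = counts.get(tuple(g.g), 0) + 1
        # the four parental haplotypes are distinct; each should appear ~1/4
        assert set(counts) == {(1, 1), (1, 0), (0, 1), (0, 0)}
        for c in counts.values():
            assert c / 4000 == pytest.approx(0.25, abs=3 * np.sqrt(0.25 * 0.75 / 4000))

    def test_identical_homozygous_parents_give_constant_gamete(self, rng):
        hap = (1, 0, 1)
        pop = pop_from_haplotypes((hap, hap), (hap, hap))
        spec = make_spec([1.0, 1.0, 1.0])
        R = accumulated_recomb(spec.r, 2, 4)
        for _ in range(20):
            g = sample_terminal_gamete(pop, spec.r, R, rng)
            assert tuple(g.g) == hap

    def test_odd_parent_count_rejected(self, rng):
        pop = pop_from_haplotypes(((1,), (0,)), ((1,), (0,)), ((1,), (0,)))
        with pytest.raises(ValueError, match="even"):
            sample_terminal_gamete(pop, np.zeros(0), np.zeros(0), rng)

    def test_sampled_path_frequencies_match_exact_enumeration(self, rng):
        """Monte-Carlo ancestry paths vs brute-force chain enumeration (L=3, S=4)."""
        from scipy import stats

        S, r, R = 4, np.array([0.3, 0.2]), np.array([0.4, 0.1])
        exact = exact_chain_distribution(S, r, R)
        n = 30_000
        parents, homologs = sample_ancestry_paths(S, r, R, n, rng)
        keys = list(exact)
        index = {k: j for j, k in enumerate(keys)}
        observed = np.zeros(len(keys))
        for k in range(n):
            path = tuple((int(parents[k, l]), int(homologs[k, l])) for l in range(3))
            observed[index[path]] += 1
        expected = np.array([exact[k] for k in keys]) * n
        assert expected.min() > 5  # chi-square validity
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=len(keys) - 1)
        assert p > 0.01


class TestEstimateFlas:
    def test_degenerate_population_returns_its_gebv(self, rng):
        hap = (1, 0, 1)
        pop = pop_from_haplotypes((hap, hap), (hap, hap))
        spec = make_spec([2.0, 1.0, 0.5])
        want = compute_gebv(pop, spec)[0]
        for horizon in (1, 2, 5):
            est = estimate_flas(pop, spec, horizon, LookaheadParams(10, 2), rng)
            assert est == pytest.approx(want)

    def test_two_homozygous_parents_expectation(self, rng):
        """S=2, r=0: terminal progeny is aa/ab/bb with probability 1/4,1/2,1/4."""
        a, b = (1, 1, 0), (0, 1, 1)
        pop = pop_from_haplotypes((a, a), (b, b))
        spec = make_spec([3.0, 1.0, 2.0], r=[0.0, 0.0])
        V = lambda h1, h2: sum((x + y) * w for x, y, w in zip(h1, h2, spec.beta))
        want = (V(a, a) + 2 * V(a, b) + V(b, b)) / 4
        est = estimate_flas(pop, spec, 2, LookaheadParams(1, 4000), rng)
        sd = np.sqrt((V(a, a) ** 2 + 2 * V(a, b) ** 2 + V(b, b) ** 2) / 4 - want**2)
        assert est == pytest.approx(want, abs=4 * sd / np.sqrt(4000))

    def test_horizon_one_cannot_combine_across_families(self, rng):
        # pair 1 carries only locus-A value, pair 2 only locus-B value; a
        # single cross cannot stack both, so the exact horizon-1 objective
        # is capped at 2, whereas the multi-generation chain could reach 4
        A, B = (1, 0), (0, 1)
        zero = (0, 0)
        pop = pop_from_haplotypes((A, A), (A, A), (B, B), (B, B))
        spec = make_spec([2.0, 2.0], r=[0.5])
        est1 = estimate_flas(pop, spec, 1, LookaheadParams(500, 1), rng)
        assert est1 == pytest.approx(4.0)  # best pair is homozygous AA x AA
        est3 = estimate_flas(pop, spec, 3, LookaheadParams(500, 1), rng)
        assert est3 > 4.0  # chain can combine A and B across families -> up to 8

    def test_monotone_in_sample_size_on_average(self, rng):
        pop = pop_from_haplotypes(((1, 0, 1), (0, 1, 0)), ((1, 1, 0), (0, 0, 1)))
        spec = make_spec([1.0, 1.0, 1.0])
        small = estimate_flas(pop, spec, 2, LookaheadParams(2, 400), rng)
        large = estimate_flas(pop, spec, 2, LookaheadParams(50, 400), rng)
        assert large >= small

    def test_fixed_seed_is_bit_identical(self):
        pop = pop_from_haplotypes(((1, 0, 1), (0, 1, 0)), ((1, 1, 0), (0, 0, 1)))
        spec = make_spec([1.0, 1.0, 1.0])
        a = estimate_flas(pop, spec, 3, LookaheadParams(50, 2), np.random.default_rng(5))
        b = estimate_flas(pop, spec, 3, LookaheadParams(50, 2), np.random.default_rng(5))
        assert a == b

    def test_evaluator_matches_estimate_on_identity_order(self):
        pop = pop_from_haplotypes(((1, 0, 1), (0, 1, 0)), ((1, 1, 0), (0, 0, 1)))
        spec = make_spec([1.0, 1.0, 1.0])
        params = LookaheadParams(20, 3)
        est = estimate_flas(pop, spec, 4, params, np.random.default_rng(11))
        ev = FlasEvaluator(pop, spec, 2, 4, params, np.random.default_rng(11))
        assert ev(np.arange(2)) == est
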