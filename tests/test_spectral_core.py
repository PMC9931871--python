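"""Gamma functions, critical points, walk moments and the enumeration oracle."""

import math

import numpy as np
import pytest

from accperc import (
    AccessibilitySetup,
    AlleleGraph,
    GenotypePair,
    beta_star_complete_poly,
    beta_star_no_return,
    build_complete,
    build_complete_no_return,
    build_path,
    enumerate_walk_expectation_oracle,
    enumeration_tail_bound,
    expected_quasi_accessible,
    gamma,
    mean_gamma,
    solve_beta_star,
    threshold_c_L,
    walk_length_moments,
)
from conftest import random_reachable_digraph


def series_gamma_entry(graph, v, w, t, terms=60):
    """Independent oracle: (e^{tA})_{vw} by truncated power series, in
    extended precision so the oracle's own round-off stays below the
    tolerance being checked."""
    A = graph.adjacency.astype(np.longdouble)
    acc = np.eye(graph.n_alleles, dtype=np.longdouble)
    total = acc.copy()
    t = np.longdouble(t)
    for k in range(1, terms):
        acc = acc @ A * (t / k)
        total += acc
    return float(total[graph.index(v), graph.index(w)])


class TestGamma:
    def test_complete2_closed_form(self, k2):
        # off-diagonal entry of e^{tA} for the 2-clique is sinh(t)
        for t in (0.3, 1.0, 2.5):
            ev = gamma(k2, "0", "1", t)
            assert ev.reachable
            assert ev.value == pytest.approx(math.log(math.sinh(t)), abs=1e-12)
            assert ev.first_deriv == pytest.approx(1 / math.tanh(t), abs=1e-10)
            assert ev.second_deriv == pytest.approx(-1 / math.sinh(t) ** 2, abs=1e-10)

    def test_diagonal_without_cycle_is_zero(self):
        g = AlleleGraph(("0", "1"), np.array([[0, 1], [0, 0]]))
        for t in (0.1, 1.0, 10.0):
            ev = gamma(g, "0", "0", t)
            assert ev.reachable
            assert ev.value == 0.0 and ev.first_deriv == 0.0

    def test_unreachable_pair_flagged(self):
        g = AlleleGraph(("0", "1"), np.array([[0, 1], [0, 0]]))
        ev = gamma(g, "1", "0", 1.0)
        assert not ev.reachable and math.isnan(ev.value)

    def test_path3_against_series_oracle(self, path3):
        ev = gamma(path3, "0", "2", 1.0)
        oracle = series_gamma_entry(path3, "0", "2", 1.0, terms=30)
        assert math.exp(ev.value) == pytest.approx(oracle, abs=1e-12)

    def test_expm_series_contract_on_random_graphs(self):
        """Matrix exponential entries agree with the truncated power series
        to 1e-13 absolute on random 5x5 allele graphs."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            g = random_reachable_digraph(rng, 5)
            t = float(rng.uniform(0.1, 3.0))
            from accperc.spectral_core import gamma_matrices

            E = gamma_matrices(g, t, max_order=0)[0]
            # float64 accuracy scales with the dominant entry of e^{tA}
            tol = 1e-13 * max(1.0, float(E.max()))
            for v in g.labels:
                for w in g.labels:
                    expect = series_gamma_entry(g, v, w, t, terms=80)
                    assert E[g.index(v), g.index(w)] == pytest.approx(expect, abs=tol)

    def test_rejects_nonpositive_t(self, k2):
        with pytest.raises(ValueError):
            gamma(k2, "0", "1", 0.0)

    def test_monotone_increasing_in_t(self, path3):
        ts = np.logspace(-2, 1, 40)
        vals = [gamma(path3, "0", "2", t).value for t in ts]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(gamma(path3, "0", "2", t).first_deriv > 0 for t in ts)


class TestMeanGamma:
    @pytest.mark.parametrize("n", [2, 3, 5])
    @pytest.mark.parametrize("delta", [0.25, 0.6, 1.0])
    def test_complete_graph_closed_form(self, n, delta):
        """Divergence-weighted mean Gamma on the complete graph equals
        -ln(n) - beta + delta ln(e^{n beta} - 1)
        + (1-delta) ln(n - 1 + e^{n beta})."""
        g = build_complete(n)
        setup = AccessibilitySetup.from_delta(g, g.labels[0], g.labels[1], delta)
        for beta in (0.2, 0.7, 1.3):
            expect = (
                -math.log(n)
                - beta
                + delta * math.log(math.expm1(n * beta))
                + (1 - delta) * math.log(n - 1 + math.exp(n * beta))
            )
            assert mean_gamma(setup, beta) == pytest.approx(expect, abs=1e-10)

    def test_signs_at_extremes(self, k2_setup):
        assert mean_gamma(k2_setup, 5.0) > 0
        assert mean_gamma(k2_setup, 1e-3) < 0

    def test_single_pair_mean_equals_gamma(self, path3, path3_setup):
        assert mean_gamma(path3_setup, 0.5) == pytest.approx(
            gamma(path3, "0", "2", 0.5).value, abs=1e-14
        )

    def test_unreachable_weighted_pair_raises(self):
        g = AlleleGraph(("0", "1"), np.array([[0, 1], [0, 0]]))
        p = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="unreachable"):
            mean_gamma(AccessibilitySetup(g, p), 1.0)


class TestBetaStar:
    def test_biallelic_value(self, k2_setup):
        res = solve_beta_star(k2_setup)
        assert res.beta_star == pytest.approx(math.log(1 + math.sqrt(2)), abs=1e-12)
        assert res.gamma_prime_star == pytest.approx(math.sqrt(2), abs=1e-10)
        assert res.accessible

    def test_three_alleles(self):
        g = build_complete(3)
        res = solve_beta_star(AccessibilitySetup.from_delta(g, "0", "1", 1.0))
        assert res.beta_star == pytest.approx(math.log(2 * math.cos(math.pi / 9)), abs=1e-10)
        assert res.gamma_prime_star == pytest.approx(
            1 + 2 * math.cos(2 * math.pi / 9), abs=1e-10
        )

    def test_path3_inaccessible(self, path3_setup):
        res = solve_beta_star(path3_setup)
        assert res.beta_star == pytest.approx(
            math.log(3 + 2 * math.sqrt(2)) / math.sqrt(2), abs=1e-10
        )
        assert not res.accessible
        assert res.beta_star > 1  # value reported unclamped

    @pytest.mark.parametrize("delta", [0.25, 0.5, 1.0])
    @pytest.mark.parametrize(
        "make_setup",
        [
            lambda d: AccessibilitySetup.from_delta(build_complete(3), "0", "1", d),
            lambda d: AccessibilitySetup.from_delta(build_complete(6), "0", "1", d),
            lambda d: AccessibilitySetup.from_delta(build_path(3), "0", "1", d),
        ],
    )
    def test_root_residual(self, make_setup, delta):
        setup = make_setup(delta)
        res = solve_beta_star(setup)
        assert abs(mean_gamma(setup, res.beta_star)) <= 1e-10

    @pytest.mark.parametrize("delta", [0.1, 0.3, 0.5, 0.7, 0.9, 1.0])
    def test_biallelic_sinh_cosh_relation(self, k2, delta):
        """The biallelic root satisfies sinh(b)^delta * cosh(b)^(1-delta) = 1."""
        setup = AccessibilitySetup.from_delta(k2, "0", "1", delta)
        b = solve_beta_star(setup).beta_star
        assert math.sinh(b) ** delta * math.cosh(b) ** (1 - delta) == pytest.approx(
            1.0, abs=1e-10
        )

    @pytest.mark.parametrize("n", range(2, 11))
    def test_complete_polynomial_equivalence(self, n):
        g = build_complete(n)
        generic = solve_beta_star(
            AccessibilitySetup.from_delta(g, g.labels[0], g.labels[1], 1.0)
        ).beta_star
        assert generic == pytest.approx(beta_star_complete_poly(n), abs=1e-10)
        x = math.exp(generic)
        assert x**n - n * x - 1 == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("n", range(2, 11))
    def test_no_return_closed_form_equivalence(self, n):
        g = build_complete_no_return(n, 0)
        setup = AccessibilitySetup.homopolymer(g, g.labels[0], g.labels[1])
        res = solve_beta_star(setup)
        bs, gp = beta_star_no_return(n)
        assert res.beta_star == pytest.approx(bs, abs=1e-10)
        assert res.gamma_prime_star == pytest.approx(gp, abs=1e-10)

    def test_no_return_biallelic_limit(self):
        assert beta_star_no_return(2) == (1.0, 1.0)
        assert beta_star_no_return(3) == pytest.approx((math.log(2), 2.0))

    def test_large_alphabet_expansion(self):
        """beta* approaches ln(n)/n + (1+ln n)/n^2 with a remainder of order
        ln(n)/n^3: the scaled residual stays bounded as n grows."""
        scaled = []
        for n in (20, 50, 100, 200):
            b = beta_star_complete_poly(n)
            resid = b - math.log(n) / n - (1 + math.log(n)) / n**2
            scaled.append(abs(resid) * n**3 / math.log(n))
        assert max(scaled) < 10.0
        assert scaled[-1] < 2.0 * max(scaled[0], 1e-3)


class TestThresholdFunction:
    def test_biallelic_plugin_value(self, k2_setup):
        c = threshold_c_L(k2_setup, 100)
        expect = math.log(1 + math.sqrt(2)) - math.log(100) / (100 * math.sqrt(2))
        assert c == pytest.approx(expect, abs=1e-10)

    def test_converges_to_beta_star(self, k2_setup):
        bs = solve_beta_star(k2_setup).beta_star
        assert abs(threshold_c_L(k2_setup, 10**7) - bs) < 1e-5

    def test_increasing_in_L(self, k2_setup):
        cs = [threshold_c_L(k2_setup, L) for L in (3, 5, 10, 50, 1000)]
        assert all(b > a for a, b in zip(cs, cs[1:]))

    def test_finite_L_uses_counting_matrix(self, k2):
        pair = GenotypePair(("0",) * 4, ("1",) * 4)
        setup = AccessibilitySetup.from_pair(k2, pair)
        res = solve_beta_star(setup, use_finite_L=True)
        # zero remainder: the finite-L root equals beta*
        assert res.beta_hat == pytest.approx(res.beta_star, abs=1e-12)


class TestWalkLengthMoments:
    def test_biallelic_critical_length(self, k2_setup):
        res = solve_beta_star(k2_setup)
        mom = walk_length_moments(k2_setup, res.beta_star)
        assert mom.mu_per_locus == pytest.approx(res.walk_length_factor, abs=1e-12)
        assert mom.mu_per_locus == pytest.approx(1.25, abs=0.005)

    def test_variance_nonnegative_on_grid(self):
        setups = [
            AccessibilitySetup.from_delta(build_complete(3), "0", "1", 1.0),
            AccessibilitySetup.homopolymer(build_complete_no_return(3, 0), "0", "1"),
            AccessibilitySetup.homopolymer(build_path(4), "0", "3"),
        ]
        for setup in setups:
            for beta in np.linspace(0.05, 3.0, 100):
                assert walk_length_moments(setup, beta).sigma2_per_locus >= -1e-12


class TestEnumerationOracle:
    def test_no_walks_below_distance(self, path3):
        pair = GenotypePair(("0",), ("2",))
        assert enumerate_walk_expectation_oracle(path3, pair, 0.8, n_max=1) == 0.0

    def test_hand_enumeration_two_step(self, k2):
        # two length-2 walks 00->10->11 and 00->01->11, each weight beta/1!
        pair = GenotypePair(("0", "0"), ("1", "1"))
        for beta in (0.3, 0.9):
            assert enumerate_walk_expectation_oracle(
                k2, pair, beta, n_max=2
            ) == pytest.approx(2 * beta, abs=1e-14)

    def test_single_locus_cosh(self, k2, k2_setup):
        pair = GenotypePair(("0",), ("1",))
        val = expected_quasi_accessible(k2_setup, 1, 1.0, pair=pair)
        assert val == pytest.approx(math.cosh(1.0), abs=1e-12)

    def test_monotone_in_truncation(self, k2):
        pair = GenotypePair(("0", "0"), ("1", "1"))
        vals = [
            enumerate_walk_expectation_oracle(k2, pair, 0.7, n_max=n)
            for n in (2, 5, 10, 20, 40)
        ]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        setup = AccessibilitySetup.from_pair(k2, pair)
        closed = expected_quasi_accessible(setup, 2, 0.7)
        assert vals[-1] == pytest.approx(closed, abs=1e-10)

    def test_oracle_matches_closed_form_on_random_setups(self):
        """Closed form L*Gamma'*exp(L*Gamma) equals brute-force walk counting
        on the product graph within the truncation tail bound, on randomized
        small setups."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 12:
            n = int(rng.integers(2, 5))
            g = random_reachable_digraph(rng, n)
            L = int(rng.integers(1, 4))
            reach = g.reachable() | np.eye(n, dtype=bool)
            # per-locus endpoint pairs drawn among reachable pairs, with the
            # first locus forced off-diagonal so the endpoints differ
            pairs = []
            ok = True
            for locus in range(L):
                cand = [
                    (v, w)
                    for v in range(n)
                    for w in range(n)
                    if reach[v, w] and (locus > 0 or v != w)
                ]
                if not cand:
                    ok = False
                    break
                pairs.append(cand[int(rng.integers(len(cand)))])
            if not ok:
                continue
            pair = GenotypePair(
                tuple(g.labels[v] for v, _ in pairs),
                tuple(g.labels[w] for _, w in pairs),
            )
            beta = float(rng.uniform(0.3, 1.0))
            setup = AccessibilitySetup.from_pair(g, pair)
            closed = expected_quasi_accessible(setup, L, beta)
            oracle = enumerate_walk_expectation_oracle(g, pair, beta, n_max=40)
            bound = enumeration_tail_bound(g, L, beta, 40)
            assert abs(closed - oracle) <= bound + 1e-9 * max(1.0, abs(closed))
            checked += 1

    def test_stabilises_near_threshold_window(self, k2_setup):
        """At beta = c_L + eta/L the expected walk count approaches a finite
        constant as L grows."""
        eta = 0.5
        vals = []
        for L in (50, 200, 800, 3200):
            beta = threshold_c_L(k2_setup, L) + eta / L
            vals.append(expected_quasi_accessible(k2_setup, L, beta))
        assert np.isfinite(vals).all()
        assert abs(vals[-1] - vals[-2]) < 0.05 * abs(vals[-1])
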