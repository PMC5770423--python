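import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from cliquehop import codec
from cliquehop.core import as_state, converge, energy
from cliquehop.mpf import probability_flow
from cliquehop.symmetric import (
    SymmetricParams,
    build_network,
    exhaustive_r_stability,
    feasible_x_interval,
    large_deviation_x,
    mpf_optimal_x,
    range_bounds,
    range_constants,
    range_feasible_lp,
    restricted_clique_flow,
    stability_certificate,
    stability_matrix,
    storable_fraction,
    symmetric_converge,
    symmetric_energy,
    symmetric_sweep,
)


def all_cliques(v, k):
    return [codec.clique_state(c, v) for c in itertools.combinations(range(v), k)]


class TestBuildNetwork:
    def test_zero_params_zero_matrix(self):
        net = build_network(SymmetricParams(0.0, 0.0, 1.0, 5))
        assert np.all(net.W == 0)

    def test_overlap_cases_v4(self):
        x, y = 0.7, -0.2
        net = build_network(SymmetricParams(x, y, 1.0, 4))
        e01 = codec.edge_index(0, 1, 4)
        e02 = codec.edge_index(0, 2, 4)
        e23 = codec.edge_index(2, 3, 4)
        assert net.W[e01, e02] == x  # share vertex 0
        assert net.W[e01, e23] == y  # disjoint
        assert net.W[e01, e01] == 0.0

    def test_vertex_relabeling_invariance(self, rng):
        v = 6
        net = build_network(SymmetricParams(0.3, 0.1, 1.0, v))
        perm = rng.permutation(v)
        # conjugation by the induced edge permutation leaves W unchanged
        I, J = codec.pair_table(v)
        edge_perm = np.array(
            [
                codec.edge_index(min(perm[i], perm[j]), max(perm[i], perm[j]), v)
                for i, j in zip(I, J)
            ]
        )
        W2 = net.W[np.ix_(edge_perm, edge_perm)]
        assert np.array_equal(W2, net.W)


class TestSymmetricEnergy:
    def test_empty_graph(self):
        assert symmetric_energy(as_state([0] * 15), SymmetricParams(1.0, 2.0, 3.0, 6)) == 0.0

    def test_k4_value(self):
        params = SymmetricParams(2 / 7, 0.0, 1.0, 6, 4)
        s = codec.clique_state([0, 1, 2, 3], 6)
        assert symmetric_energy(s, params) == pytest.approx(18 / 7, abs=1e-12)

    def test_matches_dense_energy_random_graphs(self, rng):
        v = 10
        params = SymmetricParams(0.23, -0.11, 0.7, v)
        net = build_network(params)
        for _ in range(100):
            s = as_state(rng.integers(0, 2, size=codec.edge_count(v)))
            assert symmetric_energy(s, params) == pytest.approx(
                energy(s, net), abs=1e-9
            )


class TestRestrictedFlow:
    def test_frozen_value_k4(self):
        assert restricted_clique_flow(4, 2 / 7, 1.0) == pytest.approx(
            14 * math.exp(-1 / 14) + math.exp(-1 / 2), abs=1e-12
        )

    def test_zero_params_gives_neighbor_count(self):
        # x=0, z=0: every term is 1, totalling n = C(2k-2, 2)
        for k in (4, 6, 9):
            total = restricted_clique_flow(k, 0.0, 0.0)
            assert total == pytest.approx(codec.edge_count(2 * k - 2))

    def test_matches_full_flow_random_x(self, rng):
        X = all_cliques(6, 4)
        for _ in range(20):
            x = rng.uniform(0.01, 0.6)
            net = build_network(SymmetricParams(x, 0.0, 1.0, 6, 4))
            assert probability_flow(X, net).value == pytest.approx(
                restricted_clique_flow(4, x, 1.0), abs=1e-9
            )

    def test_k_too_small(self):
        with pytest.raises(ValueError):
            restricted_clique_flow(3, 0.1, 1.0)


class TestOptimalX:
    def test_printed_reference_value_k64(self):
        assert round(mpf_optimal_x(64, 1.0), 4) == 0.0107

    def test_homogeneous_in_z(self):
        assert mpf_optimal_x(10, 2.0) == 2 * mpf_optimal_x(10, 1.0)

    @pytest.mark.parametrize("k", [4, 6, 10, 24, 64])
    @pytest.mark.parametrize("z", [0.5, 1.0, 2.0])
    def test_numeric_argmin_matches(self, k, z):
        res = minimize_scalar(
            lambda x: restricted_clique_flow(k, x, z),
            bounds=(1e-6, 2.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        assert res.x == pytest.approx(mpf_optimal_x(k, z), abs=1e-8)

    def test_k24(self):
        assert mpf_optimal_x(24, 1.0) == pytest.approx(2 / 67)


class TestLargeDeviationX:
    def test_printed_reference_value_k64_quarter(self):
        assert round(large_deviation_x(64, 0.25, 1.0), 4) == 0.0091

    def test_p_zero_limit(self):
        k = 12
        assert large_deviation_x(k, 0.0, 1.0) == pytest.approx(3 / (4 * k))

    def test_two_printed_forms_agree(self):
        for k in (4, 8, 32, 64):
            for p in (0.0, 0.1, 0.25, 0.4, 0.49):
                a = large_deviation_x(k, p, 1.0)
                b = 0.5 * (1.0 / (2 * k) + 1.0 / (k * (1 + 2 * p)))
                assert a == pytest.approx(b, abs=1e-15)

    def test_inside_feasibility_window(self):
        for k in (8, 32):
            for p in (0.1, 0.3, 0.45):
                x = large_deviation_x(k, p, 1.0)
                assert 1.0 / (2 * k) < x < 1.0 / (k * (1 + 2 * p))

    def test_p_domain(self):
        with pytest.raises(ValueError):
            large_deviation_x(8, 0.5, 1.0)


class TestCertificate:
    def test_k4_r0_reduces_to_quarter_third(self):
        # rows force 1/4 < x < 1/3 when y = 0, z = 1; the flow-optimal 2/7 is in
        for x, ok in [(2 / 7, True), (0.24, False), (0.34, False)]:
            cert = stability_certificate(4, 0, SymmetricParams(x, 0.0, 1.0, 6, 4))
            assert cert.satisfied is ok

    def test_matrix_entries_k5_r1(self):
        M = stability_matrix(5, 1)
        expected = np.array(
            [
                [4 * (2 - 5) + 2, (2 - 5) * 2],
                [4 * (2 - 5), (2 - 5) * 2 - 2],
                [2 * 4 + 2, 4 * 3],
                [2 * 4, 4 * 3 - 2],
            ],
            dtype=float,
        )
        np.testing.assert_array_equal(M, expected)

    def test_homogeneity(self, rng):
        for _ in range(20):
            k = int(rng.integers(4, 12))
            r = int(rng.integers(0, min(3, k)))
            params = SymmetricParams(
                float(rng.uniform(0.01, 0.5)),
                float(rng.uniform(-0.2, 0.2)),
                1.0,
                2 * k - 2,
                k,
            )
            c = float(rng.uniform(0.1, 10))
            a = stability_certificate(k, r, params)
            b = stability_certificate(k, r, params.scaled(c))
            assert a.satisfied == b.satisfied

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            stability_matrix(3, 0)
        with pytest.raises(ValueError):
            stability_matrix(5, 5)


class TestFeasibleIntervals:
    def test_k5_r2_text_interval_empty(self):
        iv = feasible_x_interval(5, 2)
        lo, hi, nonempty = iv["text"]
        assert lo == pytest.approx(1 / 6) and hi == pytest.approx(1 / 6)
        assert not nonempty  # consistent with k > 2r+1 failing at equality

    def test_k9_r1_both_nonempty_eq7_inside_matrix(self):
        iv = feasible_x_interval(9, 1)
        lo_m, hi, ne_m = iv["matrix"]
        assert ne_m and lo_m == pytest.approx(1 / 13) and hi == pytest.approx(1 / 9)
        assert lo_m < mpf_optimal_x(9, 1.0) < hi
        assert iv["text"][2]

    def test_matrix_interval_matches_certificate(self):
        for k in (4, 6, 8, 10):
            for r in (0, 1, 2):
                lo, hi, nonempty = feasible_x_interval(k, r)["matrix"]
                if not nonempty:
                    continue
                mid = (lo + hi) / 2
                cert = stability_certificate(
                    k, r, SymmetricParams(mid, 0.0, 1.0, 2 * k - 2, k)
                )
                assert cert.satisfied


class TestExhaustiveStability:
    def test_v6_k4_r1_full_enumeration_certified_params(self):
        # k=4, r=1 requires y != 0; (0.45, -0.3, 1) satisfies the certificate
        params = SymmetricParams(0.45, -0.3, 1.0, 6, 4)
        assert stability_certificate(4, 1, params).satisfied
        chk = exhaustive_r_stability(4, 6, 1, params)
        assert chk.ok and chk.cliques_checked == 15
        assert chk.states_checked == 15 * 16  # ball of radius 1 has 1 + 15 states

    def test_x_above_upper_bound_fails_with_witness(self):
        params = SymmetricParams(0.4, 0.0, 1.0, 6, 4)  # above 1/3
        chk = exhaustive_r_stability(4, 6, 0, params)
        assert not chk.ok and chk.counterexample is not None
        verts, start = chk.counterexample
        res = converge(as_state(start), build_network(params))
        assert not np.array_equal(res.fixed_point, codec.clique_state(verts, 6))

    def test_r0_reduces_to_fixed_point_check(self):
        params = SymmetricParams(2 / 7, 0.0, 1.0, 6, 4)
        chk = exhaustive_r_stability(4, 6, 0, params)
        assert chk.ok and chk.states_checked == 15

    def test_cap_refusal(self):
        params = SymmetricParams(2 / 7, 0.0, 1.0, 6, 4)
        with pytest.raises(ValueError, match="sample_cap"):
            exhaustive_r_stability(4, 6, 1, params, sample_cap=10)

    @pytest.mark.parametrize("k,r", [(4, 1), (5, 1), (6, 2)])
    def test_certificate_agrees_with_enumeration(self, k, r):
        # probes at matrix-interval midpoint (if nonempty), inside the
        # text-only window, and above the shared upper bound
        v = 2 * k - 2
        iv = feasible_x_interval(k, r)
        lo_m, hi, ne_m = iv["matrix"]
        lo_t = iv["text"][0]
        probes = []
        if ne_m:
            probes.append((lo_m + hi) / 2)
        if lo_t < min(lo_m, hi):
            probes.append((lo_t + min(lo_m, hi)) / 2)
        probes.append(hi * 1.2)
        cliques = list(itertools.combinations(range(v), k))[:6]
        for x in probes:
            params = SymmetricParams(x, 0.0, 1.0, v, k)
            cert = stability_certificate(k, r, params)
            chk = exhaustive_r_stability(
                k, v, r, params, cliques=cliques, sample_cap=5_000_000
            )
            assert cert.satisfied == chk.ok


class TestRangeStorage:
    def test_reference_range_5_to_15_feasible(self):
        assert range_bounds(5, 15).feasible

    def test_single_size_feasible(self):
        assert range_bounds(5, 5).feasible

    def test_closed_form_matches_lp_through_transition(self):
        # scan M upward from m and compare feasibility verdicts route-by-route
        for m in (4, 5, 8):
            for M in range(m, 14 * m):
                assert range_bounds(m, M).feasible == range_feasible_lp(m, M), (m, M)

    def test_large_m_ratio_approaches_D(self):
        _, D = range_constants()
        m = 500
        M = m
        while range_bounds(m, M + 1).feasible:
            M += 1
        assert M / m == pytest.approx(D, rel=0.02)

    def test_constants_rounding(self):
        C, D = range_constants()
        assert round(D, 2) == 13.93
        assert round(C, 2) == 0.43

    def test_D_defining_identity(self):
        _, D = range_constants()
        assert D * (2 - math.sqrt(3)) - (2 + math.sqrt(3)) == pytest.approx(0, abs=1e-12)

    def test_invalid(self):
        with pytest.raises(ValueError):
            range_bounds(2, 5)


class TestStorableFraction:
    def test_limits(self):
        assert storable_fraction(100000)["normal"] == pytest.approx(1.0, abs=1e-6)

    def test_tail_bounded_by_mills_style_exponential(self):
        # the normal tail lies below exp(-C v) = exp(-t^2/2), the printed
        # approximation; ordering (not equality) is the claim
        out = storable_fraction(100)
        assert 0.0 < out["tail"] < 1.0
        assert out["gap"] >= 0.0  # tail <= exp(-C v), full precision

    def test_monotone_in_v(self):
        vals = [storable_fraction(v)["tail"] for v in range(1, 200, 10)]
        assert all(b <= a for a, b in zip(vals, vals[1:]))


class TestSparseDynamics:
    def test_sweep_matches_dense(self, rng):
        for v in (6, 10, 16):
            params = SymmetricParams(0.21, -0.05, 1.0, v)
            net = build_network(params)
            n = codec.edge_count(v)
            from cliquehop.core import sweep

            for _ in range(10):
                s = as_state(rng.integers(0, 2, size=n))
                order = rng.permutation(n)
                assert np.array_equal(
                    symmetric_sweep(s, params, order), sweep(s, net, order)
                )

    def test_converge_matches_dense(self, rng):
        v = 12
        params = SymmetricParams(0.18, 0.0, 1.0, v)
        net = build_network(params)
        n = codec.edge_count(v)
        for seed in range(5):
            s = as_state(rng.integers(0, 2, size=n))
            a = symmetric_converge(s, params, order_policy="random", seed=seed)
            b = converge(s, net, order_policy="random", seed=seed)
            assert np.array_equal(a.fixed_point, b.fixed_point)
            assert a.sweeps == b.sweeps

    def test_energy_trace_non_increasing(self, rng):
        params = SymmetricParams(0.3, -0.1, 1.0, 8)
        s = as_state(rng.integers(0, 2, size=codec.edge_count(8)))
        res = symmetric_converge(s, params)
        assert np.all(np.diff(res.energy_trace) <= 1e-12)
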