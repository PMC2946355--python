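import numpy as np
import pytest
from scipy.linalg import null_space

from semelcoal import (
    LifeHistory,
    build_two_lineage,
    build_xi,
    ces,
    ces_surface,
    tradeoff_grid,
    generate_fixture,
    generation_length,
    kron,
    mean_absorption_time,
    mohle_limit,
    period,
    stationary,
)
from semelcoal.ancestral_chain import absorption_times


def eigen_stationary(xi: np.ndarray) -> np.ndarray:
    """Independent oracle: left null vector of (xi - I)."""
    v = null_space((xi - np.eye(len(xi))).T)
    v = v[:, 0]
    return v / v.sum()


class TestSingleLineage:
    def test_structure(self, surface_lh):
        xi = build_xi(surface_lh).xi
        np.testing.assert_array_equal(xi[0], surface_lh.p)
        np.testing.assert_array_equal(xi[1:], np.eye(5)[:4])
        np.testing.assert_allclose(xi.sum(axis=1), 1.0, atol=1e-12)

    def test_single_class_is_cycle(self, single_class_lh):
        xi = build_xi(single_class_lh).xi
        # 1 -> 5 -> 4 -> 3 -> 2 -> 1
        assert xi[0, 4] == 1.0
        order = np.linalg.matrix_power(xi, 5)
        np.testing.assert_array_equal(order, np.eye(5))
        assert period(build_xi(single_class_lh)) == 5

    def test_aperiodic_when_support_coprime(self, marsh_lh):
        assert period(build_xi(marsh_lh)) == 1

    def test_stationary_closed_form_vs_eigen(self, surface_lh):
        sl = build_xi(surface_lh)
        pi = stationary(sl)
        np.testing.assert_allclose(pi, eigen_stationary(sl.xi), atol=1e-12)
        np.testing.assert_allclose(
            pi, np.array([1, 1, 1, 0.9, 0.7]) / 4.6, atol=1e-12
        )

    def test_stationary_uniform_for_cycle(self, single_class_lh):
        np.testing.assert_allclose(
            stationary(build_xi(single_class_lh)), 0.2, atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_first_entry_is_inverse_generation_length(self, seed):
        lh = generate_fixture(seed, mode="strict")
        sl = build_xi(lh)
        pi = stationary(sl)
        assert pi[0] == pytest.approx(1.0 / generation_length(lh), abs=1e-12)
        np.testing.assert_allclose(pi @ sl.xi, pi, atol=1e-12)

    def test_reducible_raises(self):
        lh = LifeHistory(
            p=np.array([0, 0, 1.0, 0, 0]),
            c=np.array([0.2, 0.2, 0.2, 0.2, 0.2]),
            N=100,
        )
        with pytest.raises(ValueError, match="stationary"):
            stationary(build_xi(lh))


class TestKron:
    def test_identity(self):
        np.testing.assert_array_equal(kron(np.eye(2), np.eye(2)), np.eye(4))

    def test_mixed_product_property(self):
        rng = np.random.default_rng(0)
        U, V, W, X = (rng.random((3, 3)) for _ in range(4))
        np.testing.assert_allclose(
            kron(U, V) @ kron(W, X), kron(U @ W, V @ X), atol=1e-12
        )

    def test_power_of_kronecker_square(self, surface_lh):
        xi = build_xi(surface_lh).xi
        lhs = np.linalg.matrix_power(kron(xi, xi), 3)
        rhs = kron(np.linalg.matrix_power(xi, 3), np.linalg.matrix_power(xi, 3))
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestTwoLineageChain:
    def test_rows_stochastic_and_absorbing(self, marsh_lh):
        ch = build_two_lineage(marsh_lh, 1000)
        np.testing.assert_allclose(ch.Pi_N.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(ch.A.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(ch.B.sum(axis=1), 0.0, atol=1e-12)
        np.testing.assert_array_equal(ch.Pi_N[-1], np.eye(26)[25])
        assert ch.states[-1] == "C"
        assert len(ch.states) == 26

    def test_fast_block_is_kronecker_square(self, marsh_lh):
        ch = build_two_lineage(marsh_lh, 1000)
        xi = build_xi(marsh_lh).xi
        np.testing.assert_array_equal(ch.A[:25, :25], kron(xi, xi))

    def test_slow_matrix_only_in_double_newborn_row(self, marsh_lh):
        ch = build_two_lineage(marsh_lh, 1000)
        nz = np.flatnonzero(np.abs(ch.B).sum(axis=1))
        assert nz.tolist() == [ch.index((1, 1))]
        assert ch.B[0, -1] == pytest.approx(marsh_lh.sum_p2_over_c())

    def test_deterministic_backward_aging(self, marsh_lh):
        ch = build_two_lineage(marsh_lh, 1000)
        row = ch.Pi_N[ch.index((3, 5))]
        assert row[ch.index((2, 4))] == 1.0
        assert row.sum() == 1.0

    def test_coalescence_entry_single_class(self, single_class_lh):
        ch = build_two_lineage(single_class_lh, 1000)  # D_5 = 200
        assert ch.Pi_N[ch.index((1, 1)), -1] == pytest.approx(1 / 200)

    def test_coalescence_entry_mixed_classes(self):
        # parent pools 160/128/512, contributions 0.1/0.2/0.7: the one-step
        # coalescence probability sums p_m^2/D_m over parental classes
        N = 12_800.0
        lh = LifeHistory(
            p=np.array([0, 0, 0.1, 0.2, 0.7]),
            c=np.array([0, 0, 160, 128, 512]) / N,
            N=N,
        )
        ch = build_two_lineage(lh)
        expected = 0.01 / 160 + 0.04 / 128 + 0.49 / 512
        assert ch.Pi_N[ch.index((1, 1)), -1] == pytest.approx(expected, rel=1e-12)
        # exhaustive enumeration over (class, parent) choices of both lineages
        brute = sum(
            lh.p[m] * lh.p[l] * (1.0 / ch.D[m] if m == l else 0.0)
            for m in range(2, 5)
            for l in range(2, 5)
        )
        assert ch.Pi_N[ch.index((1, 1)), -1] == pytest.approx(brute, rel=1e-12)

    def test_two_timescale_decomposition_error_bound(self):
        """N*(Pi_N - A) converges to B at rate O(1/N).

        The only finite-N error is the integer rounding of the parent pools,
        bounded by sum(p^2/c^2)/N in the infinity norm.
        """
        lh = LifeHistory(
            p=np.array([0, 0, 0.04, 0.25, 0.71]),
            c=np.array([0, 0, 0.0123, 0.0456, 0.1517]),
            N=1.0,
        )
        bound = float(np.sum(lh.p[2:] ** 2 / lh.c[2:] ** 2))
        for N in (1e3, 1e4, 1e5):
            ch = build_two_lineage(lh, N)
            err = np.abs(N * (ch.Pi_N - ch.A) - ch.B).sum(axis=1).max()
            assert err <= 1.1 * bound / N


class TestMohleLimit:
    def test_fast_limit_matches_matrix_power(self, marsh_lh, surface_lh, young_lh):
        for lh in (marsh_lh, surface_lh, young_lh):
            ch = build_two_lineage(lh, 1000)
            ml = mohle_limit(ch, lh)
            An = np.linalg.matrix_power(ch.A, 4096)
            np.testing.assert_allclose(An, ml.P, atol=1e-8)

    def test_periodic_case_uses_cesaro_average(self, single_class_lh):
        """With one reproductive age the fast chain cycles; the time-averaged
        single-lineage limit is uniform and P is its Kronecker square."""
        ch = build_two_lineage(single_class_lh, 1000)
        ml = mohle_limit(ch, single_class_lh)
        xi = build_xi(single_class_lh).xi
        q = period(build_xi(single_class_lh))
        cesaro = sum(np.linalg.matrix_power(xi, 4096 + m) for m in range(q)) / q
        np.testing.assert_allclose(cesaro, np.tile(ml.pi, (5, 1)), atol=1e-12)
        np.testing.assert_allclose(ml.P[:25, :25], kron(cesaro, cesaro)[:25], atol=1e-12)

    def test_generator_rows_sum_to_zero(self, marsh_lh):
        ch = build_two_lineage(marsh_lh, 1000)
        G = mohle_limit(ch, marsh_lh).G
        np.testing.assert_allclose(G.sum(axis=1), 0.0, atol=1e-10)

    def test_generator_last_column_closed_form(self, marsh_lh):
        ch = build_two_lineage(marsh_lh, 1000)
        ml = mohle_limit(ch, marsh_lh)
        g = generation_length(marsh_lh)
        expected = marsh_lh.sum_p2_over_c() / g**2
        np.testing.assert_allclose(ml.G[:25, -1], expected, atol=1e-10)
        assert ml.ces_rate == pytest.approx(expected, abs=1e-15)


class TestCES:
    def test_single_class_equals_census_size(self, single_class_lh):
        assert ces(single_class_lh) == pytest.approx(single_class_lh.N, rel=1e-12)

    def test_conservative_weights_equal_census_size(self):
        lh = LifeHistory(
            p=np.array([0, 0, 0.3, 0.4, 0.3]),
            c=np.array([0, 0, 0.1, 0.1, 0.06]),
            N=5000,
        )
        assert ces(lh) == pytest.approx(lh.N, rel=1e-12)

    def test_closed_form_vs_numeric_generator(self, marsh_lh):
        """Dual route: the closed form must equal N / (G_last_column * g^2) * g
        with G computed by the matrix product P B P."""
        ch = build_two_lineage(marsh_lh, 1000)
        ml = mohle_limit(ch, marsh_lh)
        g = generation_length(marsh_lh)
        numeric = marsh_lh.N * g / (ml.G[0, -1] * g**2)
        assert ces(marsh_lh) == pytest.approx(numeric, rel=1e-10)
        assert ces(marsh_lh) == pytest.approx(97_889.88, abs=0.5)

    def test_scale_equivariance(self, marsh_lh):
        assert ces(marsh_lh.rescaled(3 * marsh_lh.N)) == pytest.approx(
            3 * ces(marsh_lh), rel=1e-12
        )

    def test_not_symmetric_under_class_swap(self, marsh_lh):
        swapped = LifeHistory(
            p=np.array([0, 0, 0.04, 0.71, 0.25]),
            c=np.array([0, 0, 0.01, 0.15, 0.05]),
            N=marsh_lh.N,
        )
        # same (p, c) pairs, different ages: the generation length differs,
        # so the CES is not symmetric under relabeling reproductive classes
        assert ces(swapped) != pytest.approx(ces(marsh_lh), rel=1e-6)


class TestAbsorptionOracle:
    def test_mean_time_matches_ces_scaling(self, surface_lh):
        """Exact finite-N absorption analysis approaches N_e * g years with an
        O(1/N) relative error."""
        g = generation_length(surface_lh)
        errs = {}
        for N in (1e3, 1e4):
            ch = build_two_lineage(surface_lh, N)
            mean = mean_absorption_time(ch, surface_lh)
            theory = ces(surface_lh.rescaled(N)) * g
            errs[N] = abs(mean - theory) / theory
        assert errs[1e4] == pytest.approx(errs[1e3] / 10, rel=0.05)

    def test_periodic_phase_mismatch_never_coalesces(self, single_class_lh):
        ch = build_two_lineage(single_class_lh, 1000)
        t = absorption_times(ch)
        same_phase = t[[ch.index((i, i)) for i in range(1, 6)]]
        assert np.all(np.isfinite(same_phase))
        assert t[ch.index((1, 2))] == np.inf
        # from (1,1): one attempt per cycle of g years against pool D_5
        g, D5 = 5, 200
        assert t[ch.index((1, 1))] == pytest.approx(g * D5 - (g - 1), rel=1e-9)

    def test_uniform_sample_init(self, surface_lh):
        ch = build_two_lineage(surface_lh, 1000)
        m_stat = mean_absorption_time(ch, surface_lh, init="stationary")
        m_unif = mean_absorption_time(ch, surface_lh, init="uniform-sample")
        assert np.isfinite(m_unif)
        # sampling over-weights the large young classes relative to pi x pi,
        # but both stay within a generation-scale offset of N_e * g
        theory = ces(surface_lh) * generation_length(surface_lh)
        assert abs(m_unif - theory) < 100
        assert abs(m_stat - theory) < 100


class TestSurface:
    def test_ces_increases_with_late_spawner_abundance(self):
        df = ces_surface(tradeoff_grid([0.7], [0.05, 0.10]))
        ne = df.sort_values("c5")["Ne"].to_numpy()
        assert ne[1] > ne[0]

    def test_interior_optimum_in_late_contribution(self):
        p5 = np.linspace(0.0, 0.9, 91)
        df = ces_surface(tradeoff_grid(p5, [0.05]))
        best = df["Ne"].idxmax()
        assert 0 < best < len(df) - 1

    def test_single_point(self):
        df = ces_surface([(0.2, 0.7, 0.05)])
        assert len(df) == 1
        assert bool(df["feasible"].iloc[0])

    def test_infeasible_point_flagged_not_dropped(self):
        df = ces_surface([(-0.1, 1.0, 0.05), (0.2, 0.7, 0.05)])
        assert len(df) == 2
        assert not bool(df["feasible"].iloc[0])
        assert np.isnan(df["Ne"].iloc[0])
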