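import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import epiclock as ec
from epiclock.kernels import KernelPowers, build_kernel

UNIT = st.floats(0.0, 1.0, allow_nan=False)


class TestRawMatrix:
    def test_selfing_mendelian_limit(self):
        g = ec.raw_transition_matrix("selfing", 0.0, 0.0)
        # epiheterozygote segregates 1:2:1 even without epimutation
        assert np.array_equal(g, [[1, 0, 0], [0.25, 0.5, 0.25], [0, 0, 1]])

    def test_clonal_identity_limit(self):
        assert np.array_equal(ec.raw_transition_matrix("clonal", 0.0, 0.0), np.eye(3))

    def test_selfing_uu_row_hand_value(self):
        g = ec.raw_transition_matrix("selfing", 0.1, 0.2)
        assert g[0] == pytest.approx([0.81, 0.18, 0.01])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(alpha=UNIT, beta=UNIT, system=st.sampled_from(["selfing", "clonal"]))
    def test_rows_sum_to_one(self, alpha, beta, system):
        g = ec.raw_transition_matrix(system, alpha, beta)
        assert np.max(np.abs(g.sum(axis=1) - 1.0)) < 1e-12
        assert (g >= 0).all()

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ec.raw_transition_matrix("selfing", -0.1, 0.2)


class TestSelectionWeights:
    def test_neutral_boundary_all_ones(self):
        for form in ["ABneutral", "ABnull", "ABmm", "ABuu"]:
            assert np.array_equal(ec.selection_weights(form, 1.0), np.ones((3, 3)))

    def test_against_u_rows(self):
        w = ec.selection_weights("ABmm", 0.5)
        assert np.array_equal(w, np.tile([0.5, 0.75, 1.0], (3, 1)))

    def test_lethal_boundary_against_m(self):
        w = ec.selection_weights("ABuu", 0.0)
        assert np.array_equal(w, np.tile([1.0, 0.5, 0.0], (3, 1)))

    def test_w_out_of_range(self):
        with pytest.raises(ValueError):
            ec.selection_weights("ABuu", 1.5)


class TestNormalizedKernel:
    def test_neutral_kernel_unchanged(self):
        g = ec.raw_transition_matrix("selfing", 0.02, 0.07)
        gn = ec.normalized_kernel(g, np.ones((3, 3)))
        assert np.allclose(gn, g, atol=1e-15)

    def test_hand_normalization_of_heterozygote_row(self):
        # selfing m/u row (.25,.5,.25) under ABuu w=0 -> (.5,.5,0)
        row = np.tile(ec.raw_transition_matrix("selfing", 0, 0)[1], (3, 1))
        gn = ec.normalized_kernel(row, ec.selection_weights("ABuu", 0.0))
        assert gn[0] == pytest.approx([0.5, 0.5, 0.0])

    def test_zero_row_sum_rejected(self):
        g = ec.raw_transition_matrix("selfing", 0.0, 0.0)
        with pytest.raises(ValueError, match="row sum"):
            ec.normalized_kernel(g, ec.selection_weights("ABuu", 0.0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(1e-6, 0.5), beta=st.floats(1e-6, 0.5),
        w=st.floats(0.01, 1.0), form=st.sampled_from(["ABmm", "ABuu"]),
    )
    def test_rows_stochastic_after_selection(self, alpha, beta, w, form):
        g = ec.normalized_kernel(
            ec.raw_transition_matrix("selfing", alpha, beta),
            ec.selection_weights(form, w),
        )
        assert np.max(np.abs(g.sum(axis=1) - 1.0)) < 1e-12


def random_kernel(rng):
    system = rng.choice(["selfing", "clonal"])
    form = rng.choice(["ABneutral", "ABmm", "ABuu"])
    a, b = 10 ** rng.uniform(-5, -0.5, 2)
    w = 1.0 if form == "ABneutral" else rng.uniform(0.2, 1.0)
    return build_kernel(
        ec.ModelSpec(system, form), ec.EpimutationParams(a, b, w=w)
    ).g_norm


class TestKernelPower:
    def test_zero_exponent_identity(self):
        g = random_kernel(np.random.default_rng(0))
        assert np.array_equal(ec.kernel_power(g, 0.0), np.eye(3))

    def test_integer_matches_repeated_multiplication(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            g = random_kernel(rng)
            assert np.allclose(ec.kernel_power(g, 5), np.linalg.matrix_power(g, 5), atol=1e-10)

    def test_fractional_semigroup(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            g = random_kernel(rng)
            half = ec.kernel_power(g, 0.5)
            assert np.allclose(half @ half, ec.kernel_power(g, 1.0), atol=1e-8)

    def test_negative_exponent_rejected(self):
        with pytest.raises(ValueError):
            ec.kernel_power(np.eye(3), -1.0)

    def test_power_rows_sum_to_one(self):
        g = random_kernel(np.random.default_rng(3))
        p = ec.kernel_power(g, 17.5)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)


class TestFounderDistribution:
    def test_gamma_splits_methylated_mass(self):
        assert ec.founder_distribution(0.6, 0.4, 0.25).pi == pytest.approx([0.6, 0.1, 0.3])

    def test_gamma_boundaries(self):
        assert ec.founder_distribution(0.6, 0.4, 0.0).pi == pytest.approx([0.6, 0.0, 0.4])
        assert ec.founder_distribution(0.6, 0.4, 1.0).pi == pytest.approx([0.6, 0.4, 0.0])

    def test_residual_intermediate_mass_goes_to_heterozygote(self):
        pi = ec.founder_distribution(0.5, 0.3, 0.5).pi
        assert pi == pytest.approx([0.5, 0.2 + 0.15, 0.15])
        assert pi.sum() == pytest.approx(1.0)

    def test_invalid_proportions(self):
        with pytest.raises(ValueError):
            ec.founder_distribution(0.8, 0.4, 0.5)


class TestExpectedDivergence:
    def test_clonal_identity_kernel_gives_zero(self):
        spec = ec.ModelSpec("clonal", "ABneutral")
        pi = ec.FounderDistribution(np.array([0.2, 0.3, 0.5]))
        p = ec.EpimutationParams(0.0, 0.0)
        assert ec.expected_divergence(p, spec, (30, 12, 4), pi) == 0.0

    def test_selfing_segregation_enumerated_value(self):
        # founder all m/u, one generation of selfing on each branch:
        # both offspring iid (1/4, 1/2, 1/4) -> E|s_i - s_j| = 0.375
        spec = ec.ModelSpec("selfing", "ABneutral")
        pi = ec.FounderDistribution(np.array([0.0, 1.0, 0.0]))
        p = ec.EpimutationParams(0.0, 0.0)
        assert ec.expected_divergence(p, spec, (2, 2, 1), pi) == pytest.approx(0.375)

    def test_selfing_absorption_limit(self):
        # long selfing fixes each lineage in u/u or m/m with prob 1/2 -> 0.5
        spec = ec.ModelSpec("selfing", "ABneutral")
        pi = ec.FounderDistribution(np.array([0.0, 1.0, 0.0]))
        p = ec.EpimutationParams(0.0, 0.0)
        assert ec.expected_divergence(p, spec, (500, 500, 1), pi) == pytest.approx(0.5, abs=1e-9)

    def test_time_preconditions(self):
        spec = ec.ModelSpec("clonal", "ABneutral")
        pi = ec.FounderDistribution(np.array([1.0, 0.0, 0.0]))
        p = ec.EpimutationParams(0.01, 0.01)
        with pytest.raises(ValueError):
            ec.expected_divergence(p, spec, (5, 5, 0.5), pi)
        with pytest.raises(ValueError):
            ec.expected_divergence(p, spec, (2, 5, 3), pi)

    def test_monotone_in_time_for_small_neutral_clonal(self):
        spec = ec.ModelSpec("clonal", "ABneutral")
        p = ec.EpimutationParams(1e-3, 3e-3)
        pi = ec.FounderDistribution(ec.stationary_distribution(build_kernel(spec, p).g_norm))
        vals = [ec.expected_divergence(p, spec, (t, 10, 1), pi) for t in (10, 20, 40, 80)]
        assert np.all(np.diff(vals) > 0)


class TestEquilibrium:
    def test_clonal_symmetric_rates(self):
        p = ec.EpimutationParams(0.17, 0.17)
        assert ec.equilibrium_uu(ec.ModelSpec("clonal", "ABneutral"), p) == pytest.approx(0.25)

    def test_clonal_hand_value(self):
        p = ec.EpimutationParams(0.2, 0.6)
        assert ec.equilibrium_uu(ec.ModelSpec("clonal", "ABneutral"), p) == pytest.approx(0.5625)

    def test_selfing_closed_form_matches_eigenvector(self):
        rng = np.random.default_rng(5)
        spec = ec.ModelSpec("selfing", "ABneutral")
        for _ in range(20):
            a, b = 10 ** rng.uniform(-5, -0.5, 2)
            p = ec.EpimutationParams(a, b)
            numeric = ec.stationary_distribution(build_kernel(spec, p).g_norm)[0]
            assert ec.equilibrium_uu(spec, p) == pytest.approx(numeric, abs=1e-8)

    def test_undefined_without_epimutation(self):
        with pytest.raises(ValueError):
            ec.equilibrium_uu(ec.ModelSpec("clonal", "ABneutral"), ec.EpimutationParams(0, 0))

    def test_long_run_distribution_converges_to_stationary(self):
        spec = ec.ModelSpec("selfing", "ABneutral")
        p = ec.EpimutationParams(2e-3, 6e-3)
        g = build_kernel(spec, p).g_norm
        pi0 = np.array([0.1, 0.8, 0.1])
        longrun = pi0 @ ec.kernel_power(g, 1e6)
        assert longrun[0] == pytest.approx(ec.equilibrium_uu(spec, p), abs=1e-8)
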