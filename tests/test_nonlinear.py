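"""Activation library, nonlinear fixed points and Jacobian stability."""

import numpy as np
import pytest

from netstab import (
    CanonicalFamily,
    LayeredNetworkSpec,
    build_matrices,
    classify_stability,
    derivative_range,
    effective_matrix,
    fixed_point_linear,
    from_family,
    make_activation,
    nonlinear_jacobian_stability,
    solve_nonlinear_fixed_point,
)
from netstab.network import ConfigurationError
from netstab.nonlinear import ACTIVATION_NAMES

from conftest import random_layered_spec


class TestActivations:
    def test_relu_values_and_slopes(self):
        act = make_activation("relu")
        assert act(np.array([-1.0]))[0] == 0.0
        assert act.derivative(np.array([-1.0]))[0] == 0.0
        assert act(np.array([2.0]))[0] == 2.0
        assert act.derivative(np.array([2.0]))[0] == 1.0

    def test_sigmoid_at_origin(self):
        act = make_activation("sigmoid")
        assert act(np.array([0.0]))[0] == pytest.approx(0.5)
        assert act.derivative(np.array([0.0]))[0] == pytest.approx(0.25)

    def test_elu_slope_is_continuous_at_origin_for_unit_alpha(self):
        act = make_activation("elu", {"alpha": 1.0})
        eps = 1e-9
        left = act.derivative(np.array([-eps]))[0]
        right = act.derivative(np.array([eps]))[0]
        assert left == pytest.approx(1.0, abs=1e-8)
        assert right == pytest.approx(1.0, abs=1e-8)

    def test_unknown_name_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown activation"):
            make_activation("does-not-exist")

    def test_hyphen_and_space_spellings_accepted(self):
        assert make_activation("Sigmoid-Linear").name == "sigmoid_linear"
        assert make_activation("hyperbolic tangent").name == "hyperbolic_tangent"

    @pytest.mark.parametrize("name", ACTIVATION_NAMES)
    def test_slope_matches_finite_differences(self, name):
        act = make_activation(name)
        xs = np.linspace(-4.0, 4.0, 401)
        # exclude kink neighbourhoods where the slope jumps
        for kink in act.kinks:
            xs = xs[np.abs(xs - kink) > 0.02]
        h = 1e-6
        numeric = (act(xs + h) - act(xs - h)) / (2 * h)
        assert np.max(np.abs(numeric - act.derivative(xs))) < 1e-6


class TestDerivativeRange:
    def test_gaussian_extremes_round_to_catalogue_value(self):
        lo, hi = derivative_range(make_activation("gaussian"))
        assert round(hi, 2) == 0.86
        assert round(lo, 2) == -0.86
        assert hi == pytest.approx(np.sqrt(2.0) * np.exp(-0.5), abs=1e-9)

    def test_sigmoid_linear_extremes_round_to_catalogue_values(self):
        lo, hi = derivative_range(make_activation("sigmoid_linear"))
        assert round(lo, 2) == -0.1
        assert round(hi, 2) == 1.1

    def test_identity_slope_is_one(self):
        assert derivative_range(make_activation("identity")) == (1.0, 1.0)

    def test_grid_too_coarse_rejected(self):
        with pytest.raises(ConfigurationError):
            derivative_range(make_activation("sigmoid"), grid=10)


class TestNonlinearFixedPoint:
    def test_identity_reduces_to_linear_fixed_point(self):
        spec = from_family(CanonicalFamily("fig5b", {"w_i": -0.2, "w_p": -0.3}), 3)
        mats = build_matrices(spec)
        fp = solve_nonlinear_fixed_point(mats, make_activation("identity"), 1.0)
        assert fp.converged
        assert np.allclose(fp.h_star, fixed_point_linear(mats, 1.0), atol=1e-10)

    def test_relu_is_transparent_on_the_positive_orthant(self):
        spec = LayeredNetworkSpec(3, {(1, 2): 0.6, (2, 3): 0.7, (3, 1): 0.2})
        mats = build_matrices(spec)
        lin = fixed_point_linear(mats, 1.0)
        assert np.all(lin > 0)
        fp = solve_nonlinear_fixed_point(mats, make_activation("relu"), 1.0)
        assert fp.converged
        assert np.allclose(fp.h_star, lin, atol=1e-10)

    def test_relu_clamps_negatively_driven_unit(self):
        # unit 2 receives only strongly negative input, so it pins at zero
        # and the rest behaves like the reduced linear system
        spec = LayeredNetworkSpec(2, {(1, 2): -3.0, (2, 1): 0.5})
        mats = build_matrices(spec)
        fp = solve_nonlinear_fixed_point(mats, make_activation("relu"), 1.0)
        assert fp.converged
        assert fp.h_star[1] == 0.0
        assert fp.h_star[0] == pytest.approx(1.0)  # h1 = x + 0.5 * 0

    def test_nonconvergence_returns_flag_not_exception(self):
        # unstable linear system with an unbounded activation cannot settle
        spec = LayeredNetworkSpec(2, {(1, 2): 1.0, (2, 1): 2.0})
        fp = solve_nonlinear_fixed_point(
            build_matrices(spec), make_activation("identity"), 1.0, max_iter=500
        )
        assert not fp.converged


class TestJacobianStability:
    def test_identity_reproduces_linear_classification_bitwise(self):
        spec = from_family(CanonicalFamily("fig5a", {"w_i": -0.4, "w_p": -0.5}), 2)
        mats = build_matrices(spec)
        fp = solve_nonlinear_fixed_point(mats, make_activation("identity"), 1.0)
        for scheme in ("biological", "artificial"):
            nl = nonlinear_jacobian_stability(fp, mats, make_activation("identity"), scheme)
            lin = classify_stability(effective_matrix(mats, scheme), scheme=scheme)
            assert np.array_equal(nl.eigenvalues, lin.eigenvalues)
            assert nl.classification == lin.classification

    def test_relu_active_set_selects_a_submatrix(self):
        spec = LayeredNetworkSpec(
            3, {(1, 2): -2.0, (2, 3): 0.5, (1, 1): 0.3, (3, 1): 0.4}
        )
        mats = build_matrices(spec)
        fp = solve_nonlinear_fixed_point(mats, make_activation("relu"), 1.0)
        assert fp.converged
        act = make_activation("relu")
        d = act.derivative(fp.i_star)
        assert set(np.unique(d)) <= {0.0, 1.0}
        rep = nonlinear_jacobian_stability(fp, mats, act, "biological")
        m_b = effective_matrix(mats, "biological")
        active = d > 0
        sub = m_b[np.ix_(active, active)]
        expected = np.sort_complex(
            np.concatenate([np.linalg.eigvals(sub), np.zeros(np.sum(~active))])
        )
        assert np.allclose(np.sort_complex(rep.eigenvalues), expected, atol=1e-10)

    def test_bounded_slopes_shrink_nonnegative_spectra(self, rng):
        """For entrywise-nonnegative coupling and slopes in [0, 1] the scaled
        Jacobian's spectral radius cannot exceed the linear one."""
        for _ in range(60):
            spec = random_layered_spec(rng, signed=False)
            mats = build_matrices(spec)
            fp = solve_nonlinear_fixed_point(mats, make_activation("sigmoid"), 1.0)
            if not fp.converged:
                continue
            for scheme in ("biological", "artificial"):
                lin = np.max(np.abs(np.linalg.eigvals(effective_matrix(mats, scheme))))
                rep = nonlinear_jacobian_stability(fp, mats, make_activation("sigmoid"), scheme)
                assert rep.spectral_radius <= lin + 1e-10


def test_operator_norm_bound_for_contractive_slopes(rng):
    """|F'| <= 1 bounds the scaled matrix in any operator norm induced by
    row scaling: here sup-norm and spectral norm."""
    for name in ("sigmoid", "hyperbolic_tangent", "gaussian", "relu", "elu", "softplus"):
        act = make_activation(name)
        for _ in range(10):
            spec = random_layered_spec(rng)
            mats = build_matrices(spec)
            m_b = effective_matrix(mats, "biological")
            d = act.derivative(rng.normal(size=mats.n, scale=2.0))
            assert np.all(np.abs(d) <= 1.0 + 1e-12)
            scaled = d[:, None] * m_b
            assert np.linalg.norm(scaled, np.inf) <= np.linalg.norm(m_b, np.inf) + 1e-12
            assert np.linalg.norm(scaled, 2) <= np.linalg.norm(m_b, 2) + 1e-10
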