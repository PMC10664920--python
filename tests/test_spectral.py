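"""Spectral analysis: effective matrices, polynomials, closed forms."""

import numpy as np
import pytest

from netstab import (
    CanonicalFamily,
    CharPoly,
    LayeredNetworkSpec,
    build_matrices,
    char_poly,
    classify_stability,
    effective_matrix,
    from_family,
    fully_connected_eigenvalues,
    fully_connected_stability_interval,
    mixed_feedback_prediction,
    single_q_dominant_eigenvalue,
    single_q_trace_identity,
    unit_circle_condition,
)
from netstab.spectral import ApproximationWarning, _ff_inverse
from netstab.studies import threshold_on_feedback_weight, threshold_on_per_link_weight

from conftest import random_layered_spec


def _single_q_matrix(n, q, w_ff, w_fb, scheme="artificial"):
    spec = from_family(
        CanonicalFamily("single_q", {"q": q, "w_ff": w_ff, "w_fb": w_fb}), n
    )
    return effective_matrix(build_matrices(spec), scheme)


class TestEffectiveMatrix:
    def test_no_feedback_means_zero_instantaneous_update(self):
        mats = build_matrices(LayeredNetworkSpec(4, {(l, l + 1): 0.9 for l in range(1, 4)}))
        assert np.all(effective_matrix(mats, "artificial") == 0.0)

    def test_feedforward_inverse_equals_truncated_series(self, rng):
        spec = random_layered_spec(rng)
        mats = build_matrices(spec)
        n = mats.n
        series = np.zeros((n, n))
        power = np.eye(n)
        for _ in range(n):
            series += power
            power = power @ mats.m_ff
        assert np.allclose(_ff_inverse(mats.m_ff), series, atol=1e-12)
        assert np.allclose(
            effective_matrix(mats, "artificial"),
            np.linalg.solve(np.eye(n) - mats.m_ff, mats.m_fb),
            atol=1e-12,
        )

    def test_two_layer_hand_computation(self):
        beta, f = 0.7, 0.3
        mats = build_matrices(LayeredNetworkSpec(2, {(1, 2): beta, (2, 1): f}))
        m_a = effective_matrix(mats, "artificial")
        assert m_a[0, 1] == pytest.approx(f)
        assert m_a[1, 1] == pytest.approx(beta * f)
        assert m_a[0, 0] == m_a[1, 0] == 0.0


class TestCharPoly:
    def test_two_layer_closed_forms_both_schemes(self):
        a11 = a22 = 0.2
        pair = 0.3  # product of the reciprocal pair
        mats = build_matrices(
            LayeredNetworkSpec(2, {(1, 1): a11, (2, 2): a22, (1, 2): 1.0, (2, 1): pair})
        )
        bio = char_poly(effective_matrix(mats, "biological")).coefficients
        assert bio == pytest.approx([a11 * a22 - pair, -(a11 + a22), 1.0])
        art = char_poly(effective_matrix(mats, "artificial")).coefficients
        assert art == pytest.approx([a11 * a22, -(a11 + a22 + pair), 1.0])

    def test_three_layer_closed_forms_both_schemes(self, rng):
        # generic weights; coefficients from the symmetric-function combos
        a = {(i, j): float(rng.uniform(-1, 1)) for i in range(1, 4) for j in range(1, 4)}
        w = {
            (1, 2): a[(1, 2)], (2, 3): a[(2, 3)],
            (1, 1): a[(1, 1)], (2, 2): a[(2, 2)], (3, 3): a[(3, 3)],
            (2, 1): a[(2, 1)], (3, 2): a[(3, 2)], (3, 1): a[(3, 1)],
        }
        mats = build_matrices(LayeredNetworkSpec(3, w))
        k1 = a[(1, 1)] + a[(2, 2)] + a[(3, 3)]
        k2 = a[(1, 2)] * a[(2, 1)] + a[(2, 3)] * a[(3, 2)]
        k3 = a[(1, 2)] * a[(2, 3)] * a[(3, 1)]
        k4 = (
            a[(1, 1)] * a[(2, 2)] + a[(1, 1)] * a[(3, 3)] + a[(2, 2)] * a[(3, 3)]
        )
        k5 = a[(1, 1)] * a[(2, 3)] * a[(3, 2)] + a[(3, 3)] * a[(1, 2)] * a[(2, 1)]
        k6 = a[(1, 1)] * a[(2, 2)] * a[(3, 3)]
        bio = char_poly(effective_matrix(mats, "biological")).coefficients
        assert bio == pytest.approx([-(k6 + k3 - k5), k4 - k2, -k1, 1.0], abs=1e-12)
        art = char_poly(effective_matrix(mats, "artificial")).coefficients
        assert art == pytest.approx([-k6, k4 + k5, -(k1 + k2 + k3), 1.0], abs=1e-12)

    def test_zero_matrix_has_trivial_polynomial(self):
        c = char_poly(np.zeros((4, 4))).coefficients
        assert np.array_equal(c, [0, 0, 0, 0, 1])

    def test_roots_match_eigenvalues_up_to_n12(self, rng):
        for n in range(2, 13):
            m = rng.uniform(-1, 1, (n, n))
            roots = np.sort_complex(char_poly(m).roots())
            ev = np.sort_complex(np.linalg.eigvals(m))
            assert np.max(np.abs(roots - ev)) < 1e-7


class TestUnitCircleCondition:
    def test_constructed_root_on_circle(self):
        poly = CharPoly([1.0, -1.0, 1.0])  # roots e^{+-i pi/3}
        r = unit_circle_condition(poly, np.pi / 3)
        assert len(r) == 2
        assert max(abs(x) for x in r) < 1e-12
        assert abs(poly(np.exp(1j * np.pi / 3))) < 1e-12

    def test_theta_zero_alternating_sum(self):
        poly = CharPoly([-0.5, -0.5, 1.0])  # p(1) = 0 by construction
        (res,) = unit_circle_condition(poly, 0.0)
        assert res == pytest.approx(0.0)

    def test_two_layer_conditions_reduce_to_printed_form(self, rng):
        # for degree 2: residuals are (c0 - 1, c1 + 2 cos(theta))
        c0, c1 = rng.uniform(-2, 2, 2)
        theta = float(rng.uniform(0.1, np.pi - 0.1))
        r1, r2 = unit_circle_condition(CharPoly([c0, c1, 1.0]), theta)
        assert r1 == pytest.approx(c0 - 1.0)
        assert r2 == pytest.approx(c1 + 2 * np.cos(theta))

    def test_residuals_vanish_iff_circle_root(self, rng):
        """Both residuals are zero exactly when e^{i theta} is a root."""
        hits = 0
        for _ in range(2000):
            n = int(rng.integers(2, 9))
            theta = float(rng.uniform(0.05, np.pi - 0.05))
            if rng.random() < 0.5:
                other = rng.normal(size=n - 2)
                coeffs = np.real(
                    np.poly(np.concatenate([[np.exp(1j * theta), np.exp(-1j * theta)], other]))
                )[::-1]
            else:
                coeffs = rng.normal(size=n + 1)
                coeffs[-1] = 1.0
            poly = CharPoly(coeffs)
            res = unit_circle_condition(poly, theta)
            res_zero = max(abs(x) for x in res) < 1e-9
            direct_zero = abs(poly(np.exp(1j * theta))) < 1e-9
            assert res_zero == direct_zero
            hits += res_zero
        assert hits > 500  # both branches exercised


class TestClassifyStability:
    def test_zero_matrix_is_stable(self):
        rep = classify_stability(np.zeros((3, 3)))
        assert rep.classification == "stable"
        assert rep.spectral_radius == 0.0

    def test_dense_network_closed_form_spectrum(self):
        spec = from_family(CanonicalFamily("fully_connected", {"w_i": 0.0, "w_e": 0.4}), 3)
        rep = classify_stability(effective_matrix(build_matrices(spec), "biological"))
        assert rep.classification == "stable"
        assert np.allclose(np.sort(rep.eigenvalues.real), [-0.4, -0.4, 0.8], atol=1e-12)

    def test_critical_loop_gain_is_marginal(self):
        m = _single_q_matrix(5, 3, 1.0, 0.5)
        rep = classify_stability(m)
        assert rep.classification == "marginal"
        assert rep.spectral_radius == pytest.approx(1.0, abs=1e-10)


class TestSingleDistanceClosedForms:
    def test_single_loop_eigenvalue_is_the_loop_gain(self):
        val = single_q_dominant_eigenvalue(6, 5, 0.9, 0.4)
        assert val == pytest.approx(0.4 * 0.9**5)

    def test_exact_regime_matches_eigensolver(self):
        val = single_q_dominant_eigenvalue(5, 3, 0.8, 0.5)
        assert val == pytest.approx(0.512)
        ev = np.linalg.eigvals(_single_q_matrix(5, 3, 0.8, 0.5))
        assert abs(ev[np.argmax(np.abs(ev))] - val) < 1e-10

    def test_no_feedback_degenerates_to_zero(self):
        assert single_q_dominant_eigenvalue(5, 4, 1.3, 0.0) == 0.0

    def test_trace_identity_matches_eigenvalue_sum(self):
        assert single_q_trace_identity(6, 1, 1.0, 0.2) == pytest.approx(1.0)
        ev = np.linalg.eigvals(_single_q_matrix(6, 1, 1.0, 0.2))
        assert np.sum(ev).real == pytest.approx(1.0, abs=1e-10)

    def test_zero_root_multiplicity_at_least_two_q(self, rng):
        n, q = 8, 2
        ma = _single_q_matrix(n, q, float(rng.uniform(0.5, 1.2)), float(rng.uniform(0.2, 0.9)))
        mult = n - np.linalg.matrix_rank(np.linalg.matrix_power(ma, n))
        assert mult >= 2 * q

    def test_outside_exact_regime_warns(self):
        with pytest.warns(ApproximationWarning):
            single_q_dominant_eigenvalue(10, 2, 1.0, 0.1)


class TestFullyConnected:
    def test_uncoupled_limit(self):
        assert np.allclose(fully_connected_eigenvalues(5, 0.3, 0.0), 0.3)

    def test_spectrum_against_eigensolver(self):
        ev = np.sort(fully_connected_eigenvalues(3, 0.0, 0.4))
        spec = from_family(CanonicalFamily("fully_connected", {"w_i": 0.0, "w_e": 0.4}), 3)
        num = np.sort(np.linalg.eigvals(effective_matrix(build_matrices(spec), "biological")).real)
        assert np.allclose(ev, num, atol=1e-12)

    def test_stability_interval_matches_numeric_sweep(self):
        n = 11
        lo, hi = fully_connected_stability_interval(n, 0.0)
        assert hi == pytest.approx(0.1)
        for w_e, expect_stable in [(0.099, True), (0.101, False), (-0.099, True), (-0.101, False)]:
            rho = np.max(np.abs(fully_connected_eigenvalues(n, 0.0, w_e)))
            assert bool(rho < 1.0) is expect_stable


class TestMixedFeedback:
    def test_zero_long_gain_reduces_to_single_distance_interval(self):
        pred = mixed_feedback_prediction(8, 4, 6, 0.1, 0.0)
        lo, hi = pred.g1_stable_interval
        assert (lo, hi) == pytest.approx((-0.25, 0.25))

    def test_prediction_matches_eigensolver(self):
        n, q1, q2, g = 8, 4, 6, 0.1
        pred = mixed_feedback_prediction(n, q1, q2, g, g)
        w = {(l, l + 1): 1.0 for l in range(1, n)}
        for q in (q1, q2):
            for l in range(1, n - q + 1):
                w[(l + q, l)] = g
        mats = build_matrices(LayeredNetworkSpec(n, w))
        ev = np.linalg.eigvals(effective_matrix(mats, "artificial"))
        dom = ev[np.argmax(np.abs(ev))]
        assert pred.eigenvalue == pytest.approx(0.6)
        assert abs(dom - pred.eigenvalue) < 0.05

    def test_interval_edge_sits_on_the_bifurcation(self):
        n, q1, q2, g2 = 8, 4, 6, 0.1
        pred = mixed_feedback_prediction(n, q1, q2, 0.0, g2)
        g1_edge = pred.g1_stable_interval[1]
        w = {(l, l + 1): 1.0 for l in range(1, n)}
        for l in range(1, n - q1 + 1):
            w[(l + q1, l)] = g1_edge
        for l in range(1, n - q2 + 1):
            w[(l + q2, l)] = g2
        mats = build_matrices(LayeredNetworkSpec(n, w))
        rho = np.max(np.abs(np.linalg.eigvals(effective_matrix(mats, "artificial"))))
        assert rho == pytest.approx(1.0, abs=0.05)

    def test_longer_second_loop_shifts_the_window(self):
        # positive long-loop gain lowers the admissible short-loop gain edge
        base = mixed_feedback_prediction(8, 4, 6, 0.0, 0.0).g1_stable_interval
        shifted = mixed_feedback_prediction(8, 4, 6, 0.0, 0.2).g1_stable_interval
        assert shifted[1] < base[1]
        assert shifted[0] < base[0]


class TestThresholdsInLoopDistance:
    def test_exact_regime_thresholds_increase_with_distance(self):
        for n in (5, 8, 10):
            exact_qs = [q for q in range(1, n) if n / 2 - 1 < q]
            ths = [threshold_on_feedback_weight(n, q) for q in exact_qs]
            assert ths == sorted(ths)
            for q, th in zip(exact_qs, ths):
                assert th == pytest.approx(1.0 / (n - q), abs=1e-8)

    def test_per_link_thresholds_increase_with_distance(self):
        for n in (5, 8):
            ths = [threshold_on_per_link_weight(n, q) for q in range(1, n)]
            assert all(b >= a - 1e-9 for a, b in zip(ths, ths[1:]))

    def test_short_loop_gain_threshold_is_not_monotone_below_exact_regime(self):
        """Outside the exact regime the loop-gain closed form 1/(N-q) is only
        a lower bound: at N=7 the measured threshold *drops* from q=1 to q=2,
        so monotonicity in q genuinely requires the per-link parameterization."""
        t1 = threshold_on_feedback_weight(7, 1)
        t2 = threshold_on_feedback_weight(7, 2)
        assert t1 == pytest.approx(0.2929, abs=1e-3)
        assert t2 == pytest.approx(0.2324, abs=1e-3)
        assert t1 > t2
        assert t1 > 1.0 / 6 and t2 > 1.0 / 5  # both above the closed-form bound

    def test_dense_threshold_below_every_layered_threshold(self):
        for n in range(3, 11):
            dense = 1.0 / (n - 1)
            for q in range(1, n):
                assert dense < (1.0 / (n - q)) ** (1.0 / (q + 1))
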