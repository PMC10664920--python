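"""Spectral stability analysis of the layered dynamics.

Each delay scheme reduces to a linear iteration h_t = drive + M h_{t-1}
with an *effective matrix* M:

* biological (delayed feedforward):   M_B = M_FF + M_FB
* artificial (instant feedforward):   M_A = (Id - M_FF)^{-1} M_FB

The fixed point is stable iff every eigenvalue of M satisfies |lambda| < 1;
the bifurcation boundary is where an eigenvalue crosses the unit circle,
p_M(e^{i theta}) = 0.  This module computes effective matrices,
characteristic polynomials and their unit-circle (Chebyshev) root
conditions, classifies stability, evaluates the closed forms for canonical
network families, traces bifurcation boundaries over 2D weight slices, and
checks the biological/artificial equivalence for single-feedback-distance
networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import eval_chebyu

from netstab.network import (
    CanonicalFamily,
    ConnectivityMatrices,
    ConfigurationError,
    LayeredNetworkSpec,
    SCHEMES,
    build_matrices,
    from_family,
)

DEFAULT_MARGINAL_TOL = 1e-8


class ApproximationWarning(UserWarning):
    """A closed form was evaluated outside the regime where it is exact."""


@dataclass(frozen=True)
class StabilityReport:
    """Eigenvalues of an effective matrix and the resulting verdict.

    ``classification`` is ``stable`` when the spectral radius is below
    1 - marginal_tol, ``unstable`` above 1 + marginal_tol, and ``marginal``
    inside the band (genuine bifurcation-boundary points, where simulation
    verdicts are unreliable).
    """

    eigenvalues: np.ndarray
    spectral_radius: float
    classification: str
    dominant_eigenvalue: complex
    scheme: str | None = None
    marginal_tol: float = DEFAULT_MARGINAL_TOL

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=complex)
        ev.setflags(write=False)
        object.__setattr__(self, "eigenvalues", ev)


@dataclass(frozen=True)
class CharPoly:
    """Monic characteristic polynomial det(lambda Id - M).

    ``coefficients`` are ascending: c_0 + c_1 lambda + ... + c_N lambda^N
    with c_N = 1.
    """

    coefficients: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.ndim != 1 or len(c) < 2:
            raise ConfigurationError("coefficients must be a 1D array of length >= 2")
        if abs(c[-1] - 1.0) > 1e-12:
            raise ConfigurationError("characteristic polynomial must be monic")
        c.setflags(write=False)
        object.__setattr__(self, "coefficients", c)

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, lam: complex | np.ndarray) -> complex | np.ndarray:
        return np.polyval(self.coefficients[::-1], lam)

    def roots(self) -> np.ndarray:
        return np.roots(self.coefficients[::-1])


class MixedFeedbackPrediction(NamedTuple):
    eigenvalue: float
    g1_stable_interval: tuple[float, float]
    exact_regime: bool


@dataclass(frozen=True)
class BoundarySlice:
    """Stability classification of a 2D weight slice, per delay scheme.

    ``classification[scheme]`` and ``spectral_radius[scheme]`` are arrays of
    shape (len(axis1_values), len(axis2_values)); ``boundary_points[scheme]``
    is an (k, 2) array of refined (param1, param2) bifurcation points, each
    lying on a grid edge between a stable and an unstable cell.
    """

    family: str
    axis_names: tuple[str, str]
    axis1_values: np.ndarray
    axis2_values: np.ndarray
    classification: dict[str, np.ndarray]
    spectral_radius: dict[str, np.ndarray]
    boundary_points: dict[str, np.ndarray]


@dataclass(frozen=True)
class EquivalenceReport:
    """Outcome of the biological/artificial spectrum-correspondence check.

    For a network whose feedback sits at a single distance q the two
    characteristic polynomials are related by p_A = lambda^{k1} g(lambda),
    p_B = lambda^{k2} g(lambda^{k3}); every nonzero root z of p_B then
    satisfies z^{k3} in roots(p_A), so the bifurcation boundaries of the two
    delay schemes coincide.  ``k3`` is discovered by search over 1..N (the
    expected value is q + 1, the temporal-contraction factor).
    """

    is_single_distance: bool
    k3: int
    nonzero_root_match: bool
    max_root_mismatch: float
    q: int | None = None


# --- effective matrices and polynomials ------------------------------------

def _ff_inverse(m_ff: np.ndarray) -> np.ndarray:
    """(Id - M_FF)^{-1}; exists always since Id - M_FF is unit lower triangular.

    Because M_FF is strictly subdiagonal (nilpotent), the inverse equals the
    finite series Id + M_FF + ... + M_FF^{N-1}.
    """
    n = m_ff.shape[0]
    return solve_triangular(np.eye(n) - m_ff, np.eye(n), lower=True)


def effective_matrix(mats: ConnectivityMatrices, scheme: str) -> np.ndarray:
    """One-step update matrix M_B (biological) or M_A (artificial)."""
    if scheme == "biological":
        return mats.m_ff + mats.m_fb
    if scheme == "artificial":
        return _ff_inverse(mats.m_ff) @ mats.m_fb
    raise ConfigurationError(f"scheme must be one of {SCHEMES}, got {scheme!r}")


def char_poly(m: np.ndarray) -> CharPoly:
    """Monic characteristic polynomial of a real square matrix."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConfigurationError("char_poly expects a square matrix")
    # np.poly builds the monic polynomial from the eigenvalues; for a real
    # matrix the complex parts cancel in conjugate pairs
    desc = np.atleast_1d(np.poly(m))
    return CharPoly(coefficients=np.real(desc[::-1]))


def unit_circle_condition(poly: CharPoly, theta: float) -> tuple[float, ...]:
    """Residuals of the unit-circle root conditions at lambda = e^{i theta}.

    For theta not in {0, pi} the two residuals (built from Chebyshev
    polynomials of the second kind U_n evaluated at z = cos theta)

        r1 = c_0 - sum_{n=0}^{N-2} c_{n+2} U_n(z)
        r2 = sum_{n=0}^{N-1} c_{n+1} U_n(z)

    both vanish iff e^{i theta} is a root of the polynomial.  At theta = m pi
    (m = 0, 1) a single alternating-sum residual sum_n c_n (-1)^{mn} is
    returned instead.
    """
    c = poly.coefficients
    n_deg = poly.degree
    th = float(theta) % (2 * np.pi)
    if abs(th) < 1e-12 or abs(th - 2 * np.pi) < 1e-12:
        return (float(np.sum(c)),)
    if abs(th - np.pi) < 1e-12:
        signs = (-1.0) ** np.arange(n_deg + 1)
        return (float(np.sum(c * signs)),)
    z = np.cos(th)
    ns = np.arange(n_deg - 1)
    r1 = c[0] - float(np.sum(c[2:] * eval_chebyu(ns, z)))
    ns = np.arange(n_deg)
    r2 = float(np.sum(c[1:] * eval_chebyu(ns, z)))
    return (r1, r2)


def classify_stability(
    m: np.ndarray,
    marginal_tol: float = DEFAULT_MARGINAL_TOL,
    scheme: str | None = None,
) -> StabilityReport:
    """Classify a linear iteration by the spectrum of its update matrix."""
    if marginal_tol <= 0:
        raise ConfigurationError("marginal_tol must be positive")
    ev = np.linalg.eigvals(np.asarray(m, dtype=float))
    mags = np.abs(ev)
    rho = float(np.max(mags)) if len(mags) else 0.0
    # deterministic dominant eigenvalue: max modulus, ties broken by real
    # then imaginary part
    near = np.flatnonzero(mags >= rho - 1e-12)
    order = near[np.lexsort((ev[near].imag, ev[near].real))]
    dominant = complex(ev[order[-1]]) if len(order) else 0j
    if rho < 1.0 - marginal_tol:
        verdict = "stable"
    elif rho > 1.0 + marginal_tol:
        verdict = "unstable"
    else:
        verdict = "marginal"
    return StabilityReport(
        eigenvalues=ev,
        spectral_radius=rho,
        classification=verdict,
        dominant_eigenvalue=dominant,
        scheme=scheme,
        marginal_tol=marginal_tol,
    )


# --- closed forms for canonical families ------------------------------------

def loop_gain(q: int, w_ff: float, w_fb: float) -> float:
    """Effective gain g_q = w_fb * w_ff^q of one feedback loop of distance q.

    One trip around the loop multiplies the signal by the feedback weight
    once and by the feedforward weight q times.
    """
    return float(w_fb) * float(w_ff) ** int(q)


def single_q_dominant_eigenvalue(
    n_layers: int, q: int, w_ff: float, w_fb: float
) -> complex:
    """Dominant eigenvalue g_q (N - q) of a single-distance-q network.

    A network with a uniform feedforward chain and feedback of a single
    distance q contains N - q loops of gain g_q = w_fb * w_ff^q; in the
    regime N/2 - 1 < q <= N - 1 the nonzero spectrum collapses to the single
    eigenvalue g_q (N - q), exactly.  Outside that regime the same number is
    only the trace of the nonzero block (see
    :func:`single_q_trace_identity`) and a warning is issued.
    """
    if not 0 <= q <= n_layers - 1:
        raise ConfigurationError(f"q must be in 0..{n_layers - 1}, got {q}")
    value = loop_gain(q, w_ff, w_fb) * (n_layers - q)
    if not (n_layers / 2 - 1 < q):
        warnings.warn(
            f"q={q} is outside the exact regime N/2-1 < q for N={n_layers}; "
            "returning the trace prediction",
            ApproximationWarning,
            stacklevel=2,
        )
    return complex(value)


def single_q_trace_identity(n_layers: int, q: int, w_ff: float, w_fb: float) -> float:
    """Sum of the nonzero eigenvalues of a single-distance-q network.

    For q <= N/2 - 1 the characteristic polynomial of the artificial
    effective matrix factors as lambda^{2q} g(lambda) and the N - 2q roots
    of g sum to the trace g_q (N - q).
    """
    if not 0 <= q <= n_layers - 1:
        raise ConfigurationError(f"q must be in 0..{n_layers - 1}, got {q}")
    return loop_gain(q, w_ff, w_fb) * (n_layers - q)


def fully_connected_eigenvalues(n_layers: int, w_i: float, w_e: float) -> np.ndarray:
    """Spectrum of the dense coupling matrix: w_i on the diagonal, w_e elsewhere.

    The eigenvalues are w_i - w_e with multiplicity N - 1 (anti-phase modes)
    and w_i + (N - 1) w_e with multiplicity 1 (the uniform mode).
    """
    if n_layers < 2:
        raise ConfigurationError("fully connected spectrum requires N >= 2")
    return np.array([w_i - w_e] * (n_layers - 1) + [w_i + (n_layers - 1) * w_e])


def fully_connected_stability_interval(n_layers: int, w_i: float) -> tuple[float, float]:
    """Interval of coupling weights w_e with all eigenvalues inside the unit circle.

    Stability requires -(1 + w_i)/(N - 1) < w_e < min(w_i + 1, (1 - w_i)/(N - 1)).
    """
    lo = -(1.0 + w_i) / (n_layers - 1)
    hi = min(w_i + 1.0, (1.0 - w_i) / (n_layers - 1))
    return (lo, hi)


def mixed_feedback_prediction(
    n_layers: int, q1: int, q2: int, g1: float, g2: float
) -> MixedFeedbackPrediction:
    """Dominant-eigenvalue prediction for feedback at two distances q1 < q2.

    In the regime N/2 - 1 < q1 < q2 <= N - 1 the relevant eigenvalue is
    approximately g1 (N - q1) + g2 (N - q2), and the stability interval for
    the short-loop gain g1 is

        -1/(N - q1) - g2 (N - q2)/(N - q1) <= g1
                    <= 1/(N - q1) - g2 (N - q2)/(N - q1)

    so a longer loop with positive gain shifts the admissible short-loop
    gain window: adding long-distance feedback can stabilize the dynamics.
    """
    if not 0 <= q1 < q2 <= n_layers - 1:
        raise ConfigurationError(
            f"need 0 <= q1 < q2 <= N-1, got q1={q1}, q2={q2}, N={n_layers}"
        )
    exact = n_layers / 2 - 1 < q1
    if not exact:
        warnings.warn(
            f"q1={q1} outside the asymptotic regime N/2-1 < q1 for N={n_layers}; "
            "prediction is approximate",
            ApproximationWarning,
            stacklevel=2,
        )
    n1, n2 = n_layers - q1, n_layers - q2
    eig = g1 * n1 + g2 * n2
    shift = g2 * n2 / n1
    return MixedFeedbackPrediction(
        eigenvalue=float(eig),
        g1_stable_interval=(-1.0 / n1 - shift, 1.0 / n1 - shift),
        exact_regime=exact,
    )


# --- boundary tracing -------------------------------------------------------

_SLICE_AXES = {
    "fig5a": ("w_i", "w_p"),
    "fig5b": ("w_i", "w_p"),
    "fig5c": ("w_short", "w_long"),
}
_SLICE_LAYERS = {"fig5a": 2, "fig5b": 3, "fig5c": 5}


def bisect_crossing(
    f: Callable[[float], float],
    lo: float,
    hi: float,
    tol: float = 1e-6,
    max_iter: int = 30,
) -> float:
    """Bisection for a sign change of f on [lo, hi]; returns the crossing point."""
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if np.sign(flo) == np.sign(fhi):
        raise ConfigurationError("bisect_crossing requires a sign change on [lo, hi]")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fmid = f(mid)
        if abs(fmid) < tol:
            return mid
        if np.sign(fmid) == np.sign(flo):
            lo, flo = mid, fmid
        else:
            hi, fhi = mid, fmid
    return 0.5 * (lo + hi)


def slice_spectral_radius(
    family: CanonicalFamily,
    axis_names: tuple[str, str],
    p1: float,
    p2: float,
    scheme: str,
    n_layers: int | None = None,
) -> float:
    """Spectral radius of the effective matrix at one point of a 2D slice."""
    n = n_layers if n_layers is not None else _SLICE_LAYERS[family.family]
    params = dict(family.parameters)
    params[axis_names[0]] = p1
    params[axis_names[1]] = p2
    spec = from_family(CanonicalFamily(family.family, params), n_layers=n)
    m = effective_matrix(build_matrices(spec), scheme)
    ev = np.linalg.eigvals(m)
    return float(np.max(np.abs(ev))) if len(ev) else 0.0


def trace_boundary(
    slice_family: CanonicalFamily,
    grid: int | tuple[int, int],
    ranges: tuple[tuple[float, float], tuple[float, float]],
    axis_names: tuple[str, str] | None = None,
    n_layers: int | None = None,
    marginal_tol: float = DEFAULT_MARGINAL_TOL,
    refine_tol: float = 1e-6,
    schemes: tuple[str, ...] = SCHEMES,
) -> BoundarySlice:
    """Classify a 2D weight slice on a grid and refine its bifurcation boundary.

    Every grid point is classified for each delay scheme from the spectral
    radius of its effective matrix.  Wherever the classification flips
    between horizontally or vertically adjacent cells, the crossing of
    spectral radius = 1 is refined by bisection along the connecting segment
    (the spectral radius varies continuously along these slices).
    """
    if axis_names is None:
        if slice_family.family not in _SLICE_AXES:
            raise ConfigurationError(
                f"axis_names must be given for family {slice_family.family!r}"
            )
        axis_names = _SLICE_AXES[slice_family.family]
    if n_layers is None:
        if slice_family.family not in _SLICE_LAYERS:
            raise ConfigurationError(
                f"n_layers must be given for family {slice_family.family!r}"
            )
        n_layers = _SLICE_LAYERS[slice_family.family]
    g1, g2 = (grid, grid) if isinstance(grid, int) else grid
    (lo1, hi1), (lo2, hi2) = ranges
    if not (hi1 > lo1 and hi2 > lo2) or g1 < 2 or g2 < 2:
        raise ConfigurationError("each axis needs a nonzero-width range and >= 2 points")
    ax1 = np.linspace(lo1, hi1, g1)
    ax2 = np.linspace(lo2, hi2, g2)

    # batched eigendecomposition over the whole grid, one call per scheme
    n = n_layers
    mats_b = np.empty((g1, g2, n, n))
    mats_a = np.empty((g1, g2, n, n))
    for i, p1 in enumerate(ax1):
        for j, p2 in enumerate(ax2):
            params = dict(slice_family.parameters)
            params[axis_names[0]] = p1
            params[axis_names[1]] = p2
            cm = build_matrices(
                from_family(CanonicalFamily(slice_family.family, params), n_layers=n)
            )
            mats_b[i, j] = cm.m_ff + cm.m_fb
            mats_a[i, j] = _ff_inverse(cm.m_ff) @ cm.m_fb
    per_scheme = {"biological": mats_b, "artificial": mats_a}

    classification: dict[str, np.ndarray] = {}
    radius: dict[str, np.ndarray] = {}
    boundary: dict[str, np.ndarray] = {}
    for scheme in schemes:
        rho = np.abs(np.linalg.eigvals(per_scheme[scheme])).max(axis=-1)
        cls = np.full(rho.shape, "marginal", dtype=object)
        cls[rho < 1.0 - marginal_tol] = "stable"
        cls[rho > 1.0 + marginal_tol] = "unstable"
        radius[scheme] = rho
        classification[scheme] = cls

        pts: list[tuple[float, float]] = []
        flips: list[tuple[float, float, float, float]] = []
        sign = np.where(rho >= 1.0, 1.0, -1.0)
        flip_h = sign[:, :-1] * sign[:, 1:] < 0
        for i, j in zip(*np.nonzero(flip_h)):
            flips.append((ax1[i], ax2[j], ax1[i], ax2[j + 1]))
        flip_v = sign[:-1, :] * sign[1:, :] < 0
        for i, j in zip(*np.nonzero(flip_v)):
            flips.append((ax1[i], ax2[j], ax1[i + 1], ax2[j]))
        for p1a, p2a, p1b, p2b in flips:
            def f(t: float) -> float:
                return (
                    slice_spectral_radius(
                        slice_family,
                        axis_names,
                        p1a + t * (p1b - p1a),
                        p2a + t * (p2b - p2a),
                        scheme,
                        n_layers=n,
                    )
                    - 1.0
                )
            t = bisect_crossing(f, 0.0, 1.0, tol=refine_tol)
            pts.append((p1a + t * (p1b - p1a), p2a + t * (p2b - p2a)))
        boundary[scheme] = np.array(pts).reshape(-1, 2)

    return BoundarySlice(
        family=slice_family.family,
        axis_names=tuple(axis_names),
        axis1_values=ax1,
        axis2_values=ax2,
        classification=classification,
        spectral_radius=radius,
        boundary_points=boundary,
    )


# --- biological/artificial equivalence --------------------------------------

def verify_equivalence(
    spec: LayeredNetworkSpec,
    tol: float = 1e-8,
    zero_cutoff: float = 1e-6,
) -> EquivalenceReport:
    """Check the spectrum correspondence between the two delay schemes.

    Roots are taken as the eigenvalues of M_B and M_A; roots of magnitude
    below ``zero_cutoff`` count as the zero root.  The contraction exponent
    k3 is searched over 1..N, taking the value with the smallest mismatch
    max_z min_w |z^{k3} - w| over nonzero roots z of p_B and w of p_A.
    """
    distances = spec.feedback_distances
    single = len(distances) <= 1
    q = next(iter(distances)) if len(distances) == 1 else None
    mats = build_matrices(spec)
    roots_b = np.linalg.eigvals(effective_matrix(mats, "biological"))
    roots_a = np.linalg.eigvals(effective_matrix(mats, "artificial"))
    nz_a = roots_a[np.abs(roots_a) > zero_cutoff]
    if len(nz_a) == 0:
        # both spectra are (numerically) all-zero: trivially equivalent
        trivial = np.all(np.abs(roots_b) <= zero_cutoff)
        return EquivalenceReport(
            is_single_distance=single,
            k3=1,
            nonzero_root_match=bool(trivial),
            max_root_mismatch=0.0 if trivial else float("inf"),
            q=q,
        )
    best_k, best_mismatch = 1, float("inf")
    for k in range(1, spec.n_layers + 1):
        # a root z of p_B maps onto the zero root of p_A when |z|^k is
        # negligible, so classify zero roots per candidate exponent
        powered = roots_b ** k
        powered = powered[np.abs(powered) > zero_cutoff]
        if len(powered) == 0:
            continue
        mismatch = float(
            np.max(np.min(np.abs(powered[:, None] - nz_a[None, :]), axis=1))
        )
        if mismatch < best_mismatch - 1e-15:
            best_k, best_mismatch = k, mismatch
    return EquivalenceReport(
        is_single_distance=single,
        k3=best_k,
        nonzero_root_match=best_mismatch < tol,
        max_root_mismatch=best_mismatch,
        q=q,
    )
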