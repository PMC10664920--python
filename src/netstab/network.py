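"""Construction and random generation of layered-network specifications.

Layers are numbered 1..N (matrices are stored 0-based, so the weight of the
connection j -> i sits at matrix entry [i-1, j-1]).  A weight alpha_{j->i}
is *feedforward* when j = i-1 and *feedback* when i <= j; the feedback
distance is q = j - i, with q = 0 a self-loop.  The feedforward matrix M_FF
is therefore strictly subdiagonal and the feedback matrix M_FB is upper
triangular (diagonal included).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

SCHEMES = ("biological", "artificial")

FAMILIES = (
    "single_q",
    "fully_connected",
    "fig5a",
    "fig5b",
    "fig5c",
    "chain_time_decay",
)


class StructureError(ValueError):
    """A weight was placed on a (source, target) pair the layered structure forbids."""


class ConfigurationError(ValueError):
    """A family or run configuration is incomplete or inconsistent."""


class DegenerateNetworkWarning(UserWarning):
    """The generated network has no connections at all."""


def _check_weight_key(key: object) -> tuple[int, int]:
    if (
        not isinstance(key, tuple)
        or len(key) != 2
        or not all(isinstance(k, (int, np.integer)) for k in key)
    ):
        raise StructureError(f"weight key must be an integer pair (source, target), got {key!r}")
    return int(key[0]), int(key[1])


@dataclass(frozen=True)
class LayeredNetworkSpec:
    """Declarative description of a layered recurrent network.

    Parameters
    ----------
    n_layers
        Number of layers N (one unit per layer unless ``units_per_layer`` > 1).
    weights
        Sparse map ``(source j, target i) -> alpha_{j->i}`` with 1-based layer
        indices.  For a layered network only feedforward pairs (j = i-1) and
        feedback pairs (i <= j) are allowed.
    delay_scheme
        ``"biological"`` (feedforward delayed by one step) or ``"artificial"``
        (instantaneous feedforward within a time step).  Feedback is always
        delayed by one step.
    input_amplitude
        Constant external input x driving layer 1.
    units_per_layer
        When > 1 each scalar weight expands to a uniform block; see
        :func:`expand_units`.
    layered
        ``False`` marks a spec (such as a fully connected network) that
        deliberately bypasses the layered structural constraint.
    """

    n_layers: int
    weights: Mapping[tuple[int, int], float] = field(default_factory=dict)
    delay_scheme: str = "biological"
    input_amplitude: float = 1.0
    units_per_layer: int = 1
    layered: bool = True

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise StructureError(f"n_layers must be positive, got {self.n_layers}")
        if self.delay_scheme not in SCHEMES:
            raise ConfigurationError(
                f"delay_scheme must be one of {SCHEMES}, got {self.delay_scheme!r}"
            )
        if self.units_per_layer < 1:
            raise StructureError(f"units_per_layer must be >= 1, got {self.units_per_layer}")
        clean: dict[tuple[int, int], float] = {}
        for key, value in dict(self.weights).items():
            j, i = _check_weight_key(key)
            if not (1 <= j <= self.n_layers and 1 <= i <= self.n_layers):
                raise StructureError(
                    f"connection {j}->{i} outside layer range 1..{self.n_layers}"
                )
            if self.layered and not (j == i - 1 or i <= j):
                raise StructureError(
                    f"connection {j}->{i} is neither feedforward (j = i-1) "
                    f"nor feedback (target <= source)"
                )
            clean[(j, i)] = float(value)
        object.__setattr__(self, "weights", clean)

    @property
    def feedback_distances(self) -> set[int]:
        """Distances q = j - i of all nonzero feedback connections."""
        return {
            j - i for (j, i), a in self.weights.items() if i <= j and a != 0.0
        }

    def has_feedforward(self) -> bool:
        return any(j == i - 1 and a != 0.0 for (j, i), a in self.weights.items())


@dataclass(frozen=True)
class ConnectivityMatrices:
    """Feedforward / feedback matrix pair (M_FF, M_FB).

    ``m_ff`` is strictly subdiagonal ((M_FF)_{ij} = alpha_{j->i} delta_{j,i-1})
    and ``m_fb`` upper triangular including the diagonal
    ((M_FB)_{ij} = alpha_{j->i} Theta(i <= j)); Id - M_FF is then unit lower
    triangular and always invertible.  A spec flagged non-layered may place
    entries of ``m_fb`` below the subdiagonal as well.
    """

    m_ff: np.ndarray
    m_fb: np.ndarray
    layered: bool = True
    units: int = 1

    def __post_init__(self) -> None:
        m_ff = np.asarray(self.m_ff, dtype=float)
        m_fb = np.asarray(self.m_fb, dtype=float)
        if m_ff.shape != m_fb.shape or m_ff.ndim != 2 or m_ff.shape[0] != m_ff.shape[1]:
            raise StructureError("m_ff and m_fb must be square matrices of equal shape")
        n = m_ff.shape[0]
        if self.units < 1 or n % self.units != 0:
            raise StructureError("matrix size must be a multiple of units")
        # structural masks at layer resolution, expanded to unit blocks
        n_layers = n // self.units
        sub = np.zeros((n_layers, n_layers), dtype=bool)
        idx = np.arange(n_layers - 1)
        sub[idx + 1, idx] = True
        block = np.ones((self.units, self.units), dtype=bool)
        sub = np.kron(sub, block)
        upper = np.kron(
            np.triu(np.ones((n_layers, n_layers), dtype=bool)), block
        )
        if np.any(m_ff[~sub] != 0.0):
            raise StructureError("m_ff may only have entries on the first block subdiagonal")
        if self.layered and np.any(m_fb[~upper] != 0.0):
            raise StructureError("m_fb of a layered network must be block upper triangular")
        m_ff.setflags(write=False)
        m_fb.setflags(write=False)
        object.__setattr__(self, "m_ff", m_ff)
        object.__setattr__(self, "m_fb", m_fb)

    @property
    def n(self) -> int:
        return self.m_ff.shape[0]

    @property
    def n_layers(self) -> int:
        return self.m_ff.shape[0] // self.units


@dataclass(frozen=True)
class CanonicalFamily:
    """A named structural family plus its defining parameters.

    Families
    --------
    ``single_q``
        Feedforward chain of weight ``w_ff`` with feedback of a single
        distance ``q`` and weight ``w_fb``.
    ``fully_connected``
        Dense coupling: self-weight ``w_i`` on the diagonal, ``w_e``
        everywhere else (non-layered).
    ``fig5a``
        N = 2 slice: self-loops ``w_i`` and reciprocal-pair product ``w_p``.
    ``fig5b``
        N = 3 slice: self-loops ``w_i``, both distance-1 pair products
        ``w_p``, zero long feedback.
    ``fig5c``
        N = 5 slice: distance-1 pair products ``w_short`` among layers 2..5
        and the long-loop product ``w_long`` = alpha_23 alpha_34 alpha_45
        alpha_52.
    ``chain_time_decay``
        Feedforward chain with leaky self-feedback tau_l per layer (the
        scalar reduction of a time-decay recurrence
        h_{l,t} = tau_l h_{l,t-1} + I_{l,t}).
    """

    family: str
    parameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        object.__setattr__(self, "parameters", dict(self.parameters))

    def require(self, *names: str) -> list[object]:
        missing = [n for n in names if n not in self.parameters]
        if missing:
            raise ConfigurationError(
                f"family {self.family!r} is missing parameters {missing}"
            )
        return [self.parameters[n] for n in names]


def build_matrices(spec: LayeredNetworkSpec) -> ConnectivityMatrices:
    """Populate (M_FF, M_FB) from a spec; unspecified entries are zero.

    The weight alpha_{j->i} goes to M_FF when j = i-1 and to M_FB when
    i <= j.  For a non-layered spec any remaining pair (j < i-1) is kept in
    M_FB so that M_FF + M_FB still reproduces the full coupling matrix.
    """
    n = spec.n_layers
    m_ff = np.zeros((n, n))
    m_fb = np.zeros((n, n))
    for (j, i), a in spec.weights.items():
        if j == i - 1:
            m_ff[i - 1, j - 1] = a
        elif i <= j:
            m_fb[i - 1, j - 1] = a
        elif spec.layered:  # pragma: no cover - rejected by the spec already
            raise StructureError(f"connection {j}->{i} violates the layered structure")
        else:
            m_fb[i - 1, j - 1] = a
    return ConnectivityMatrices(m_ff=m_ff, m_fb=m_fb, layered=spec.layered)


def _chain_weights(n: int, w_ff: float) -> dict[tuple[int, int], float]:
    return {(l, l + 1): float(w_ff) for l in range(1, n)}


def from_family(
    family: CanonicalFamily,
    n_layers: int,
    delay_scheme: str = "biological",
    input_amplitude: float = 1.0,
) -> LayeredNetworkSpec:
    """Instantiate a canonical family as a concrete network spec.

    The slice families are parameterized by loop-gain *products*; individual
    weights are fixed by setting every feedforward weight to 1 and carrying
    the whole product on the feedback weight.  Redistributing weight within
    a loop while keeping the product fixed is a diagonal similarity, so this
    choice is spectrum-neutral.
    """
    name = family.family
    w: dict[tuple[int, int], float] = {}
    layered = True

    if name == "single_q":
        q, w_ff, w_fb = family.require("q", "w_ff", "w_fb")
        q = int(q)
        if not 0 <= q <= n_layers - 1:
            raise ConfigurationError(
                f"single_q requires 0 <= q <= N-1, got q={q} with N={n_layers}"
            )
        w.update(_chain_weights(n_layers, w_ff))
        for l in range(1, n_layers - q + 1):
            w[(l + q, l)] = float(w_fb)
    elif name == "fully_connected":
        w_i, w_e = family.require("w_i", "w_e")
        layered = False
        for i in range(1, n_layers + 1):
            for j in range(1, n_layers + 1):
                w[(j, i)] = float(w_i) if i == j else float(w_e)
    elif name == "fig5a":
        if n_layers != 2:
            raise ConfigurationError("fig5a requires N=2")
        w_i, w_p = family.require("w_i", "w_p")
        w[(1, 2)] = 1.0
        w[(2, 1)] = float(w_p)
        w[(1, 1)] = w[(2, 2)] = float(w_i)
    elif name == "fig5b":
        if n_layers != 3:
            raise ConfigurationError("fig5b requires N=3")
        w_i, w_p = family.require("w_i", "w_p")
        w.update(_chain_weights(3, 1.0))
        w[(2, 1)] = w[(3, 2)] = float(w_p)
        w[(1, 1)] = w[(2, 2)] = w[(3, 3)] = float(w_i)
    elif name == "fig5c":
        if n_layers != 5:
            raise ConfigurationError("fig5c requires N=5")
        w_short, w_long = family.require("w_short", "w_long")
        w.update(_chain_weights(5, 1.0))
        w[(3, 2)] = w[(4, 3)] = w[(5, 4)] = float(w_short)
        w[(5, 2)] = float(w_long)
    elif name == "chain_time_decay":
        w_ff, tau = family.require("w_ff", "tau")
        tau = np.broadcast_to(np.asarray(tau, dtype=float), (n_layers,))
        w.update(_chain_weights(n_layers, w_ff))
        for l in range(1, n_layers + 1):
            w[(l, l)] = float(tau[l - 1])
    else:  # pragma: no cover - guarded by CanonicalFamily
        raise ConfigurationError(f"unknown family {name!r}")

    # drop exact zeros so structural queries (feedback distances) stay sharp,
    # except for the non-layered dense family where zeros are meaningful
    if layered:
        w = {k: v for k, v in w.items() if v != 0.0}
    return LayeredNetworkSpec(
        n_layers=n_layers,
        weights=w,
        delay_scheme=delay_scheme,
        input_amplitude=input_amplitude,
        layered=layered,
    )


def _draw(rng: np.random.Generator, dist: object, size: int) -> np.ndarray:
    """Draw from a bounded distribution spec.

    Accepted forms: ``("uniform", low, high)``, ``("constant", value)``, or a
    mapping ``{"name": "uniform", "low": .., "high": ..}``.
    """
    if isinstance(dist, Mapping):
        name = dist["name"]
        if name == "uniform":
            return rng.uniform(dist["low"], dist["high"], size)
        if name == "constant":
            return np.full(size, float(dist["value"]))
        raise ConfigurationError(f"unknown weight distribution {name!r}")
    if isinstance(dist, (tuple, list)):
        if dist[0] == "uniform":
            return rng.uniform(dist[1], dist[2], size)
        if dist[0] == "constant":
            return np.full(size, float(dist[1]))
        raise ConfigurationError(f"unknown weight distribution {dist[0]!r}")
    raise ConfigurationError(f"cannot interpret weight distribution {dist!r}")


def random_network(
    n_layers: int,
    feedback_distances: set[int] | frozenset[int],
    weight_distribution: object = ("uniform", -0.5, 0.5),
    seed: int | None = None,
    feedforward_distribution: object | None = ("constant", 1.0),
    delay_scheme: str = "biological",
    input_amplitude: float = 1.0,
) -> LayeredNetworkSpec:
    """Draw a random layered spec with feedback at the given distances.

    Feedforward chain weights come from ``feedforward_distribution`` (pass
    ``None`` for no feedforward connections at all); every feedback entry at
    each requested distance is drawn from ``weight_distribution``.  Fixed
    seeds give bit-reproducible specs.
    """
    distances = sorted(int(q) for q in feedback_distances)
    if any(q < 0 or q > n_layers - 1 for q in distances):
        raise ConfigurationError(
            f"feedback distances must lie in 0..{n_layers - 1}, got {distances}"
        )
    rng = np.random.default_rng(seed)
    w: dict[tuple[int, int], float] = {}
    if feedforward_distribution is not None:
        vals = _draw(rng, feedforward_distribution, n_layers - 1)
        for l, v in zip(range(1, n_layers), vals):
            w[(l, l + 1)] = float(v)
    for q in distances:
        vals = _draw(rng, weight_distribution, n_layers - q)
        for l, v in zip(range(1, n_layers - q + 1), vals):
            w[(l + q, l)] = float(v)
    if not w:
        warnings.warn(
            "network has no connections at all (no feedback distances and no "
            "feedforward weights)",
            DegenerateNetworkWarning,
            stacklevel=2,
        )
    return LayeredNetworkSpec(
        n_layers=n_layers,
        weights=w,
        delay_scheme=delay_scheme,
        input_amplitude=input_amplitude,
    )


def expand_units(spec: LayeredNetworkSpec, units: int) -> ConnectivityMatrices:
    """Expand each scalar weight to a uniform (alpha/units) * J block.

    J is the all-ones units x units block, so every block-row sum preserves
    the scalar gain and the nonzero part of the spectrum is exactly that of
    the one-unit-per-layer system (each block is rank one with the uniform
    vector as its range).
    """
    if units < 1:
        raise StructureError(f"units must be >= 1, got {units}")
    scalar = build_matrices(spec)
    block = np.ones((units, units)) / units
    return ConnectivityMatrices(
        m_ff=np.kron(scalar.m_ff, block),
        m_fb=np.kron(scalar.m_fb, block),
        layered=scalar.layered,
        units=units,
    )


# --- JSON serialization ----------------------------------------------------

def spec_to_json(spec: LayeredNetworkSpec) -> str:
    payload = {
        "n_layers": spec.n_layers,
        "delay_scheme": spec.delay_scheme,
        "input": spec.input_amplitude,
        "weights": [
            {"from": j, "to": i, "value": a}
            for (j, i), a in sorted(spec.weights.items())
        ],
        "units_per_layer": spec.units_per_layer,
        "layered": spec.layered,
    }
    return json.dumps(payload, indent=2)


def spec_from_json(text: str | Mapping) -> LayeredNetworkSpec:
    """Parse a spec from JSON; accepts the family shorthand as well.

    Direct form::

        {"n_layers": 3, "delay_scheme": "biological", "input": 1.0,
         "weights": [{"from": 1, "to": 2, "value": 0.5}], "units_per_layer": 1}

    Family shorthand::

        {"family": "single_q", "n_layers": 5,
         "parameters": {"q": 3, "w_ff": 1.0, "w_fb": 0.5}}
    """
    data = json.loads(text) if isinstance(text, str) else dict(text)
    if "family" in data:
        fam = CanonicalFamily(data["family"], data.get("parameters", {}))
        return from_family(
            fam,
            n_layers=int(data["n_layers"]),
            delay_scheme=data.get("delay_scheme", "biological"),
            input_amplitude=float(data.get("input", 1.0)),
        )
    weights = {
        (int(e["from"]), int(e["to"])): float(e["value"])
        for e in data.get("weights", [])
    }
    return LayeredNetworkSpec(
        n_layers=int(data["n_layers"]),
        weights=weights,
        delay_scheme=data.get("delay_scheme", "biological"),
        input_amplitude=float(data.get("input", 1.0)),
        units_per_layer=int(data.get("units_per_layer", 1)),
        layered=bool(data.get("layered", True)),
    )
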