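"""Sign-constrained recurrent network: structure, dynamics, persistence.

Units are arranged as task inputs (Gate, Signal1[, Signal2]), a constant bias
input, excitatory hidden units, inhibitory hidden units, and output units.
Non-input activity follows the one-step-delay update

    A_i(t) = f( sum_j A_j(t-1) W_ji - offset ),   f(x) = 1 / (1 + exp(-x / T))

with a logistic f saturating at 0 and 1, an offset of 4 so that units are
nearly silent without positive drive, and a "temperature" T that sets the
inverse slope of the sigmoid about that midpoint (T = 1 for the standard
simulations).

Connectivity obeys Dale's principle: each hidden unit's outgoing weights are
all positive (excitatory, bounded to [0.001, 8]) or all negative (inhibitory,
[-8, -0.001]); input and bias weights are unsigned in [-8, 8].  Self
connections and inhibitory-to-inhibitory connections are disallowed; task
inputs project only to hidden units, the bias also to outputs, hidden units
project to hidden and output units, outputs project nowhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .task import Episode, as_rng

__all__ = [
    "NetworkSpec",
    "Network",
    "build_network",
    "activation",
    "step",
    "run_episode",
    "count_weights",
    "count_live_units",
    "save_network",
    "load_network",
    "NetworkFormatError",
]

NETWORK_FORMAT = "sahnet-network"
NETWORK_FORMAT_VERSION = 1

# unit role labels
ROLE_INPUT = "task-input"
ROLE_BIAS = "bias"
ROLE_EXC = "excitatory-hidden"
ROLE_INH = "inhibitory-hidden"
ROLE_OUTPUT = "output"


class NetworkFormatError(ValueError):
    """Raised for malformed or unsupported network files."""


@dataclass(frozen=True)
class NetworkSpec:
    """Static architecture parameters.

    ``n_task_inputs`` counts the task-driven inputs (gate + signals); a bias
    input with constant activity 1 is appended when ``has_bias``.  Weight
    bounds per sign class follow the standard constraint scheme: input/bias
    weights unsigned in [-input_bound, input_bound], excitatory outgoing
    weights in [min_magnitude, max_magnitude], inhibitory in
    [-max_magnitude, -min_magnitude].
    """

    n_task_inputs: int = 3
    has_bias: bool = True
    n_excitatory: int = 16
    n_inhibitory: int = 16
    n_outputs: int = 2
    offset: float = 4.0
    temperature: float = 1.0
    input_bound: float = 8.0
    max_magnitude: float = 8.0
    min_magnitude: float = 0.001

    def __post_init__(self):
        for name in ("n_task_inputs", "n_excitatory", "n_inhibitory", "n_outputs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def n_inputs(self) -> int:
        return self.n_task_inputs + (1 if self.has_bias else 0)

    @property
    def n_hidden(self) -> int:
        return self.n_excitatory + self.n_inhibitory

    @property
    def n_units(self) -> int:
        return self.n_inputs + self.n_hidden + self.n_outputs

    def unit_roles(self) -> list[str]:
        roles = [ROLE_INPUT] * self.n_task_inputs
        if self.has_bias:
            roles.append(ROLE_BIAS)
        roles += [ROLE_EXC] * self.n_excitatory
        roles += [ROLE_INH] * self.n_inhibitory
        roles += [ROLE_OUTPUT] * self.n_outputs
        return roles

    def input_names(self) -> list[str]:
        n_sig = self.n_task_inputs - 1
        names = ["gate"] + [f"signal{k + 1}" for k in range(n_sig)]
        if self.has_bias:
            names.append("bias")
        return names


def activation(net_input, offset: float, temperature: float):
    """Logistic activation ``1 / (1 + exp(-(net_input - offset) / T))``."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return 1.0 / (1.0 + np.exp(-(np.asarray(net_input, dtype=float) - offset) / temperature))


def _structural_mask(spec: NetworkSpec) -> np.ndarray:
    """Allowed connections, indexed (from-unit, to-unit)."""
    n = spec.n_units
    roles = np.asarray(spec.unit_roles())
    is_task = roles == ROLE_INPUT
    is_bias = roles == ROLE_BIAS
    is_exc = roles == ROLE_EXC
    is_inh = roles == ROLE_INH
    is_hidden = is_exc | is_inh
    is_out = roles == ROLE_OUTPUT

    mask = np.zeros((n, n), dtype=bool)
    mask[np.ix_(is_task, is_hidden)] = True
    mask[np.ix_(is_bias, is_hidden | is_out)] = True
    mask[np.ix_(is_exc, is_hidden | is_out)] = True
    mask[np.ix_(is_inh, is_exc | is_out)] = True  # no inhibitory cross-coupling
    np.fill_diagonal(mask, False)
    return mask


def _bound_rows(spec: NetworkSpec):
    """Per from-unit lower/upper weight bounds (n_units each)."""
    roles = np.asarray(spec.unit_roles())
    lo = np.zeros(len(roles))
    hi = np.zeros(len(roles))
    free = (roles == ROLE_INPUT) | (roles == ROLE_BIAS)
    lo[free], hi[free] = -spec.input_bound, spec.input_bound
    exc = roles == ROLE_EXC
    lo[exc], hi[exc] = spec.min_magnitude, spec.max_magnitude
    inh = roles == ROLE_INH
    lo[inh], hi[inh] = -spec.max_magnitude, -spec.min_magnitude
    return lo, hi


@dataclass
class Network:
    """A concrete network: mask, weights, live units.

    ``mask[j, i]`` is True when a connection from unit j to unit i is present;
    masked-out entries of ``weights`` are exactly zero.  ``alive`` is False
    for hidden units removed by unit deletion.
    """

    spec: NetworkSpec
    mask: np.ndarray
    weights: np.ndarray
    alive: np.ndarray
    roles: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.roles:
            self.roles = self.spec.unit_roles()
        self._lo_rows, self._hi_rows = _bound_rows(self.spec)

    # --- structure helpers -------------------------------------------------
    @property
    def n_units(self) -> int:
        return self.spec.n_units

    @property
    def input_slice(self) -> slice:
        return slice(0, self.spec.n_inputs)

    @property
    def hidden_slice(self) -> slice:
        return slice(self.spec.n_inputs, self.spec.n_inputs + self.spec.n_hidden)

    @property
    def output_slice(self) -> slice:
        n = self.spec.n_units
        return slice(n - self.spec.n_outputs, n)

    def copy(self) -> "Network":
        return Network(
            spec=self.spec,
            mask=self.mask.copy(),
            weights=self.weights.copy(),
            alive=self.alive.copy(),
            roles=list(self.roles),
        )

    def with_temperature(self, temperature: float) -> "Network":
        out = self.copy()
        out.spec = replace(self.spec, temperature=temperature)
        return out

    def input_index(self, name: str) -> int:
        names = self.spec.input_names()
        if name not in names:
            raise KeyError(f"unknown input {name!r}; known inputs: {names}")
        return names.index(name)

    def count_weights(self) -> int:
        return int(self.mask.sum())

    def count_live_units(self) -> int:
        """Live hidden units."""
        return int(self.alive[self.hidden_slice].sum())

    # --- constraints -------------------------------------------------------
    def bound_matrices(self):
        lo = np.broadcast_to(self._lo_rows[:, None], self.mask.shape)
        hi = np.broadcast_to(self._hi_rows[:, None], self.mask.shape)
        return lo, hi

    def project(self, weights: np.ndarray | None = None) -> np.ndarray:
        """Clip a weight matrix into sign-class bounds on the mask support."""
        w = self.weights if weights is None else weights
        lo, hi = self.bound_matrices()
        out = np.clip(w, lo, hi)
        out[~self.mask] = 0.0
        if weights is None:
            self.weights = out
        return out

    def validate(self, strict_bounds: bool = True) -> None:
        """Raise AssertionError if structure or constraints are violated."""
        spec = self.spec
        assert self.mask.shape == (spec.n_units, spec.n_units)
        assert not np.diagonal(self.mask).any(), "self-connections present"
        structural = _structural_mask(spec)
        assert not (self.mask & ~structural).any(), "connection outside allowed topology"
        assert np.all(self.weights[~self.mask] == 0.0), "weight outside mask"
        dead = ~self.alive
        if dead.any():
            assert not self.mask[dead, :].any(), "dead unit has outgoing connections"
            assert not self.mask[:, dead].any(), "dead unit has incoming connections"
        if strict_bounds:
            lo, hi = self.bound_matrices()
            w = self.weights[self.mask]
            assert np.all(w >= lo[self.mask] - 1e-12), "weight below lower bound"
            assert np.all(w <= hi[self.mask] + 1e-12), "weight above upper bound"


def build_network(spec: NetworkSpec, init_scale: float = 1.0, rng_state=None) -> Network:
    """Build a network with random weights in (-init_scale, init_scale),
    mapped into each sign class and clipped to its bounds."""
    rng = as_rng(rng_state)
    mask = _structural_mask(spec)
    roles = np.asarray(spec.unit_roles())
    u = rng.uniform(-init_scale, init_scale, size=mask.shape)
    w = u.copy()
    w[roles == ROLE_EXC, :] = np.abs(u[roles == ROLE_EXC, :])
    w[roles == ROLE_INH, :] = -np.abs(u[roles == ROLE_INH, :])
    w[~mask] = 0.0
    net = Network(
        spec=spec,
        mask=mask,
        weights=w,
        alive=np.ones(spec.n_units, dtype=bool),
    )
    net.project()
    return net


# --- dynamics ---------------------------------------------------------------

def step(network: Network, activities: np.ndarray, input_row: np.ndarray) -> np.ndarray:
    """One synchronous update: non-input units read previous activities,
    input units take ``input_row`` verbatim, dead units stay at zero."""
    n_in = network.spec.n_inputs
    if activities.shape != (network.n_units,):
        raise ValueError(
            f"activities must have shape ({network.n_units},), got {activities.shape}"
        )
    if len(input_row) != n_in:
        raise ValueError(f"input_row must supply {n_in} values, got {len(input_row)}")
    spec = network.spec
    new = activation(activities @ network.weights, spec.offset, spec.temperature)
    new[:n_in] = input_row
    new[~network.alive] = 0.0
    return new


def run_episode(
    network: Network,
    episode: Episode,
    initial_activities: np.ndarray | None = None,
) -> np.ndarray:
    """Iterate the dynamics over an episode; returns the (time x units) trace."""
    inputs = np.asarray(episode.inputs, dtype=float)
    if inputs.ndim != 2 or inputs.shape[1] != network.spec.n_inputs:
        raise ValueError(
            f"episode provides {inputs.shape[1] if inputs.ndim == 2 else '?'} input "
            f"columns, network expects {network.spec.n_inputs}"
        )
    return run_inputs(network, inputs, initial_activities)


def run_inputs(
    network: Network,
    inputs: np.ndarray,
    initial_activities: np.ndarray | None = None,
) -> np.ndarray:
    """Like :func:`run_episode` but on a raw (time x n_inputs) input array."""
    spec = network.spec
    n_in = spec.n_inputs
    n = network.n_units
    T_steps = inputs.shape[0]
    trace = np.empty((T_steps, n))
    a = np.zeros(n) if initial_activities is None else np.asarray(initial_activities, float)
    W = network.weights
    offset, temp = spec.offset, spec.temperature
    dead = ~network.alive
    any_dead = bool(dead.any())
    for t in range(T_steps):
        a = 1.0 / (1.0 + np.exp(-((a @ W) - offset) / temp))
        a[:n_in] = inputs[t]
        if any_dead:
            a[dead] = 0.0
        trace[t] = a
    return trace


def count_weights(network: Network) -> int:
    return network.count_weights()


def count_live_units(network: Network) -> int:
    return network.count_live_units()


# --- persistence -------------------------------------------------------------

def save_network(network: Network, path) -> None:
    """Write a network to versioned JSON (lossless float round-trip)."""
    j, i = np.nonzero(network.mask)
    doc = {
        "format": NETWORK_FORMAT,
        "version": NETWORK_FORMAT_VERSION,
        "spec": asdict(network.spec),
        "roles": list(network.roles),
        "alive": network.alive.astype(int).tolist(),
        "connections": {
            "from": j.tolist(),
            "to": i.tolist(),
            "weight": network.weights[j, i].tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_network(path) -> Network:
    """Read a network written by :func:`save_network`."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise NetworkFormatError(f"not valid JSON: {exc}") from exc
    if doc.get("format") != NETWORK_FORMAT:
        raise NetworkFormatError(f"unrecognized format field: {doc.get('format')!r}")
    if doc.get("version") != NETWORK_FORMAT_VERSION:
        raise NetworkFormatError(
            f"unsupported network file version {doc.get('version')!r} "
            f"(expected {NETWORK_FORMAT_VERSION})"
        )
    for key in ("spec", "alive", "connections"):
        if key not in doc:
            raise NetworkFormatError(f"missing required field {key!r}")
    conns = doc["connections"]
    for key in ("from", "to", "weight"):
        if key not in conns:
            raise NetworkFormatError(f"missing required field connections.{key!r}")
    try:
        spec = NetworkSpec(**doc["spec"])
    except (TypeError, ValueError) as exc:
        raise NetworkFormatError(f"bad spec field: {exc}") from exc
    n = spec.n_units
    mask = np.zeros((n, n), dtype=bool)
    weights = np.zeros((n, n))
    j = np.asarray(conns["from"], dtype=int)
    i = np.asarray(conns["to"], dtype=int)
    if j.size and (j.max() >= n or i.max() >= n or j.min() < 0 or i.min() < 0):
        raise NetworkFormatError("connection index out of range")
    mask[j, i] = True
    weights[j, i] = np.asarray(conns["weight"], dtype=float)
    alive = np.asarray(doc["alive"], dtype=bool)
    if alive.shape != (n,):
        raise NetworkFormatError("alive vector does not match unit count")
    net = Network(spec=spec, mask=mask, weights=weights, alive=alive,
                  roles=doc.get("roles") or spec.unit_roles())
    net.validate(strict_bounds=False)
    return net
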