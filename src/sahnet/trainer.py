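"""Training by gradient descent through time with line search.

Each epoch draws one fresh 20-step episode, backpropagates the exact gradient
of the mean-squared output error through the unrolled dynamics, and line
searches two candidate directions: the plain (first-order) gradient and a
Polak-Ribiere conjugate-gradient combination of the current and previous
gradients (the "second-order" estimate).  Whichever line-searched update
yields the lower episode error is accepted; a failed search leaves the
weights unchanged for that epoch.  After every accepted step the weights are
projected back into their sign-class bounds.  With weight decay enabled, all
weight magnitudes shrink toward zero by a fixed amount after each epoch,
exposing non-load-bearing weights for later deletion.

Errors are descended as mean squared error and reported as RMS
(root-mean-square) over valid time-steps, multiplied by 100 for percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import Network, run_episode
from .task import TaskConfig, Episode, generate_episode, as_rng

__all__ = [
    "TrainingConfig",
    "HistoryRecord",
    "TrainingHistory",
    "rms_error",
    "compute_gradient",
    "apply_weight_decay",
    "train",
    "evaluate_network",
]


@dataclass
class TrainingConfig:
    """Optimizer and bookkeeping settings.

    ``weight_decay_amount`` is the per-epoch magnitude shrinkage used during
    decay phases.  The line search backtracks from an adaptive initial step
    (doubled after success, halved after failure), spending at most
    ``line_search_max_evals`` error evaluations per direction.
    """

    episodes_per_epoch: int = 1
    weight_decay_amount: float = 0.001
    line_search_max_evals: int = 12
    line_search_initial_step: float = 0.5
    line_search_max_step: float = 3.0
    record_every: int = 500
    eval_episodes: int = 100

    def __post_init__(self):
        if self.weight_decay_amount < 0:
            raise ValueError("weight_decay_amount must be >= 0")
        if self.line_search_max_evals < 1:
            raise ValueError("line_search_max_evals must be >= 1")


@dataclass
class HistoryRecord:
    epoch: int
    percent_error: float
    n_weights: int
    n_hidden_units: int


@dataclass
class TrainingHistory:
    """Per-checkpoint records of training progress."""

    records: list[HistoryRecord] = field(default_factory=list)

    def append(self, record: HistoryRecord) -> None:
        if self.records and record.epoch <= self.records[-1].epoch:
            # keep epoch indices strictly increasing; replace stale duplicates
            self.records = [r for r in self.records if r.epoch < record.epoch]
        self.records.append(record)

    def extend(self, other: "TrainingHistory") -> None:
        for r in other.records:
            self.append(r)

    @property
    def epochs(self) -> np.ndarray:
        return np.asarray([r.epoch for r in self.records])

    @property
    def percent_errors(self) -> np.ndarray:
        return np.asarray([r.percent_error for r in self.records])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": [r.epoch for r in self.records],
                "hidden_units": [r.n_hidden_units for r in self.records],
                "weights": [r.n_weights for r in self.records],
                "percent_error": [r.percent_error for r in self.records],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# --- error ------------------------------------------------------------------

def rms_error(outputs: np.ndarray, targets: np.ndarray, valid_mask: np.ndarray) -> float:
    """RMS difference over all valid (step, output) cells, as a fraction.

    Multiply by 100 for the percent figure used in reports.
    """
    outputs = np.asarray(outputs, float)
    targets = np.asarray(targets, float)
    if outputs.ndim == 1:
        outputs = outputs[:, None]
    if targets.ndim == 1:
        targets = targets[:, None]
    if outputs.shape != targets.shape:
        raise ValueError(f"shape mismatch: outputs {outputs.shape} vs targets {targets.shape}")
    valid = np.asarray(valid_mask, bool)
    if not valid.any():
        raise ValueError("no valid time-steps: error undefined")
    diff = outputs[valid] - targets[valid]
    return float(np.sqrt(np.mean(diff**2)))


def _mse(outputs, targets, valid):
    diff = outputs[valid] - targets[valid]
    return float(np.mean(diff**2))


# --- gradient ----------------------------------------------------------------

def compute_gradient(network: Network, episodes: list[Episode] | Episode):
    """Exact gradient of mean squared error w.r.t. every present weight,
    backpropagated through all time-steps of the given episode(s).

    Returns ``(gradient, mse)`` with the gradient conformable with
    ``network.weights`` and zero outside the connection mask.
    """
    if isinstance(episodes, Episode):
        episodes = [episodes]
    grad = np.zeros_like(network.weights)
    total_mse = 0.0
    n_used = 0
    for ep in episodes:
        g, m = _episode_gradient(network, ep)
        grad += g
        total_mse += m
        n_used += 1
    if n_used == 0:
        return grad, 0.0
    return grad / n_used, total_mse / n_used


def _episode_gradient(network: Network, episode: Episode):
    spec = network.spec
    n = network.n_units
    n_in = spec.n_inputs
    out_sl = network.output_slice
    T_steps = episode.n_steps
    if T_steps == 0:
        return np.zeros_like(network.weights), 0.0

    trace = run_episode(network, episode)
    valid = episode.valid_mask
    n_valid_cells = int(valid.sum()) * spec.n_outputs
    outputs = trace[:, out_sl]
    mse = _mse(outputs, episode.targets, valid) if valid.any() else 0.0
    if n_valid_cells == 0:
        return np.zeros_like(network.weights), mse

    # dE/da at the output units of valid steps
    dE_da_out = np.zeros((T_steps, spec.n_outputs))
    dE_da_out[valid] = 2.0 * (outputs[valid] - episode.targets[valid]) / n_valid_cells

    W = network.weights
    temp = spec.temperature
    dead = ~network.alive
    grad = np.zeros_like(W)
    delta_next = np.zeros(n)
    prev = np.vstack([np.zeros((1, n)), trace[:-1]])  # activities feeding each step
    for t in range(T_steps - 1, -1, -1):
        g = W @ delta_next  # credit flowing back from step t+1
        g[out_sl] += dE_da_out[t]
        a = trace[t]
        delta = g * a * (1.0 - a) / temp
        delta[:n_in] = 0.0
        delta[dead] = 0.0
        grad += np.outer(prev[t], delta)
        delta_next = delta
    grad[~network.mask] = 0.0
    return grad, mse


# --- weight decay -------------------------------------------------------------

def apply_weight_decay(network: Network, amount: float) -> Network:
    """Shrink every weight magnitude by ``amount`` toward zero (in place).

    Magnitudes clamp at zero and may transiently fall below the sign-class
    minimum; such weights become candidates for deletion.
    """
    if amount < 0:
        raise ValueError("decay amount must be >= 0")
    w = network.weights
    np.sign(w, out=(s := np.empty_like(w)))
    mag = np.abs(w) - amount
    np.maximum(mag, 0.0, out=mag)
    network.weights = s * mag
    network.weights[~network.mask] = 0.0
    return network


# --- line search ---------------------------------------------------------------

class _SearchState:
    """Adaptive initial step per direction family.

    The step is capped: unbounded per-episode minimization overfits each
    20-step episode and turns the epoch sequence into a random walk, while a
    modest cap keeps steps in the regime where per-episode improvement also
    improves the task objective.
    """

    def __init__(self, initial: float, max_step: float):
        self.step = min(initial, max_step)
        self.max_step = max_step

    def success(self, accepted: float):
        self.step = min(accepted * 2.0, self.max_step)

    def failure(self):
        self.step = max(self.step * 0.5, 1e-7)


def _line_search(network, episode, direction, base_mse, state, max_evals):
    """Backtracking search along ``direction``; candidates are projected into
    bounds before evaluation.  Returns (best_weights, best_mse) or (None, base)."""
    W0 = network.weights
    norm = np.linalg.norm(direction)
    if norm == 0.0 or not np.isfinite(norm):
        return None, base_mse
    d = direction / norm
    s = min(state.step, state.max_step)
    evals = 0
    best_w, best_mse, best_s = None, base_mse, None
    while evals < max_evals:
        cand = network.project(W0 + s * d)
        network.weights = cand
        m = _mse(run_episode(network, episode)[:, network.output_slice],
                 episode.targets, episode.valid_mask)
        network.weights = W0
        evals += 1
        if m < best_mse:
            best_w, best_mse, best_s = cand, m, s
            # greedy extension: keep doubling while it helps, up to the cap
            while evals < max_evals:
                s2 = min(s * 2.0, state.max_step)
                if s2 == s:
                    break
                cand2 = network.project(W0 + s2 * d)
                network.weights = cand2
                m2 = _mse(run_episode(network, episode)[:, network.output_slice],
                          episode.targets, episode.valid_mask)
                network.weights = W0
                evals += 1
                if m2 < best_mse:
                    best_w, best_mse, best_s = cand2, m2, s2
                    s = s2
                else:
                    break
            break
        s *= 0.5
    if best_w is None:
        state.failure()
        return None, base_mse
    state.success(best_s)
    return best_w, best_mse


# --- training loop --------------------------------------------------------------

def train(
    network: Network,
    task: TaskConfig,
    n_epochs: int,
    config: TrainingConfig | None = None,
    decay: bool = False,
    rng_state=None,
    history: TrainingHistory | None = None,
    start_epoch: int = 0,
    eval_rng_state=None,
    _opt_state: dict | None = None,
) -> TrainingHistory:
    """Train ``network`` in place for ``n_epochs`` epochs.

    One fresh episode per epoch; two line-searched candidate directions per
    epoch; sign-class projection after each accepted step; optional weight
    decay after every epoch.  History rows (test error, weight and unit
    counts) are recorded every ``config.record_every`` epochs against an
    independent evaluation stream.
    """
    config = config or TrainingConfig()
    rng = as_rng(rng_state)
    eval_rng_seed = eval_rng_state
    history = history if history is not None else TrainingHistory()
    state = _opt_state if _opt_state is not None else {}
    s1 = state.setdefault(
        "s1", _SearchState(config.line_search_initial_step, config.line_search_max_step))
    s2 = state.setdefault(
        "s2", _SearchState(config.line_search_initial_step, config.line_search_max_step))

    def record(epoch):
        err = evaluate_network(network, task, config.eval_episodes,
                               _eval_rng(eval_rng_seed, epoch))
        history.append(HistoryRecord(
            epoch=epoch, percent_error=err,
            n_weights=network.count_weights(),
            n_hidden_units=network.count_live_units(),
        ))

    if start_epoch == 0 and n_epochs > 0:
        record(0)

    for k in range(n_epochs):
        epoch = start_epoch + k + 1
        episodes = [generate_episode(task, rng) for _ in range(config.episodes_per_epoch)]
        ep = episodes[0] if len(episodes) == 1 else _concat_episodes(episodes)
        grad, base_mse = compute_gradient(network, ep)

        d1 = -grad
        g_prev, d_prev = state.get("g_prev"), state.get("d_prev")
        if g_prev is not None:
            denom = float(np.sum(g_prev * g_prev))
            beta = max(0.0, float(np.sum(grad * (grad - g_prev))) / denom) if denom > 0 else 0.0
            d2 = -grad + beta * d_prev
        else:
            d2 = -grad
        state["g_prev"] = grad
        state["d_prev"] = d2

        w1, m1 = _line_search(network, ep, d1, base_mse, s1, config.line_search_max_evals)
        w2, m2 = _line_search(network, ep, d2, base_mse, s2, config.line_search_max_evals)
        if w2 is not None and m2 <= m1:
            network.weights = w2
        elif w1 is not None:
            network.weights = w1
        # else: failed search, weights unchanged this epoch

        if decay and config.weight_decay_amount > 0:
            apply_weight_decay(network, config.weight_decay_amount)

        if epoch % config.record_every == 0 or k == n_epochs - 1:
            record(epoch)
    return history


def _concat_episodes(episodes):
    return Episode(
        inputs=np.vstack([e.inputs for e in episodes]),
        targets=np.vstack([e.targets for e in episodes]),
        valid_mask=np.concatenate([e.valid_mask for e in episodes]),
        config=episodes[0].config,
    )


def _eval_rng(seed, epoch):
    if seed is None:
        return np.random.default_rng(epoch)
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(epoch))))


def evaluate_network(network: Network, task: TaskConfig, n_episodes: int, rng_state) -> float:
    """Mean percent RMS error over fresh test episodes (valid steps only)."""
    rng = as_rng(rng_state)
    out_sl = network.output_slice
    errs = np.empty(n_episodes)
    for i in range(n_episodes):
        ep = generate_episode(task, rng)
        trace = run_episode(network, ep)
        errs[i] = rms_error(trace[:, out_sl], ep.targets, ep.valid_mask)
    return float(errs.mean() * 100.0)
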