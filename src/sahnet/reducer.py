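"""Staged network reduction: weight decay, weight deletion, unit deletion.

The full protocol trains an oversized network for 5000 epochs, then runs
three decay iterations (1000 epochs with weight decay, deletion of small
weights, 1000 epochs without decay) reaching epoch 11000, and finally three
unit-deletion rounds: the first deletes low-activity hidden units, retrains
1000 epochs, runs 500 more with decay and deletes small weights; the second
and third delete units and retrain 500 epochs each, ending at epoch 13500.
Checkpoint copies are kept at epochs 5000 (unreduced), 11000 (partially
reduced) and 13500 (reduced).

Hidden units are deleted when their peak activity over a 200-step probe of
fresh task input stays below ``(1 - alpha) / 2`` (with a small floor so fully
silent units remain deletable at high alpha).  Deleted weights and units
never return.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Network, run_inputs
from .task import TaskConfig, generate_episode, as_rng
from .trainer import TrainingConfig, TrainingHistory, train

__all__ = [
    "ReductionSchedule",
    "delete_small_weights",
    "delete_inactive_units",
    "unit_deletion_threshold",
    "run_reduction_schedule",
]


@dataclass(frozen=True)
class ReductionSchedule:
    """Constants of the staged train/decay/delete protocol."""

    initial_epochs: int = 5000
    decay_iterations: int = 3
    decay_phase_epochs: int = 1000
    post_decay_epochs: int = 1000
    first_unit_round_retrain: int = 1000
    first_unit_round_decay: int = 500
    later_unit_rounds: int = 2
    later_round_retrain: int = 500
    weight_delete_threshold: float = 0.05
    activity_window: int = 200
    activity_floor: float = 0.01

    def __post_init__(self):
        if self.weight_delete_threshold < 0:
            raise ValueError("weight_delete_threshold must be >= 0")
        if self.activity_window < 1:
            raise ValueError("activity_window must be >= 1")

    @property
    def total_epochs(self) -> int:
        return (
            self.initial_epochs
            + self.decay_iterations * (self.decay_phase_epochs + self.post_decay_epochs)
            + self.first_unit_round_retrain
            + self.first_unit_round_decay
            + self.later_unit_rounds * self.later_round_retrain
        )

    @property
    def checkpoints(self) -> tuple[int, int, int]:
        unreduced = self.initial_epochs
        partial = unreduced + self.decay_iterations * (
            self.decay_phase_epochs + self.post_decay_epochs
        )
        return (unreduced, partial, self.total_epochs)


def delete_small_weights(network: Network, threshold: float) -> Network:
    """Permanently remove weights with ``|w| < threshold`` (in place);
    survivors are re-clipped into their sign-class bounds."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    small = network.mask & (np.abs(network.weights) < threshold)
    network.mask = network.mask & ~small
    network.weights[~network.mask] = 0.0
    network.project()
    return network


def unit_deletion_threshold(alpha: float, floor: float = 0.01) -> float:
    """Peak-activity threshold below which a hidden unit is deleted."""
    return max((1.0 - alpha) / 2.0, floor)


def delete_inactive_units(
    network: Network,
    task: TaskConfig,
    rng_state,
    activity_window: int = 200,
    floor: float = 0.01,
) -> Network:
    """Delete hidden units whose peak activity over a fresh-input probe of
    ``activity_window`` steps falls below the alpha-dependent threshold."""
    rng = as_rng(rng_state)
    chunks = []
    steps = 0
    while steps < activity_window:
        ep = generate_episode(task, rng)
        chunks.append(ep.inputs)
        steps += ep.n_steps
    probe = np.vstack(chunks)[:activity_window]
    trace = run_inputs(network, probe)

    thr = unit_deletion_threshold(task.alpha, floor)
    hid = network.hidden_slice
    peak = trace[:, hid].max(axis=0)
    doomed_local = np.flatnonzero(network.alive[hid] & (peak < thr))
    doomed = doomed_local + hid.start
    if doomed.size:
        network.alive[doomed] = False
        network.mask[doomed, :] = False
        network.mask[:, doomed] = False
        network.weights[doomed, :] = 0.0
        network.weights[:, doomed] = 0.0
    return network


@dataclass
class ReductionResult:
    """Checkpoint networks and the full training history of a schedule run."""

    checkpoints: dict[int, Network] = field(default_factory=dict)
    history: TrainingHistory = field(default_factory=TrainingHistory)

    @property
    def unreduced(self) -> Network:
        return self.checkpoints[sorted(self.checkpoints)[0]]

    @property
    def partially_reduced(self) -> Network:
        return self.checkpoints[sorted(self.checkpoints)[1]]

    @property
    def reduced(self) -> Network:
        return self.checkpoints[sorted(self.checkpoints)[-1]]


def run_reduction_schedule(
    network: Network,
    task: TaskConfig,
    schedule: ReductionSchedule | None = None,
    rng_state=None,
    training: TrainingConfig | None = None,
) -> ReductionResult:
    """Execute the full staged protocol on ``network`` (modified in place).

    Returns the three checkpoint networks (copies) and the concatenated
    training history sampled every ``training.record_every`` epochs.
    """
    schedule = schedule or ReductionSchedule()
    training = training or TrainingConfig()
    ck_unred, ck_partial, ck_final = schedule.checkpoints
    if ck_final != schedule.total_epochs:  # pragma: no cover - defensive
        raise ValueError("schedule totals inconsistent")

    ss = np.random.SeedSequence(rng_state) if not isinstance(
        rng_state, np.random.SeedSequence) else rng_state
    train_seed, probe_seed, eval_seed = ss.spawn(3)
    train_rng = np.random.default_rng(train_seed)
    probe_rng = np.random.default_rng(probe_seed)
    eval_key = int(eval_seed.generate_state(1)[0] % (2**31))

    result = ReductionResult()
    opt_state: dict = {}
    epoch = 0

    def phase(n_epochs, decay=False):
        nonlocal epoch
        train(network, task, n_epochs, training, decay=decay, rng_state=train_rng,
              history=result.history, start_epoch=epoch, eval_rng_state=eval_key,
              _opt_state=opt_state)
        epoch += n_epochs

    def prune_weights():
        delete_small_weights(network, schedule.weight_delete_threshold)
        opt_state.pop("g_prev", None)
        opt_state.pop("d_prev", None)

    def prune_units():
        delete_inactive_units(network, task, probe_rng,
                              schedule.activity_window, schedule.activity_floor)
        opt_state.pop("g_prev", None)
        opt_state.pop("d_prev", None)

    phase(schedule.initial_epochs)
    result.checkpoints[epoch] = network.copy()

    for _ in range(schedule.decay_iterations):
        phase(schedule.decay_phase_epochs, decay=True)
        prune_weights()
        phase(schedule.post_decay_epochs)
    result.checkpoints[epoch] = network.copy()

    prune_units()
    phase(schedule.first_unit_round_retrain)
    phase(schedule.first_unit_round_decay, decay=True)
    prune_weights()
    for _ in range(schedule.later_unit_rounds):
        prune_units()
        phase(schedule.later_round_retrain)
    result.checkpoints[epoch] = network.copy()
    return result
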