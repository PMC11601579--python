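"""Sample-and-hold (SAH) task generation.

The task presents one or two continuous random signals together with a binary
gate pulse.  At every gate the network must capture ("sample") the current
signal values and sustain them at its outputs ("hold") until the next gate,
with a fixed two-step delay that accommodates the propagation delay of a
layered recurrent network.

When two signals are used they share a *common-mode* component controlled by
``alpha``: at each time-step a common value ``C ~ U(0, alpha)`` is drawn and
added to independent per-signal components,

    Signal_k = C + U_k(0, 1 - alpha)

so every signal lies in [0, 1] with mean 0.5 at every ``alpha``.
``alpha = 0`` gives two independent uniform signals, ``alpha = 1`` makes them
identical; in between the Pearson correlation of the two signals is
``alpha^2 / (alpha^2 + (1 - alpha)^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "Episode",
    "generate_episode",
    "episode_stream",
    "signal_correlation",
    "as_rng",
]


def as_rng(seed_or_rng) -> np.random.Generator:
    """Normalize an int seed / SeedSequence / Generator to a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the sample-and-hold task.

    Parameters
    ----------
    alpha : float
        Common-mode fraction in [0, 1]; degree of commonality of the two
        signals.  Ignored (must still be valid) when ``n_signals == 1``.
    epoch_length : int
        Number of time-steps per episode (one training epoch).
    gate_spacing_min, gate_spacing_max : int
        Successive gate pulses are spaced by an integer drawn uniformly from
        ``{gate_spacing_min, ..., gate_spacing_max}`` time-steps.
    target_delay : int
        Targets are the held samples delayed by this many steps.
    n_signals : int
        1 for the classic single-input SAH task, 2 for the dual task.
    distribution_matched : bool
        Optional variant for ``alpha`` in {0, 1} (or ``n_signals == 1``) in
        which signals keep their level of commonality but take the marginal
        distribution of the nearest two-component mixture (see docs/methods).
    """

    alpha: float = 0.0
    epoch_length: int = 20
    gate_spacing_min: int = 3
    gate_spacing_max: int = 6
    target_delay: int = 2
    n_signals: int = 2
    distribution_matched: bool = False

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.gate_spacing_min < 1 or self.gate_spacing_min > self.gate_spacing_max:
            raise ValueError(
                "require 1 <= gate_spacing_min <= gate_spacing_max, got "
                f"[{self.gate_spacing_min}, {self.gate_spacing_max}]"
            )
        if self.epoch_length < 0:
            raise ValueError("epoch_length must be non-negative")
        if self.target_delay < 0 or (
            self.epoch_length > 0 and self.target_delay >= self.epoch_length
        ):
            raise ValueError("require 0 <= target_delay < epoch_length")
        if self.n_signals not in (1, 2):
            raise ValueError("n_signals must be 1 or 2")
        if self.distribution_matched and self.n_signals == 2 and self.alpha not in (0.0, 1.0):
            raise ValueError(
                "distribution_matched variant is defined only for alpha in {0, 1}"
            )

    @property
    def n_inputs(self) -> int:
        """Number of network input columns: gate + signals + bias."""
        return 1 + self.n_signals + 1

    def with_alpha(self, alpha: float) -> "TaskConfig":
        return replace(self, alpha=alpha)


@dataclass
class Episode:
    """One generated task sequence.

    ``inputs`` has one row per time-step with columns ordered
    (Gate, Signal1[, Signal2], Bias); ``targets`` has one column per signal;
    ``valid_mask`` is False for the initial steps where no target is defined.
    """

    inputs: np.ndarray
    targets: np.ndarray
    valid_mask: np.ndarray
    config: TaskConfig = field(repr=False, default=None)

    @property
    def n_steps(self) -> int:
        return self.inputs.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        n_sig = self.targets.shape[1]
        cols = {"step": np.arange(self.n_steps), "gate": self.inputs[:, 0]}
        for k in range(n_sig):
            cols[f"signal{k + 1}"] = self.inputs[:, 1 + k]
        cols["bias"] = self.inputs[:, -1]
        for k in range(n_sig):
            cols[f"target{k + 1}"] = self.targets[:, k]
        cols["valid"] = self.valid_mask.astype(int)
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _draw_signals(config: TaskConfig, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Per-step signal values, shape (n_steps, n_signals)."""
    a = config.alpha
    if config.distribution_matched:
        return _draw_signals_matched(config, n_steps, rng)
    if config.n_signals == 1:
        return rng.uniform(0.0, 1.0, size=(n_steps, 1))
    c = rng.uniform(0.0, a, size=n_steps) if a > 0 else np.zeros(n_steps)
    u = rng.uniform(0.0, 1.0 - a, size=(n_steps, 2)) if a < 1 else np.zeros((n_steps, 2))
    return c[:, None] + u


def _draw_signals_matched(config: TaskConfig, n_steps: int, rng) -> np.ndarray:
    # Marginals are matched to the nearest genuine two-component mixture
    # (alpha=0.1 for the low end, alpha=0.9 for the high end) while the level
    # of commonality is preserved exactly.
    if config.n_signals == 1:
        # single signal with the alpha=0.1 sum-of-uniforms marginal
        return (rng.uniform(0.0, 0.1, size=(n_steps, 1))
                + rng.uniform(0.0, 0.9, size=(n_steps, 1)))
    if config.alpha == 0.0:
        # independent per-signal components: zero commonality, alpha=0.1 marginal
        return (rng.uniform(0.0, 0.1, size=(n_steps, 2))
                + rng.uniform(0.0, 0.9, size=(n_steps, 2)))
    # alpha == 1: identical signals with the alpha=0.9 sum-of-uniforms marginal
    s = rng.uniform(0.0, 0.9, size=n_steps) + rng.uniform(0.0, 0.1, size=n_steps)
    return np.repeat(s[:, None], 2, axis=1)


def _gate_steps(config: TaskConfig, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Gate pulse positions: step 0, then uniform spacing in the allowed range."""
    steps = []
    t = 0
    while t < n_steps:
        steps.append(t)
        t += int(rng.integers(config.gate_spacing_min, config.gate_spacing_max + 1))
    return np.asarray(steps, dtype=int)


def generate_episode(config: TaskConfig, rng_state) -> Episode:
    """Generate one SAH episode.

    Gates occur at step 0 and thereafter at random spacings; held samples take
    the signal values at gate steps and stay constant in between; targets are
    the held samples delayed ``target_delay`` steps.  Steps before the first
    defined target are masked out.
    """
    rng = as_rng(rng_state)
    n = config.epoch_length
    n_sig = config.n_signals
    signals = _draw_signals(config, n, rng)
    gate = np.zeros(n)
    if n > 0:
        gate[_gate_steps(config, n, rng)] = 1.0

    samples = np.empty_like(signals)
    held = np.zeros(n_sig)
    for t in range(n):
        if gate[t] == 1.0:
            held = signals[t]
        samples[t] = held

    d = config.target_delay
    targets = np.zeros_like(signals)
    valid = np.zeros(n, dtype=bool)
    if n > d:
        targets[d:] = samples[: n - d]
        valid[d:] = True

    inputs = np.column_stack([gate, signals, np.ones(n)])
    return Episode(inputs=inputs, targets=targets, valid_mask=valid, config=config)


def episode_stream(config: TaskConfig, n_episodes: int, rng_state):
    """Yield ``n_episodes`` episodes drawn from one generator stream."""
    rng = as_rng(rng_state)
    for _ in range(n_episodes):
        yield generate_episode(config, rng)


def signal_correlation(alpha: float, n_steps: int, rng_state, config: TaskConfig | None = None) -> float:
    """Pearson correlation of the two signal columns over a long stream.

    Diagnostic for the degree of signal commonality; requires the dual task.
    """
    if n_steps < 100:
        raise ValueError("n_steps must be >= 100 for a stable estimate")
    if config is None:
        config = TaskConfig(alpha=alpha, epoch_length=n_steps, target_delay=0)
    else:
        config = replace(config, alpha=alpha, epoch_length=n_steps, target_delay=0)
    if config.n_signals != 2:
        raise ValueError("signal correlation requires the two-signal task")
    rng = as_rng(rng_state)
    signals = _draw_signals(config, n_steps, rng)
    if alpha == 1.0:
        return 1.0
    return float(np.corrcoef(signals[:, 0], signals[:, 1])[0, 1])
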