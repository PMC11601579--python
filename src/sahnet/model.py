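"""High-level Model / Results interface.

:class:`SampleHoldModel` bundles a task definition and a network architecture;
``fit`` trains (and optionally reduces) a network and returns a
:class:`SampleHoldResults` carrying the trained network, checkpoint networks,
the training history, and evaluation / analysis methods.

Example
-------
>>> from sahnet import SampleHoldModel
>>> model = SampleHoldModel.from_alpha(0.0)
>>> res = model.fit(seed=1, reduce=True)      # full 13,500-epoch schedule
>>> res.final_error                            # percent RMS on fresh episodes
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import analysis
from .network import Network, NetworkSpec, build_network, save_network
from .reducer import ReductionSchedule, run_reduction_schedule
from .task import TaskConfig
from .trainer import TrainingConfig, TrainingHistory, train, evaluate_network

__all__ = ["SampleHoldModel", "SampleHoldResults"]


@dataclass
class SampleHoldModel:
    """A sample-and-hold memory network to be fitted to its task.

    Parameters
    ----------
    task : TaskConfig
        Episode generator settings (common-mode fraction, epoch length, ...).
    spec : NetworkSpec
        Architecture: unit counts, activation offset and temperature, bounds.
    training : TrainingConfig
        Optimizer settings (line search, weight decay amount, bookkeeping).
    """

    task: TaskConfig = field(default_factory=TaskConfig)
    spec: NetworkSpec | None = None
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self):
        if self.spec is None:
            self.spec = NetworkSpec(n_task_inputs=self.task.n_signals + 1)
        if self.spec.n_task_inputs != self.task.n_signals + 1:
            raise ValueError(
                f"network expects {self.spec.n_task_inputs - 1} signal(s), "
                f"task provides {self.task.n_signals}"
            )

    @classmethod
    def from_alpha(cls, alpha: float, **kwargs) -> "SampleHoldModel":
        """Model for the dual-signal task at common-mode fraction ``alpha``."""
        task = kwargs.pop("task", None) or TaskConfig(alpha=alpha)
        return cls(task=replace(task, alpha=alpha), **kwargs)

    def build(self, seed=None) -> Network:
        """A freshly initialized (untrained) network for this model."""
        return build_network(self.spec, rng_state=seed)

    def fit(
        self,
        n_epochs: int = 5000,
        seed=0,
        reduce: bool = False,
        schedule: ReductionSchedule | None = None,
        network: Network | None = None,
    ) -> "SampleHoldResults":
        """Train a network on the task.

        With ``reduce=True`` the full staged reduction schedule is executed
        (training, weight decay/deletion, unit deletion; ``n_epochs`` is
        ignored in favour of the schedule) and checkpoint networks are kept.
        Otherwise the network is trained for ``n_epochs`` plain epochs.
        """
        ss = np.random.SeedSequence(seed) if not isinstance(
            seed, np.random.SeedSequence) else seed
        init_seed, run_seed, eval_seed = ss.spawn(3)
        net = network.copy() if network is not None else build_network(
            self.spec, rng_state=np.random.default_rng(init_seed))
        eval_key = int(eval_seed.generate_state(1)[0] % (2**31))

        if reduce:
            schedule = schedule or ReductionSchedule()
            result = run_reduction_schedule(net, self.task, schedule,
                                            rng_state=run_seed, training=self.training)
            history, checkpoints = result.history, result.checkpoints
        else:
            history = train(net, self.task, n_epochs, self.training,
                            rng_state=np.random.default_rng(run_seed),
                            eval_rng_state=eval_key)
            checkpoints = {n_epochs: net.copy()}
        final_error = evaluate_network(net, self.task, self.training.eval_episodes,
                                       np.random.default_rng(eval_key))
        return SampleHoldResults(
            model=self, network=net, checkpoints=checkpoints,
            history=history, final_error=final_error, seed=seed,
        )


@dataclass
class SampleHoldResults:
    """Fitted network plus training diagnostics and analysis entry points."""

    model: SampleHoldModel
    network: Network
    checkpoints: dict[int, Network]
    history: TrainingHistory
    final_error: float
    seed: object = None

    @property
    def task(self) -> TaskConfig:
        return self.model.task

    @property
    def unreduced(self) -> Network:
        """Checkpoint network at the end of initial training."""
        return self.checkpoints[sorted(self.checkpoints)[0]]

    @property
    def reduced(self) -> Network:
        """Final checkpoint network."""
        return self.checkpoints[sorted(self.checkpoints)[-1]]

    # --- evaluation -------------------------------------------------------
    def evaluate(self, alpha: float | None = None, n_epochs: int = 100,
                 seed=0, network: Network | None = None) -> float:
        """Percent RMS error on fresh episodes, optionally at another alpha."""
        task = self.task if alpha is None else self.task.with_alpha(alpha)
        return analysis.evaluate(network or self.network, task, n_epochs, seed)

    def error_across_common_mode(self, tested_alphas=analysis.ALPHA_GRID,
                                 n_epochs: int = 100, seed=0) -> dict[float, float]:
        """This network's error at every tested common-mode level."""
        ss = np.random.SeedSequence(seed)
        return {
            float(a): analysis.evaluate(
                self.network, self.task.with_alpha(float(a)), n_epochs,
                np.random.default_rng(s.generate_state(1)[0] % (2**31)))
            for a, s in zip(tested_alphas, ss.spawn(len(tested_alphas)))
        }

    def lesion_report(self, input_names, n_epochs: int = 100, seed=0):
        return analysis.lesion_report(self.network, self.task, input_names,
                                      n_epochs, seed)

    def solution_type(self, seed=0, config=None) -> str:
        return analysis.solution_type(self.network, self.task, seed, config)

    def attractor_map(self, network: Network | None = None, **kwargs):
        """Attractor map of the unreduced checkpoint (the pre-pruning network)."""
        return analysis.attractor_map(network or self.unreduced, **kwargs)

    def relaxation_trace(self, sample_values, n_steps: int = 100, **kwargs):
        return analysis.relaxation_trace(self.network, sample_values, n_steps, **kwargs)

    # --- reporting ----------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit report: task, architecture, checkpoint table."""
        spec = self.model.spec
        task = self.task
        lines = [
            "Sample-and-hold network fit",
            "=" * 60,
            f"Task: {task.n_signals} signal(s), common mode alpha = {task.alpha:.2f}, "
            f"{task.epoch_length}-step epochs",
            f"Architecture: {spec.n_excitatory}E + {spec.n_inhibitory}I hidden, "
            f"{spec.n_outputs} output(s), offset {spec.offset:g}, T = {spec.temperature:g}",
            f"Final: {self.network.count_live_units()} hidden units, "
            f"{self.network.count_weights()} weights, "
            f"{self.final_error:.2f}% test error",
            "-" * 60,
            f"{'epoch':>8} {'hidden':>8} {'weights':>8} {'% error':>9}",
        ]
        for r in self.history.records:
            lines.append(
                f"{r.epoch:>8d} {r.n_hidden_units:>8d} {r.n_weights:>8d} "
                f"{r.percent_error:>9.2f}"
            )
        return "\n".join(lines)

    def save(self, directory) -> None:
        """Write checkpoint networks (JSON) and the history (CSV)."""
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for epoch, net in self.checkpoints.items():
            save_network(net, directory / f"network_epoch{epoch}.json")
        save_network(self.network, directory / "network_final.json")
        self.history.to_csv(directory / "history.csv")

    # --- plotting -----------------------------------------------------------
    def plot_history(self, ax=None):
        """Percent test error vs training epoch."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history.epochs, self.history.percent_errors, marker="o")
        ax.set_xlabel("training epoch")
        ax.set_ylabel("test error (%)")
        ax.set_title(f"alpha = {self.task.alpha:.1f}")
        return ax

    def plot_attractor_map(self, output: int = 0, ax=None, **kwargs):
        """Heat map of one output's attractor values over the sample grid."""
        import matplotlib.pyplot as plt

        amap = self.attractor_map(**kwargs)
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(amap.output(output).T, origin="lower", vmin=0, vmax=1,
                       extent=(0, 1, 0, 1), cmap="viridis")
        ax.set_xlabel("sample 1")
        ax.set_ylabel("sample 2")
        ax.set_title(f"output {output + 1} attractor values")
        ax.figure.colorbar(im, ax=ax)
        return ax
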