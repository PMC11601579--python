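"""Evaluation of trained networks.

Percent-error measurement on fresh test streams, cross-common-mode error
matrices (every trained network tested at every common-mode level), lesion
tests that remove all outgoing weights of an input to quantify how strongly
each output depends on each signal, fixed-point attractor maps obtained by
pulsing a sample and letting the network relax with no further input, and a
coarse classification of the solution a trained network has found
(decoupled / common-differential / averaging).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import Network, run_episode, run_inputs
from .task import TaskConfig, generate_episode, as_rng
from .trainer import rms_error, evaluate_network

__all__ = [
    "ALPHA_GRID",
    "CrossCMMatrix",
    "AttractorMap",
    "LesionReport",
    "ClassifierConfig",
    "evaluate",
    "per_output_errors",
    "cross_cm_matrix",
    "lesion_inputs",
    "lesion_report",
    "attractor_map",
    "relaxation_trace",
    "attractor_count",
    "solution_type",
]

ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


def evaluate(network: Network, task: TaskConfig, n_epochs: int = 100, rng_state=None) -> float:
    """Mean percent RMS error over ``n_epochs`` fresh episodes (valid steps)."""
    return evaluate_network(network, task, n_epochs, rng_state)


def per_output_errors(network: Network, task: TaskConfig, n_epochs: int = 100,
                      rng_state=None) -> np.ndarray:
    """Mean percent RMS error per output unit over fresh episodes."""
    rng = as_rng(rng_state)
    out_sl = network.output_slice
    n_out = network.spec.n_outputs
    errs = np.empty((n_epochs, n_out))
    for i in range(n_epochs):
        ep = generate_episode(task, rng)
        trace = run_episode(network, ep)
        for k in range(n_out):
            errs[i, k] = rms_error(trace[:, out_sl][:, k], ep.targets[:, k], ep.valid_mask)
    return errs.mean(axis=0) * 100.0


# --- cross-common-mode matrix -------------------------------------------------

@dataclass
class CrossCMMatrix:
    """Mean percent error indexed by (trained alpha, tested alpha)."""

    trained_alphas: np.ndarray
    tested_alphas: np.ndarray
    mean_percent_error: np.ndarray
    n_test_epochs: int = 100

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.mean_percent_error,
            index=pd.Index(self.trained_alphas, name="trained_alpha"),
            columns=pd.Index(self.tested_alphas, name="tested_alpha"),
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def row(self, trained_alpha: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.trained_alphas - trained_alpha)))
        return self.mean_percent_error[i]

    def diagonal(self) -> np.ndarray:
        """Each network's error at its own trained level (requires matching grids)."""
        out = np.empty(len(self.trained_alphas))
        for i, a in enumerate(self.trained_alphas):
            j = int(np.argmin(np.abs(self.tested_alphas - a)))
            out[i] = self.mean_percent_error[i, j]
        return out


def cross_cm_matrix(
    networks: dict[float, Network],
    task_template: TaskConfig,
    rng_state=None,
    tested_alphas=ALPHA_GRID,
    n_test_epochs: int = 100,
) -> CrossCMMatrix:
    """Evaluate every trained network at every tested common-mode level.

    Test streams are matched: all networks see the same episodes at a given
    tested alpha.
    """
    if not networks:
        raise ValueError("no networks supplied")
    trained = np.asarray(sorted(networks), dtype=float)
    tested = np.asarray(tested_alphas, dtype=float)
    ss = np.random.SeedSequence(rng_state) if not isinstance(
        rng_state, np.random.SeedSequence) else rng_state
    col_seeds = ss.spawn(len(tested))
    errors = np.empty((len(trained), len(tested)))
    for jc, (a_test, seed) in enumerate(zip(tested, col_seeds)):
        cfg = task_template.with_alpha(float(a_test))
        for ir, a_train in enumerate(trained):
            errors[ir, jc] = evaluate_network(
                networks[float(a_train)], cfg, n_test_epochs,
                np.random.default_rng(seed.generate_state(1)[0] % (2**31)))
    return CrossCMMatrix(trained, tested, errors, n_test_epochs)


# --- lesions ------------------------------------------------------------------

def lesion_inputs(network: Network, input_names) -> Network:
    """Copy of ``network`` with all outgoing weights of the named inputs removed."""
    if isinstance(input_names, str):
        input_names = [input_names]
    out = network.copy()
    for name in input_names:
        idx = out.input_index(name)
        out.mask[idx, :] = False
        out.weights[idx, :] = 0.0
    return out


@dataclass
class LesionReport:
    """Per-output percent error before/after an input lesion."""

    lesioned_inputs: tuple[str, ...]
    error_before: np.ndarray
    error_after: np.ndarray

    @property
    def decoupling_index(self) -> np.ndarray:
        """Error increase per output attributable to the lesion (pp)."""
        return self.error_after - self.error_before

    def to_dataframe(self) -> pd.DataFrame:
        n_out = len(self.error_before)
        return pd.DataFrame(
            {
                "output": [f"output{k + 1}" for k in range(n_out)],
                "error_before": self.error_before,
                "error_after": self.error_after,
                "error_increase": self.decoupling_index,
            }
        )


def lesion_report(network: Network, task: TaskConfig, input_names,
                  n_epochs: int = 100, rng_state=None) -> LesionReport:
    """Measure each output's error before and after lesioning the inputs."""
    if isinstance(input_names, str):
        input_names = [input_names]
    ss = np.random.SeedSequence(rng_state) if not isinstance(
        rng_state, np.random.SeedSequence) else rng_state
    seed = ss.generate_state(1)[0] % (2**31)
    before = per_output_errors(network, task, n_epochs, np.random.default_rng(seed))
    lesioned = lesion_inputs(network, input_names)
    after = per_output_errors(lesioned, task, n_epochs, np.random.default_rng(seed))
    return LesionReport(tuple(input_names), before, after)


# --- attractors ---------------------------------------------------------------

@dataclass
class AttractorMap:
    """Asymptotic output values over a grid of held sample pairs."""

    sample1_values: np.ndarray
    sample2_values: np.ndarray
    values: np.ndarray  # (len(s1), len(s2), n_outputs)
    relaxation_steps: int = 100

    def output(self, k: int) -> np.ndarray:
        return self.values[:, :, k]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, s1 in enumerate(self.sample1_values):
            for j, s2 in enumerate(self.sample2_values):
                row = {"sample1": s1, "sample2": s2}
                for k in range(self.values.shape[2]):
                    row[f"output{k + 1}"] = self.values[i, j, k]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def inter_output_correlation(self) -> float:
        """Grid correlation between the two outputs' attractor values."""
        if self.values.shape[2] < 2:
            raise ValueError("needs two outputs")
        return float(np.corrcoef(self.values[:, :, 0].ravel(),
                                 self.values[:, :, 1].ravel())[0, 1])


def _pulse_inputs(network: Network, samples, n_steps: int, bias_during_relaxation: bool):
    """Step 0: gate + sample values + bias on; afterwards all inputs at zero
    (the bias can be kept on via the flag)."""
    spec = network.spec
    n_in = spec.n_inputs
    inputs = np.zeros((n_steps + 1, n_in))
    inputs[0, 0] = 1.0  # gate
    samples = np.atleast_1d(samples)
    n_sig = spec.n_task_inputs - 1
    if len(samples) != n_sig:
        raise ValueError(f"expected {n_sig} sample value(s), got {len(samples)}")
    inputs[0, 1:1 + n_sig] = samples
    if spec.has_bias:
        inputs[0, -1] = 1.0
        if bias_during_relaxation:
            inputs[1:, -1] = 1.0
    return inputs


def attractor_map(
    network: Network,
    relaxation_steps: int = 100,
    grid=None,
    bias_during_relaxation: bool = True,
) -> AttractorMap:
    """Map output fixed points over an 11 x 11 grid of held sample pairs.

    Each grid point presents Gate=1, Signal1=s1, Signal2=s2 and the bias for a
    single time-step, then gate and signals are held at zero for
    ``relaxation_steps`` steps while the bias stays at 1 (set
    ``bias_during_relaxation=False`` for a fully autonomous relaxation; the
    constant bias is what keeps the stored value alive, so the autonomous
    variant collapses to the activation leak level).  The output values at the
    final step are the attractor values.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.01, 0.1), 1)
    grid = np.asarray(grid, dtype=float)
    n_sig = network.spec.n_task_inputs - 1
    if n_sig != 2:
        raise ValueError("attractor_map requires a two-signal network")
    out_sl = network.output_slice
    values = np.empty((len(grid), len(grid), network.spec.n_outputs))
    for i, s1 in enumerate(grid):
        for j, s2 in enumerate(grid):
            inputs = _pulse_inputs(network, (s1, s2), relaxation_steps,
                                   bias_during_relaxation)
            trace = run_inputs(network, inputs)
            values[i, j] = trace[-1, out_sl]
    return AttractorMap(grid, grid.copy(), values, relaxation_steps)


def relaxation_trace(
    network: Network,
    sample_values,
    n_steps: int = 100,
    bias_during_relaxation: bool = True,
) -> np.ndarray:
    """Full activity trace of the single-pulse-then-silence protocol.

    Row 0 is the pulse step; rows 1..n_steps are the input-free relaxation.
    Useful for plotting convergence to fixed points and temperature
    bifurcation diagrams.
    """
    if n_steps == 0:
        return np.zeros((0, network.n_units))
    inputs = _pulse_inputs(network, sample_values, n_steps, bias_during_relaxation)
    return run_inputs(network, inputs)


def attractor_count(
    network: Network,
    output: int = 0,
    initial_samples=None,
    n_steps: int = 100,
    gap: float = 0.05,
) -> int:
    """Number of distinct terminal output values across initial sample levels.

    Terminal values are sorted and split into clusters wherever the gap
    between neighbours exceeds ``gap``; the cluster count is the attractor
    count (1 = single fixed point, 2 = bistable, ...).
    """
    if initial_samples is None:
        initial_samples = np.round(np.arange(0.0, 1.01, 0.1), 1)
    n_sig = network.spec.n_task_inputs - 1
    out_idx = network.output_slice.start + output
    finals = []
    for s in initial_samples:
        trace = relaxation_trace(network, [s] * n_sig, n_steps)
        finals.append(trace[-1, out_idx])
    finals = np.sort(finals)
    return int(1 + np.sum(np.diff(finals) > gap))


# --- solution classification --------------------------------------------------

@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds for :func:`solution_type`.

    ``decoupling_threshold`` is the maximum lesion-induced error increase (pp)
    on the opposite output for the network to count as decoupled;
    ``averaging_correlation`` is the minimum correlation between the two
    output traces on independent-signal (alpha=0) probes for the averaging
    class.  Values are implementation choices placed at the qualitative
    boundaries where the solution families change.
    """

    decoupling_threshold: float = 2.0
    averaging_correlation: float = 0.95
    n_probe_epochs: int = 100


def _output_agreement(network: Network, task: TaskConfig, n_epochs: int, rng) -> float:
    """Correlation of the two output traces under independent-signal probes."""
    probe = task.with_alpha(0.0)
    o1, o2 = [], []
    out_sl = network.output_slice
    for _ in range(n_epochs):
        ep = generate_episode(probe, rng)
        trace = run_episode(network, ep)
        o1.append(trace[ep.valid_mask, out_sl.start])
        o2.append(trace[ep.valid_mask, out_sl.start + 1])
    o1, o2 = np.concatenate(o1), np.concatenate(o2)
    if o1.std() == 0 or o2.std() == 0:
        return 1.0
    return float(np.corrcoef(o1, o2)[0, 1])


def solution_type(
    network: Network,
    task: TaskConfig,
    rng_state=None,
    config: ClassifierConfig | None = None,
) -> str:
    """Classify the solution a trained dual-signal network implements.

    Returns ``"averaging"`` when the two outputs are nearly identical
    functions of the inputs (both track the mean sample), ``"decoupled"``
    when each output is insensitive to lesioning the opposite signal, and
    ``"common-differential"`` otherwise.
    """
    if network.spec.n_task_inputs - 1 != 2:
        raise ValueError("solution_type requires a two-signal network")
    config = config or ClassifierConfig()
    ss = np.random.SeedSequence(rng_state) if not isinstance(
        rng_state, np.random.SeedSequence) else rng_state
    s_agree, s_l2, s_l1 = ss.spawn(3)

    agreement = _output_agreement(network, task, config.n_probe_epochs,
                                  np.random.default_rng(s_agree))
    if agreement > config.averaging_correlation:
        return "averaging"

    rep2 = lesion_report(network, task, "signal2", config.n_probe_epochs, s_l2)
    rep1 = lesion_report(network, task, "signal1", config.n_probe_epochs, s_l1)
    cross1 = rep2.decoupling_index[0]  # effect of signal2 lesion on output1
    cross2 = rep1.decoupling_index[1]  # effect of signal1 lesion on output2
    if cross1 < config.decoupling_threshold and cross2 < config.decoupling_threshold:
        return "decoupled"
    return "common-differential"
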