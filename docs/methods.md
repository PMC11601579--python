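# Methods

## The model

`sahnet` simulates and trains discrete-time recurrent neural networks on a
*sample-and-hold* (SAH) short-term memory task.  Units are arranged as input,
hidden and output layers.  Non-input activity evolves with a one-step delay,

    A_i(t) = f( Σ_j A_j(t−1) W_ji − offset ),     f(x) = 1 / (1 + e^(−x/T)),

with a logistic activation saturating at 0 and 1.  The **offset** (default 4)
shifts the logistic so units are nearly silent (f(−4) ≈ 0.018) without
positive drive; the **temperature** T (default 1) is the inverse slope of the
activation about its midpoint and is only varied in the attractor analyses.

Connectivity follows Dale's principle: each hidden unit is excitatory (all
outgoing weights in [0.001, 8]) or inhibitory ([−8, −0.001]); input and bias
weights are unsigned in [−8, 8].  Self-connections and
inhibitory→inhibitory connections are disallowed; task inputs project only
to hidden units; a constant bias input projects to hidden and output units
and serves as a trainable per-unit threshold; hidden units project to hidden
and output units; output units project nowhere.  The default dual-task
architecture (3 task inputs + bias, 16 excitatory and 16 inhibitory hidden
units, 2 outputs) has exactly 946 trainable weights.

## The task

Each episode is `epoch_length` (default 20) time-steps.  Two signals share a
common-mode component controlled by α ∈ [0, 1]: per step, draw
C ~ U(0, α) and independent U_k ~ U(0, 1−α) and set

    Signal_k = C + U_k ,    k = 1, 2 .

Signals always span [0, 1] with mean 0.5; their correlation is
α² / (α² + (1−α)²), rising from 0 (independent) to 1 (identical).  A binary
gate fires at step 0 and then at spacings drawn uniformly from {3, …, 6}
steps.  The held sample takes the signal value at each gate and stays
constant in between; targets are the held samples delayed 2 steps (matching
the input→hidden→output propagation delay), and the first 2 steps of an
episode are excluded from the error.  With `n_signals=1` the generator
reproduces the classic single-input SAH task.

Two constructions for the signals appear in descriptions of this task: a
literal mixing form `α·C + U(0, 1−α)` and the additive form above.  The
literal form compresses the signal range at intermediate α (maximum
1 − α + α², e.g. 0.79 at α = 0.7), which changes the marginal distribution
across α levels and makes cross-common-mode testing confounded by
distribution shift.  We use the additive form, under which every α level
presents the same [0, 1] range.

The optional `distribution_matched` variant (defined for α ∈ {0, 1} and the
single-signal task) keeps the level of commonality but draws each signal as
the sum of U(0, 0.1) and U(0, 0.9) components, giving the same marginal
distribution as the α = 0.1/0.9 tasks.  It exists to make learning-speed
comparisons across α levels fair and is not used by the standard pipeline.

## Training

The objective descended is the mean squared output error over valid steps of
one freshly generated episode per epoch; reported errors are the RMS of the
same quantity (× 100 for percent).  MSE is used for gradients because the
derivative of the RMS is singular at zero error.

Per epoch:

1. Backpropagate the exact gradient through the unrolled 20-step dynamics
   (verified against central finite differences to < 10⁻⁴ relative error).
2. Form two candidate directions: the plain negative gradient, and a
   Polak–Ribière conjugate-gradient combination of the current and previous
   gradients (the "second-order" estimate; the memory is reset whenever the
   network structure changes).
3. Backtracking line search along each unit-normalized direction from an
   adaptive initial step (doubled after success, halved after failure,
   ≤ 12 error evaluations per direction).  Candidates are projected into the
   sign-class bounds before evaluation, so an accepted step never violates
   constraints and never increases the error on the training episode.
4. Accept whichever direction's best candidate has the lower episode error;
   if neither improves, the weights are unchanged that epoch.
5. During decay phases, shrink every weight magnitude by 0.001 toward zero.

The line-search step is capped at 3 (in units of the normalized direction).
This matters in two ways: fully minimizing each 20-step episode's error lets
single episodes drag the weights far from the task optimum and training
stalls around 40–50% error, while very large caps occasionally allow a
catastrophic step that spikes the test error by tens of points mid-run.  The
capped search descends to the few-percent regime within a few thousand
epochs and stays there.  The cap, the ≤ 12 evaluations and the initial step
0.5 are exposed in `TrainingConfig`.

Weight initialization is uniform in (−1, 1) mapped into each class's sign
and clipped to bounds.  Initial activities are zero at episode start.
Training, evaluation, probing and initialization use independent random
streams spawned from one root seed, so runs are exactly reproducible.

## Reduction

The standard schedule totals 13,500 epochs:

| phase | epochs | action |
|---|---|---|
| initial training | 5000 | plain training (checkpoint: *unreduced*) |
| 3 × decay iteration | 3 × (1000 + 1000) | decay on, delete weights < 0.05, decay off (checkpoint at 11,000: *partially reduced*) |
| unit round 1 | 1000 + 500 | delete inactive units, retrain, decay, delete small weights |
| unit rounds 2–3 | 2 × 500 | delete inactive units, retrain (checkpoint: *reduced*) |

Weight deletion removes masked connections permanently (strict `<` at the
threshold).  Unit deletion simulates 200 steps of fresh task input and
removes hidden units whose peak activity stays below (1 − α)/2, with a floor
of 0.01 so the threshold never reaches zero at α = 1.  Note the idle
activity of an isolated unit is f(−4) ≈ 0.018 > 0.01, so at α = 1 only units
actively suppressed below their idle level are removed; the floor is
exposed in `ReductionSchedule`.  Deleted weights and units never return.
The weight-deletion threshold 0.05 is chosen so that a 1000-epoch decay
phase (total magnitude drain 1.0) leaves load-bearing weights, which
training keeps re-inflating, clearly above it.

## Analysis

* **Evaluation**: mean percent RMS error over 100 fresh 20-step episodes.
* **Cross-common-mode matrix**: every trained network evaluated at every
  tested α ∈ {0.0, …, 1.0}; test streams are matched across networks within
  a tested level.
* **Lesions**: removing all outgoing weights of one input; the *decoupling
  index* of an (input, output) pair is the lesion-induced increase in that
  output's percent error.
* **Attractor maps**: present Gate = 1 and a sample pair for one step, then
  hold gate and signals at zero for 100 steps and read the outputs.  The
  constant bias input stays at 1 during relaxation by default: the bias
  weights implement each unit's operating threshold, and silencing them
  collapses every trained network to its activation leak level, erasing the
  stored value.  A fully autonomous variant
  (`bias_during_relaxation=False`) is available.  At temperature 1 some
  trained networks relax all the way to a sample-independent fixed point
  before the 100-step mark (which trained level and output does so is
  seed-dependent); trend statistics that compare interdependence across
  trained α therefore use 25-step maps, where every network still carries
  its stored samples, while the map protocol itself keeps the 100-step
  default.
* **Attractor counting**: terminal output values across initial samples
  {0.0, …, 1.0} are sorted and split where neighbours differ by more than
  0.05; the cluster count is the number of attractors.  Temperatures around
  0.5 give bistable storage in trained single-input networks; by T ≈ 3 the
  fixed points merge.
* **Error baselines**: a constant 0.5 output scores √(1/12) ≈ 28.9% against
  uniform targets; a network that outputs the mean of the two held samples
  scores √(1/24) ≈ 20.4% per output on independent (α = 0) signals, since
  its per-output residual is (t₁ − t₂)/2.  Averaging-type networks tested
  at α = 0 land near the 20.4% floor.
* **Solution classification**: *averaging* if the two output traces
  correlate > 0.95 on independent-signal (α = 0) probes; else *decoupled*
  if both cross-lesion decoupling indices are < 2 percentage points at the
  trained α; else *common-differential*.  The thresholds sit at the
  qualitative boundaries where the solution families change (around α ≈
  0.3–0.4 and 0.7–0.8) and live in `ClassifierConfig`.

## Problem sizes and determinism

Default experiments use the 946-weight architecture, 20-step epochs, 100
test episodes per error figure, and the full 13,500-epoch schedule (tens of
seconds per run on one core).  All stochastic stages consume generators
spawned from a single root seed; simulation itself is deterministic, so a
saved network plus a seed reproduces every figure bit-for-bit.

## What the generator does and does not emulate

The synthetic task *is* the study system: there is no external data.  The
generator reproduces the uniform signal statistics, gate spacing and delay
structure exactly as specified.  It does not model temporally correlated
natural signals, non-uniform value distributions, or variance-normalized
inputs; conclusions about trained networks therefore concern this idealized
stimulus family, not natural sensory streams.

## Known limitations

* The "second-order" training direction is a conjugate-gradient surrogate;
  true curvature information is not computed.
* With high common mode (α ≥ 0.8) unit deletion at the 0.01 floor removes
  little, so reduced high-α networks stay larger than mid-α ones.
* The solution-type classifier is threshold-based and can flip for networks
  near the family boundaries (by design, the transitions are gradual).
* The separation transition of this optimizer sits near α ≈ 0.55 with
  20-step epochs: networks trained at α = 0.5 usually split into largely
  independent sub-networks (cross-lesion indices of order 1 pp), while
  α = 0.6 runs often retain partial averaging and land at 4–8% error.
  Where exactly this transition falls is sensitive to the optimizer and to
  epoch length, and run-to-run variation around it is large.
* Training on one 20-step episode per epoch makes run-to-run spread of
  final errors a substantial fraction of their mean (seeds matter; bands in
  the tests reflect this).
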