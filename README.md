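# sahnet

Sign-constrained recurrent neural networks for *sample-and-hold* (SAH)
short-term memory of one or two analog inputs with a controllable common-mode
component — training, automated network reduction, cross-common-mode
generalization analysis, and fixed-point attractor mapping.

## The problem

Sustained neural activity is a candidate mechanism for short-term memory of
analog sensory values.  A classic model task asks a recurrent network to
*sample* the value of a continuous input whenever a gate pulse fires and to
*hold* that value at its output until the next gate.  Real sensory channels
(two ears, two eyes, populations of muscle spindle afferents) rarely carry
independent signals: they share a **common mode**.  `sahnet` studies how
networks remember *two* gated signals whose commonality is parameterized: at
each time-step

    C ~ U(0, α),   Signal_k = C + U_k(0, 1 − α),   k = 1, 2,

so `α = 0` gives independent signals, `α = 1` identical ones, and the target
outputs are the gated samples delayed two time-steps.  Networks obey Dale's
principle (hidden units are purely excitatory or purely inhibitory, weights
bounded, no self-connections), use logistic units
`f(x) = 1/(1 + e^(−(x−4)/T))`, and are trained by backpropagation through
time with a line-searched descent, then pruned by weight decay, small-weight
deletion and inactivity-based unit deletion down to a minimal network.

The interesting outcomes are behavioral: depending on the trained α the
networks discover qualitatively different solutions — fully **decoupled**
sub-networks, **common + differential** mode processing, or a single
**averaging** channel — and their stored values relax to fixed-point
attractors whose number depends on the activation slope ("temperature").

## Worked example

```python
from sahnet import SampleHoldModel

model = SampleHoldModel.from_alpha(0.0)       # independent signals
res = model.fit(seed=1, reduce=True)          # full 13,500-epoch schedule
print(res.summary())
```

prints (abridged; the full table has one row every 500 epochs):

```
Sample-and-hold network fit
============================================================
Task: 2 signal(s), common mode alpha = 0.00, 20-step epochs
Architecture: 16E + 16I hidden, 2 output(s), offset 4, T = 1
Final: 8 hidden units, 44 weights, 4.79% test error
------------------------------------------------------------
   epoch   hidden  weights   % error
       0       32      946     54.85
    5000       32      946      3.44
   11000       32       55      6.33
   13500        8       44      4.80
```

The untrained 946-weight network starts near 55% RMS error (chance level for
this task; a network that always outputs 0.5 scores `sqrt(1/12) ≈ 29%`).
Plain training brings it to ~3% by epoch 5000; the staged reduction then
removes 95% of the weights and three-quarters of the hidden units while the
error stays at the few-percent level — the pruned network has kept the
underlying algorithm.  From the same object you can ask *how* it solved the
task:

```python
res.solution_type()                  # -> 'decoupled'
res.lesion_report("signal2").to_dataframe()   # output1 barely moves
res.error_across_common_mode()       # flat 4-5% row across tested alpha
res.attractor_map()                  # 11x11 grid of stored-value fixed points
```

A network trained at high common mode (`from_alpha(0.9)`) instead returns
`'averaging'` and collapses to ~29% error when tested on independent
signals, while mid-range training (`from_alpha(0.5)`) yields
`'common-differential'` processing.

## Command line

```sh
sahnet train --alpha 0.0 --seed 1 --out runs      # one full schedule
sahnet sweep --seed 1 --out runs                  # alpha = 0.0 ... 1.0
sahnet crosstest --sweep-dir runs --out cross.csv # trained x tested errors
sahnet attractors --network runs/alpha_000/network_final.json
sahnet lesion --network ... --alpha 0.0 --inputs signal2
sahnet classify --network ... --alpha 0.0
```

Every run directory contains the checkpoint networks (epochs 5000 / 11,000 /
13,500) as versioned JSON, the training history CSV, and a manifest with the
full configuration and seeds.

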