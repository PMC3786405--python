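# downsel

Integrate-and-fire network simulations of sleep-dependent **synaptic
down-selection**: the hypothesis that sleep benefits memory not by replaying
and further strengthening circuits, but by renormalising synaptic strength —
competitively depressing the synapses that fit least well with the brain's
stored structure, while sparing those that are reactivated coherently.

The package is for computational neuroscientists who want a small, fully
reproducible model in which wake learning, slow-wave sleep, recall testing,
and the classic sleep-and-memory phenomena (procedural consolidation,
declarative interference, cued reactivation, gist extraction, memory
integration) can be simulated end to end in seconds.

## The model

Networks are built from densely interconnected *neuronal groups* of 18
binary integrate-and-fire neurons evaluated on a 1 ms grid.  Per step, a
neuron's membrane potential is

```
V_preFB = V_FF + V_noise                      (voltage-independent drive)
V       = V_preFB + V_intra                   if V_preFB <= Z_th
V       = V_preFB + V_intra + V_FB(t-1, t-2)  otherwise
A(t)    = 1  iff  V > threshold,   threshold = 2 W_max,  Z_th = W_max / 5
```

with the membrane reset every step.  Feedforward synapses (AMPA-like) are
driving; feedback synapses (NMDA-like) are voltage-dependent and integrate
spikes over the past two steps; three noise synapses per neuron (weight
`W_max`) model extrinsic input, with activation probability 20 % in sleep
up-states and 5 % in down-states.

Plastic synapses are grouped into **dendritic domains** (several feedforward
plus feedback synapses on one neuron).  In wake, a domain whose feedforward
*and* feedback inputs coincide while the neuron fires a sustained burst has
its active synapses potentiated (`alpha = 0.1` feedforward / `0.05`
feedback).  In sleep, a bursting neuron *depresses* the active synapses of
any domain whose input was mismatched (`beta = 0.01` / `0.005`), while
matched domains are protected — the down-selection rule.  Recall is scored
as the percentage of trials in which stimulating a start group activates the
learned groups (at least 50 % of a group co-firing) without activating any
spurious group, and the signal-to-noise ratio S/N = correct / incorrect
recalls.

## Worked example

```python
import downsel as ds

report = ds.run_experiment("procedural", seeds=[0, 1, 2], n_trials=20,
                           conditions=["baseline", "wake", "cycle1"])
for cond, stats in report.aggregate().items():
    print(f"{cond:>10}: recall {stats['recall_mean']:5.1f}%  "
          f"incorrect {stats['incorrect_mean']:5.1f}%  S/N {stats['s_n']:.2f}")
```

prints

```
  baseline: recall   0.0%  incorrect   1.7%  S/N 0.00
      wake: recall  91.7%  incorrect   8.3%  S/N 11.00
    cycle1: recall 100.0%  incorrect   0.0%  S/N inf
```

The untrained six-group channel recalls nothing.  After 10 s of pairwise
sequence training (A=>B, B=>C, C=>D, with 10 % erroneous presentations) the
sequence is recalled on most trials but spurious routes occasionally fire
(the incorrect recalls).  One 10 s period of slow-wave sleep under
down-selection removes the spurious responses while the trained chain
survives — consolidation purely by depression.

The same interface drives the other experiments:
`ds.run_experiment("declarative", ...)` (8 paired associates, cuing during
sleep), `ds.run_gist(seed)` (hierarchical gist extraction),
`ds.run_percolation(seed)` (top-down vs bottom-up spontaneous activity),
`ds.run_integration(seed, "substantial" | "single")` (integration of new
with old memories), and `ds.run_wake_renormalization(seed)` (the hazard of
renormalising during wake).  From a shell:

```bash
downsel run procedural --seeds 0..9 --out results/
downsel table 1 --n-seeds 20
downsel validate-config my_overrides.yaml
```

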