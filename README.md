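# connlif

Connectome-constrained leaky integrate-and-fire (LIF) network simulation,
for systems neuroscientists who want to turn a wiring diagram into testable
activity predictions. Given a directed synapse table (who connects to whom,
with how many synapses) and per-site neurotransmitter predictions, `connlif`
builds a signed synaptic weight matrix, simulates the whole network as
spiking LIF neurons under Poisson sensory drive, and runs the standard
in-silico experiment battery: activation screens, single-neuron silencing
screens, co-activation matrices, input-rate calibration, weight-shuffle
null controls, robustness sweeps, and connectivity-based clustering of
sensory neurons into modalities. A synthetic-connectome generator provides
circuits with planted ground truth, so every behaviour can be exercised
without downloading a real connectome; the Flywire-style table export is
supported as an input dialect.

## The model

Each neuron *i* carries a membrane potential *v<sub>i</sub>* and an
aggregate synaptic drive *g<sub>i</sub>*:

```
dv_i/dt = (g_i − (v_i − V_resting)) / T_mbr
dg_i/dt = −g_i / τ
g_i ← g_i + w_{j,i}   on a spike of presynaptic neuron j, after delay T_dly
```

with *V*<sub>resting</sub> = *V*<sub>reset</sub> = −52 mV,
*V*<sub>threshold</sub> = −45 mV, *T*<sub>mbr</sub> = *R*·*C* = 20 ms,
τ = 5 ms, *T*<sub>dly</sub> = 1.8 ms and refractory period 2.2 ms. The
neuron spikes when *v* ≥ *V*<sub>threshold</sub>; then *v* ← *V*<sub>reset</sub>,
*g* ← 0, and *v* is clamped for the refractory period while *g* keeps
evolving. The connection weight is

```
w_{j,i} = syn_count(j, i) × sign(j) × W_syn
```

where *W*<sub>syn</sub> = 0.275 mV is the single free parameter and
sign(*j*) ∈ {+1, −1} comes from the neuron's transmitter predictions: drop
sites with cleft score < 50, take each surviving site's arg-max
transmitter, and call the neuron inhibitory iff strictly more than half of
its sites vote GABA or glutamate (monoamines count as excitatory; a
glutamate-excitatory variant is available). Basal firing is 0 Hz, so
inhibition onto an inactive neuron has no effect — a deliberate,
consequential assumption that the gate-circuit generator demonstrates.

## Worked example

```python
import connlif as cl

P = cl.DEFAULT_PARAMS
chain = cl.make_feedforward_chain(layers=(5, 3, 1), syn_count=40, seed=7)
signs = cl.assign_neuron_signs(chain.sites)          # majority sign rule
w = cl.build_weight_matrix(chain.edges, signs, P)    # signed, Dale-consistent
res = cl.activation_screen(w, P, chain.neurons(role="sensory"),
                           rate_grid=[25, 50, 100, 150],
                           n_trials=5, duration_ms=500, seed=1)
print(res.matrix("neuron_id", "stim_rate_hz").round(1))
```

prints the trial-averaged firing rate (Hz) of every neuron at each sensory
drive rate:

```
stim_rate_hz  25.0   50.0   100.0  150.0
neuron_id
l0n0           28.4   46.4   84.4  114.8
...
l1n0           14.0   38.4   70.0   92.0
l2n0            1.2   15.2   33.6   45.2
```

Sensory neurons (`l0*`) fire near their commanded rates (capped by the
2.2 ms refractory dead time), the interneuron layer follows, and the motor
readout `l2n0` rises monotonically with drive — the screen's heatmap rows.
`cl.responder_set(res, 100)` returns every neuron with rate > 0 Hz, here
all nine. The other capabilities each have a narrative script under
`examples/` (silencing with the ≤ 80 %-of-control phenotype rule, shuffle
controls, co-activation synergy and suppression, calibration, robustness
variants, modality clustering).

A thin CLI wraps the same machinery for config-driven runs:
`connlif run config.yaml`, with subcommands `activate | silence |
coactivate | calibrate | shuffle-control | robustness | cluster | synth |
replay`; every run writes a `manifest.json` from which `connlif replay`
reproduces the outputs byte-exactly.

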