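# Methods

## Model

`connlif` simulates a directed connectome as a network of leaky
integrate-and-fire point neurons with exponential-decay synaptic drive.
Each neuron i has membrane potential v_i (mV) and drive variable g_i (mV):

    dv_i/dt = (g_i − (v_i − V_resting)) / T_mbr
    dg_i/dt = −g_i / τ

A spike of presynaptic neuron j increments g_i by w_{j,i} after the
transmission delay T_dly. When v_i ≥ V_threshold (closed boundary) the
neuron spikes: v_i ← V_reset, g_i ← 0, and for T_refractory the membrane
is clamped at V_reset with threshold checks suspended, while g_i continues
to decay and to accumulate arriving increments (they shape the
post-refractory trajectory). At t = 0, v_i = V_resting and g_i = 0.

Parameters (`LIFParameters`), all in mV/ms except the membrane constants:

| parameter | default | meaning |
|---|---|---|
| V_resting, V_reset | −52 mV | resting and post-spike potential |
| V_threshold | −45 mV | spike threshold |
| R_mbr × C_mbr | 10 kΩ·cm² × 2 µF/cm² | gives T_mbr = 20 ms, always recomputed |
| τ | 5 ms | synaptic-drive decay |
| T_refractory | 2.2 ms | absolute refractory period |
| T_dly | 1.8 ms | spike-to-effect delay |
| W_syn | 0.275 mV | per-synapse weight — the one free parameter |

The rest-to-threshold gap is 7 mV. Because the drive enters v through a
low-pass stage, a drive jump G peaks in v at only ≈ 0.157·G (the
double-exponential peak factor for T_mbr = 20, τ = 5), so one 0.275 mV
synapse moves the membrane ≈ 0.043 mV and ≈ 162 simultaneous synapses are
needed to fire a resting neuron. These closed forms anchor the test suite.

Weights: w_{j,i} = syn_count(j,i) × sign(j) × W_syn, Dale-consistent by
construction. `inh_scale` multiplies inhibitory entries only (0.5 / 1.5
probe the inhibitory:excitatory ratio); scaling excitatory weights instead
is equivalent up to a global W_syn rescale and is not separately exposed.

Sign assignment: sites with cleft score < 50 are dropped; each surviving
site votes for its arg-max transmitter among {GABA, ACh, Glu, DA, OA,
5-HT}; a neuron is inhibitory iff strictly more than half its surviving
sites vote GABA or Glu (monoamines excitatory). The boundary is read
literally: exactly half → excitatory. Ties within a site's scores are
broken by a fixed priority (the canonical column order, GABA first), so
results are reproducible; neurons whose every site falls below the cutoff
are flagged and default to +1 — if they truly have no surviving output
sites the sign is inert, and the flag lets users override. The
glutamate-excitatory variant re-runs the same rule with the inhibitory set
reduced to {GABA}.

## Integration scheme

Both ODEs are linear, so the engine advances each fixed step dt (default
0.1 ms) with the exact propagator of the coupled system: g decays by
e^(−dt/τ) and v picks up the closed-form response to an exponentially
decaying drive. This removes truncation error; the remaining
discretization effects are event quantization (spikes, deliveries and
stimulus times land on the step grid) and threshold detection at grid
points, both O(dt). Delays are implemented as a ring-buffer event queue of
length T_dly/dt; dt must not exceed T_dly or T_refractory (configuration
error otherwise — event ordering would break). The degenerate cases
τ = T_mbr (confluent propagator) and τ = ∞ (decay disabled, used by the
analytic charging checks) are handled explicitly. Refractory-release and
event-quantization comparisons carry a ~1e-9 ms slack so that interspike
intervals of exactly T_refractory are not spuriously delayed by float
rounding.

Against a separately coded scalar reference integrator at dt = 0.001 ms,
the engine at dt = 0.1 ms reproduces identical spike counts on random
small networks with spike-time discrepancies ≤ 2·dt, provided threshold
crossings are decisive; a trajectory that grazes the threshold can shift
its crossing by more than 2·dt at coarse dt without changing any count —
an inherent property of clock-driven integration worth knowing when
interpreting single spike times.

## Stimulation

Stimulated neurons receive homogeneous Poisson drive. By default the
neuron is *forced* to spike at its Poisson times (times falling in the
refractory dead period are dropped), so a commanded rate r realizes
≈ r/(1 + r·T_refractory) — 82 Hz at r = 100 Hz — the non-paralyzable
dead-time law, which the suite checks against the renewal-process
prediction. The alternative `stim_mode="synapse"` injects a suprathreshold
drive increment at the Poisson times instead (default amplitude: 1.5× the
rest-to-threshold gap divided by the PSP peak factor); unlike forcing,
this route can be vetoed by concurrent inhibition, which the disinhibition
example exploits. Every (trial, stimulus entry, neuron) triple draws from
its own seeded generator keyed by (seed, trial, entry index, crc32(id)),
so adding unrelated neurons or zero-rate entries never perturbs existing
draws — this is what makes silencing controls and co-activation marginals
bit-exact.

## Screens

Experiments follow the standard in-silico designs: trials default to
30 × 1000 ms (tests and examples use smaller sizes, noted below).
Responders are neurons with trial-averaged rate strictly > 0 Hz.
Silencing removes all *outputs* of a candidate (inputs and its own
dynamics untouched); readout rates are normalized to the unsilenced
control at the same drive and seeds, and a candidate is a phenotype iff
normalized rate ≤ 0.8 at any tested drive (default grid 50–120 Hz in
10 Hz steps). "Top N responders" are ranked by rate at the maximum grid
rate, ties broken by neuron id. Multi-neuron cell types are activated or
silenced as units via an annotation mapping. Calibration is a grid search
(smallest rate reaching, or suppressing to, the target), reporting the
bracketing rates on failure. The shuffle control permutes the multiset of
signed weights across the fixed edge set — preserving the global weight
distribution and the degree structure exactly; a rewiring variant that
also randomizes edge positions is available behind `method="rewire"`.
Shuffled matrices may violate Dale's principle; that is accepted, since
the control operates on weights, not neurons. The robustness sweep reruns
a user-declared set of binary predictions under W_syn × 0.7/1.3,
inh_scale 0.5/1.5 and the glutamate-excitatory sign variant, reporting
per-variant agreement with the default model.

## Modality clustering

Sensory neurons are represented by their vectors of synapse counts onto a
partner set (or from upstream sources) and clustered agglomeratively under
cosine distance d(x,y) = 1 − x·y/(‖x‖‖y‖), average linkage by default
(the common pairing with cosine; configurable). Cosine distance is
scale-invariant, so raw counts and per-row proportions are equivalent; a
binarized variant is exposed because cross-row count disparities can still
matter. All-zero rows are an error (cosine undefined) naming the neuron.
Either a cluster count k or a dendrogram cut height selects the partition;
two clusterings of the same neurons (e.g. by downstream vs upstream
partners) are compared by adjusted Rand index on their intersection.
Dendrograms export as newick.

## Synthetic circuits

The generators are pure functions of their arguments and seed, and their
site tables aggregate back to their edge tables exactly:

* feedforward chain — all-cholinergic layered pathway, sensory → motor;
* crossed circuit — bilateral motif whose sensory neurons project more
  strongly to the contralateral readout (40 vs 10 synapses by default),
  emulating lateralized sensorimotor routing;
* inhibitory gate — disinhibition chain (inhibitory → inhibitory →
  excitatory → readout) exhibiting the zero-basal-rate consequence:
  driving the inhibitory head alone cannot move the readout;
* random connectome — i.i.d. directed edges with discretized-lognormal
  synapse counts (heavy tail, as in real connectomes; default
  mean 0.7, σ 1.0 on the log scale) and per-neuron transmitters drawn to
  a target inhibitory fraction (default 0.38 = 24 % Glu + 14 % GABA,
  with the ACh/monoamine remainder in fly-brain proportions);
* planted pathway — a strong sensory→relay→readout pathway embedded in a
  500-neuron random background with sparse cross edges, for shuffle
  controls.

What the generators do *not* emulate: realistic degree correlations,
reciprocity, spatial structure, or the full weight statistics of a real
connectome. Passing tests on planted circuits validates the machinery
(sign rule, propagation, screen logic, null controls), not the biological
accuracy of predictions on any particular brain.

## Problem sizes and numerical choices

Default dt = 0.1 ms. The test suite and examples use 2–5 trials of
300–600 ms on circuits of ≤ ~500 neurons, and the shuffle control uses
100 shuffles × 2 trials × 500 ms on the planted-pathway fixture — sizes
chosen so the whole suite runs in a few minutes on one core while leaving
the measured properties far from their decision boundaries. The
acceptance script uses 20 random networks for the integrator comparison
and the same planted fixtures. Weights in the random oracle networks are
drawn at 5–11 mV so threshold crossings are steep (see the grazing-
crossing caveat above). Real-connectome-scale runs (10⁵ neurons) are
supported by the same code path but are cluster-scale work, not part of
the test suite.

## Known limitations

Point neurons only: no morphology, receptor kinetics, gap junctions,
neuromodulation, plasticity or non-spiking neurons. One sign per neuron
(per-synapse signs are out of scope). Zero basal rate means inhibition is
invisible wherever the target is not concurrently driven; circuits that
rely on tonic inhibition will be modelled poorly, and absolute rates
should be read as ordinal, not quantitative. Forced stimulation bypasses
inhibition onto the stimulated neurons themselves; use synapse-mode
stimulation when that matters.
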