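# Methods

`fedsplitsim` is a desk-scale simulator for studying the
privacy / energy / accuracy trilemma of federated learning on wearable ECG
classifiers. It couples four models: a synthetic heartbeat generator, an
exact (float64, framework-free) splittable 1D-CNN, a set of training
protocols, and a linear energy/time cost model. This note records the
science, the tunable parameters, and the design choices made where the
design was genuinely open.

## Synthetic heartbeat data

Each training example is a 187-sample waveform centred on the R-peak
(index 93), in arbitrary amplitude units. Class 0 (normal) is a sum of five
Gaussian bumps forming a stereotyped P-QRS-T morphology; class 1
(arrhythmia) has no P wave and a widened (width 5.0 vs 2.2 samples),
attenuated (amplitude 0.55 vs 1.0) and delayed (centre 97 vs 93) QRS with a
broad T wave — the morphology of a typical ventricular ectopic beat. White
Gaussian noise of standard deviation `noise_sd` is added per sample.

The noiseless templates are separated by an L2 distance of ≈ 2.19. Under
additive white noise the optimal (likelihood-ratio) per-segment error is
Φ(−d/2σ); the default `noise_sd = 0.5` was fixed from that formula to give
an optimal error near 1.4 % — classes that overlap enough that training
quality matters, but are learnable by a small CNN. Default prevalence of the
arrhythmia class is 0.15 (imbalanced, as beat-level arrhythmia labels are in
practice).

What the generator deliberately does **not** emulate: baseline wander,
electrode artefacts, beat-to-beat morphology variability within a patient,
more than two rhythm classes, and any patient-level covariate shift beyond
label-proportion skew. Passing results here therefore demonstrate protocol
and accounting correctness and qualitative trade-off directions — not
clinical performance on real ECG.

Partitioning mirrors a federated study design: `floor(test_fraction ×
n_users)` whole users (default 20 %) become the global test set; the
remaining users' segments are pooled and divided across `n_clients` silos by
drawing each class's silo shares from Dirichlet(α,…,α) — the standard
label-skew construction for non-IID federated benchmarks. α defaults to 0.5
(strong skew); α → ∞ recovers IID. Within a silo, an 80/20
train/validation split is stratified by label when both classes are present.
Integer allocation uses largest-remainder rounding so segment counts are
conserved exactly.

Feature scaling is the per-position z-score (each of the 187 positions is a
feature) with the population (divide-by-n) standard deviation convention.
Zero-variance positions raise an error rather than dividing silently. In
the pre-wired studies one public scaler is fitted on the pooled client
training data and applied to every partition, so all regimes see identical
inputs; fitting scalers per silo would confound protocol comparisons with
normalisation mismatch.

All randomness derives from one master seed through `numpy` `SeedSequence`
spawn keys `(stream, index)` with fixed stream labels per module, so the
waveform draw, the partition, the weight initialisation and each client's
shuffling order are independently reproducible.

## The splittable 1D-CNN

The canonical model is

```
device : Conv1D(16 filters, kernel 5, same, ReLU) → MaxPool(2)
         → Conv1D(32 filters, kernel 3, same, ReLU) → Flatten   (2,976 features)
server : Dense(32, ReLU) → Dense(2) → Softmax
```

with the cut layer after Flatten. "Same" padding for convolutions and floor
division for pooling were chosen so the flatten width (187 → 187 → 93 → 93 ×
32 = 2,976) is well defined. The server half's depth (one hidden dense
layer of 32 units) is a configuration knob. The loss is mean cross-entropy
over the 2-class softmax, differentiated jointly with the softmax in closed
form for stability. Initialisation is He-style fan-in uniform
(±√(6/fan_in)), biases zero. Everything runs in float64; payload byte
accounting uses a 4-byte-per-element wire convention (single-precision
transmission).

The engine's defining property is **split-equivalence**: the device and
server halves execute the same per-layer kernels in the same floating-point
order as the unsplit network, so smashed-data forward + cut-gradient
backward reproduces the full model's probabilities and every parameter
gradient *bit-for-bit* at every cut position. Gradient correctness is
verified independently against central finite differences (h = 1e-5,
relative error < 1e-5). Argmax prediction breaks ties toward the lower
class index.

## Profiling

Parameter counts use the bias-inclusive conventions
`filters × (kernel × in_channels + 1)` (conv) and `units × (inputs + 1)`
(dense), which reproduce the published per-layer counts (96, 1,568, total
1,664) exactly.

FLOP accounting ships two conventions because the published per-layer MFLOP
figures cannot be derived from any standard MAC count for these shapes (they
exceed analytic MAC-based counts by roughly an order of magnitude and assign
0.26 MFLOPs to a reshape). `mac2x3` is the analytic path: 2 FLOPs per MAC
forward, times 3 for a forward+backward training step; pooling and reshapes
carry none. `reference` returns the published table verbatim (treated as
instrumented fixture data); `hybrid` (the cost model's default) uses the
published value where a canonical layer name matches and `mac2x3`
otherwise. Peak RAM is likewise fixture data; an analytic estimator
(activations + parameters at 4 bytes) is provided but labelled approximate,
and both the summed-per-layer and max-single-layer RAM readings are
reported since either may be the binding deployment constraint.

## Cost model

Compute energy is FLOPs × (active power / FLOP rate); communication energy
and time are linear in bytes; a client waiting for a synchronous round to
close is billed at its idle power. The ledger is conservative by
construction: total = compute + communication + idle, checked every round.

Calibration against the bundled published comparison rows: energy-per-FLOP
constants are computation energy over total FLOPs per role (≈ 0.30 nJ/FLOP
centralized, ≈ 0.70 nJ/FLOP on-device). The published component energies do
not sum to the published totals (1.66 + 3.80 = 5.46 vs 5.93 kJ; 0.86 + 0.06
= 0.92 vs 3.84 kJ); the simulator books the residual (0.47 kJ / 2.92 kJ) as
an idle/overhead component, consistent with the straggler-idle narrative.
This is a modelling decision of this package, not a statement of the source
table. The round-trip (constants → rebuilt rows) agrees to < 0.5 %.

Per-byte link energy in the scaled studies is obtained by spreading each
regime's published communication budget over that regime's deterministic
simulated byte total. This mapping is deliberate: at full scale, raw ECG
streams dwarf parameter traffic, while a desk-scale dataset is small enough
that model parameters would otherwise dominate and invert the published
energy structure. The mapping preserves the structure; absolute
communication joules at desk scale are therefore not independently
meaningful.

Synchronous round time is the maximum over selected clients (the straggler
gates the round). The asynchronous makespan model is work-sharing: given
per-client iteration durations and a total update budget, the server merges
each update on arrival and fast clients contribute more updates, so the
asynchronous makespan never exceeds the synchronous one and is strictly
smaller for heterogeneous fleets. Batteries convert at 1 mWh = 3.6 J, and a
drained device is unavailable.

## Protocols

* **Centralized**: raw segments (187 × 4 bytes each) are uploaded once,
  then pooled mini-batch SGD runs on the server. Training proceeds in
  "rounds" of E epochs purely so the evaluation cadence matches the
  federated regimes.
* **FedAvg**: per round, selected clients run E local epochs from the
  broadcast model, upload parameters (params × 4 bytes each way), and the
  server takes the sample-size-weighted mean. Asynchronous mode replaces
  the barrier with merge-on-arrival, down-weighting stale updates by
  α = α₀/(1+s) where s counts global updates since the client's base
  version (α₀ default 0.5; the rule sits behind the aggregation-policy
  interface and is this package's choice).
* **Split learning**: per batch, the device runs the shallow layers and
  ships smashed data; the edge runs the deep layers, backpropagates, and
  returns the cut gradient. Optional Gaussian noise of standard deviation
  σ on the smashed data implements the noise-injection privacy mechanism
  (no formal (ε,δ) accounting). With σ = 0 the trajectory is bit-identical
  to centralized SGD on the same silo and shuffle stream.
* **H-FedSL**: clients pair with edge servers round-robin. In **relay**
  mode (default) the clients of one edge share its weights within a round:
  the edge multiplexes their mini-batches round-robin through a single
  relayed model (a batch-interleaved split-learning weight relay), and the
  cloud FedAvg-aggregates across edges each round (scope configurable to
  device-half only). Because each edge's weights see all of its clients'
  data finely mixed within a round, the gradient sequence approximates
  pooled shuffled SGD and label skew is largely neutralised; this is the
  mechanism by which the hierarchy recovers the accuracy naive FedAvg
  loses. A coarser per-client relay (whole local epochs per client before
  the hand-off) converges noticeably slower under strong skew because each
  block is nearly single-class. In **parallel**
  mode each client trains a private copy of the server half and everything
  is averaged — algorithmically identical to FedAvg; it is retained as an
  oracle and ablation.

Resource-aware selection admits clients with battery fraction strictly
above the threshold (default 0.20) and link speed at or above a configured
floor; an empty selection raises a protocol-stall error rather than passing
silently. The ledger tags every payload (raw / params / smashed /
cut-gradient), and federated regimes are asserted to carry zero raw-data
bytes on any client uplink.

Client participation defaults to all selected clients each round; local
data order is reshuffled every epoch from the client's child stream.
Accuracy is evaluated once per global round on the full global test set.

## The scaled-down trade-off study

`experiments.run_tradeoff_study` fixes the desk-scale conditions: 25 users
× 250 segments (20 % of users held out → 10 silos of ≈ 500 segments),
Dirichlet α = 0.5, the canonical model, learning rate 0.001, batch 32, 10
global rounds × 2 local epochs (chosen so all three regimes reach their
plateaus at this data size), a 50 MFLOP/s wearable fleet with 2× log-uniform
speed spread and client 0 slowed 5× as the straggler, 5 GFLOP/s edge/cloud
servers, two edge servers, and the calibrated energy constants above.
Centralized training uses the same total number of passes (rounds ×
epochs) as each federated client, so compute budgets match.

The study targets directions, not absolute published accuracies (which
belong to real ECG data): federated total energy below centralized,
federated wall-clock above centralized under the straggler, FedAvg final
accuracy below centralized under strong skew, and H-FedSL final accuracy
within one percentage point of centralized. Seed-level noise is smoothed by
sweeping five seeds and comparing seed means for the accuracy criteria.

## Numerical choices and degenerate inputs

* Pooling drops the tail when the length is not divisible (187 → 93).
* Max-pool backward routes the gradient to the argmax (first maximum on
  ties, `argmax` convention).
* Weighted averaging uses Σwᵢpᵢ / Σwᵢ; a single-input aggregate returns a
  copy, keeping one-client runs bitwise faithful.
* Zero-variance scaler positions, empty selections, out-of-range cut
  layers, shape mismatches (named by layer) and zero-denominator clinical
  metrics all raise typed errors; metrics are never silently reported as 0.
* JSON parameter serialisation relies on Python float repr, which
  round-trips IEEE-754 doubles exactly.

## Known limitations

No radio-protocol or queuing simulation; no DVFS or thermal effects; no
cryptographic aggregation; DP noise without a privacy budget; synthetic
waveforms as above; analytic RAM is approximate; the published FLOP table is
reproduced, not re-derived. Time and energy are simulated quantities driven
by the calibrated constants, so only comparisons between regimes — not
absolute values — carry meaning.
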