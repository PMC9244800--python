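# Methods

## The model cell

Both interneuron classes — Ucn3⁺ (excitatory, mechanical-itch transmission)
and NPY⁺ (inhibitory, itch gating) — are represented by the same reduced
morphology: a ball-and-stick cell with a myelinated axon. The compartment
chain is

    dendrite (500 µm × 1 µm, 5 segments) — soma (10 µm × 10 µm) —
    axon hillock (20 µm, tapering 2 → 1 µm, 2 segments) —
    41 × [internode (100 µm, myelinated) + node of Ranvier (1 µm)]

with axial resistivity 100 Ω·cm and membrane capacitance 1 µF/cm²
(0.02 µF/cm² under myelin). Soma and dendrite are passive
(g_pas = 3.5 × 10⁻⁵ S/cm², E_pas = −65 mV, giving a somatic input
resistance near 1 GΩ and τ_m ≈ 29 ms, at the high-impedance end of
superficial dorsal-horn interneurons). The published description of this
model cites an earlier spinal-interneuron model for all geometric and
passive constants without reprinting them; the values above are defaults
chosen to land in the physiological range for these small cells, and every
one of them can be overridden through the morphology config
(`Morphology.save`/`Morphology.load` round-trips the YAML exactly).

All seven fitted conductances live only in the axon hillock; the nodes of
Ranvier carry squid-type Hodgkin–Huxley kinetics so spikes propagate
saltatorily to the last node (which drives the inhibitory synapse in the
microcircuit).

### Why the nodal kinetics are voltage-shifted

With textbook HH kinetics at the nodes, the first node — which sees somatic
DC almost unattenuated through the low-leak internode — reaches threshold
(~−50 mV) before the hillock does. Spike initiation then no longer depends
on the fitted Nav1.6 conductance, and every model measures an AP threshold
near −50 mV regardless of its parameters, incompatible with the recorded
thresholds around −35 mV. The nodal rate functions are therefore evaluated
at V − 15 mV (a parameter of `node_hh.yaml`): the functional forms are
unchanged, the operating range is depolarized so that the hillock is the
initiation site and the nodes regenerate rather than initiate. The nodal
leak reversal (−64.5 mV) is set so an isolated node rests near −65 mV.

## Channel kinetics

The published model lists its seven mechanisms by name (Nav1.6, KDR, KA,
SK, BK, R-type Ca, leak) and cites a source model for each without
reprinting equations. The kinetics here are standard first-order HH-type
gates — Boltzmann steady states with bell-shaped voltage-dependent time
constants — with every rate parameter in a per-channel YAML file
(`data/channels/`), hash-stamped into population provenance
(`kinetics_hash`). No Q10 scaling is applied; parameters are understood as
already at the recording temperature (23 °C).

Choices that matter:

- **Nav1.6** gates m³hs. Activation at −30 mV (half); fast inactivation is
  steep and partially engaged during the slow approach to threshold
  (V½ = −50 mV, slope −6), so rheobase is availability-limited and responds
  strongly to the maximal conductance, as the recorded populations do; the
  *slow* inactivation gate s (V½ = −47 mV, τ ≈ 10–30 ms) accumulates at
  depolarized interspike potentials.
  The slow gate is what produces the two recorded phenotypes from one
  kinetics set: cells with weak spike repolarization hold a depolarized
  interspike potential, run down s, and fall silent after a few early
  spikes (the Ucn3-like *initial bursting* pattern); cells with strong
  delayed-rectifier repolarization keep s high and fire *tonically* (the
  NPY-like pattern). Slow inactivation is a documented property of Nav1.6.
- **KDR** (n⁴, V½ = −18 mV) is deliberately slow (τ up to ~11 ms) to give
  the broad spikes recorded in these cells (half-widths 2.9–4.2 ms at
  23 °C).
- **SK** is purely calcium-gated (Hill, n = 4, K_d = 0.35 µM, τ = 15 ms)
  and acts as the firing-rate brake; **BK** is jointly calcium- and
  voltage-gated via a calcium-shifted half-activation voltage
  (−40 mV/decade around 1 µM).
- **R-type Ca** (q²r) is the only calcium source for the submembrane pool:
  [Ca] relaxes to baseline 0.05 µM with τ_Ca = 20 ms and rises in
  proportion to the R-type current (k = 1.5 µM·cm²/(ms·mA)). With
  g_SK = g_BK = 0 the pool is decoupled from the voltage dynamics (a
  tested invariant).

## Numerics

Backward-Euler voltage steps on the tridiagonal compartment chain at a
fixed dt = 20 µs, with Rush–Larsen (exact-exponential) gate updates
staggered before each solve; the stiff nodal kinetics rule out explicit
schemes at this step. Voltage-dependent steady states and per-step
relaxation factors are tabulated on a 0.05 mV grid over [−120, 60] mV and
linearly interpolated, which keeps the inner loop free of transcendental
calls (the calcium-dependent SK/BK gates are evaluated directly). Halving
dt moves spike times by less than 0.1 ms (tested). Each model is settled
for 200 ms before any recorded window; the settled state is cached per
model so protocol sweeps (rheobase bisection) pay the settling cost once.

## Feature extraction

Current-clamp features follow the conventions of the recordings they are
compared with: 500 ms somatic steps; spikes are upward 0 mV crossings with
a 2 ms refractory gap *and* a minimum rate-of-rise of 10 mV/ms (without
the slope requirement a passive ~1 GΩ cell "spikes" whenever a strong step
charges it past 0 mV); AP threshold is the membrane potential where the
phase-plot slope crosses 10 mV/ms on the upstroke of the first spike
(the last such crossing before the peak, which ignores stimulus-onset
transients); max dV/dt is taken over the rising phase; half-width is
measured at half amplitude above the threshold voltage; rheobase is found
by bisection to 1 pA on [0, 200] pA. The firing-pattern rule quantifies
the recorded phenotypes: silent (no spikes), tonic (spike span ≥ 50% of
the step), initial bursting (all spikes in the first 25%), other. AP
waveform features are measured on the first spike of the 60 pA response,
the amplitude used for the published phase-plot analysis.

## Population fitting

Seven-dimensional uniform box priors (upper bounds 1.0, 0.2, 0.02, 0.1,
0.03, 0.05, 5 × 10⁻⁴ S/cm² for gNav1.6, gKDR, gKA, gSK, gBK, gCaR, gLk).
The score of a candidate is the equally weighted mean of normalized
distances |feature − target| / dispersion over:

| metric | Ucn3 target | NPY target | source |
|---|---|---|---|
| rheobase | 40 pA | 40 pA | anchor (assumption; only relative changes were published) |
| spikes at 60 pA | 3 | 8 | anchor (assumption; published as figure panels) |
| AP threshold | −35.5 mV | −35.6 mV | published control means |
| half-width | 4.2 ms | 2.9 ms | published control means |

Dispersions are 20% of the target magnitude, floored at one spike for the
count metric (a dispersion below the count's granularity over-constrains
the score). A candidate whose firing pattern is not the class's required
phenotype (initial bursting for Ucn3, tonic for NPY) is charged a fixed
large distance — the pattern gate — which by itself pushes the score past
the acceptance threshold. Undefined features (silent at 60 pA) are charged
the same fixed distance rather than any fabricated value. Maximum dV/dt is
extracted and exported for every model but *not* scored: only its relative
change was published, and scoring it would pin the fit to an invented
absolute anchor.

Sampling uses the Goodman–Weare affine-invariant stretch move (a = 2,
sequential walker updates) on the density exp(−β·score²/2). β is annealed
geometrically from 1 to 25 across the iterations of each run: at β = 1 the
density is nearly flat over scores 0–2 and the search is effectively
random (consistent with the published full-scale yield of ~184 accepted
models from ~41,600 evaluations); the annealed schedule explores freely
early and concentrates inside the sub-threshold pocket late. The first run
of a fit initializes walkers uniformly over the prior; subsequent runs
initialize them in a Gaussian ball (σ = 10% of each prior range) around
the best candidate found so far — the conventional ensemble-sampler
initialization around an initial guess. The temperature and initialization
affect efficiency only: the accepted population is defined by the
temperature-independent filter.

Every parameter set evaluated anywhere along any chain (initial positions,
accepted and rejected proposals) enters the candidate pool. The accepted
population is the pool filtered to score ≤ 0.6 with the required firing
pattern, deduplicated after rounding conductances to six significant
digits, ordered by score. Populations serialize to a tab-separated table
with a provenance header (kinetics hash, sampler settings, seed).

Problem sizes: the published populations used 400 walkers × 25 iterations
× 4 runs per class. The scaled runs used by the test suite and the
acceptance script use 36–40 walkers × 10–12 iterations × 2–5 runs
(roughly 1,000–1,800 model evaluations per class), which accepts 50–150
unique models per class; the pairwise network scans then cover up to
50 × 50 = 2,500 microcircuits instead of the published 184 × 200 = 36,800.

## Perturbation analysis

Chronic-itch expression changes map onto multiplicative scaling of maximal
conductances (proportional expression→conductance assumption). For each
model, rheobase (or 60 pA spike count) is recomputed before and after
scaling under identical protocols; rheobase changes below the 1 pA search
resolution are reported as exactly 0. Models with undefined baselines are
excluded from summaries and surfaced; so are individual models whose
response opposes the population's direction (the published populations
contained two such outliers).

## The gating microcircuit

One Aβ event excites both cells at the dendrite midpoint (double-
exponential conductances, rise 0.1 ms / decay 5 ms, E = 0 mV) with
synaptic latencies 2.2 ms (NPY) and 4.0 ms (Ucn3); every NPY spike
arriving at the last node of Ranvier triggers inhibition at the Ucn3 soma
(rise 0.1 ms / decay 20 ms, E = −75 mV). The circuit is feed-forward, so
each pair is simulated as an NPY pass followed by a Ucn3 pass driven by
the recorded inhibitory train; identical inhibitory trains share one Ucn3
simulation (a pure cache, order-independent by construction — both are
tested). The gate of a pair is open when the Ucn3 cell fires a somatic
spike within 30 ms of the Aβ event. Direct evoked spikes occur 12–17 ms
after the event, so the window brackets them with margin; it deliberately
excludes later activity, because a strong IPSP can de-inactivate sodium
and fire a *post-inhibitory rebound* spike tens of milliseconds later,
which is not an evoked response to the volley (and inverts the
disinhibition phenotype if counted). Simulations run 60 ms after a 100 ms
settle.

Peak synaptic conductances are calibrated by simulated somatic voltage
clamp of a passive reference cell (the PSC amplitude a given peak
conductance produces), with the drive amplitudes themselves fixed by a
population-adaptive rule. The published description sets the amplitudes
only as "similar amplitude to previous experimental measurements", and
with a shared morphology the population's synaptic firing thresholds span
just a few pA, so any fixed amplitude sits on a knife edge that flips the
circuit between all-closed and all-open across refitted populations.
`calibrate_abeta_drives` therefore sets, once on the unperturbed
populations and frozen across all perturbation conditions:

- the **Ucn3 drive** at the population's *median synaptic threshold* (the
  smallest EPSC at which half the disinhibited Ucn3 models fire) — the
  scale-free choice expressing that the true amplitude is unknown;
- the **NPY drive** at the smallest EPSC at which ≥95% of NPY models fire
  — inhibition is reliable at baseline yet close enough to threshold that
  the recorded Nav1.6 loss still silences most NPY output. The stronger
  drive onto NPY that results is consistent with the published response
  asymmetry (most control NPY cells respond to the volley, few control
  Ucn3 cells do);
- the unitary IPSC at 300 pA (0 mV holding), an effectively saturating
  somatic shunt.

Because the near-threshold Ucn3 cells reach threshold slowly (~9–13 ms
after EPSP onset) while the reliably driven NPY cells spike faster, the
feed-forward IPSP — onset 2.2 ms + NPY spike latency + ~1 ms axonal
conduction — arrives in time to veto most would-be Ucn3 spikes at
baseline.

Open-vs-closed comparisons of baseline NPY Nav1.6 conductance use the
Mann–Whitney U test (two-sided; exact enumeration when both groups have at
most 8 networks, otherwise the tie-corrected normal approximation), with
each network contributing one observation, as in the published analysis.

## Synthetic data

`calibration.make_surrogate_population` draws Gaussian per-cell feature
samples around the published group values (SD = 20% of the mean, since
only group means and sizes were published) — surrogates for the
unavailable per-cell recordings, reproducible per seed.
`calibration.make_test_trace` generates voltage traces with analytically
planted features (spike counts, threshold-crossing voltages, half-widths)
used as extractor ground truth. Neither captures recording noise,
electrode artifacts, or the correlation structure of real measurements:
passing tests demonstrate the pipeline's internal correctness and the
reproduction of published population-level numbers, not fidelity to any
individual recorded neuron.

## Known limitations

- Channel kinetics are standard formulations calibrated to the published
  feature ranges, not the authors' exact cited models; absolute conductance
  values are therefore not comparable across implementations (relative
  perturbation effects, the quantities compared here, are).
- The rheobase/spike-count anchors (40 pA; 3 and 8 spikes) are assumptions
  standing in for values shown only graphically.
- Single calcium pool shared by SK and BK; constant calcium reversal.
- One Aβ event rather than a volley train; no synaptic depression or
  facilitation; no NPY-receptor volume transmission.
- Scaled-down sampler runs trade posterior coverage for time; population
  diversity is narrower than a full-scale 40,000-evaluation run would give.
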