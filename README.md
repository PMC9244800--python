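# itchgate

Population modelling of the spinal **mechanical-itch gating microcircuit**:
conductance-based multicompartment models of the superficial dorsal-horn
interneurons that transmit (Ucn3⁺, excitatory) and gate (NPY⁺, inhibitory)
mechanical itch, fitted as *populations of models* to patch-clamp
calibration targets, plus the tools to ask how chronic-itch-associated ion
channel changes (chiefly Nav1.6) alter single-cell excitability and open
the itch gate.

The package is aimed at computational neuroscientists studying
sensitization: it reproduces, at desk scale, a published modelling pipeline
in which

1. each model neuron is a ball-and-stick cable with a myelinated axon
   (41 nodes of Ranvier) whose seven active conductances
   (g<sub>Nav1.6</sub>, g<sub>KDR</sub>, g<sub>KA</sub>, g<sub>SK</sub>,
   g<sub>BK</sub>, g<sub>CaR</sub>, g<sub>Lk</sub>) live in the axon
   hillock;
2. populations of parameter sets are generated by affine-invariant
   ensemble MCMC (Goodman–Weare stretch move) against electrophysiological
   targets — rheobase, 60 pA spike count, AP threshold (10 mV/ms
   phase-plot criterion), AP half-width, and the class firing phenotype
   (initial-bursting vs tonic) — keeping every candidate whose normalized
   average distance (score) is at most 0.6;
3. channel perturbations are applied as multiplicative conductance scaling
   (the proportional expression→conductance assumption), and
4. every pairwise (Ucn3, NPY) microcircuit is simulated under a single
   Aβ-fiber input (latencies 2.2 ms to NPY, 4.0 ms to Ucn3; feed-forward
   NPY→Ucn3 inhibition from the last node of Ranvier) to count networks
   whose "gate" opens, i.e. whose Ucn3 cell fires.

See `docs/methods.md` for the model, its assumptions, and every numerical
choice.

## Worked example

```python
from itchgate import (
    Morphology, ConductanceSet, build_neuron, evaluate_features,
    target_set, score_model,
)

g = ConductanceSet(gNav16=0.499, gKDR=0.0716, gKA=0.0001, gSK=0.0,
                   gBK=0.0084, gCaR=0.0426, gLk=0.00019)  # S/cm2 at the hillock
model = build_neuron(Morphology(), g)
fv = evaluate_features(model)
print(fv)
print("score vs Ucn3 control targets:", round(score_model(fv, target_set("ucn3")), 3))
```

prints

```
FeatureVector(rheobase_pA=40.0, n_spikes_60pA=3,
              ap_threshold_mV=-38.236..., max_dvdt_mV_ms=332.63...,
              half_width_ms=3.7165..., firing_pattern='initial_bursting')
score vs Ucn3 control targets: 0.24
```

— a cell that needs a 40 pA step to fire, responds to 60 pA with a
three-spike initial burst, crosses the 10 mV/ms phase-plot criterion at
−38.2 mV and has a 3.7 ms-wide spike: an accepted Ucn3-like model
(score ≤ 0.6), about a quarter of a normalized dispersion from the
target centre.

Population fitting and the network scan run the same way from the shell:

```bash
itchgate fit-population --cell npy --walkers 48 --iters 12 --runs 3 --seed 1 --out npy.tsv
itchgate perturb --population npy.tsv --channel gNav16 --factor 0.5 --feature rheobase_pA
itchgate gate-scan --ucn3 ucn3.tsv --npy npy.tsv --npy-scale gNav16=0.5
```

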