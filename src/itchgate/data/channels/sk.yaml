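# Small-conductance calcium-activated potassium conductance (axon hillock).
# Purely calcium-gated: Hill activation z_inf = Ca^n / (Ca^n + kd^n) with a
# fixed relaxation time constant; no voltage dependence.
name: sk
ion: k
reversal_mV: -80.0
ca_gate:
  name: z
  power: 1
  kd_uM: 0.35
  hill: 4
  tau_ms: 15.0
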