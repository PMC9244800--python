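# Big-conductance calcium- and voltage-activated potassium conductance
# (axon hillock).  Single activation gate whose half-activation voltage
# shifts leftward as submembrane calcium rises:
#   vhalf(Ca) = vhalf0 - shift_per_decade * log10(Ca / ca_ref)
name: bk
ion: k
reversal_mV: -80.0
cav_gate:
  name: w
  power: 1
  vhalf0: -10.0
  slope: 8.0
  shift_per_decade_mV: 40.0
  ca_ref_uM: 1.0
  tau_ms: 1.5
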