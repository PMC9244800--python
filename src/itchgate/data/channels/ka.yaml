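# A-type (rapidly inactivating) potassium conductance (axon hillock).
name: ka
ion: k
reversal_mV: -80.0
gates:
  - name: a
    power: 1
    vhalf: -45.0
    slope: 9.0
    tau: {base: 0.5, amp: 1.5, vmax: -50.0, s1: 18.0, s2: 18.0}
  - name: b
    power: 1
    vhalf: -72.0
    slope: -7.0
    tau: {base: 12.0, amp: 30.0, vmax: -70.0, s1: 18.0, s2: 18.0}
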