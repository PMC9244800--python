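# Delayed-rectifier potassium conductance (axon hillock).
# Slow activation at 23 degC gives the broad (2.5-4.5 ms) spikes seen in
# superficial dorsal-horn interneurons.
name: kdr
ion: k
reversal_mV: -80.0
gates:
  - name: n
    power: 4
    vhalf: -18.0
    slope: 9.0
    tau: {base: 2.5, amp: 16.0, vmax: -20.0, s1: 16.0, s2: 16.0}
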