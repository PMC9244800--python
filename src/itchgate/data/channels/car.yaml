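# R-type (Cav2.3-containing) high-voltage-activated calcium conductance
# (axon hillock).  Sole calcium source for the submembrane pool that drives
# SK and BK.  Constant calcium reversal potential (no GHK correction).
name: car
ion: ca
reversal_mV: 60.0
gates:
  - name: q
    power: 2
    vhalf: -18.0
    slope: 5.5
    tau: {base: 0.7, amp: 2.0, vmax: -30.0, s1: 16.0, s2: 16.0}
  - name: r
    power: 1
    vhalf: -60.0
    slope: -9.0
    tau: {base: 25.0, amp: 50.0, vmax: -60.0, s1: 18.0, s2: 18.0}
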