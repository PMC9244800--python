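# Nav1.6-type transient sodium conductance (axon hillock).
# Fast activation (m^3), fast inactivation (h) and slow inactivation (s).
# Inactivation is steep and only partially available during the slow
# approach to threshold, so rheobase is limited by sodium availability
# (safety factor) and responds strongly to the maximal conductance, as the
# recorded populations do.  Asymmetric tau profiles give slow inactivation
# at spike voltages (broad spikes) but fast recovery during the AHP
# (repetitive firing).  x_inf = 1/(1+exp((vhalf-V)/slope));
# tau(V) = base + amp / (exp((V-vmax)/s1) + exp(-(V-vmax)/s2)), ms.
name: nav16
ion: na
reversal_mV: 50.0
gates:
  - name: m
    power: 3
    vhalf: -30.0
    slope: 6.0
    tau: {base: 0.1, amp: 0.4, vmax: -30.0, s1: 14.0, s2: 14.0}
  - name: h
    power: 1
    vhalf: -50.0
    slope: -6.0
    tau: {base: 0.8, amp: 8.0, vmax: -52.0, s1: 40.0, s2: 10.0}
  - name: s
    power: 1
    vhalf: -47.0
    slope: -4.0
    tau: {base: 10.0, amp: 20.0, vmax: -48.0, s1: 20.0, s2: 8.0}
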