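# Squid-type Hodgkin-Huxley kinetics for the nodes of Ranvier, supporting
# saltatory AP propagation along the myelinated axon.  Conventional
# alpha/beta rate forms (ms^-1), no temperature rescaling (fixed 23 degC).
# Densities (S/cm2) are elevated relative to squid axon, as appropriate for
# nodal membrane.  The gating voltage dependence is shifted depolarized by
# vshift so the nodes regenerate and propagate spikes initiated at the
# hillock but do not themselves initiate under slow somatic depolarization
# (the axon initial segment, not the axon, sets the cell's threshold).
# The leak reversal is chosen so an isolated node rests near -65 mV.
name: node_hh
gna_S_cm2: 1.2
gk_S_cm2: 0.36
gl_S_cm2: 0.003
ena_mV: 50.0
ek_mV: -77.0
el_mV: -64.5
vshift_mV: 15.0
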