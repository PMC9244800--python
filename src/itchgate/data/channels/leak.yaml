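# Linear (ohmic, voltage-independent) leak conductance at the axon hillock.
# The leak density gLk is one of the seven free parameters searched by the
# population fit; soma/dendrite passive leak is fixed separately.
name: leak
ion: leak
reversal_mV: -65.0
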