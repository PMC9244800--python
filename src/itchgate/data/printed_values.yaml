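# Published control / chronic-itch (calcipotriol) electrophysiological values
# for Ucn3+ and NPY+ superficial dorsal-horn interneurons.  version 1.
# Every entry carries a citation tag naming the measurement it came from;
# entries are immutable at run time.  "change_pct" entries are relative
# changes (calcipotriol vs control) where no absolute value was published.
version: 1
ucn3:
  firing_pattern:
    value: initial_bursting
    tag: "majority firing pattern of Ucn3+ neurons under depolarizing current steps"
  rheobase_change_pct:
    value: -27.7
    n_control: 88
    n_treated: 55
    tag: "relative change in mean AP rheobase, calcipotriol vs control"
  ap_threshold_mV:
    control: {value: -35.5, n: 22}
    calcipotriol: {value: -41.7, n: 16}
    tag: "mean AP threshold at the 10 mV/ms phase-plot-slope criterion"
  max_dvdt_change_pct:
    value: 11.0
    tag: "relative change in maximum dV/dt (rest-to-peak), calcipotriol vs control"
  half_width_ms:
    control: {value: 4.2, n: 19}
    calcipotriol: {value: 4.0, n: 14}
    tag: "mean single-AP half width"
  abeta_excited_pct:
    control: {value: 13.0, n: 46}
    calcipotriol: {value: 86.5, n: 37}
    tag: "fraction of Ucn3+ neurons excited by Abeta-fiber stimulation"
npy:
  firing_pattern:
    value: tonic
    tag: "majority firing pattern of NPY+ neurons under depolarizing current steps"
  rheobase_change_pct:
    value: 23.4
    sem: 2.2
    n_control: 86
    n_treated: 63
    tag: "relative change in mean AP rheobase, calcipotriol vs control"
  ap_threshold_mV:
    control: {value: -35.6, n: 16}
    calcipotriol: {value: -29.3, n: 22}
    tag: "mean AP threshold at the 10 mV/ms phase-plot-slope criterion"
  max_dvdt_change_pct:
    value: -6.8
    tag: "relative change in maximum dV/dt (rest-to-peak), calcipotriol vs control"
  half_width_ms:
    control: {value: 2.9, n: 14}
    calcipotriol: {value: 3.5, n: 15}
    tag: "mean single-AP half width"
  abeta_excited_pct:
    control: {value: 60.0, n: 30}
    calcipotriol: {value: 19.0, n: 42}
    tag: "fraction of NPY+ neurons excited by Abeta-fiber stimulation"
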