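"""Current-clamp protocols and action-potential feature extraction.

Features mirror standard patch-clamp analysis of dorsal-horn interneurons:
rheobase (1 pA bisection on a 500 ms step), spike count during a 60 pA step,
AP threshold by the 10 mV/ms phase-plot-slope criterion, maximum dV/dt over
the rising phase, half-width at half amplitude above threshold, and a
firing-pattern label (initial-bursting vs tonic vs other vs silent).

Extraction is purely observational: it never mutates model state, and all
derivatives are central differences at the recording time step.  Features
that cannot be measured (no spike, no 10 mV/ms crossing) are ``None`` —
never a fabricated number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cable import NeuronModel, VoltageTrace, simulate
from .morphology import SimulationConfig

__all__ = [
    "StimulusProtocol",
    "FeatureVector",
    "FIRING_PATTERNS",
    "detect_spikes",
    "phase_plot",
    "ap_threshold",
    "max_dvdt",
    "half_width",
    "classify_firing_pattern",
    "compute_rheobase",
    "step_response",
    "evaluate_features",
    "UNEXCITABLE",
]

FIRING_PATTERNS = ("initial_bursting", "tonic", "other", "silent")

#: sentinel distinct from any numeric rheobase
UNEXCITABLE = None

DEFAULT_STEP_MS = 500.0
DEFAULT_DELAY_MS = 10.0
DEFAULT_TAIL_MS = 40.0
DETECTION_THRESHOLD_MV = 0.0
REFRACTORY_MS = 2.0
THRESHOLD_SLOPE_MV_MS = 10.0


@dataclass(frozen=True)
class StimulusProtocol:
    """Somatic current step."""

    amplitude_pA: float
    duration_ms: float = DEFAULT_STEP_MS
    delay_ms: float = DEFAULT_DELAY_MS
    site: str = "soma"
    kind: str = "current_step"

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration must be > 0")


@dataclass
class FeatureVector:
    """Calibration features of one model neuron; ``None`` marks undefined."""

    rheobase_pA: float | None
    n_spikes_60pA: int | None
    ap_threshold_mV: float | None
    max_dvdt_mV_ms: float | None
    half_width_ms: float | None
    firing_pattern: str

    METRICS = ("rheobase_pA", "n_spikes_60pA", "ap_threshold_mV", "max_dvdt_mV_ms", "half_width_ms")

    def metric(self, name: str):
        return getattr(self, name)


# ---------------------------------------------------------------------------
# Trace-level extractors


def detect_spikes(
    trace: VoltageTrace,
    site: str = "soma",
    threshold_mV: float = DETECTION_THRESHOLD_MV,
    refractory_ms: float = REFRACTORY_MS,
    min_slope_mV_ms: float = THRESHOLD_SLOPE_MV_MS,
) -> np.ndarray:
    """Times (ms) of upward crossings of the detection voltage, with a
    refractory gap enforced; sorted and unique.

    A crossing counts as a spike only if the local rate of rise reaches
    ``min_slope_mV_ms``, which distinguishes regenerative upstrokes from
    slow passive charging through the detection voltage (possible in
    unexcitable high-impedance cells under strong current steps).
    """
    v = trace.v(site)
    t = trace.time_ms
    above = v >= threshold_mV
    crossings = np.nonzero(~above[:-1] & above[1:])[0] + 1
    times = []
    last = -math.inf
    for i in crossings:
        slope = (v[i] - v[i - 1]) / trace.dt_ms
        if slope >= min_slope_mV_ms and t[i] - last > refractory_ms:
            times.append(t[i])
            last = t[i]
    return np.array(times)


def phase_plot(trace: VoltageTrace, site: str = "soma"):
    """Paired (V, dV/dt) series using central differences at the trace dt."""
    v = trace.v(site)
    dvdt = np.gradient(v, trace.dt_ms)
    return v, dvdt


def _first_peak_index(trace: VoltageTrace, site: str) -> int | None:
    spikes = detect_spikes(trace, site)
    if len(spikes) == 0:
        return None
    i0 = int(round(spikes[0] / trace.dt_ms))
    v = trace.v(site)
    i1 = min(len(v), i0 + int(round(5.0 / trace.dt_ms)))
    return i0 + int(np.argmax(v[i0:i1]))


def ap_threshold(
    trace: VoltageTrace,
    site: str = "soma",
    slope_criterion_mV_ms: float = THRESHOLD_SLOPE_MV_MS,
) -> float | None:
    """Membrane potential at the upward crossing of the phase-plot slope
    criterion (10 mV/ms) on the upstroke of the first spike; ``None`` when
    the trace never reaches the criterion.

    The upstroke crossing is the last upward crossing before the spike peak,
    which ignores slope transients at stimulus onset; on a trace with a
    single crossing (ramp-then-spike) it is also the first.
    """
    ipk = _first_peak_index(trace, site)
    if ipk is None:
        return None
    v, dvdt = phase_plot(trace, site)
    seg = dvdt[:ipk]
    cross = np.nonzero((seg[:-1] < slope_criterion_mV_ms) & (seg[1:] >= slope_criterion_mV_ms))[0]
    if len(cross) == 0:
        return None
    return float(v[cross[-1] + 1])


def max_dvdt(trace: VoltageTrace, site: str = "soma") -> float | None:
    """Maximum dV/dt (mV/ms) over the rising phase of the first AP
    (threshold crossing to peak)."""
    ipk = _first_peak_index(trace, site)
    if ipk is None:
        return None
    v, dvdt = phase_plot(trace, site)
    seg = dvdt[:ipk]
    cross = np.nonzero(
        (seg[:-1] < THRESHOLD_SLOPE_MV_MS) & (seg[1:] >= THRESHOLD_SLOPE_MV_MS)
    )[0]
    i0 = cross[-1] + 1 if len(cross) else 0
    return float(np.max(dvdt[i0 : ipk + 1]))


def half_width(trace: VoltageTrace, site: str = "soma") -> float | None:
    """AP duration (ms) at half amplitude, amplitude = peak minus the
    threshold voltage (10 mV/ms criterion voltage) of the first AP."""
    ipk = _first_peak_index(trace, site)
    if ipk is None:
        return None
    vthr = ap_threshold(trace, site)
    if vthr is None:
        return None
    v = trace.v(site)
    vpk = v[ipk]
    level = vthr + 0.5 * (vpk - vthr)

    # walk outwards from the peak to the half-amplitude crossings,
    # sub-sample precision by linear interpolation
    i = ipk
    while i > 0 and v[i] > level:
        i -= 1
    if v[i] == v[i + 1]:
        t_up = i * trace.dt_ms
    else:
        t_up = (i + (level - v[i]) / (v[i + 1] - v[i])) * trace.dt_ms
    j = ipk
    n = len(v)
    while j < n - 1 and v[j] > level:
        j += 1
    if j == n - 1 and v[j] > level:
        return None  # repolarization not captured
    if v[j] == v[j - 1]:
        t_dn = j * trace.dt_ms
    else:
        t_dn = (j - (level - v[j]) / (v[j - 1] - v[j])) * trace.dt_ms
    return float(t_dn - t_up)


def classify_firing_pattern(
    spike_times_ms: Sequence[float], protocol: StimulusProtocol
) -> str:
    """Quantified firing-pattern rule.

    silent: no spikes.  tonic: spikes span >= 50% of the step.  initial
    bursting: every spike falls in the first 25% of the step.  other: the rest.
    """
    s = np.asarray(spike_times_ms, dtype=float)
    if len(s) == 0:
        return "silent"
    rel = s - protocol.delay_ms
    span = (rel[-1] - rel[0]) / protocol.duration_ms
    if span >= 0.5:
        return "tonic"
    if np.all(rel <= 0.25 * protocol.duration_ms):
        return "initial_bursting"
    return "other"


# ---------------------------------------------------------------------------
# Model-level protocols


def _config_for(protocol: StimulusProtocol, dt: float, settle_ms: float, tail_ms: float):
    record = protocol.delay_ms + protocol.duration_ms + tail_ms
    return SimulationConfig(
        dt_ms=dt,
        total_duration_ms=settle_ms + record,
        settle_duration_ms=settle_ms,
    )


def step_response(
    model: NeuronModel,
    amplitude_pA: float,
    duration_ms: float = DEFAULT_STEP_MS,
    delay_ms: float = DEFAULT_DELAY_MS,
    dt: float = 0.02,
    settle_ms: float = 200.0,
    tail_ms: float = DEFAULT_TAIL_MS,
) -> tuple[VoltageTrace, np.ndarray]:
    """Somatic step response: full trace plus detected spike times."""
    protocol = StimulusProtocol(amplitude_pA, duration_ms, delay_ms)
    config = _config_for(protocol, dt, settle_ms, tail_ms)
    trace = simulate(model, protocol, config)
    return trace, detect_spikes(trace)


def _spikes_only(model, amplitude_pA, duration_ms, delay_ms, dt, settle_ms, early_stop):
    """Spike count at one step amplitude without building a trace."""
    nsteps = int(round((delay_ms + duration_ms) / dt))
    V, hg, ng, ca = model.rest_state(dt, settle_ms)
    protocol = StimulusProtocol(amplitude_pA, duration_ms, delay_ms)
    n_spk, _, _ = model._run(
        V, hg, ng, ca, dt, nsteps, [protocol], [], np.empty((0, 1)),
        np.empty(0, dtype=np.int64), stop_after_first=early_stop,
    )
    return n_spk


def compute_rheobase(
    model: NeuronModel,
    bracket_pA: tuple[float, float] = (0.0, 200.0),
    resolution_pA: float = 1.0,
    duration_ms: float = DEFAULT_STEP_MS,
    delay_ms: float = DEFAULT_DELAY_MS,
    dt: float = 0.02,
    settle_ms: float = 200.0,
    known_subthreshold_pA: float | None = None,
    known_suprathreshold_pA: float | None = None,
) -> float | None:
    """Minimum step amplitude (pA) eliciting >= 1 spike, by bisection to the
    stated resolution; ``None`` (unexcitable) if the bracket maximum is silent.

    The returned amplitude elicits a spike while amplitude - resolution does
    not, on the resolution grid.
    """
    lo, hi = bracket_pA
    if known_subthreshold_pA is not None:
        lo = max(lo, known_subthreshold_pA)
    if known_suprathreshold_pA is not None and known_suprathreshold_pA < hi:
        hi = known_suprathreshold_pA
        hi_spikes = True
    else:
        hi_spikes = (
            _spikes_only(model, hi, duration_ms, delay_ms, dt, settle_ms, True) > 0
        )
    if not hi_spikes:
        return UNEXCITABLE
    # invariant: lo silent (or bracket floor), hi spikes
    while hi - lo > resolution_pA + 1e-9:
        mid = lo + math.floor((hi - lo) / (2 * resolution_pA)) * resolution_pA
        if mid <= lo:
            mid = lo + resolution_pA
        n = _spikes_only(model, mid, duration_ms, delay_ms, dt, settle_ms, True)
        if n > 0:
            hi = mid
        else:
            lo = mid
    return float(hi)


def evaluate_features(
    model: NeuronModel,
    dt: float = 0.02,
    settle_ms: float = 200.0,
    rheobase_bracket_pA: tuple[float, float] = (0.0, 200.0),
    resolution_pA: float = 1.0,
    probe_pA: float = 60.0,
    skip_rheobase_if_silent: bool = False,
) -> FeatureVector:
    """Full calibration feature set of one model.

    AP waveform features (threshold, max dV/dt, half-width) are measured on
    the first AP of the 60 pA step response; rheobase by bisection, reusing
    the 60 pA outcome as a bracket endpoint.  With
    ``skip_rheobase_if_silent`` the bisection above the probe amplitude is
    skipped for probe-silent models and rheobase reported as undefined (a
    fitting-context shortcut; such models already carry undefined AP
    features).
    """
    trace, spikes = step_response(model, probe_pA, dt=dt, settle_ms=settle_ms)
    protocol = StimulusProtocol(probe_pA)
    pattern = classify_firing_pattern(spikes, protocol)
    n60 = len(spikes)
    if n60 > 0:
        thr = ap_threshold(trace)
        dvm = max_dvdt(trace)
        hw = half_width(trace)
        rheo = compute_rheobase(
            model, rheobase_bracket_pA, resolution_pA, dt=dt, settle_ms=settle_ms,
            known_suprathreshold_pA=probe_pA,
        )
    else:
        thr = dvm = hw = None
        if skip_rheobase_if_silent:
            rheo = None
        else:
            rheo = compute_rheobase(
                model, rheobase_bracket_pA, resolution_pA, dt=dt, settle_ms=settle_ms,
                known_subthreshold_pA=probe_pA,
            )
    return FeatureVector(
        rheobase_pA=rheo,
        n_spikes_60pA=n60,
        ap_threshold_mV=thr,
        max_dvdt_mV_ms=dvm,
        half_width_ms=hw,
        firing_pattern=pattern,
    )
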