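"""The two-neuron mechanical-itch gating microcircuit.

A single Abeta-fiber event excites both interneurons at the middle of their
dendrites — the inhibitory NPY+ cell with a 2.2 ms synaptic latency, the
excitatory Ucn3+ cell with 4.0 ms — and every NPY spike that propagates to
the last node of Ranvier triggers feed-forward inhibition onto the Ucn3 soma.
The circuit is strictly feed-forward, so each pair is simulated as an NPY
pass (recording last-node spike times) followed by a Ucn3 pass driven by the
excitatory event plus the recorded inhibitory train.

The "itch gate" of a pair is open when the Ucn3 cell fires at least one
somatic spike inside the gate window after the Abeta event.
:func:`enumerate_networks` simulates every (Ucn3, NPY) permutation of two
populations under optional class-wise conductance perturbations and reports
the open fraction; :func:`compare_open_vs_closed` tests whether the baseline
NPY Nav1.6 conductance differs between open and closed networks
(Mann-Whitney U).

Synaptic peak conductances are not constrained directly by published values;
they are calibrated by simulated somatic voltage clamp of a passive cell so
the unitary excitatory PSC at -70 mV holding and inhibitory PSC at 0 mV
holding match configurable target amplitudes (defaults 100 pA and 200 pA).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cable import NeuronModel, SynapticInput, build_neuron, _dblexp_norm
from .channels import CalciumPool, ConductanceSet
from .morphology import Morphology
from .population import ModelPopulation
from .perturbation import PerturbationSpec, scale_conductance

__all__ = [
    "SynapseSpec",
    "NetworkConfig",
    "GateResult",
    "GateScan",
    "synaptic_conductance",
    "calibrate_synapse",
    "default_network_config",
    "simulate_gate",
    "enumerate_networks",
    "compare_open_vs_closed",
]

log = logging.getLogger(__name__)

ABETA_LATENCY_UCN3_MS = 4.0
ABETA_LATENCY_NPY_MS = 2.2
#: unitary PSC calibration targets, per postsynaptic class.  Chosen (and
#: documented in the methods note) so the calibrated circuit reproduces the
#: published behaviour of the control microcircuit: the Abeta volley drives
#: fast, reliable spiking in NPY cells, whose feed-forward inhibition
#: arrives in time to veto the more weakly driven Ucn3 cells; halving NPY
#: Nav1.6 silences most NPY axonal output.  The stronger drive onto NPY is
#: consistent with the published response asymmetry (most control NPY cells
#: respond to the volley; few control Ucn3 cells do).
DEFAULT_EPSC_UCN3_PA = 102.0
DEFAULT_EPSC_NPY_PA = 114.0
DEFAULT_IPSC_TARGET_PA = 300.0
EPSC_HOLDING_MV = -70.0
IPSC_HOLDING_MV = 0.0


@dataclass(frozen=True)
class SynapseSpec:
    """Double-exponential ("alpha-function family") synaptic conductance."""

    rise_ms: float
    decay_ms: float
    reversal_mV: float
    gpeak_uS: float
    latency_ms: float = 0.0
    trigger: str = "abeta_event"  # or "presynaptic_spike"
    site: str = "dendrite_mid"

    def __post_init__(self) -> None:
        if not 0 < self.rise_ms < self.decay_ms:
            raise ValueError("need 0 < rise < decay")
        if self.gpeak_uS < 0:
            raise ValueError("peak conductance must be >= 0")


def synaptic_conductance(spec: SynapseSpec, t_since_event_ms) -> np.ndarray | float:
    """Conductance (uS) at time t after the triggering event.

    Difference of exponentials normalized so the maximum equals the
    configured peak conductance (the equal-time-constant alpha function is
    the limiting case); zero before the event.
    """
    t = np.asarray(t_since_event_ms, dtype=float)
    norm = _dblexp_norm(spec.rise_ms, spec.decay_ms)
    g = spec.gpeak_uS * norm * (np.exp(-t / spec.decay_ms) - np.exp(-t / spec.rise_ms))
    g = np.where(t < 0, 0.0, np.maximum(g, 0.0))
    return float(g) if np.isscalar(t_since_event_ms) else g


def _default_exc(latency: float, gpeak: float = 1e-3) -> SynapseSpec:
    return SynapseSpec(
        rise_ms=0.1, decay_ms=5.0, reversal_mV=0.0, gpeak_uS=gpeak,
        latency_ms=latency, trigger="abeta_event", site="dendrite_mid",
    )


def _default_inh(gpeak: float = 2e-3) -> SynapseSpec:
    return SynapseSpec(
        rise_ms=0.1, decay_ms=20.0, reversal_mV=-75.0, gpeak_uS=gpeak,
        latency_ms=0.0, trigger="presynaptic_spike", site="soma",
    )


def calibrate_synapse(
    spec: SynapseSpec,
    target_pA: float,
    holding_mV: float,
    morphology: Morphology | None = None,
    dt: float = 0.02,
) -> SynapseSpec:
    """Set gpeak so the somatic voltage-clamp PSC matches ``target_pA``.

    The postsynaptic cell is the class morphology with all active hillock
    conductances zero (passive reference); the soma is clamped through a
    large series conductance, one synaptic event is delivered, and the peak
    clamp-current deflection is scaled to the target (the passive response
    is linear in gpeak).  Returns a copy of ``spec`` with calibrated gpeak.
    """
    morphology = morphology or Morphology()
    passive = ConductanceSet(0, 0, 0, 0, 0, 0, 1e-4)
    model = build_neuron(morphology, passive)
    g_clamp = 50.0  # uS; effectively ideal somatic clamp
    trial_gpeak = 1e-3
    record_ms, event_ms = 120.0, 40.0
    nsteps = int(round(record_ms / dt))
    syn = SynapticInput(
        site=spec.site, reversal_mV=spec.reversal_mV, gpeak_uS=trial_gpeak,
        rise_ms=spec.rise_ms, decay_ms=spec.decay_ms, event_times_ms=(event_ms,),
    )
    V, hg, ng, ca = model.rest_state(dt, 100.0)
    # hold the soma at the holding potential via a stiff linear conductance:
    # emulate by directly pinning V and measuring the synaptic current
    # analytically is not possible for a dendritic synapse, so integrate with
    # the clamp conductance added through the passive-leak channel of the
    # somatic compartment.
    ch = model.chain
    soma = ch.soma_index
    gpas_backup = ch.gpas_uS[soma]
    epas_backup = ch.epas_mV[soma]
    ch.gpas_uS[soma] = gpas_backup + g_clamp
    ch.epas_mV[soma] = (gpas_backup * epas_backup + g_clamp * holding_mV) / (
        gpas_backup + g_clamp
    )
    try:
        rec = np.array([soma], dtype=np.int64)
        out = np.empty((1, nsteps + 1))
        V[:] = holding_mV  # start near the clamp point
        model._run(V, hg, ng, ca, dt, nsteps, [], [syn], out, rec)
    finally:
        ch.gpas_uS[soma] = gpas_backup
        ch.epas_mV[soma] = epas_backup
    v_soma = out[0]
    i_clamp_pA = g_clamp * (v_soma - holding_mV) * 1e3  # uS*mV -> nA -> pA
    i0 = int(round(event_ms / dt))
    baseline = i_clamp_pA[i0 - 1]
    peak = np.max(np.abs(i_clamp_pA[i0:] - baseline))
    if peak <= 0:
        raise RuntimeError("synaptic calibration saw no clamp current deflection")
    gpeak = trial_gpeak * target_pA / peak
    log.info(
        "calibrated %s synapse: gpeak=%.4g uS for %g pA at %g mV holding",
        "inhibitory" if spec.reversal_mV < holding_mV else "excitatory",
        gpeak, target_pA, holding_mV,
    )
    return replace(spec, gpeak_uS=gpeak)


@dataclass(frozen=True)
class NetworkConfig:
    """One (Ucn3, NPY) pair plus synapse and timing settings."""

    ucn3: ConductanceSet
    npy: ConductanceSet
    exc_ucn3: SynapseSpec
    exc_npy: SynapseSpec
    inh: SynapseSpec
    abeta_event_ms: float = 10.0
    # direct Abeta-evoked Ucn3 spikes occur 12-17 ms after the event; the
    # window brackets them with margin while excluding late post-inhibitory
    # rebound spikes (the -75 mV IPSP can de-inactivate sodium and fire the
    # cell tens of ms later, which is not an evoked response to the volley)
    gate_window_ms: float = 30.0
    record_ms: float = 60.0
    settle_ms: float = 100.0
    dt_ms: float = 0.02
    pair_ids: tuple = ("ucn3", "npy")

    def __post_init__(self) -> None:
        if self.exc_ucn3.latency_ms <= self.exc_npy.latency_ms:
            raise ValueError(
                "feed-forward inhibition requires the Ucn3 Abeta latency to "
                "exceed the NPY latency"
            )


def default_network_config(
    ucn3: ConductanceSet,
    npy: ConductanceSet,
    morphology: Morphology | None = None,
    epsc_ucn3_pA: float = DEFAULT_EPSC_UCN3_PA,
    epsc_npy_pA: float = DEFAULT_EPSC_NPY_PA,
    ipsc_target_pA: float = DEFAULT_IPSC_TARGET_PA,
    **kwargs,
) -> NetworkConfig:
    """Config with calibrated synapses and the standard 4.0/2.2 ms latencies."""
    exc_u = calibrate_synapse(
        _default_exc(0.0), epsc_ucn3_pA, EPSC_HOLDING_MV, morphology
    )
    exc_n = calibrate_synapse(
        _default_exc(0.0), epsc_npy_pA, EPSC_HOLDING_MV, morphology
    )
    inh = calibrate_synapse(
        _default_inh(), ipsc_target_pA, IPSC_HOLDING_MV, morphology
    )
    return NetworkConfig(
        ucn3=ucn3,
        npy=npy,
        exc_ucn3=replace(exc_u, latency_ms=ABETA_LATENCY_UCN3_MS),
        exc_npy=replace(exc_n, latency_ms=ABETA_LATENCY_NPY_MS),
        inh=inh,
        **kwargs,
    )


def calibrate_abeta_drives(
    pop_ucn3,
    pop_npy,
    morphology: Morphology | None = None,
    calcium: CalciumPool | None = None,
    ucn3_open_fraction: float = 0.5,
    npy_responder_fraction: float = 0.95,
    bracket_pA: tuple = (60.0, 260.0),
    resolution_pA: float = 1.0,
    ipsc_target_pA: float = DEFAULT_IPSC_TARGET_PA,
) -> tuple:
    """Population-adaptive calibration of the two excitatory drive amplitudes.

    The unitary Abeta PSC amplitudes are not published, and with a shared
    morphology the population's synaptic firing thresholds span only a few
    pA, so any fixed amplitude sits on a knife edge.  This calibration fixes
    the drives relative to the baseline populations themselves:

    - the Ucn3 drive is the smallest EPSC amplitude at which at least
      ``ucn3_open_fraction`` (default one half — the population's *median
      synaptic threshold*, the scale-free choice) of disinhibited Ucn3
      models fire;
    - the NPY drive is the smallest amplitude at which at least
      ``npy_responder_fraction`` of NPY models fire, i.e. inhibition is
      reliable at baseline while staying as close to threshold as possible
      (so that conductance loss can still silence it).

    Calibrated once on the unperturbed populations and then frozen across
    all perturbation conditions.  Returns (epsc_ucn3_pA, epsc_npy_pA).
    """
    morphology = morphology or Morphology()
    calcium = calcium or CalciumPool()
    cfg0 = default_network_config(
        pop_ucn3[0].conductances, pop_npy[0].conductances, morphology,
        ipsc_target_pA=ipsc_target_pA,
    )
    exc_unit_u = calibrate_synapse(_default_exc(0.0), 1.0, EPSC_HOLDING_MV, morphology)

    models_u = [build_neuron(morphology, r.conductances, calcium) for r in pop_ucn3]
    models_n = [build_neuron(morphology, r.conductances, calcium) for r in pop_npy]

    def ucn3_fraction(amp):
        exc = replace(
            exc_unit_u, gpeak_uS=exc_unit_u.gpeak_uS * amp,
            latency_ms=ABETA_LATENCY_UCN3_MS,
        )
        cfg = replace(cfg0, exc_ucn3=exc)
        n = sum(
            len(_ucn3_response(m, (), replace(cfg, ucn3=m.conductances))) > 0
            for m in models_u
        )
        return n / len(models_u)

    def npy_fraction(amp):
        exc = replace(
            exc_unit_u, gpeak_uS=exc_unit_u.gpeak_uS * amp,
            latency_ms=ABETA_LATENCY_NPY_MS,
        )
        cfg = replace(cfg0, exc_npy=exc)
        n = sum(
            len(_npy_axon_spikes(m, replace(cfg, npy=m.conductances))) > 0
            for m in models_n
        )
        return n / len(models_n)

    def bisect_smallest(fraction_fn, target):
        lo, hi = bracket_pA
        if fraction_fn(hi) < target:
            log.warning("drive calibration: target fraction unreachable at %g pA", hi)
            return hi
        while hi - lo > resolution_pA:
            mid = 0.5 * (lo + hi)
            if fraction_fn(mid) >= target:
                hi = mid
            else:
                lo = mid
        return hi

    epsc_u = bisect_smallest(ucn3_fraction, ucn3_open_fraction)
    epsc_n = bisect_smallest(npy_fraction, npy_responder_fraction)
    log.info("calibrated Abeta drives: Ucn3 %.1f pA, NPY %.1f pA", epsc_u, epsc_n)
    return epsc_u, epsc_n


@dataclass
class GateResult:
    pair_ids: tuple
    ucn3_spike_times_ms: np.ndarray  # somatic, relative to trace start
    npy_spike_times_ms: np.ndarray  # last node, relative to trace start
    gate_open: bool

    @property
    def first_ucn3_latency_ms(self) -> float | None:
        return None if len(self.ucn3_spike_times_ms) == 0 else float(
            self.ucn3_spike_times_ms[0]
        )


def _run_cell(
    model: NeuronModel,
    synapses: Sequence[SynapticInput],
    watch_site: str,
    config: NetworkConfig,
):
    dt = config.dt_ms
    nsteps = int(round(config.record_ms / dt))
    V, hg, ng, ca = model.rest_state(dt, config.settle_ms)
    n_spk, _, spikes = model._run(
        V, hg, ng, ca, dt, nsteps, [], list(synapses), np.empty((0, 1)),
        np.empty(0, dtype=np.int64), watch_site=watch_site,
    )
    return spikes


def _npy_axon_spikes(model: NeuronModel, config: NetworkConfig) -> np.ndarray:
    syn = replace(config.exc_npy, latency_ms=0.0)
    ev = config.abeta_event_ms + config.exc_npy.latency_ms
    return _run_cell(
        model,
        [
            SynapticInput(
                site=syn.site, reversal_mV=syn.reversal_mV, gpeak_uS=syn.gpeak_uS,
                rise_ms=syn.rise_ms, decay_ms=syn.decay_ms, event_times_ms=(ev,),
            )
        ],
        "last_node",
        config,
    )


def _ucn3_response(
    model: NeuronModel, inh_event_times: tuple, config: NetworkConfig
) -> np.ndarray:
    ev = config.abeta_event_ms + config.exc_ucn3.latency_ms
    syns = [
        SynapticInput(
            site=config.exc_ucn3.site, reversal_mV=config.exc_ucn3.reversal_mV,
            gpeak_uS=config.exc_ucn3.gpeak_uS, rise_ms=config.exc_ucn3.rise_ms,
            decay_ms=config.exc_ucn3.decay_ms, event_times_ms=(ev,),
        )
    ]
    if inh_event_times:
        syns.append(
            SynapticInput(
                site=config.inh.site, reversal_mV=config.inh.reversal_mV,
                gpeak_uS=config.inh.gpeak_uS, rise_ms=config.inh.rise_ms,
                decay_ms=config.inh.decay_ms,
                event_times_ms=tuple(t + config.inh.latency_ms for t in inh_event_times),
            )
        )
    return _run_cell(model, syns, "soma", config)


def simulate_gate(
    config: NetworkConfig,
    morphology: Morphology | None = None,
    calcium: CalciumPool | None = None,
) -> GateResult:
    """Simulate one pair; the gate is open iff the Ucn3 cell fires a somatic
    spike within the gate window after the Abeta event."""
    morphology = morphology or Morphology()
    calcium = calcium or CalciumPool()
    npy_model = build_neuron(morphology, config.npy, calcium)
    npy_spikes = _npy_axon_spikes(npy_model, config)
    ucn3_model = build_neuron(morphology, config.ucn3, calcium)
    ucn3_spikes = _ucn3_response(ucn3_model, tuple(npy_spikes), config)
    t0, t1 = config.abeta_event_ms, config.abeta_event_ms + config.gate_window_ms
    gate_open = bool(np.any((ucn3_spikes >= t0) & (ucn3_spikes <= t1)))
    return GateResult(
        pair_ids=config.pair_ids,
        ucn3_spike_times_ms=ucn3_spikes,
        npy_spike_times_ms=npy_spikes,
        gate_open=gate_open,
    )


@dataclass
class GateScan:
    """Result of enumerating all pairwise networks."""

    n_networks: int
    n_open: int
    pairs: pd.DataFrame  # ucn3_id, npy_id, gate_open, first_ucn3_latency_ms
    ucn3_factors: dict
    npy_factors: dict

    @property
    def open_fraction_pct(self) -> float:
        return 100.0 * self.n_open / self.n_networks if self.n_networks else math.nan


def enumerate_networks(
    pop_ucn3: ModelPopulation,
    pop_npy: ModelPopulation,
    ucn3_perturbation: PerturbationSpec | None = None,
    npy_perturbation: PerturbationSpec | None = None,
    morphology: Morphology | None = None,
    calcium: CalciumPool | None = None,
    epsc_ucn3_pA: float = DEFAULT_EPSC_UCN3_PA,
    epsc_npy_pA: float = DEFAULT_EPSC_NPY_PA,
    ipsc_target_pA: float = DEFAULT_IPSC_TARGET_PA,
    config_kwargs: dict | None = None,
) -> GateScan:
    """Simulate every (Ucn3_i, NPY_j) permutation and count open gates.

    Class-wise perturbations are applied to every member of the respective
    population before simulation.  The NPY pass of each pair depends only on
    the NPY model, and the Ucn3 pass only on the Ucn3 model and the NPY
    spike train, so both passes are cached; results are independent of
    evaluation order.
    """
    if len(pop_ucn3) == 0 or len(pop_npy) == 0:
        raise ValueError("populations must be nonempty")
    morphology = morphology or Morphology()
    calcium = calcium or CalciumPool()
    cfg0 = default_network_config(
        pop_ucn3[0].conductances, pop_npy[0].conductances, morphology,
        epsc_ucn3_pA, epsc_npy_pA, ipsc_target_pA, **(config_kwargs or {}),
    )

    npy_trains = {}
    for rec in pop_npy:
        g = rec.conductances
        if npy_perturbation is not None:
            g = scale_conductance(g, npy_perturbation)
        model = build_neuron(morphology, g, calcium)
        spikes = _npy_axon_spikes(model, replace(cfg0, npy=g))
        npy_trains[rec.model_id] = tuple(np.round(spikes, 6))

    t0, t1 = cfg0.abeta_event_ms, cfg0.abeta_event_ms + cfg0.gate_window_ms
    rows = []
    n_open = 0
    ucn3_cache: dict = {}
    for urec in pop_ucn3:
        gu = urec.conductances
        if ucn3_perturbation is not None:
            gu = scale_conductance(gu, ucn3_perturbation)
        model = build_neuron(morphology, gu, calcium)
        per_train: dict = {}
        for nrec in pop_npy:
            train = npy_trains[nrec.model_id]
            if train not in per_train:
                spikes = _ucn3_response(model, train, replace(cfg0, ucn3=gu))
                in_window = spikes[(spikes >= t0) & (spikes <= t1)]
                per_train[train] = (
                    bool(len(in_window)),
                    float(in_window[0]) if len(in_window) else np.nan,
                )
            is_open, lat = per_train[train]
            n_open += is_open
            rows.append(
                {
                    "ucn3_id": urec.model_id,
                    "npy_id": nrec.model_id,
                    "gate_open": is_open,
                    "first_ucn3_latency_ms": lat,
                    "n_npy_spikes": len(train),
                }
            )
        ucn3_cache[urec.model_id] = per_train

    pairs = pd.DataFrame(rows)
    return GateScan(
        n_networks=len(pairs),
        n_open=n_open,
        pairs=pairs,
        ucn3_factors=dict(ucn3_perturbation.factors) if ucn3_perturbation else {},
        npy_factors=dict(npy_perturbation.factors) if npy_perturbation else {},
    )


def compare_open_vs_closed(
    scan: GateScan, pop_npy: ModelPopulation, exact_max_n: int = 8
) -> dict:
    """Mann-Whitney U on baseline NPY Nav1.6 conductance, grouped by whether
    each network's gate opened.

    Uses exact enumeration when both groups have at most ``exact_max_n``
    networks, otherwise the normal approximation with tie correction.
    Returns a no-test result when either group is empty.
    """
    gna = {rec.model_id: rec.conductances.gNav16 for rec in pop_npy}
    open_vals = scan.pairs.loc[scan.pairs.gate_open, "npy_id"].map(gna).to_numpy()
    closed_vals = scan.pairs.loc[~scan.pairs.gate_open, "npy_id"].map(gna).to_numpy()
    if len(open_vals) == 0 or len(closed_vals) == 0:
        return {
            "n_open": int(len(open_vals)),
            "n_closed": int(len(closed_vals)),
            "U": None,
            "p_value": None,
            "note": "one group empty; no test performed",
        }
    method = "exact" if max(len(open_vals), len(closed_vals)) <= exact_max_n else "asymptotic"
    res = stats.mannwhitneyu(
        open_vals, closed_vals, alternative="two-sided", method=method
    )
    return {
        "n_open": int(len(open_vals)),
        "n_closed": int(len(closed_vals)),
        "U": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_gNav16_open": float(np.median(open_vals)),
        "median_gNav16_closed": float(np.median(closed_vals)),
        "method": method,
    }
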