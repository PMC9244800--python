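"""Multicompartment cable engine for the model interneuron.

:func:`build_neuron` attaches a :class:`~itchgate.channels.ConductanceSet` to
a :class:`~itchgate.morphology.Morphology` and returns a simulatable
:class:`NeuronModel`.  Integration is implicit (backward Euler) on the
unbranched compartment chain at a fixed time step (20 us by default), with
exact-exponential gate relaxation; the stiff nodal and hillock kinetics make
explicit schemes unusable at this step size.

``simulate`` first settles the cell to its resting equilibrium (unrecorded,
no inputs), then integrates the recorded window with any step stimuli and
synaptic event trains attached.  The settled state is cached per model and
time step, so repeated protocol sweeps on one model (e.g. rheobase bisection)
pay the settling cost once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _kernel
from .channels import (
    CHANNEL_IDS,
    CalciumPool,
    ConductanceSet,
    hh_rates,
    load_all_channels,
    node_hh_parameters,
)
from .morphology import CompartmentChain, Morphology, SimulationConfig, discretize

__all__ = [
    "IntegrationError",
    "VoltageTrace",
    "NeuronModel",
    "SynapticInput",
    "build_neuron",
    "simulate",
]

_VGRID_MIN, _VGRID_MAX, _VGRID_STEP = -120.0, 60.0, 0.05


class IntegrationError(RuntimeError):
    """Numerical failure during integration, carrying the failure time."""

    def __init__(self, time_ms: float):
        super().__init__(f"integration failed (non-finite state) at t = {time_ms:.3f} ms")
        self.time_ms = time_ms


@dataclass
class VoltageTrace:
    """Uniformly sampled voltages per recorded site, with the somatic
    stimulus current aligned to the same grid."""

    time_ms: np.ndarray
    voltage_mV: dict  # {site: np.ndarray}
    stimulus_pA: np.ndarray
    dt_ms: float

    def __post_init__(self) -> None:
        for site, v in self.voltage_mV.items():
            if len(v) != len(self.time_ms):
                raise ValueError(f"site {site!r}: len(voltage) != len(time)")

    def v(self, site: str = "soma") -> np.ndarray:
        return self.voltage_mV[site]

    @property
    def sites(self) -> list:
        return list(self.voltage_mV)

    # -- tabular text round-trip --------------------------------------------

    def to_table(self, path) -> None:
        sites = self.sites
        header = (
            f"# itchgate voltage trace; dt_ms={self.dt_ms!r}; units: t ms, V mV, I pA\n"
            "t\t" + "\t".join(f"V[{s}]" for s in sites) + "\tI\n"
        )
        cols = [self.time_ms] + [self.voltage_mV[s] for s in sites] + [self.stimulus_pA]
        body = "\n".join("\t".join(repr(float(c[i])) for c in cols) for i in range(len(self.time_ms)))
        Path(path).write_text(header + body + "\n")

    @classmethod
    def from_table(cls, path) -> "VoltageTrace":
        lines = Path(path).read_text().splitlines()
        dt = float(lines[0].split("dt_ms=")[1].split(";")[0])
        names = lines[1].split("\t")
        sites = [n[2:-1] for n in names if n.startswith("V[")]
        data = np.array([[float(x) for x in ln.split("\t")] for ln in lines[2:]])
        return cls(
            time_ms=data[:, 0],
            voltage_mV={s: data[:, 1 + i] for i, s in enumerate(sites)},
            stimulus_pA=data[:, -1],
            dt_ms=dt,
        )

    @staticmethod
    def save_batch(path, traces: Sequence["VoltageTrace"]) -> None:
        """Binary container (npz) for batches of traces; carries dt and units."""
        arrs = {"units": np.array(["ms", "mV", "pA"])}
        for i, tr in enumerate(traces):
            arrs[f"trace{i}_time"] = tr.time_ms
            arrs[f"trace{i}_stim"] = tr.stimulus_pA
            arrs[f"trace{i}_dt"] = np.array([tr.dt_ms])
            for s in tr.sites:
                arrs[f"trace{i}_V_{s}"] = tr.voltage_mV[s]
        np.savez_compressed(path, **arrs)

    @staticmethod
    def load_batch(path) -> list:
        z = np.load(path, allow_pickle=False)
        out = []
        i = 0
        while f"trace{i}_time" in z:
            sites = {
                k[len(f"trace{i}_V_") :]: z[k]
                for k in z.files
                if k.startswith(f"trace{i}_V_")
            }
            out.append(
                VoltageTrace(
                    time_ms=z[f"trace{i}_time"],
                    voltage_mV=sites,
                    stimulus_pA=z[f"trace{i}_stim"],
                    dt_ms=float(z[f"trace{i}_dt"][0]),
                )
            )
            i += 1
        return out


@dataclass(frozen=True)
class SynapticInput:
    """A double-exponential conductance at a named site, driven by a sorted
    train of presynaptic event times (ms, in recorded-trace time)."""

    site: str
    reversal_mV: float
    gpeak_uS: float
    rise_ms: float
    decay_ms: float
    event_times_ms: tuple

    def __post_init__(self) -> None:
        if self.gpeak_uS < 0:
            raise ValueError("peak conductance must be >= 0")
        if not 0 < self.rise_ms:
            raise ValueError("rise time must be > 0")
        if self.rise_ms >= self.decay_ms:
            raise ValueError("need rise < decay")


def _dblexp_norm(rise: float, decay: float) -> float:
    tp = rise * decay / (decay - rise) * math.log(decay / rise)
    return 1.0 / (math.exp(-tp / decay) - math.exp(-tp / rise))


class NeuronModel:
    """A parameterized, simulatable model neuron.

    Active mechanisms are present only at the axon hillock (the seven fitted
    conductances) and the nodes of Ranvier (fixed HH kinetics); soma and
    dendrite are passive.  The initial state is the settled resting state
    with gating variables at their voltage steady state.
    """

    def __init__(
        self,
        morphology: Morphology,
        conductances: ConductanceSet,
        calcium: CalciumPool | None = None,
        active_axon: bool = True,
    ):
        self.morphology = morphology
        self.conductances = conductances
        self.calcium = calcium if calcium is not None else CalciumPool()
        self.chain: CompartmentChain = discretize(morphology)
        self.resting_potential_mV = morphology.passive_reversal_mV
        self.leak_reversal_mV = load_all_channels()["leak"].reversal_mV
        self._channels = load_all_channels()
        self._hh = node_hh_parameters()
        self._tables: dict = {}
        self._rest: dict = {}
        self._attached: list = []

        ch = self.chain
        nh = len(ch.hillock_indices)
        area_h = ch.area_cm2[ch.hillock_indices]
        g_arr = conductances.as_array()  # S/cm2, CHANNEL_IDS order
        self._hill_g = np.outer(area_h * 1e6, g_arr)  # (nh, 7) uS
        self._erev = np.array([self._channels[c].reversal_mV for c in CHANNEL_IDS])
        self._ica_conv = 1e-6 / area_h  # nA -> mA/cm2
        gate_powers = []
        ngates = []
        for cid in ("nav16", "kdr", "ka", "car"):
            gates = self._channels[cid].gates
            ngates.append(len(gates))
            gate_powers.extend(g.power for g in gates)
        self._pw = np.array(gate_powers, dtype=np.int64)
        self._chan_ngates = np.array(ngates, dtype=np.int64)
        self._nhv = len(gate_powers)  # hillock voltage-gate count

        area_n = ch.area_cm2[ch.node_indices]
        self._node_g = np.column_stack(
            [
                area_n * 1e6 * self._hh["gna_S_cm2"],
                area_n * 1e6 * self._hh["gk_S_cm2"],
                area_n * 1e6 * self._hh["gl_S_cm2"],
            ]
        )
        if not active_axon:
            # fully passive cell (unexcitable reference): nodes carry no
            # mechanism, their membrane reverts to the passive leak
            self._node_g[:, :] = 0.0
            ch.gpas_uS[ch.node_indices] = (
                morphology.passive_leak_S_cm2 * area_n * 1e6
            )
        self._hh_e = np.array([self._hh["ena_mV"], self._hh["ek_mV"], self._hh["el_mV"]])
        sk = next(g for g in self._channels["sk"].gates)
        bk = next(g for g in self._channels["bk"].gates)
        self._sk_params = (sk.params["kd_uM"], float(sk.params["hill"]), sk.params["tau_ms"])
        self._bk_params = (
            bk.params["vhalf0"],
            bk.params["slope"],
            bk.params["shift_per_decade_mV"],
            bk.params["ca_ref_uM"],
            bk.params["tau_ms"],
        )

    # -- rate tables ---------------------------------------------------------

    def _rate_tables(self, dt: float):
        key = round(dt, 9)
        if key in self._tables:
            return self._tables[key]
        vg = np.arange(_VGRID_MIN, _VGRID_MAX + _VGRID_STEP / 2, _VGRID_STEP)
        M = len(vg)
        inf_tab = np.empty((self._nhv + 3, M))
        rel_tab = np.empty((self._nhv + 3, M))
        row = 0
        for cid in ("nav16", "kdr", "ka", "car"):
            for g in self._channels[cid].gates:
                for m, v in enumerate(vg):
                    inf_tab[row, m] = g.steady_state(v)
                    rel_tab[row, m] = math.exp(-dt / g.time_constant(v))
                row += 1
        vshift = self._hh.get("vshift_mV", 0.0)
        for k, gate in enumerate(("m", "h", "n")):
            for m, v in enumerate(vg):
                a, b = hh_rates(v, vshift)[gate]
                inf_tab[row + k, m] = a / (a + b)
                rel_tab[row + k, m] = math.exp(-dt * (a + b))
        tabs = (vg[0], _VGRID_STEP, inf_tab, rel_tab)
        self._tables[key] = tabs
        return tabs

    # -- state ---------------------------------------------------------------

    def _initial_state(self):
        ch = self.chain
        v0 = self.resting_potential_mV
        V = np.full(ch.n, v0)
        ca0 = self.calcium.baseline
        nh = len(ch.hillock_indices)
        hg = np.empty((nh, self._nhv + 2))
        gate_specs = []
        for cid in ("nav16", "kdr", "ka", "car"):
            gate_specs.extend(self._channels[cid].gates)
        for j in range(nh):
            for row, g in enumerate(gate_specs):
                hg[j, row] = g.steady_state(v0, ca0)
            hg[j, self._nhv] = self._channels["sk"].gates[0].steady_state(v0, ca0)
            hg[j, self._nhv + 1] = self._channels["bk"].gates[0].steady_state(v0, ca0)
        nn = len(ch.node_indices)
        ng = np.empty((nn, 3))
        rates = hh_rates(v0, self._hh.get("vshift_mV", 0.0))
        for k, gate in enumerate(("m", "h", "n")):
            a, b = rates[gate]
            ng[:, k] = a / (a + b)
        ca = np.full(nh, ca0)
        return V, hg, ng, ca

    def rest_state(self, dt: float, settle_ms: float):
        """Settled state (V, gates, calcium) after ``settle_ms`` of free run."""
        key = (round(dt, 9), round(settle_ms, 6))
        if key in self._rest:
            return tuple(a.copy() for a in self._rest[key])
        V, hg, ng, ca = self._initial_state()
        if settle_ms > 0:
            self._run(
                V, hg, ng, ca, dt, int(round(settle_ms / dt)), [], [], np.empty((0, 1)),
                np.empty(0, dtype=np.int64),
            )
        self._rest[key] = (V, hg, ng, ca)
        return tuple(a.copy() for a in self._rest[key])

    # -- integration ---------------------------------------------------------

    def _run(
        self,
        V,
        hg,
        ng,
        ca,
        dt,
        nsteps,
        stimuli,
        synapses,
        out,
        rec_idx,
        watch_site="soma",
        watch_thresh=0.0,
        watch_min_slope=10.0,
        refrac_ms=2.0,
        stop_after_first=False,
        max_spikes=4000,
    ):
        ch = self.chain
        vmin, dv, inf_tab, rel_tab = self._rate_tables(dt)
        S = len(stimuli)
        stim_comp = np.empty(S, dtype=np.int64)
        stim_on = np.empty(S, dtype=np.int64)
        stim_off = np.empty(S, dtype=np.int64)
        stim_nA = np.empty(S)
        for s, st in enumerate(stimuli):
            stim_comp[s] = ch.index_of(getattr(st, "site", "soma") or "soma")
            stim_on[s] = int(round(st.delay_ms / dt))
            stim_off[s] = int(round((st.delay_ms + st.duration_ms) / dt))
            stim_nA[s] = st.amplitude_pA * 1e-3

        Y = len(synapses)
        syn_comp = np.empty(Y, dtype=np.int64)
        syn_e = np.empty(Y)
        syn_gnorm = np.empty(Y)
        syn_rr = np.empty(Y)
        syn_rd = np.empty(Y)
        events = []
        for y, syn in enumerate(synapses):
            syn_comp[y] = ch.index_of(syn.site)
            syn_e[y] = syn.reversal_mV
            rise, decay = syn.rise_ms, syn.decay_ms
            syn_gnorm[y] = syn.gpeak_uS * _dblexp_norm(rise, decay)
            syn_rr[y] = math.exp(-dt / rise)
            syn_rd[y] = math.exp(-dt / decay)
            for t in syn.event_times_ms:
                events.append((int(round(t / dt)), y))
        events.sort()
        ev_step = np.array([e[0] for e in events], dtype=np.int64)
        ev_syn = np.array([e[1] for e in events], dtype=np.int64)
        synA = np.zeros(Y)
        synB = np.zeros(Y)

        sk_kd, sk_hill, sk_tau = self._sk_params
        bk_vh0, bk_slope, bk_shift, bk_caref, bk_tau = self._bk_params
        cap = self.calcium
        spike_steps = np.full(max_spikes, -1, dtype=np.int64)
        n_spk, steps_done, status = _kernel.integrate(
            nsteps,
            dt,
            ch.c_nF / dt,
            ch.gpas_uS,
            ch.gpas_uS * ch.epas_mV,
            ch.g_axial_uS,
            ch.hillock_indices,
            self._hill_g,
            self._erev,
            self._ica_conv,
            self._chan_ngates,
            self._pw,
            vmin,
            dv,
            inf_tab,
            rel_tab,
            sk_kd,
            sk_hill,
            math.exp(-dt / sk_tau),
            bk_vh0,
            bk_slope,
            bk_shift,
            bk_caref,
            math.exp(-dt / bk_tau),
            cap.baseline,
            cap.k_uM_cm2_per_ms_mA * cap.tau_ms,
            math.exp(-dt / cap.tau_ms),
            ch.node_indices,
            self._node_g,
            self._hh_e,
            stim_comp,
            stim_on,
            stim_off,
            stim_nA,
            syn_comp,
            syn_e,
            syn_gnorm,
            syn_rr,
            syn_rd,
            ev_step,
            ev_syn,
            V,
            hg,
            ng,
            ca,
            synA,
            synB,
            rec_idx,
            out,
            ch.index_of(watch_site),
            watch_thresh,
            watch_min_slope,
            int(round(refrac_ms / dt)),
            spike_steps,
            stop_after_first,
        )
        if status == _kernel.STATUS_NUMERIC_FAILURE:
            raise IntegrationError(steps_done * dt)
        spikes = spike_steps[: min(n_spk, max_spikes)] * dt
        return n_spk, steps_done, spikes

    # -- public attachment API ----------------------------------------------

    def attach_point_stimulus(self, site: str, waveform) -> "StimulusHandle":
        """Attach a step-current stimulus at a named site; stimuli sum linearly."""
        import dataclasses

        self.chain.index_of(site)  # validate site before accepting
        entry = dataclasses.replace(waveform, site=site)
        self._attached.append(entry)
        return StimulusHandle(self, entry)


@dataclass
class StimulusHandle:
    model: NeuronModel
    stimulus: object

    def detach(self) -> None:
        self.model._attached.remove(self.stimulus)


def build_neuron(
    morphology: Morphology,
    conductances: ConductanceSet,
    calcium: CalciumPool | None = None,
    active_axon: bool = True,
) -> NeuronModel:
    """Validate inputs and return a simulatable :class:`NeuronModel`.

    ``active_axon=False`` strips the nodal mechanism as well, which together
    with an all-zero :class:`ConductanceSet` yields a fully passive
    (unexcitable) cell.
    """
    return NeuronModel(morphology, conductances, calcium, active_axon)


def simulate(
    model: NeuronModel,
    stimulus=None,
    config: SimulationConfig | None = None,
    synapses: Sequence[SynapticInput] = (),
) -> VoltageTrace:
    """Integrate the model and return the recorded voltage trace.

    The model is settled for ``config.settle_duration_ms`` (unrecorded, no
    inputs); the recorded window spans the remaining
    ``total_duration_ms - settle_duration_ms``, with stimulus delays measured
    from the start of the recorded window.  Deterministic given identical
    inputs.
    """
    if config is None:
        config = SimulationConfig()
    dt = config.dt_ms
    record_ms = config.total_duration_ms - config.settle_duration_ms
    nsteps = int(round(record_ms / dt))
    stimuli = list(model._attached)
    if stimulus is not None:
        stimuli.append(stimulus)
    for st in stimuli:
        if st.delay_ms + st.duration_ms > record_ms + 1e-9:
            raise ValueError("stimulus window extends beyond the recorded duration")

    V, hg, ng, ca = model.rest_state(dt, config.settle_duration_ms)
    rec_idx = np.array(
        [model.chain.index_of(s) for s in config.record_sites], dtype=np.int64
    )
    out = np.empty((len(rec_idx), nsteps + 1))
    model._run(V, hg, ng, ca, dt, nsteps, stimuli, list(synapses), out, rec_idx)

    time = np.arange(nsteps + 1) * dt
    stim_arr = np.zeros(nsteps + 1)
    soma_idx = model.chain.soma_index
    for st in stimuli:
        if model.chain.index_of(getattr(st, "site", "soma") or "soma") == soma_idx:
            i0 = int(round(st.delay_ms / dt))
            i1 = int(round((st.delay_ms + st.duration_ms) / dt))
            stim_arr[i0:i1] += st.amplitude_pA
    return VoltageTrace(
        time_ms=time,
        voltage_mV={s: out[i] for i, s in enumerate(config.record_sites)},
        stimulus_pA=stim_arr,
        dt_ms=dt,
    )
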