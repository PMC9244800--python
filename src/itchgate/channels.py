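"""Voltage- and calcium-dependent membrane mechanisms of the axon hillock.

Seven conductances define one model neuron: a Nav1.6-type transient sodium
channel, a delayed-rectifier potassium channel, an A-type potassium channel,
an SK (calcium-activated) potassium channel, a BK (calcium- and
voltage-activated) potassium channel, an R-type calcium channel, and a linear
leak.  Their maximal densities form the seven-dimensional parameter space
searched during population fitting (:class:`ConductanceSet`).

Kinetics are first-order Hodgkin-Huxley-type gates.  Voltage-dependent gates
use Boltzmann steady states and bell-shaped time constants; the SK gate is
purely calcium-dependent (Hill activation); the BK gate is jointly calcium-
and voltage-dependent via a calcium-shifted half-activation voltage.  All
rate parameters live in per-channel YAML files under ``data/channels`` so the
kinetics that produced a model population are auditable (see
:func:`kinetics_hash`).

This module is the single source of truth for the kinetics: the fast cable
engine tabulates the functions defined here.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "CHANNEL_IDS",
    "CONDUCTANCE_FIELDS",
    "ConductanceSet",
    "GatingState",
    "CalciumPool",
    "ChannelSpec",
    "load_channel",
    "load_all_channels",
    "node_hh_parameters",
    "gate_steady_state",
    "gate_time_constant",
    "channel_current",
    "advance_gates",
    "update_calcium",
    "hh_rates",
    "kinetics_hash",
]

#: The seven hillock mechanisms, in canonical order.
CHANNEL_IDS = ("nav16", "kdr", "ka", "sk", "bk", "car", "leak")

#: Field names of :class:`ConductanceSet`, aligned with :data:`CHANNEL_IDS`.
CONDUCTANCE_FIELDS = ("gNav16", "gKDR", "gKA", "gSK", "gBK", "gCaR", "gLk")


@dataclass(frozen=True)
class ConductanceSet:
    """Maximal conductance densities (S/cm2) of the seven hillock mechanisms.

    This is the parameter vector the ensemble MCMC explores; instances are
    immutable and validated on construction.
    """

    gNav16: float
    gKDR: float
    gKA: float
    gSK: float
    gBK: float
    gCaR: float
    gLk: float

    def __post_init__(self) -> None:
        for name in CONDUCTANCE_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"conductance {name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in CONDUCTANCE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ConductanceSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (7,):
            raise ValueError(f"expected 7 conductances, got shape {arr.shape}")
        return cls(*arr)

    def density(self, channel_id: str) -> float:
        return getattr(self, CONDUCTANCE_FIELDS[CHANNEL_IDS.index(channel_id)])

    def scaled(self, factors: Mapping[str, float]) -> "ConductanceSet":
        """Return a copy with the listed conductances multiplied by factors.

        Keys may be channel ids ("nav16") or field names ("gNav16").
        """
        updates = {}
        for key, f in factors.items():
            if f < 0:
                raise ValueError(f"scale factor for {key} must be >= 0, got {f}")
            name = key
            if key in CHANNEL_IDS:
                name = CONDUCTANCE_FIELDS[CHANNEL_IDS.index(key)]
            if name not in CONDUCTANCE_FIELDS:
                raise KeyError(f"unknown channel {key!r}")
            updates[name] = getattr(self, name) * f
        return replace(self, **updates)


@dataclass
class CalciumPool:
    """Single-compartment submembrane calcium shell (uM) with first-order
    extrusion toward baseline and influx proportional to the R-type current.

    d[Ca]/dt = -k * ICa - ([Ca] - baseline) / tau   (inward ICa < 0 raises Ca)
    with k in uM*cm2/(ms*mA).
    """

    concentration: float = 0.05
    baseline: float = 0.05
    tau_ms: float = 20.0
    k_uM_cm2_per_ms_mA: float = 1.5

    def __post_init__(self) -> None:
        if self.concentration < 0 or self.baseline < 0:
            raise ValueError("calcium concentrations must be >= 0")
        if self.tau_ms <= 0:
            raise ValueError("tau_ms must be > 0")


def update_calcium(pool: CalciumPool, ica_mA_cm2: float, dt: float) -> CalciumPool:
    """Advance the calcium pool one step (exact exponential update)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    ca_inf = pool.baseline - pool.k_uM_cm2_per_ms_mA * ica_mA_cm2 * pool.tau_ms
    ca = ca_inf + (pool.concentration - ca_inf) * math.exp(-dt / pool.tau_ms)
    return replace(pool, concentration=max(ca, 0.0))


# ---------------------------------------------------------------------------
# Channel parameter files


@dataclass(frozen=True)
class GateSpec:
    """One first-order gate: steady state and relaxation time constant."""

    name: str
    power: int
    kind: str  # "v" (Boltzmann in V) | "ca" (Hill in Ca) | "cav" (Ca-shifted Boltzmann)
    params: dict

    def steady_state(self, v: float, ca: float = 0.05) -> float:
        p = self.params
        if self.kind == "v":
            return 1.0 / (1.0 + math.exp((p["vhalf"] - v) / p["slope"]))
        if self.kind == "ca":
            can = max(ca, 0.0) ** p["hill"]
            return can / (can + p["kd_uM"] ** p["hill"])
        if self.kind == "cav":
            vh = p["vhalf0"] - p["shift_per_decade_mV"] * math.log10(
                max(ca, 1e-6) / p["ca_ref_uM"]
            )
            return 1.0 / (1.0 + math.exp((vh - v) / p["slope"]))
        raise ValueError(f"unknown gate kind {self.kind}")

    def time_constant(self, v: float) -> float:
        p = self.params
        if self.kind == "v":
            t = p["tau"]
            return t["base"] + t["amp"] / (
                math.exp((v - t["vmax"]) / t["s1"]) + math.exp(-(v - t["vmax"]) / t["s2"])
            )
        return p["tau_ms"]


@dataclass(frozen=True)
class ChannelSpec:
    """One hillock mechanism: its gates, reversal potential and ion."""

    name: str
    ion: str
    reversal_mV: float
    gates: tuple[GateSpec, ...] = field(default_factory=tuple)

    def open_fraction(self, gate_values: Mapping[str, float]) -> float:
        f = 1.0
        for g in self.gates:
            f *= gate_values[g.name] ** g.power
        return f


def _gate_from_yaml(d: dict) -> GateSpec:
    if "kd_uM" in d:
        kind = "ca"
    elif "vhalf0" in d:
        kind = "cav"
    else:
        kind = "v"
    return GateSpec(name=d["name"], power=int(d.get("power", 1)), kind=kind, params=d)


def _channel_files():
    return resources.files("itchgate").joinpath("data/channels")


def load_channel(channel_id: str) -> ChannelSpec:
    """Load one channel's kinetics from its parameter file."""
    if channel_id not in CHANNEL_IDS:
        raise KeyError(f"unknown channel {channel_id!r}; expected one of {CHANNEL_IDS}")
    raw = yaml.safe_load(_channel_files().joinpath(f"{channel_id}.yaml").read_text())
    gates = []
    for key in ("gates",):
        for g in raw.get(key, []) or []:
            gates.append(_gate_from_yaml(g))
    for key in ("ca_gate", "cav_gate"):
        if key in raw:
            gates.append(_gate_from_yaml(raw[key]))
    return ChannelSpec(
        name=raw["name"],
        ion=raw["ion"],
        reversal_mV=float(raw["reversal_mV"]),
        gates=tuple(gates),
    )


def load_all_channels() -> dict[str, ChannelSpec]:
    return {cid: load_channel(cid) for cid in CHANNEL_IDS}


def node_hh_parameters() -> dict:
    """Squid-type Hodgkin-Huxley parameters used at the nodes of Ranvier."""
    return yaml.safe_load(_channel_files().joinpath("node_hh.yaml").read_text())


def kinetics_hash() -> str:
    """SHA-256 over all channel parameter files (kinetics provenance tag)."""
    h = hashlib.sha256()
    for name in sorted(p.name for p in _channel_files().iterdir() if p.name.endswith(".yaml")):
        h.update(name.encode())
        h.update(_channel_files().joinpath(name).read_text().encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Gating state and the reference (pure-Python) kinetics API


@dataclass
class GatingState:
    """Gate values per channel, each in [0, 1], plus reversal potentials."""

    values: dict  # {channel_id: {gate_name: value}}
    reversals: dict  # {channel_id: E_rev mV}

    @classmethod
    def at_steady_state(cls, v: float, ca: float = 0.05) -> "GatingState":
        chans = load_all_channels()
        values = {
            cid: {g.name: g.steady_state(v, ca) for g in spec.gates}
            for cid, spec in chans.items()
        }
        reversals = {cid: spec.reversal_mV for cid, spec in chans.items()}
        return cls(values=values, reversals=reversals)

    def validate(self) -> None:
        for cid, gates in self.values.items():
            for name, x in gates.items():
                if not 0.0 <= x <= 1.0:
                    raise ValueError(f"gate {cid}.{name} = {x} outside [0, 1]")


def gate_steady_state(channel_id: str, v: float, ca: float = 0.05) -> dict:
    """Steady-state gate values of one channel at voltage ``v`` and calcium ``ca``."""
    if not math.isfinite(v):
        raise ValueError("voltage must be finite")
    spec = load_channel(channel_id)
    return {g.name: g.steady_state(v, ca) for g in spec.gates}


def gate_time_constant(channel_id: str, v: float) -> dict:
    spec = load_channel(channel_id)
    return {g.name: g.time_constant(v) for g in spec.gates}


def channel_current(
    channel_id: str, state: GatingState, v: float, ca: float = 0.05, g_density: float = 1.0
) -> float:
    """Ohmic current density (mA/cm2) of one mechanism at density ``g_density`` S/cm2.

    I = g * (product of gates^power) * (V - E_rev); positive = outward.
    """
    spec = load_channel(channel_id)
    openf = spec.open_fraction(state.values[channel_id]) if spec.gates else 1.0
    return g_density * openf * (v - state.reversals[channel_id])


def advance_gates(
    state: GatingState, pool: CalciumPool, v: float, dt: float
) -> GatingState:
    """Relax every gate toward its steady state (exact exponential update)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    chans = load_all_channels()
    new_values = {}
    for cid, spec in chans.items():
        new_values[cid] = {}
        for g in spec.gates:
            x = state.values[cid][g.name]
            xinf = g.steady_state(v, pool.concentration)
            tau = g.time_constant(v)
            xnew = xinf + (x - xinf) * math.exp(-dt / tau)
            new_values[cid][g.name] = min(max(xnew, 0.0), 1.0)
    return GatingState(values=new_values, reversals=dict(state.reversals))


def hh_rates(v: float, vshift: float = 0.0) -> dict:
    """Classic Hodgkin-Huxley alpha/beta rates (ms^-1) for the nodal m, h, n gates.

    Conventional forms referenced to a resting potential of -65 mV; a
    positive ``vshift`` moves the gating voltage dependence depolarized
    (rates are evaluated at v - vshift).
    """
    v = v - vshift

    def vtrap(x, y):
        # removable singularity of x/(exp(x/y)-1)
        if abs(x / y) < 1e-6:
            return y * (1.0 - x / y / 2.0)
        return x / (math.exp(x / y) - 1.0)

    am = 0.1 * vtrap(-(v + 40.0), 10.0)
    bm = 4.0 * math.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * math.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    an = 0.01 * vtrap(-(v + 55.0), 10.0)
    bn = 0.125 * math.exp(-(v + 65.0) / 80.0)
    return {"m": (am, bm), "h": (ah, bh), "n": (an, bn)}
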