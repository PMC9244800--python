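"""Ball-and-stick interneuron morphology with a myelinated axon.

The model cell is a soma with one equivalent dendritic cable on one side and,
on the other, a tapering axon hillock followed by a myelinated axon of 41
internode/node-of-Ranvier pairs (one internode preceding each node).  Active
conductances live only in the hillock (the seven fitted mechanisms) and at the
nodes (squid-type Hodgkin-Huxley kinetics for propagation); soma and dendrite
are passive.

Topologically the cell is an unbranched chain, discretized here as

    dend_0 ... dend_{n-1} | soma | hillock_0 ... | inter_0 node_0 ... inter_40 node_40

with 0-based compartment indexing and named sites ("soma", "dendrite_mid",
"node_40", ...).  Exact geometric and passive constants of real superficial
dorsal-horn interneurons are not tightly constrained; the defaults below give
a somatic input resistance in the several-hundred-megohm range typical of
these small cells and are all overridable via the config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SectionSpec",
    "TaperSpec",
    "MyelinSpec",
    "NodeSpec",
    "Morphology",
    "SimulationConfig",
    "CompartmentChain",
    "discretize",
]

N_NODES_REQUIRED = 41


@dataclass(frozen=True)
class SectionSpec:
    length_um: float
    diameter_um: float
    n_segments: int = 1


@dataclass(frozen=True)
class TaperSpec:
    """Axon hillock: linear taper from soma-side to axon-side diameter."""

    length_um: float
    diameter_start_um: float
    diameter_end_um: float
    n_segments: int = 2


@dataclass(frozen=True)
class MyelinSpec:
    """Internodes: passive cable with strongly reduced capacitance and leak."""

    count: int
    length_um: float
    diameter_um: float
    capacitance_uF_cm2: float = 0.02
    leak_S_cm2: float = 5.0e-7


@dataclass(frozen=True)
class NodeSpec:
    count: int
    length_um: float
    diameter_um: float


@dataclass(frozen=True)
class Morphology:
    soma: SectionSpec = SectionSpec(length_um=10.0, diameter_um=10.0)
    dendrite: SectionSpec = SectionSpec(length_um=500.0, diameter_um=1.0, n_segments=5)
    axon_hillock: TaperSpec = TaperSpec(
        length_um=20.0, diameter_start_um=2.0, diameter_end_um=1.0, n_segments=2
    )
    internodes: MyelinSpec = MyelinSpec(count=41, length_um=100.0, diameter_um=1.0)
    nodes_of_ranvier: NodeSpec = NodeSpec(count=41, length_um=1.0, diameter_um=1.0)
    axial_resistivity_ohm_cm: float = 100.0
    membrane_capacitance_uF_cm2: float = 1.0
    # fixed passive membrane of soma/dendrite (not part of the fitted space)
    passive_leak_S_cm2: float = 3.5e-5
    passive_reversal_mV: float = -65.0

    def __post_init__(self) -> None:
        if self.nodes_of_ranvier.count != N_NODES_REQUIRED:
            raise ValueError(
                f"model axon requires {N_NODES_REQUIRED} nodes of Ranvier, "
                f"got {self.nodes_of_ranvier.count}"
            )
        if self.internodes.count != self.nodes_of_ranvier.count:
            raise ValueError("one internode must precede each node")
        if self.dendrite.n_segments < 3:
            raise ValueError("dendrite needs >= 3 segments (midpoint attachment site)")
        for name, length, diam in [
            ("soma", self.soma.length_um, self.soma.diameter_um),
            ("dendrite", self.dendrite.length_um, self.dendrite.diameter_um),
            ("hillock", self.axon_hillock.length_um, self.axon_hillock.diameter_start_um),
            ("hillock", self.axon_hillock.length_um, self.axon_hillock.diameter_end_um),
            ("internode", self.internodes.length_um, self.internodes.diameter_um),
            ("node", self.nodes_of_ranvier.length_um, self.nodes_of_ranvier.diameter_um),
        ]:
            if length <= 0 or diam <= 0:
                raise ValueError(f"{name} lengths/diameters must be > 0")
        if self.axial_resistivity_ohm_cm <= 0 or self.membrane_capacitance_uF_cm2 <= 0:
            raise ValueError("axial resistivity and capacitance must be > 0")

    # -- config round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Morphology":
        return cls(
            soma=SectionSpec(**d["soma"]),
            dendrite=SectionSpec(**d["dendrite"]),
            axon_hillock=TaperSpec(**d["axon_hillock"]),
            internodes=MyelinSpec(**d["internodes"]),
            nodes_of_ranvier=NodeSpec(**d["nodes_of_ranvier"]),
            **{
                k: d[k]
                for k in (
                    "axial_resistivity_ohm_cm",
                    "membrane_capacitance_uF_cm2",
                    "passive_leak_S_cm2",
                    "passive_reversal_mV",
                )
                if k in d
            },
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "Morphology":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class SimulationConfig:
    """Global integration settings.

    Kinetics are defined at the fixed recording temperature (23 degC); the
    temperature field is declarative, no Q10 rescaling is applied.
    """

    temperature_C: float = 23.0
    dt_ms: float = 0.02
    total_duration_ms: float = 700.0
    settle_duration_ms: float = 200.0
    record_sites: tuple[str, ...] = ("soma",)

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt must be > 0")
        if not 0 <= self.settle_duration_ms < self.total_duration_ms:
            raise ValueError("need 0 <= settle_duration < total_duration")


# ---------------------------------------------------------------------------
# Discretization


@dataclass
class CompartmentChain:
    """Flat arrays describing the discretized unbranched cable.

    Units: areas cm2, capacitances nF, conductances uS, lengths cm.
    ``g_axial[i]`` couples compartment i to i+1.
    """

    names: list
    area_cm2: np.ndarray
    c_nF: np.ndarray
    gpas_uS: np.ndarray
    epas_mV: np.ndarray
    g_axial_uS: np.ndarray
    soma_index: int
    dendrite_mid_index: int
    hillock_indices: np.ndarray
    node_indices: np.ndarray

    @property
    def n(self) -> int:
        return len(self.names)

    def index_of(self, site: str) -> int:
        """Resolve a named site to a compartment index."""
        if site == "soma":
            return self.soma_index
        if site == "dendrite_mid":
            return self.dendrite_mid_index
        if site == "last_node":
            return int(self.node_indices[-1])
        try:
            return self.names.index(site)
        except ValueError:
            raise KeyError(f"unknown site {site!r}") from None


def _half_r_Mohm(ra_ohm_cm: float, length_cm: float, diam_cm: float) -> float:
    area_cross = np.pi * (diam_cm / 2.0) ** 2
    return ra_ohm_cm * (length_cm / 2.0) / area_cross / 1e6


def discretize(morph: Morphology) -> CompartmentChain:
    """Build the compartment chain (dendrite -> soma -> hillock -> axon)."""
    um = 1e-4  # cm per um
    names: list[str] = []
    L: list[float] = []
    D: list[float] = []
    cm: list[float] = []
    gp: list[float] = []

    nd = morph.dendrite.n_segments
    for i in range(nd):
        names.append(f"dend_{nd - 1 - i}")  # distal first
        L.append(morph.dendrite.length_um / nd * um)
        D.append(morph.dendrite.diameter_um * um)
        cm.append(morph.membrane_capacitance_uF_cm2)
        gp.append(morph.passive_leak_S_cm2)
    soma_index = len(names)
    names.append("soma")
    L.append(morph.soma.length_um * um)
    D.append(morph.soma.diameter_um * um)
    cm.append(morph.membrane_capacitance_uF_cm2)
    gp.append(morph.passive_leak_S_cm2)

    nh = morph.axon_hillock.n_segments
    hillock_indices = []
    for i in range(nh):
        frac = (i + 0.5) / nh
        d = morph.axon_hillock.diameter_start_um + frac * (
            morph.axon_hillock.diameter_end_um - morph.axon_hillock.diameter_start_um
        )
        hillock_indices.append(len(names))
        names.append(f"hillock_{i}")
        L.append(morph.axon_hillock.length_um / nh * um)
        D.append(d * um)
        cm.append(morph.membrane_capacitance_uF_cm2)
        gp.append(0.0)  # hillock leak comes from the fitted gLk mechanism

    node_indices = []
    for k in range(morph.nodes_of_ranvier.count):
        names.append(f"inter_{k}")
        L.append(morph.internodes.length_um * um)
        D.append(morph.internodes.diameter_um * um)
        cm.append(morph.internodes.capacitance_uF_cm2)
        gp.append(morph.internodes.leak_S_cm2)
        node_indices.append(len(names))
        names.append(f"node_{k}")
        L.append(morph.nodes_of_ranvier.length_um * um)
        D.append(morph.nodes_of_ranvier.diameter_um * um)
        cm.append(morph.membrane_capacitance_uF_cm2)
        gp.append(0.0)  # nodal leak comes from the HH mechanism

    L_arr = np.array(L)
    D_arr = np.array(D)
    area = np.pi * D_arr * L_arr  # lateral cylinder area, cm2
    c_nF = np.array(cm) * area * 1e3  # uF/cm2 * cm2 = uF -> nF
    gpas_uS = np.array(gp) * area * 1e6  # S -> uS
    epas = np.full(len(names), morph.passive_reversal_mV)

    ra = morph.axial_resistivity_ohm_cm
    g_ax = np.empty(len(names) - 1)
    for i in range(len(names) - 1):
        r = _half_r_Mohm(ra, L_arr[i], D_arr[i]) + _half_r_Mohm(ra, L_arr[i + 1], D_arr[i + 1])
        g_ax[i] = 1.0 / r  # uS (1/Mohm)

    return CompartmentChain(
        names=names,
        area_cm2=area,
        c_nF=c_nF,
        gpas_uS=gpas_uS,
        epas_mV=epas,
        g_axial_uS=g_ax,
        soma_index=soma_index,
        dendrite_mid_index=nd // 2,
        hillock_indices=np.array(hillock_indices, dtype=np.int64),
        node_indices=np.array(node_indices, dtype=np.int64),
    )
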