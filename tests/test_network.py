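"""Microcircuit tests: synaptic waveform closed forms, gate logic on
exemplar pairs, and the Mann-Whitney comparison vs exhaustive enumeration."""

import itertools
import math
from dataclasses import replace

import numpy as np
import pytest

from itchgate import ConductanceSet
from itchgate.network import (
    GateScan,
    NetworkConfig,
    SynapseSpec,
    calibrate_synapse,
    compare_open_vs_closed,
    default_network_config,
    enumerate_networks,
    simulate_gate,
    synaptic_conductance,
)
from itchgate.population import ModelPopulation, ModelRecord
from itchgate.protocols import FeatureVector

from conftest import NPY_EXEMPLAR, PASSIVE, UCN3_EXEMPLAR


def tiny_pop(cell, *gsets):
    recs = [
        ModelRecord(
            f"{cell}_{i:04d}", g, FeatureVector(None, None, None, None, None, "other"),
            0.0, 0, 0,
        )
        for i, g in enumerate(gsets)
    ]
    return ModelPopulation(cell_class=cell, records=recs)


@pytest.fixture(scope="module")
def exemplar_config():
    return default_network_config(UCN3_EXEMPLAR, NPY_EXEMPLAR)


class TestSynapticConductance:
    SPEC = SynapseSpec(rise_ms=0.1, decay_ms=5.0, reversal_mV=0.0, gpeak_uS=2e-3)

    def test_zero_at_event_and_before(self):
        assert synaptic_conductance(self.SPEC, 0.0) == 0.0
        assert synaptic_conductance(self.SPEC, -3.0) == 0.0

    def test_peak_location_and_amplitude_closed_form(self):
        r, d = self.SPEC.rise_ms, self.SPEC.decay_ms
        tp = r * d / (d - r) * math.log(d / r)
        t = np.linspace(0, 50, 200_001)
        g = synaptic_conductance(self.SPEC, t)
        i = np.argmax(g)
        assert t[i] == pytest.approx(tp, abs=1e-3)
        assert g[i] == pytest.approx(self.SPEC.gpeak_uS, rel=1e-6)

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(ValueError):
            SynapseSpec(rise_ms=5.0, decay_ms=5.0, reversal_mV=0.0, gpeak_uS=1.0)
        with pytest.raises(ValueError):
            SynapseSpec(rise_ms=0.1, decay_ms=5.0, reversal_mV=0.0, gpeak_uS=-1.0)

    def test_latency_ordering_enforced(self, exemplar_config):
        with pytest.raises(ValueError):
            replace(
                exemplar_config,
                exc_ucn3=replace(exemplar_config.exc_ucn3, latency_ms=1.0),
            )

    def test_calibrated_psc_amplitude(self):
        """Re-simulating the clamp with the calibrated gpeak returns the
        target amplitude (calibration is self-consistent)."""
        from itchgate.network import EPSC_HOLDING_MV, _default_exc

        spec = calibrate_synapse(_default_exc(0.0), 150.0, EPSC_HOLDING_MV)
        double = calibrate_synapse(_default_exc(0.0), 300.0, EPSC_HOLDING_MV)
        assert double.gpeak_uS == pytest.approx(2 * spec.gpeak_uS, rel=1e-6)


class TestGateLogic:
    def test_no_excitation_all_silent(self, exemplar_config):
        cfg = replace(
            exemplar_config,
            exc_ucn3=replace(exemplar_config.exc_ucn3, gpeak_uS=0.0),
            exc_npy=replace(exemplar_config.exc_npy, gpeak_uS=0.0),
        )
        res = simulate_gate(cfg)
        assert not res.gate_open
        assert len(res.ucn3_spike_times_ms) == 0
        assert len(res.npy_spike_times_ms) == 0

    def test_feed_forward_inhibition_closes_gate(self, exemplar_config):
        res = simulate_gate(exemplar_config)
        assert len(res.npy_spike_times_ms) >= 1
        assert not res.gate_open

    def test_unexcitable_npy_opens_gate(self, exemplar_config):
        """Replacing the NPY cell with a passive model reduces the pair to
        the single-cell EPSP-to-spike simulation, which is open."""
        cfg = replace(exemplar_config, npy=PASSIVE)
        res = simulate_gate(cfg)
        assert len(res.npy_spike_times_ms) == 0
        assert res.gate_open
        # oracle: direct single-cell simulation with no inhibitory events
        cfg_noinh = replace(
            exemplar_config, inh=replace(exemplar_config.inh, gpeak_uS=0.0)
        )
        oracle = simulate_gate(cfg_noinh)
        np.testing.assert_allclose(
            res.ucn3_spike_times_ms, oracle.ucn3_spike_times_ms, atol=1e-9
        )

    def test_deterministic(self, exemplar_config):
        r1 = simulate_gate(exemplar_config)
        r2 = simulate_gate(exemplar_config)
        np.testing.assert_array_equal(r1.npy_spike_times_ms, r2.npy_spike_times_ms)
        assert r1.gate_open == r2.gate_open


class TestEnumerate:
    def test_one_by_one(self):
        pu = tiny_pop("ucn3", UCN3_EXEMPLAR)
        pn = tiny_pop("npy", NPY_EXEMPLAR)
        scan = enumerate_networks(pu, pn)
        assert scan.n_networks == 1

    def test_pair_count_is_product(self):
        pu = tiny_pop("ucn3", UCN3_EXEMPLAR, UCN3_EXEMPLAR.scaled({"gNav16": 1.1}))
        pn = tiny_pop(
            "npy",
            NPY_EXEMPLAR,
            NPY_EXEMPLAR.scaled({"gNav16": 0.9}),
            NPY_EXEMPLAR.scaled({"gKDR": 1.1}),
        )
        scan = enumerate_networks(pu, pn)
        assert scan.n_networks == 6

    def test_empty_population_rejected(self):
        pu = tiny_pop("ucn3", UCN3_EXEMPLAR)
        with pytest.raises(ValueError):
            enumerate_networks(pu, tiny_pop("npy"))


class TestMannWhitney:
    @staticmethod
    def _scan(open_ids, closed_ids):
        import pandas as pd

        pairs = pd.DataFrame(
            [{"ucn3_id": "u", "npy_id": i, "gate_open": True} for i in open_ids]
            + [{"ucn3_id": "u", "npy_id": i, "gate_open": False} for i in closed_ids]
        )
        return GateScan(
            n_networks=len(pairs), n_open=len(open_ids), pairs=pairs,
            ucn3_factors={}, npy_factors={},
        )

    @staticmethod
    def _pop(gnavals):
        return tiny_pop(
            "npy",
            *[
                ConductanceSet(g, 0.1, 0.005, 0.02, 0.01, 0.005, 1e-4)
                for g in gnavals
            ],
        )

    def test_identical_groups_symmetric(self):
        pop = self._pop([0.4, 0.4, 0.4, 0.4])
        scan = self._scan(["npy_0000", "npy_0001"], ["npy_0002", "npy_0003"])
        out = compare_open_vs_closed(scan, pop)
        assert out["U"] == pytest.approx(2 * 2 / 2)
        assert out["p_value"] == pytest.approx(1.0)

    def test_separated_groups_exact_p(self):
        # open {1,2} vs closed {3,4}: U = 0, exact two-sided p = 2/6
        pop = self._pop([0.1, 0.2, 0.3, 0.4])
        scan = self._scan(["npy_0000", "npy_0001"], ["npy_0002", "npy_0003"])
        out = compare_open_vs_closed(scan, pop)
        assert out["U"] == 0
        assert out["p_value"] == pytest.approx(2 / 6)
        assert out["method"] == "exact"

    def test_exact_matches_enumeration(self):
        """U and p agree with a brute-force enumeration over all rank
        assignments for small groups."""
        rng = np.random.default_rng(0)
        gna = np.round(rng.uniform(0.1, 0.9, size=7), 3)
        pop = self._pop(gna)
        ids = [f"npy_{i:04d}" for i in range(7)]
        scan = self._scan(ids[:3], ids[3:])
        out = compare_open_vs_closed(scan, pop)

        x, y = gna[:3], gna[3:]
        u_obs = sum(
            (xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y
        )
        u_obs = min(u_obs, len(x) * len(y) - u_obs)
        # enumerate all choices of which 3 of 7 values form group 1
        count = total = 0
        for comb in itertools.combinations(range(7), 3):
            xs = gna[list(comb)]
            ys = gna[[i for i in range(7) if i not in comb]]
            u = sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)
            u = min(u, len(xs) * len(ys) - u)
            total += 1
            if u <= u_obs:
                count += 1
        p_exact = count / total
        assert out["p_value"] == pytest.approx(p_exact, abs=1e-9)

    def test_empty_group_no_test(self):
        pop = self._pop([0.1, 0.2])
        scan = self._scan([], ["npy_0000", "npy_0001"])
        out = compare_open_vs_closed(scan, pop)
        assert out["U"] is None and "note" in out
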