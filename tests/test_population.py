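"""Score, density, ensemble-sampler and filtering tests.

The sampler tests target analytically known densities (uniform box,
Gaussian), independent of the neuron simulator; a separate test cross-checks
the stretch move against the emcee reference implementation on the same
density.
"""

import math

import numpy as np
import pytest
from scipy import stats

from itchgate.channels import ConductanceSet
from itchgate.population import (
    EnsembleState,
    MetricTarget,
    ModelPopulation,
    PriorBox,
    SCORE_THRESHOLD,
    TargetSet,
    UNDEFINED_FEATURE_DISTANCE,
    filter_population,
    log_probability,
    run_parameterization,
    score_model,
    stretch_move,
)
from itchgate.protocols import FeatureVector


def fv(rheo=40.0, n60=3, thr=-35.5, dvdt=250.0, hw=4.2, pattern="initial_bursting"):
    return FeatureVector(
        rheobase_pA=rheo,
        n_spikes_60pA=n60,
        ap_threshold_mV=thr,
        max_dvdt_mV_ms=dvdt,
        half_width_ms=hw,
        firing_pattern=pattern,
    )


def targets_2d(required_pattern="initial_bursting"):
    return TargetSet(
        cell_class="ucn3",
        group="control",
        metrics={
            "rheobase_pA": MetricTarget(40.0, 10.0),
            "half_width_ms": MetricTarget(4.0, 1.0),
        },
        required_pattern=required_pattern,
    )


class TestScore:
    def test_exact_match_scores_zero(self):
        t = targets_2d()
        assert score_model(fv(rheo=40.0, hw=4.0), t) == 0.0

    def test_mean_of_normalized_distances(self):
        # distances 0.4 and 0.8 with equal weights -> 0.6
        t = targets_2d()
        s = score_model(fv(rheo=44.0, hw=4.8), t)
        assert s == pytest.approx(0.6)

    def test_monotone_in_deviation(self):
        t = targets_2d()
        s1 = score_model(fv(rheo=42.0, hw=4.0), t)
        s2 = score_model(fv(rheo=50.0, hw=4.0), t)
        assert s2 > s1 > 0

    def test_undefined_feature_fixed_distance(self):
        t = targets_2d()
        s = score_model(fv(rheo=None, hw=4.0), t)
        assert s == pytest.approx(UNDEFINED_FEATURE_DISTANCE / 2)

    def test_pattern_gate_exceeds_threshold_alone(self):
        t = targets_2d()
        s = score_model(fv(rheo=40.0, hw=4.0, pattern="tonic"), t)
        assert s > SCORE_THRESHOLD

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            TargetSet("ucn3", "control", {}, "tonic")


class TestLogProbability:
    class ConstScoreSim:
        """Simulator stub whose features produce a chosen score."""

        def __init__(self, rheo):
            self.rheo = rheo

        def features(self, x):
            return fv(rheo=self.rheo, hw=4.0)

    def test_stated_density(self):
        # score 1 -> logp = -0.5 at the default unit inverse temperature
        t = targets_2d()
        sim = self.ConstScoreSim(rheo=60.0)  # distances (2.0, 0) -> score 1
        assert score_model(sim.features(None), t) == pytest.approx(1.0)
        lp = log_probability(np.full(7, 1e-4), t, sim)
        assert lp == pytest.approx(-0.5)

    def test_perfect_match_is_maximum(self):
        t = targets_2d()
        sim = self.ConstScoreSim(rheo=40.0)
        assert log_probability(np.full(7, 1e-4), t, sim) == 0.0

    def test_negative_conductance_outside_support(self):
        t = targets_2d()
        sim = self.ConstScoreSim(rheo=40.0)
        x = np.full(7, 1e-4)
        x[0] = -1e-9
        assert log_probability(x, t, sim) == -math.inf


class TestStretchMove:
    @staticmethod
    def _run_chain(log_prob, x0, n_sweeps, rng, a=2.0):
        lp = np.array([log_prob(x) for x in x0])
        ens = EnsembleState(positions=x0, log_probs=lp, stretch_a=a)
        samples = []
        for _ in range(n_sweeps):
            ens = stretch_move(ens, log_prob, rng)
            samples.append(ens.positions.copy())
        return ens, np.concatenate(samples)

    def test_degenerate_stretch_keeps_positions(self):
        rng = np.random.default_rng(0)
        x0 = rng.random((8, 2))
        ens, _ = self._run_chain(lambda x: 0.0, x0.copy(), 3, rng, a=1.0)
        np.testing.assert_array_equal(ens.positions, x0)

    def test_uniform_box_marginals(self):
        """Long-run walker positions on a uniform box pass a per-coordinate
        KS test against U(0,1) at alpha = 0.01."""

        def logp(x):
            return 0.0 if np.all((x >= 0) & (x <= 1)) else -math.inf

        rng = np.random.default_rng(42)
        n_walkers = 20
        x0 = rng.random((n_walkers, 3))
        _, samples = self._run_chain(logp, x0, 12_000, rng)
        sweeps = samples.reshape(12_000, n_walkers, 3)
        # discard burn-in and thin by the measured integrated
        # autocorrelation time (~50 sweeps) so the KS independence
        # assumption approximately holds
        draws = sweeps[2000::50].reshape(-1, 3)  # 4000 draws
        for d in range(3):
            p = stats.kstest(draws[:, d], "uniform").pvalue
            assert p > 0.01, f"coordinate {d}: KS p={p}"

    def test_standard_normal_moments(self):
        """Sample mean within 3 standard errors of 0 and variance near 1 for
        a 1-D standard normal target."""

        def logp(x):
            return -0.5 * float(x[0]) ** 2

        rng = np.random.default_rng(7)
        x0 = rng.normal(size=(16, 1))
        _, samples = self._run_chain(logp, x0, 800, rng)
        s = samples[len(samples) // 2 :, 0]
        n_eff = len(s) / 20.0  # crude autocorrelation discount
        assert abs(np.mean(s)) < 3.0 / math.sqrt(n_eff)
        assert np.var(s) == pytest.approx(1.0, rel=0.15)

    def test_matches_emcee_on_gaussian(self):
        """Independent cross-check: our stretch move and emcee target the
        same 2-D Gaussian; first and second moments agree."""
        emcee = pytest.importorskip("emcee")

        def logp(x):
            return -0.5 * float(np.sum(x**2))

        rng = np.random.default_rng(3)
        x0 = rng.normal(size=(20, 2))
        _, ours = self._run_chain(logp, x0.copy(), 1500, rng)
        ours = ours[len(ours) // 2 :]

        sampler = emcee.EnsembleSampler(20, 2, logp)
        sampler.run_mcmc(x0, 1500, progress=False)
        theirs = sampler.get_chain(discard=750, flat=True)
        for d in range(2):
            assert abs(np.mean(ours[:, d]) - np.mean(theirs[:, d])) < 0.2
            assert abs(np.std(ours[:, d]) - np.std(theirs[:, d])) < 0.2

    def test_walker_count_validation(self):
        with pytest.raises(ValueError):
            EnsembleState(positions=np.zeros((4, 3)), log_probs=np.zeros(4))


class TestFilterAndDedupe:
    def _cand(self, x, score, pattern="initial_bursting"):
        return (np.asarray(x, dtype=float), fv(pattern=pattern), score, 0, 0)

    def test_empty_input(self):
        pop = filter_population([], "ucn3")
        assert len(pop) == 0

    def test_duplicates_collapse(self):
        x = [0.1, 0.02, 0.003, 0.0004, 0.5, 0.06, 0.0007]
        pop = filter_population([self._cand(x, 0.3)] * 400, "ucn3")
        assert len(pop) == 1

    def test_sixth_significant_digit_dedupe(self):
        a = self._cand([0.1000000, 0.02, 0.003, 0.0004, 0.5, 0.06, 0.0007], 0.3)
        b = self._cand([0.10000004, 0.02, 0.003, 0.0004, 0.5, 0.06, 0.0007], 0.4)
        c = self._cand([0.100002, 0.02, 0.003, 0.0004, 0.5, 0.06, 0.0007], 0.5)
        pop = filter_population([a, b, c], "ucn3")
        assert len(pop) == 2  # a == b after rounding; c distinct

    def test_boundary_score_retained(self):
        pops = filter_population(
            [
                self._cand([0.1] * 7, 0.59),
                self._cand([0.2] * 7, 0.60),
                self._cand([0.3] * 7, 0.61),
            ],
            "ucn3",
        )
        assert len(pops) == 2
        assert max(r.score for r in pops) == pytest.approx(0.60)

    def test_pattern_requirement(self):
        pop = filter_population(
            [self._cand([0.1] * 7, 0.3, "tonic"), self._cand([0.2] * 7, 0.3)],
            "ucn3",
            required_pattern="initial_bursting",
        )
        assert len(pop) == 1

    def test_ordering_by_score(self):
        pop = filter_population(
            [self._cand([0.3] * 7, 0.5), self._cand([0.1] * 7, 0.1)], "ucn3"
        )
        assert [r.score for r in pop] == [0.1, 0.5]


class TestPopulationIO:
    def test_save_load_roundtrip(self, tmp_path):
        pop = filter_population(
            [
                (np.array([0.1, 0.02, 0.003, 0.0004, 0.5, 0.06, 0.0007]), fv(), 0.25, 1, 9),
                (np.array([0.2, 0.01, 0.004, 0.0014, 0.4, 0.05, 0.0002]),
                 fv(rheo=None, pattern="tonic"), 0.5, 0, 9),
            ],
            "npy",
            provenance={"kinetics_hash": "abc"},
        )
        path = tmp_path / "pop.tsv"
        pop.save(path)
        back = ModelPopulation.load(path)
        assert back.cell_class == "npy"
        assert len(back) == 2
        assert back[0].conductances == pop[0].conductances
        assert back[1].features.rheobase_pA is None
        assert back[1].features.firing_pattern == "tonic"
        assert back.provenance.get("kinetics_hash") == "abc"


class TestDeterminism:
    def test_same_seed_same_population(self):
        """Two identical scaled runs give identical populations (fast
        surrogate simulator keyed on the parameter vector)."""

        class SurrogateSim:
            def features(self, x):
                x = np.asarray(x)
                rheo = 40.0 + 200.0 * (x[0] - 0.05)
                hw = 4.0 + 20.0 * (x[1] - 0.01)
                return fv(rheo=rheo, hw=hw)

        t = targets_2d()
        kw = dict(
            n_walkers=16, n_iterations=25, n_runs=3, seed=5,
            simulator=SurrogateSim(), progress=False,
        )
        p1 = run_parameterization("ucn3", t, **kw)
        p2 = run_parameterization("ucn3", t, **kw)
        assert len(p1) == len(p2) > 0
        np.testing.assert_array_equal(p1.conductance_matrix(), p2.conductance_matrix())
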