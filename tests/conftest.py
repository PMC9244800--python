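import numpy as np
import pytest

from itchgate import ConductanceSet, Morphology, build_neuron
from itchgate.calibration import target_set
from itchgate.population import FeatureSimulator, run_parameterization

# exemplar conductance sets in the two phenotype regimes (S/cm2): accepted
# members of scaled control fits (score ~0.24 / ~0.16)
UCN3_EXEMPLAR = ConductanceSet(
    gNav16=0.49894, gKDR=0.07157, gKA=9e-05, gSK=0.0, gBK=0.00837,
    gCaR=0.04263, gLk=0.00019,
)
NPY_EXEMPLAR = ConductanceSet(
    gNav16=0.58036, gKDR=0.08135, gKA=0.00023, gSK=0.00207, gBK=0.0291,
    gCaR=0.0235, gLk=0.00022,
)
PASSIVE = ConductanceSet(0, 0, 0, 0, 0, 0, 1e-4)

# scaled-down fit settings shared by the population-level tests: an
# exploration run plus refinement runs, topped up until at least 50
# accepted models per class (top-ups are cheap via the evaluation cache);
# few walkers with a long annealing schedule descend into the acceptance
# pocket far more efficiently than many walkers with a short one
FIT_KW = dict(n_walkers=24, n_iterations=25)


@pytest.fixture(scope="session")
def morphology():
    return Morphology()


@pytest.fixture(scope="session")
def ucn3_model(morphology):
    return build_neuron(morphology, UCN3_EXEMPLAR)


@pytest.fixture(scope="session")
def npy_model(morphology):
    return build_neuron(morphology, NPY_EXEMPLAR)


@pytest.fixture(scope="session")
def passive_model(morphology):
    return build_neuron(morphology, PASSIVE, active_axon=False)


def _fit(cell_class, seed, min_accepted=50):
    sim = FeatureSimulator()
    for n_runs in (2, 3, 4, 5, 6):
        pop = run_parameterization(
            cell_class, target_set(cell_class), n_runs=n_runs, seed=seed,
            simulator=sim, **FIT_KW
        )
        if len(pop) >= min_accepted:
            break
    return pop


@pytest.fixture(scope="session")
def pop_ucn3():
    pop = _fit("ucn3", seed=101)
    assert len(pop) >= 50, (
        f"scaled Ucn3 fit yielded {len(pop)} accepted models "
        f"(best score {pop.provenance.get('best_score')})"
    )
    return pop


@pytest.fixture(scope="session")
def pop_npy():
    pop = _fit("npy", seed=202)
    assert len(pop) >= 50, (
        f"scaled NPY fit yielded {len(pop)} accepted models "
        f"(best score {pop.provenance.get('best_score')})"
    )
    return pop


def subsample(pop, n, seed=0):
    """Deterministic subsample of a population (keeps record order)."""
    if len(pop) <= n:
        return pop
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(pop), size=n, replace=False))
    from itchgate.population import ModelPopulation

    return ModelPopulation(
        cell_class=pop.cell_class,
        records=[pop.records[i] for i in idx],
        provenance=dict(pop.provenance),
    )
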