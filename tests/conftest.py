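import numpy as np
import pytest

from occgaps import absence, simulate as sim
from occgaps.persistence import ModelConfig
from occgaps.persistence import persistence_table


@pytest.fixture(scope="session")
def high_effort():
    """One fixed draw of the reference recovery scenario."""
    return sim.simulate(sim.scenario_preset("high-effort", seed=7))


@pytest.fixture(scope="session")
def gridded(high_effort):
    return sim.gridded_from_counts(high_effort.counts, cutoff_year=1980)


@pytest.fixture(scope="session")
def statuses(gridded):
    return absence.classify_cells(gridded)


@pytest.fixture(scope="session")
def joined(statuses, high_effort):
    joined, _ = absence.attach_covariates(statuses, high_effort.cells)
    return joined


@pytest.fixture(scope="session")
def persistence_tab(gridded):
    return persistence_table(gridded, ModelConfig())


def random_history(rng, max_years=40, rate=1.0):
    """A random sighting history honouring the model's invariants:
    effort >= 0, counts Poisson given effort, at least one sighting, and
    sightings only where effort is positive."""
    n_years = int(rng.integers(3, max_years + 1))
    effort = rng.poisson(1.2, n_years).astype(float)
    effort[rng.random(n_years) < 0.3] = 0.0  # lapses in surveying
    effort[0] = max(effort[0], 1.0)
    counts = rng.poisson(rate * effort)
    if counts.sum() == 0:
        counts[0] = 1
    return counts.astype(float), effort


def balanced_accuracy(pred, truth):
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    sens = (pred & truth).sum() / truth.sum()
    spec = (~pred & ~truth).sum() / (~truth).sum()
    return 0.5 * (sens + spec)
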