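import numpy as np
import pytest
from hypothesis import settings

from gazedecode import rates, synthdata

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_task() -> synthdata.TaskConfig:
    return synthdata.TaskConfig(trials_per_condition=6)


@pytest.fixture(scope="session")
def small_population():
    return synthdata.sample_population(10, seed=101)


@pytest.fixture(scope="session")
def small_session(small_population, small_task):
    return synthdata.simulate_session(small_population, small_task, seed=102)


@pytest.fixture(scope="session")
def small_tensor(small_session):
    return rates.bin_rates(small_session)


def noiseless_rate_matrices(
    population,
    task=None,
    span=(-900.0, 900.0),
    window_ms=50.0,
) -> rates.RateMatrices:
    """Expected (infinite-trial) binned rate matrices for a population.

    Evaluates each neuron's rate profile on a 1 ms lattice, averages over
    the five initial positions, and applies the same half-open counting
    window as the binning stage.  Serves as the noise-free limit against
    which Poisson simulations and decoder recovery are checked.
    """
    task = task or synthdata.TaskConfig()
    grid = np.arange(span[0], span[1] + 0.5, 1.0)
    times = rates.default_grid()
    half = window_ms / 2.0
    mats = {}
    for direction in synthdata.DIRECTIONS:
        cols = []
        for neuron in population:
            prof = np.mean(
                [
                    synthdata.rate_profile(neuron, direction, pos, task, grid)
                    for pos in task.initial_positions
                ],
                axis=0,
            )
            cols.append(
                [prof[(grid >= t - half) & (grid < t + half)].mean() for t in times]
            )
        mats[direction] = np.array(cols).T
    return rates.RateMatrices(
        times=times,
        R_rwd=mats[synthdata.RIGHTWARD],
        R_dwd=mats[synthdata.DOWNWARD],
    )
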