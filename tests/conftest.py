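"""Shared fixtures: the toy model and small synthetic datasets."""

import copy

import numpy as np
import pytest

from pyadapt import (TRUE_BASELINE, benchmark_suite, calibrate_baseline,
                     generate_observations, generate_truth, toy_lipid_model)


@pytest.fixture(scope="session")
def toy_model():
    return toy_lipid_model()


@pytest.fixture(scope="session")
def p_true(toy_model):
    return np.array([TRUE_BASELINE[n] for n in toy_model.parameter_names])


@pytest.fixture(scope="session")
def scenarios():
    return benchmark_suite(0)


@pytest.fixture(scope="session")
def scenario_a_noisefree(scenarios):
    scen = copy.deepcopy(scenarios["A"])
    scen.cv = 0.0
    scen.cv_overrides = {}
    return scen


@pytest.fixture(scope="session")
def noisefree_data(scenario_a_noisefree):
    truth = generate_truth(scenario_a_noisefree)
    return generate_observations(truth, scenario_a_noisefree, 0)


@pytest.fixture(scope="session")
def baseline_fits_noisefree(scenario_a_noisefree, noisefree_data):
    return calibrate_baseline(
        scenario_a_noisefree.model, noisefree_data,
        n_scatter=1000, keep_fraction=0.1, rng_seed=3)
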