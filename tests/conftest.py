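import numpy as np
import pytest

from a2fsim import (EcgSimConfig, ExperimentConfig, InertialSimConfig,
                    build_haar_dictionary, run_experiment)
from a2fsim.classify import ClassifierSpec
from a2fsim.selection import SelectionConfig


@pytest.fixture(scope="session")
def haar_dict_256():
    return build_haar_dictionary(256, 360.0)


@pytest.fixture(scope="session")
def haar_dict_128_const():
    return build_haar_dictionary(128, 50.0, include_constant=True)


def ecg_experiment_config(seed: int = 1) -> ExperimentConfig:
    """Adapted-SFS arrhythmia run on synthetic heartbeats, reduced epochs."""
    return ExperimentConfig(
        application="arrhythmia",
        sim=EcgSimConfig(seed=seed),
        sfs_mode="adapted",
        selection=SelectionConfig(
            NF_max=7, n_ext_max=3, seed=seed,
            classifier=ClassifierSpec(hidden_sizes=[10], epochs=100,
                                      initializer="random_uniform"),
        ),
        seed=seed,
    )


def inertial_experiment_config(seed: int = 1) -> ExperimentConfig:
    """Adapted-SFS multiclass activity run on synthetic inertial windows."""
    return ExperimentConfig(
        application="har_multiclass",
        sim=InertialSimConfig(seed=seed),
        sfs_mode="adapted",
        selection=SelectionConfig(
            NF_max=10, n_ext_max=8, seed=seed,
            classifier=ClassifierSpec(hidden_sizes=[20], epochs=100,
                                      initializer="random_uniform"),
        ),
        seed=seed,
    )


@pytest.fixture(scope="session")
def ecg_report():
    return run_experiment(ecg_experiment_config())


@pytest.fixture(scope="session")
def inertial_report():
    return run_experiment(inertial_experiment_config())
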