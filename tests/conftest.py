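import numpy as np
import pytest

import pibridge as pb
from pibridge.tables import concat_par_tables


@pytest.fixture(scope="session")
def panel():
    return pb.default_panel()


@pytest.fixture(scope="session")
def noise_free_config():
    return pb.SimulationConfig(
        n_samples=20, n_batches=2, seed=101,
        noise_cv=0.0, drift_amplitude=0.0, batch_effect_sd=0.0,
        is_area_cv=0.0, low_signal_noise=0.0,
    )


@pytest.fixture(scope="session")
def batch_only_partable():
    """Two batches with large multiplicative offsets, zero noise and drift."""
    cfg = pb.SimulationConfig(
        n_samples=30, n_batches=2, seed=55,
        noise_cv=0.0, drift_amplitude=0.0, batch_effect_sd=0.6,
        is_area_cv=0.0, low_signal_noise=0.0,
    )
    table, truth = pb.simulate_study(cfg)
    return table.par_table(), truth


@pytest.fixture(scope="session")
def realistic_joint():
    """Bridged two-study design with batch effects, drift and noise."""
    cfg = pb.SimulationConfig(
        n_samples=60, n_batches=2, batch_effect_sd=0.3,
        drift_amplitude=0.1, noise_cv=0.10, seed=11,
    )
    a, b, truth = pb.simulate_bridged_studies(cfg)
    joint = concat_par_tables([a.par_table(), b.par_table()])
    return cfg, joint, truth


@pytest.fixture(scope="session")
def realistic_serrf(realistic_joint):
    cfg, joint, truth = realistic_joint
    result = pb.run_serrf(joint, anchor="MAAQC", n_trees=200, seed=11)
    return cfg, joint, truth, result
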