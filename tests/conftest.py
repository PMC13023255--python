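import copy

import numpy as np
import pytest

from fermkin import StudyConfig, generate_study

#: printed proximate-composition table used as ground truth in tests
DIET_NFE = {"W1": 70.36, "W2": 67.18, "G1": 69.48,
            "G2": 69.80, "F1": 73.46, "F2": 69.40}

#: gas-model parameter triples (A mL, B, C h) per diet x method
KINETIC_TRIPLES = {
    ("W1", "S"): (85.76, 1.27, 3.42), ("W1", "D"): (92.86, 1.32, 8.91),
    ("W1", "SD"): (80.64, 1.01, 5.74),
    ("W2", "S"): (86.19, 1.43, 6.37), ("W2", "D"): (84.96, 2.12, 9.51),
    ("W2", "SD"): (73.24, 1.32, 7.96),
    ("G1", "S"): (81.29, 1.56, 2.86), ("G1", "D"): (70.06, 1.40, 5.18),
    ("G1", "SD"): (64.84, 1.52, 4.73),
    ("G2", "S"): (95.84, 1.90, 3.88), ("G2", "D"): (77.46, 1.06, 7.72),
    ("G2", "SD"): (73.15, 1.26, 3.90),
    ("F1", "S"): (107.76, 1.25, 4.25), ("F1", "D"): (102.50, 0.84, 10.28),
    ("F1", "SD"): (80.05, 1.35, 3.10),
    ("F2", "S"): (91.52, 2.39, 5.99), ("F2", "D"): (89.49, 1.71, 7.12),
    ("F2", "SD"): (75.88, 1.49, 5.42),
}

HALF_HOUR_GRID = np.arange(0.5, 48.0 + 0.25, 0.5)


@pytest.fixture(scope="session")
def default_config() -> StudyConfig:
    return StudyConfig.default(seed=7)


def make_tiny_config(base: StudyConfig, *, noiseless: bool = False,
                     seed: int = 11) -> StudyConfig:
    """Shrunken study (2 diets x 2 methods x 3 reps, coarse gas grid)
    for end-to-end tests."""
    cfg = copy.deepcopy(base)
    keep = ["W1", "G2"]
    cfg.diets = {d: cfg.diets[d] for d in keep}
    cfg.methods = ["S", "D"]
    cfg.replicates = 3
    cfg.kinetic_params = {d: {m: cfg.kinetic_params[d][m]
                              for m in cfg.methods} for d in keep}
    cfg.invivo_attd = {d: cfg.invivo_attd[d] for d in keep}
    cfg.gas_sampling_times_h = np.arange(1.0, 48.01, 2.0)
    cfg.seed = seed
    return cfg.noiseless() if noiseless else cfg


@pytest.fixture(scope="session")
def tiny_config(default_config) -> StudyConfig:
    return make_tiny_config(default_config)


@pytest.fixture(scope="session")
def noiseless_tiny_config(default_config) -> StudyConfig:
    return make_tiny_config(default_config, noiseless=True)


@pytest.fixture(scope="session")
def noiseless_tables(noiseless_tiny_config):
    return generate_study(noiseless_tiny_config)
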