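import numpy as np
import pytest

from concordtf.pwm import PWM
from concordtf.simulate import (
    PlantSpec,
    StudyConfig,
    TripletSpec,
    generate_study,
)


@pytest.fixture(scope="session")
def sharp_pwm() -> PWM:
    """A fully informative (point-mass) 8-mer matrix."""
    m = np.zeros((8, 4))
    for i, b in enumerate([0, 1, 2, 3, 0, 1, 2, 3]):
        m[i, b] = 1.0
    return PWM(id="SHARP", matrix=m)


@pytest.fixture(scope="session")
def soft_pwm() -> PWM:
    """A mixed-frequency 6-mer matrix with known column frequencies."""
    rows = [
        [0.7, 0.1, 0.1, 0.1],
        [0.1, 0.7, 0.1, 0.1],
        [0.25, 0.25, 0.25, 0.25],
        [0.4, 0.4, 0.1, 0.1],
        [0.1, 0.1, 0.1, 0.7],
        [0.85, 0.05, 0.05, 0.05],
    ]
    return PWM(id="SOFT", matrix=np.array(rows))


def tiny_study_config(seed: int = 0, **overrides) -> StudyConfig:
    """A miniature two-tissue study that runs the whole pipeline in a few
    seconds; planted structure mirrors the default study."""
    defaults = dict(
        n_pwms=10,
        pwm_length_range=(10, 12),
        n_tissues=2,
        genes_per_tissue=60,
        n_housekeeping=80,
        planted_pairs=(
            PlantSpec("M000", "M001", tissues=("tissue0",)),
            PlantSpec("M002", "M003", tissues=("tissue1",)),
            PlantSpec("M004", "M005", gene_fraction=0.15,
                      housekeeping=True, tissues=("tissue0", "tissue1")),
        ),
        planted_triplets=(
            TripletSpec("M000", "M001", "M002", tissue="tissue0", n_carriers=8),
        ),
        seed=seed,
    )
    defaults.update(overrides)
    return StudyConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_study():
    return generate_study(tiny_study_config(seed=11))
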