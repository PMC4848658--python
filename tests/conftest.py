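import numpy as np
import pytest

from bia_asm import CohortConfig, SubjectRecord, generate_cohort


@pytest.fixture
def worked_subject():
    """The hand-computed reference subject used across equation tests."""
    return SubjectRecord(
        id="worked", sex="male", age=40, height=1.70, weight=70.0,
        resistance=500.0, reactance=50.0,
    )


def random_records(n, seed, with_reference=False):
    """Uniformly random valid subjects spanning the full validity ranges."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        recs.append(
            SubjectRecord(
                id=f"r{i}",
                sex="male" if rng.random() < 0.5 else "female",
                age=float(rng.uniform(18, 95)),
                height=float(rng.uniform(1.3, 2.1)),
                weight=float(rng.uniform(35, 180)),
                resistance=float(rng.uniform(200, 1100)),
                reactance=float(rng.uniform(5, 120)),
                reference_asm=float(rng.uniform(8, 45)) if with_reference else None,
            )
        )
    return recs


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default-configuration cohort shared across tests."""
    return generate_cohort(CohortConfig(seed=7))
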