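import numpy as np
import pytest

from coxfuse.survival import SurvivalRecord


def make_records(times, events, prefix="P", covariates=None):
    covariates = covariates or [{}] * len(times)
    return [
        SurvivalRecord(patient_id=f"{prefix}{i:03d}", time=float(t),
                       event=int(e), covariates=c)
        for i, (t, e, c) in enumerate(zip(times, events, covariates))
    ]


@pytest.fixture
def records_factory():
    return make_records


@pytest.fixture
def uncensored_cohort():
    rng = np.random.default_rng(42)
    times = rng.exponential(10.0, 40) + 0.1
    return make_records(times, np.ones(40, dtype=int))


@pytest.fixture
def censored_cohort():
    rng = np.random.default_rng(43)
    n = 60
    times = rng.exponential(10.0, n) + 0.1
    events = rng.random(n) < 0.7
    return make_records(times, events.astype(int))


@pytest.fixture(scope="session")
def tiny_multimodal_cohort():
    """Small cohort with planted signal in both modalities, reused by the
    slower integration tests."""
    from coxfuse.synthetic import SyntheticConfig, simulate_cohort

    return simulate_cohort(SyntheticConfig(
        n_patients=80, patches_per_patient=4, image_size=32,
        n_genes=60, module_size=10, seed=7))


@pytest.fixture
def fast_trainer_config():
    from coxfuse.training import TrainerConfig

    return TrainerConfig(epochs_image=3, epochs_expr=10, epochs_early=15,
                         epochs_joint=3, k_folds=2)
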