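import pytest

import bridgepress as bp


@pytest.fixture(scope="session")
def zero_noise_session() -> bp.Session:
    """Calibrated session with every noise source disabled: digital
    samples equal the underlying trajectory, plateaus are exact."""
    cfg = bp.default_reference_config(
        noise_sd_mmHg=0.0,
        drift_sd_mmHg_per_s=0.0,
        analog_read_sd_mmHg=0.0,
        trial_jitter_sd_mmHg=0.0,
    )
    return bp.simulate_session(cfg)


@pytest.fixture(scope="session")
def noisy_session() -> bp.Session:
    """Calibrated session with the default noise model."""
    return bp.simulate_session(bp.default_reference_config(rng_seed=11))


@pytest.fixture(scope="session")
def small_cohort() -> list[bp.Session]:
    """Eight participants under the default noise model."""
    return bp.simulate_cohort(bp.default_reference_config(rng_seed=5), 8)


@pytest.fixture(scope="session")
def zero_noise_values(zero_noise_session) -> list[bp.StableValue]:
    return bp.extract_session(zero_noise_session.traces, zero_noise_session.windows)
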