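import numpy as np
import pytest

from itdlab import behavior_sim, neuro_sim


@pytest.fixture(scope="session")
def session_log():
    """3000-analysis-trial session from a moderately sensitive model."""
    model = behavior_sim.GroundTruthModel(alpha_per_ms=12.53)
    return behavior_sim.simulate_session(
        model, n_trials=3000, seed=42, count="analysis"
    )


@pytest.fixture(scope="session")
def small_recording():
    """Compact tuned recording: 5 ITD levels x 5 repeats, high SNR."""
    tuning = neuro_sim.TuningFunction(shape="sigmoid", depth=1.0, width_us=60.0)
    schedule = neuro_sim.make_trial_schedule(
        itd_min_us=-80.0, itd_max_us=80.0, step_us=40.0, n_repeats=5, seed=7
    )
    return neuro_sim.simulate_recording(tuning, schedule, snr=10.0, seed=7)


@pytest.fixture(scope="session")
def full_recording():
    """Full-scale recording design: 17 levels x 30 repeats, sigmoid tuning."""
    tuning = neuro_sim.TuningFunction(shape="sigmoid", depth=0.8)
    schedule = neuro_sim.make_trial_schedule(seed=3)
    return neuro_sim.simulate_recording(tuning, schedule, snr=10.0, seed=3)
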