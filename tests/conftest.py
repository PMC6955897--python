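import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rt_study():
    """One default-generator RT study (12 per group), filtered."""
    from avmsi import behavior, synthdata

    rts = synthdata.simulate_rt_study(n_per_group=12, seed=0)
    return behavior.filter_rts(rts)


@pytest.fixture(scope="session")
def toy_anova_data():
    """4 subjects, 2 groups, 2 within levels; oracle values frozen in tests."""
    y = {("s1", "g1"): (10.0, 12.0), ("s2", "g1"): (14.0, 18.0),
         ("s3", "g2"): (20.0, 26.0), ("s4", "g2"): (24.0, 30.0)}
    rows = [{"participant": s, "group": g, "condition": l, "value": v}
            for (s, g), (v1, v2) in y.items()
            for l, v in zip(("L1", "L2"), (v1, v2))]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def mini_erp_study():
    """Small simulated EEG cohort with the default (nonzero) interaction."""
    from avmsi import experiments, synthdata

    task = synthdata.TaskConfig(n_blocks=1, trials_per_condition_per_block=10,
                                sampling_rate_hz=256.0)
    templates = synthdata.default_templates(task.montage, fs=256.0)
    noise = synthdata.NoiseConfig(artifact_rate=0.0)
    return experiments.erp_study(4, task, templates, noise, seed=11)


def make_epochset(epochs, fs=256.0, conditions=None):
    """Hand-built EpochSet for rejection tests."""
    from avmsi import erp

    epochs = np.asarray(epochs, dtype=float)
    n = epochs.shape[0]
    conditions = np.array(conditions if conditions is not None else ["A"] * n)
    times = np.arange(epochs.shape[2]) / fs * 1000.0 - 100.0
    labels = [f"ch{i}" for i in range(epochs.shape[1])]
    return erp.EpochSet(epochs, times, conditions, fs, labels)
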