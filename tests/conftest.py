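import numpy as np
import pytest

from gaitphys import autodiff, biomech, synthetic, train_eval
from gaitphys.model import GaitFatigueNet, ModelConfig

NOISELESS = {"acc": 0.0, "gyro": 0.0, "mag": 0.0, "grf": 0.0}


@pytest.fixture(scope="session")
def anthro():
    return biomech.anthropometrics(1.75, 68.0)


@pytest.fixture(scope="session")
def profile():
    return synthetic.SubjectProfile(height=1.75, mass=68.0, base_cadence=108.0, seed=5)


@pytest.fixture(scope="session")
def clean_recording(profile):
    """20-cycle noiseless baseline recording."""
    return synthetic.generate_recording(profile, 0, 20, seed=3, noise_sd=NOISELESS)


@pytest.fixture(scope="session")
def easy_dataset():
    recs = synthetic.easy_cohort(seed=11)
    return train_eval.build_dataset(recs)


@pytest.fixture(scope="session")
def trained(easy_dataset):
    """One tiny-profile model trained on the easy cohort (seed 0), float32."""
    autodiff.set_default_dtype(np.float32)
    try:
        model = GaitFatigueNet(ModelConfig.tiny(), seed=0)
        tcfg = train_eval.TrainConfig.desk_profile(seed=0)
        tcfg.target_val_accuracy = 0.9
        res = train_eval.train(easy_dataset, model, tcfg)
    finally:
        autodiff.set_default_dtype(np.float64)
    return res
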