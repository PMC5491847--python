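import numpy as np
import pytest

from emgsynergy import Recording, TrialAnnotation


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_recording(rng):
    """5-channel, 5,000-sample recording with one annotation covering it all."""
    samples = rng.standard_normal((5, 5000))
    return Recording(
        samples=samples,
        fs=1000.0,
        channels=("mDEL", "FCR", "FDS", "ECR", "EDC"),
        annotations=[TrialAnnotation(0, 5000, "grasp", "sabd50", 1)],
        subject_id="S99",
    )


@pytest.fixture()
def multi_rep_recording(rng):
    """Recording with 12 repetitions of 5,000 samples each for one task cell."""
    n_rep, rep_len = 12, 5000
    samples = rng.standard_normal((5, n_rep * rep_len))
    anns = [
        TrialAnnotation(i * rep_len, (i + 1) * rep_len, "grasp", "sabd50", i + 1)
        for i in range(n_rep)
    ]
    return Recording(samples=samples, fs=1000.0,
                     channels=("mDEL", "FCR", "FDS", "ECR", "EDC"),
                     annotations=anns)
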