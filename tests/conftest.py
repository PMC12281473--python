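import numpy as np
import pytest

from toldmri import make_brain_phantom, make_told_series, reference as ref

TR_S = np.asarray(ref.TR_LADDER_MS, dtype=float) / 1000.0


@pytest.fixture(scope="session")
def tr_s():
    return TR_S.copy()


@pytest.fixture(scope="session")
def brain_scene():
    """Noiseless three-region brain phantom."""
    return make_brain_phantom(noise_sigma=0.0)


@pytest.fixture(scope="session")
def challenge_schedule():
    """5 min air, 5 min carbogen, 5 min air."""
    return ref.standard_challenge_schedule()


@pytest.fixture(scope="session")
def noiseless_told(brain_scene, challenge_schedule):
    """Noiseless 45-frame TOLD series (20-s frames) plus its ground truth."""
    series, truth = make_told_series(brain_scene, challenge_schedule,
                                     frame_interval_s=20.0, n_frames=45, seed=0)
    return series, truth
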