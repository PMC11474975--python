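import numpy as np
import pytest

from pocketdyn import synthetic


@pytest.fixture(scope="session")
def pose_system():
    """The planted-pose fixture in its stated world: 3 poses, 3000 frames,
    noise 0.2 Å, seed 7."""
    return synthetic.make_pose_trajectory(synthetic.PoseSpec(rng_seed=7))


@pytest.fixture(scope="session")
def pose_features(pose_system):
    from pocketdyn.interactions import featurize
    return featurize(pose_system.trajectory, pose_system.fragments)


@pytest.fixture(scope="session")
def harmonic_big():
    """20000-frame isotropic jitter ensemble (sigma 0.5 Å)."""
    return synthetic.make_harmonic(
        synthetic.HarmonicSpec(n_atoms=60, sigma=0.5, n_frames=20000,
                               rng_seed=7))


@pytest.fixture(scope="session")
def cylinder():
    return synthetic.make_channel(
        synthetic.ChannelSpec(radius_fn=lambda y: 6.5, axis_range=(0.0, 20.0),
                              rng_seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
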