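import numpy as np
import pytest

from meglabel.geometry import Frame, FrameTransform, Volume
from meglabel.synthetic import make_subject_folder, make_template


@pytest.fixture(scope="session")
def template():
    """The standard-space phantom: (t1, head_mask, brain_mask)."""
    return make_template()


@pytest.fixture(scope="session")
def subject(tmp_path_factory):
    """One complete synthetic subject folder with ground truth."""
    return make_subject_folder(tmp_path_factory.mktemp("subject"), seed=7)


@pytest.fixture
def identity_volume():
    """8x8x8 volume whose voxel->world affine is the identity."""
    rng = np.random.default_rng(0)
    return Volume(
        rng.normal(size=(8, 8, 8)),
        FrameTransform(np.eye(4), Frame.VOXEL, Frame.WORLD),
        role="intensity",
    )


def random_affine(rng, max_t=10.0, max_angle_deg=10.0):
    """A well-conditioned random 4x4 affine (rotation + scale + translation)."""
    from meglabel.synthetic import affine_from_params

    return affine_from_params(
        rng.uniform(-max_t, max_t, 3),
        rng.uniform(-max_angle_deg, max_angle_deg, 3),
        1.0 + rng.uniform(-0.1, 0.1, 3),
    )
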