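import numpy as np
import pytest

from fastcat import BlobSpec, FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def moving_blob_fixture():
    """160-frame fixture: one constant-velocity blob, two exact-repeat freezes."""
    spec = FixtureSpec(
        n_frames=160,
        width=256,
        height=192,
        seed=11,
        freeze_segments=[(30, 55), (110, 130)],
        blobs=[
            BlobSpec(
                start_frame=10, end_frame=150,
                initial_box=(40, 50, 44, 36), velocity=(1.0, 0.5),
            )
        ],
    )
    frames, gt, segments = generate_fixture(spec)
    return spec, frames, gt, segments


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_frame(rng, h=32, w=32):
    return rng.integers(0, 256, (h, w, 3)).astype(np.uint8)
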