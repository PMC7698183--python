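import numpy as np
import pytest

from mocap_hht import fixtures, pipeline
from mocap_hht.memd import memd_decompose

FS = 120.0


@pytest.fixture(scope="session")
def two_tone_series():
    """Univariate 10 Hz + 2 Hz mixture, 4 s at 120 Hz, with ground truth."""
    t = np.arange(0, 4, 1 / FS)
    hi = np.sin(2 * np.pi * 10 * t)
    lo = np.sin(2 * np.pi * 2 * t)
    return hi + lo, hi, lo, t


@pytest.fixture(scope="session")
def two_tone_bundle():
    """12-channel (3-joint skeleton) two-tone preset, random phases, seed 1."""
    return fixtures.make_preset("two-tone", joint_count=3, seed=1)


@pytest.fixture(scope="session")
def two_tone_memd(two_tone_bundle):
    return memd_decompose(two_tone_bundle.motion.values)


@pytest.fixture(scope="session")
def two_tone_decomposition(two_tone_bundle):
    """Full pipeline result on the two-tone preset (shared: EMD is the
    expensive stage and all readouts are pure functions of it)."""
    b = two_tone_bundle
    return pipeline.decompose_motion(b.skeleton, b.motion)


@pytest.fixture()
def bvh_path(tmp_path, two_tone_bundle):
    from mocap_hht.bvh_io import write_bvh

    p = tmp_path / "two_tone.bvh"
    write_bvh(two_tone_bundle.skeleton, two_tone_bundle.motion, p)
    return p


def match_corr(imf: np.ndarray, truth: np.ndarray) -> float:
    """|Pearson correlation| between a recovered mode and a planted one."""
    return abs(float(np.corrcoef(imf, truth)[0, 1]))
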