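import numpy as np
import pytest

from arrayqc import build_lut
from arrayqc.synthetic import SessionSpec, generate_ground_truth, generate_session


@pytest.fixture(scope="session")
def default_lut():
    return build_lut()


@pytest.fixture(scope="session")
def small_lut():
    # 4 arrays x 4 electrodes: 2 NSPs, 2 reference groups
    return build_lut(n_arrays=4, electrodes_per_array=4)


@pytest.fixture(scope="session")
def tiny_resting():
    """A 30-s resting session: 2 NSPs, 8 neural channels + eye channels."""
    spec = SessionSpec(task_kind="resting", duration=30.0, n_arrays=4,
                       electrodes_per_array=2, seed=11,
                       closure_schedule=((8.0, 18.0),),
                       nsp_offsets=np.array([[0, 1500], [3000, 0]]))
    session, gt = generate_session(spec)
    return spec, session, gt


@pytest.fixture(scope="session")
def snr_ground_truth():
    """Ground truth (no signals) for a small checkerboard-task session."""
    spec = SessionSpec(task_kind="snr", duration=60.0, n_arrays=2,
                       electrodes_per_array=4,
                       per_channel_snr=np.array([1, 1, 3, 3, 8, 8, 3, 8]),
                       seed=21)
    return spec, generate_ground_truth(spec)
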