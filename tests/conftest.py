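import numpy as np
import pytest

from axotrace import AxonSpec, RecordingStack, generate_experiment


@pytest.fixture(scope="session")
def static_stack():
    """Artifact-free, noiseless 3-axon recording with ground truth."""
    return generate_experiment(3, 40, seed=7, artifact_magnitude=0.0, noise=False)


@pytest.fixture(scope="session")
def overlap_stack():
    """Two overlapping axons that segment as a single ROI (static, noisy)."""
    axons = [
        AxonSpec(0, (32.0, 28.0), np.diag([7.0, 7.0]), 0.9, 1.0),
        AxonSpec(1, (32.0, 36.5), np.diag([6.0, 6.0]), 0.6, 1.0),
    ]
    return generate_experiment(
        2, 120, seed=5, artifact_magnitude=0.0, noise=True, axons=axons
    )


def stack_from_gray(frames, fps=4.0):
    """Build a two-channel stack whose red and green channels both equal the
    given grayscale frames."""
    arr = np.asarray(frames, dtype=float)
    return RecordingStack(green=arr.copy(), red=arr.copy(), fps=fps)
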