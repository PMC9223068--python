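import pytest

from bedwatch.fall_detector import LabeledWindow, TrainConfig, train
from bedwatch.sensors import ImuSample


def imu(t_ms, ax=0.0, ay=0.0, az=0.0, gx=0.0, gy=0.0, gz=0.0):
    return ImuSample(t_ms, ax, ay, az, gx, gy, gz)


def constant_window(magnitude, n=5, dt=20, axis="ax"):
    """Window of constant acceleration along one axis, all else zero."""
    values = {"ax": 0.0, "ay": 0.0, "az": 0.0}
    values[axis] = magnitude
    return tuple(imu(i * dt, **values) for i in range(n))


@pytest.fixture(scope="session")
def toy_model():
    """Linearly separable toy classifier: falls at svm_mean 3, ADLs at 1."""
    dataset = [
        LabeledWindow(constant_window(3.0), "FALL", "forward_fall") for _ in range(4)
    ] + [LabeledWindow(constant_window(1.0), "ADL", "sit") for _ in range(4)]
    return train(dataset, TrainConfig(), seed=0)
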