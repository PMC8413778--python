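import numpy as np
import pytest

from mmnkit.epochs import DifferenceWave, EpochSet, Evoked
from mmnkit.montage import standard_montage_32


@pytest.fixture(scope="session")
def montage32():
    return standard_montage_32()


def build_evoked(data, fs=500.0, tmin_ms=-100.0, names=None,
                 condition="simple", stimulus="standard", n_trials=10):
    data = np.asarray(data, float)
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[0])]
    return Evoked(
        data=data, sampling_rate_hz=fs, tmin_ms=tmin_ms,
        channel_names=list(names), condition=condition,
        stimulus=stimulus, n_trials_averaged=n_trials,
    )


def build_diff(diff, **kw):
    """DifferenceWave with zero standard and deviant == diff."""
    diff = np.asarray(diff, float)
    std = build_evoked(np.zeros_like(diff), **kw)
    dev = build_evoked(diff, stimulus="deviant", **{k: v for k, v in kw.items()
                                                    if k != "stimulus"})
    return DifferenceWave(standard=std, deviant=dev, diff=dev.data - std.data)


def build_epochs(data, fs=500.0, tmin_ms=-100.0, names=None,
                 condition="simple", stimulus=None, provenance=None):
    data = np.asarray(data, float)
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[1])]
    if stimulus is None:
        stimulus = np.full(data.shape[0], "standard")
    return EpochSet(
        data=data, sampling_rate_hz=fs, tmin_ms=tmin_ms,
        channel_names=list(names), condition=condition,
        stimulus=np.asarray(stimulus),
        provenance=list(provenance or []),
    )
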