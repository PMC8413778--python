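import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from mmnkit import preprocess as pp
from mmnkit.measures import average_evoked
from mmnkit.sequences import SequenceConfig, generate_stimulus_sequence

from conftest import build_epochs

FS = 512.0


def _tone_gain(freq_hz, fs=FS, seconds=4.0):
    t = np.arange(int(seconds * fs)) / fs
    x = np.sin(2 * np.pi * freq_hz * t)[None, :]
    y = pp.bandpass_filter(x, fs)
    # compare spectral amplitude at the tone frequency (edges trimmed)
    sl = slice(int(fs // 2), -int(fs // 2))
    spec_in = np.abs(np.fft.rfft(x[0, sl]))
    spec_out = np.abs(np.fft.rfft(y[0, sl]))
    k = np.argmax(spec_in)
    return spec_out[k] / spec_in[k]


def test_passband_and_stopband_gain():
    assert 0.95 <= _tone_gain(10.0) <= 1.05
    assert _tone_gain(100.0) < 0.1


def test_dc_rejected():
    x = np.full((2, 2048), 5.0)
    y = pp.bandpass_filter(x, FS)
    assert np.abs(y).max() < 1e-3


def test_band_edges_validated():
    with pytest.raises(ValueError, match="Nyquist"):
        pp.bandpass_filter(np.zeros((1, 512)), 50.0,
                           pp.PreprocessConfig(band_high_hz=30.0))


@settings(derandomize=True, max_examples=10, deadline=None)
@given(seed=hst.integers(0, 1000), a=hst.floats(-3, 3), b=hst.floats(-3, 3))
def test_filter_linearity(seed, a, b):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((2, 1024))
    y = rng.standard_normal((2, 1024))
    lhs = pp.bandpass_filter(a * x + b * y, FS)
    rhs = a * pp.bandpass_filter(x, FS) + b * pp.bandpass_filter(y, FS)
    assert np.abs(lhs - rhs).max() < 1e-8


def test_rereference_zero_mastoids_noop(montage32):
    rng = np.random.default_rng(0)
    data = rng.standard_normal((3, 32, 50))
    data[:, montage32.index("A1"), :] = 0.0
    data[:, montage32.index("A2"), :] = 0.0
    es = build_epochs(data, names=montage32.names)
    out = pp.rereference(es)
    assert np.array_equal(out.data, es.data)
    assert out.reference == "linked_mastoids"


def test_rereference_idempotent(montage32):
    rng = np.random.default_rng(1)
    es = build_epochs(rng.standard_normal((2, 32, 40)), names=montage32.names)
    once = pp.rereference(es)
    twice = pp.rereference(once)
    assert np.allclose(once.data, twice.data, atol=1e-12)


def test_average_reference_zero_mean():
    rng = np.random.default_rng(2)
    es = build_epochs(rng.standard_normal((4, 8, 30)))
    out = pp.rereference(es, "average")
    assert np.abs(out.data.mean(axis=1)).max() < 1e-10


def test_rereference_preserves_pairwise_differences(montage32):
    rng = np.random.default_rng(3)
    es = build_epochs(rng.standard_normal((2, 32, 25)), names=montage32.names)
    out = pp.rereference(es)
    for i, j in [(0, 5), (3, 12), (20, 31)]:
        assert np.allclose(es.data[:, i] - es.data[:, j],
                           out.data[:, i] - out.data[:, j], atol=1e-12)


def test_rereference_missing_mastoids_named():
    es = build_epochs(np.zeros((1, 3, 10)), names=["Fz", "Cz", "Pz"])
    with pytest.raises(ValueError, match=r"A1.*A2|\['A1', 'A2'\]"):
        pp.rereference(es)


def test_epoch_sample_counts_512hz():
    """500 ms epochs with 100 ms baseline at 512 Hz: 256 samples, 51 pre."""
    n_pre, n_total = pp.epoch_sample_counts(pp.PreprocessConfig(), 512.0)
    assert (n_pre, n_total) == (51, 256)


def test_epoching_cuts_and_drops_edges(caplog):
    ev = generate_stimulus_sequence(
        SequenceConfig(condition="simple", n_deviants=5, p_deviant=0.25, seed=0)
    )
    n_rec = int(ev["onset_sample"].iloc[-1]) + 256
    rec = np.zeros((3, n_rec))
    es = pp.epoch(rec, ev, FS, ["Fz", "A1", "A2"])
    # the first event (onset 0) cannot supply a 51-sample baseline
    assert es.n_trials == len(ev) - 1
    assert es.n_samples == 256
    assert es.tmin_ms == pytest.approx(-51 * 1000 / 512)


def test_epoch_pattern_selects_first_tones():
    ev = generate_stimulus_sequence(
        SequenceConfig(condition="pattern", n_deviants=4, p_deviant=0.2,
                       head_standards=2, seed=0)
    )
    n_rec = int(ev["onset_sample"].iloc[-1]) + 600
    es = pp.epoch(np.zeros((1, n_rec)), ev, FS, ["Fz"])
    assert es.n_trials <= ev.attrs["n_units"]
    assert set(es.stimulus) <= {"standard", "deviant"}


def test_empty_selection_gives_empty_epochs_and_average_refuses():
    ev = generate_stimulus_sequence(
        SequenceConfig(condition="simple", n_deviants=2, p_deviant=0.2, seed=0)
    )
    es = pp.epoch(np.zeros((1, 50)), ev[0:0], FS, ["Fz"])
    assert es.n_trials == 0
    with pytest.raises(ValueError, match="no retained"):
        average_evoked(es, "standard")


def test_baseline_removes_offsets_exactly():
    rng = np.random.default_rng(4)
    data = rng.standard_normal((5, 3, 250)) + rng.normal(size=(5, 3, 1)) * 10
    es = build_epochs(data)
    out = pp.baseline_correct(es)
    pre = out.times_ms < 0
    assert np.abs(out.data[:, :, pre].mean(axis=2)).max() < 1e-10
    # zero-mean baseline input is untouched
    centered = es.data - es.data[:, :, pre].mean(axis=2, keepdims=True)
    out2 = pp.baseline_correct(build_epochs(centered))
    assert np.allclose(out2.data, centered, atol=1e-12)


def test_baseline_requires_prestimulus_samples():
    es = build_epochs(np.zeros((1, 2, 10)), tmin_ms=0.0)
    with pytest.raises(ValueError, match="pre-stimulus"):
        pp.baseline_correct(es)


def _baselined(data, names=None):
    es = build_epochs(data, names=names, provenance=["baseline"])
    return es


def test_rejection_boundary_strict():
    data = np.zeros((2, 3, 20))
    data[0, 1, 5] = 71.0   # just above threshold -> rejected
    data[1, 1, 5] = 70.0   # exactly at threshold -> retained
    out = pp.reject_artifacts(_baselined(data, names=["Fz", "FC1", "Cz"]))
    assert out.rejected.tolist() == [True, False]


def test_rejection_ignores_mastoids():
    data = np.zeros((1, 3, 20))
    names = ["Fz", "A1", "A2"]
    data[0, 1, 3] = 500.0
    out = pp.reject_artifacts(_baselined(data, names=names))
    assert not out.rejected.any()


def test_rejection_count_oracle():
    rng = np.random.default_rng(5)
    data = rng.standard_normal((100, 4, 50))  # background well below 70
    k_idx = [3, 17, 42, 66, 91]
    data[k_idx, 0, 10] = 120.0
    out = pp.reject_artifacts(_baselined(data))
    assert int(out.rejected.sum()) == len(k_idx)
    assert sorted(np.flatnonzero(out.rejected)) == k_idx


@settings(derandomize=True, max_examples=20, deadline=None)
@given(seed=hst.integers(0, 500), lo=hst.floats(10, 50), hi=hst.floats(50, 120))
def test_rejection_monotone_in_threshold(seed, lo, hi):
    rng = np.random.default_rng(seed)
    es = _baselined(rng.standard_normal((30, 3, 40)) * 30)
    n_hi = pp.reject_artifacts(es, threshold_uv=hi).n_retained
    n_lo = pp.reject_artifacts(es, threshold_uv=lo).n_retained
    assert n_lo <= n_hi


def test_rejection_requires_baseline_provenance():
    es = build_epochs(np.zeros((1, 2, 10)))
    with pytest.raises(ValueError, match="baseline"):
        pp.reject_artifacts(es)
    pp.reject_artifacts(es, require_baseline=False)  # explicit override


def test_peak_to_peak_mode():
    data = np.zeros((2, 1, 20))
    data[0, 0, :10] = 40.0
    data[0, 0, 10:] = -40.0   # range 80 > 70 but |v| < 70
    out_abs = pp.reject_artifacts(_baselined(data), mode="absolute")
    out_pp = pp.reject_artifacts(_baselined(data), mode="peak_to_peak")
    assert not out_abs.rejected[0]
    assert out_pp.rejected[0]


def test_pipeline_order_recorded(montage32):
    rng = np.random.default_rng(6)
    es = build_epochs(rng.standard_normal((3, 32, 256)) * 5,
                      fs=512.0, names=montage32.names,
                      tmin_ms=-51 * 1000 / 512)
    out = pp.preprocess_epochs(es)
    stages = [p.split("[")[0] for p in out.provenance]
    assert stages == ["bandpass", "rereference", "baseline", "reject"]
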