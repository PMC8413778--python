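"""Offline preprocessing chain: band-pass filter, re-reference, epoch,
baseline-correct, amplitude-based artifact rejection.

The canonical order is filter -> re-reference -> epoch -> baseline ->
reject; each stage appends to the EpochSet's provenance so the order is on
record. Rejection requires a prior baseline stage (configurable off).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .epochs import EpochSet
from .montage import NON_SCALP

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    band_low_hz: float = 1.0
    band_high_hz: float = 30.0
    filter_order: int = 4  # Butterworth design order, applied forward-backward
    rejection_threshold_uv: float = 70.0
    rejection_mode: str = "absolute"  # "absolute" | "peak_to_peak"
    epoch_tmin_ms: float = -100.0
    epoch_tmax_ms: float = 400.0  # half-open [tmin, tmax)
    apply_filter: bool = True

    def validate(self, sampling_rate_hz: float | None = None) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        if sampling_rate_hz is not None and self.band_high_hz >= sampling_rate_hz / 2:
            raise ValueError("band_high_hz must be below the Nyquist frequency")
        if self.rejection_threshold_uv <= 0:
            raise ValueError("rejection threshold must be positive")
        if self.rejection_mode not in ("absolute", "peak_to_peak"):
            raise ValueError(f"unknown rejection mode {self.rejection_mode!r}")
        if not self.epoch_tmin_ms <= 0 < self.epoch_tmax_ms:
            raise ValueError("epoch window must satisfy tmin <= 0 < tmax")


def epoch_sample_counts(cfg: PreprocessConfig, fs: float) -> tuple[int, int]:
    """(n_pre, n_total) samples for the epoch window at rate ``fs``.

    Both are rounded from the requested window; n_total covers the full
    half-open [tmin, tmax) span (e.g. 512 Hz, [-100, 400) -> 51 pre-stimulus
    of 256 total).
    """
    n_pre = int(round(-cfg.epoch_tmin_ms / 1000.0 * fs))
    n_total = int(round((cfg.epoch_tmax_ms - cfg.epoch_tmin_ms) / 1000.0 * fs))
    return n_pre, n_total


def bandpass_filter(data: np.ndarray, sampling_rate_hz: float,
                    cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last (time) axis.

    Accepts continuous (channels x samples) or epoched (trials x channels x
    samples) arrays; output has the same shape and no phase shift (the
    filter is applied forward and backward).
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(sampling_rate_hz)
    sos = signal.butter(
        cfg.filter_order,
        [cfg.band_low_hz, cfg.band_high_hz],
        btype="bandpass",
        fs=sampling_rate_hz,
        output="sos",
    )
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def filter_epochs(epochs: EpochSet, cfg: PreprocessConfig | None = None) -> EpochSet:
    cfg = cfg or PreprocessConfig()
    out = bandpass_filter(epochs.data, epochs.sampling_rate_hz, cfg)
    new = epochs.copy_with(data=out)
    new.provenance.append(f"bandpass[{cfg.band_low_hz}-{cfg.band_high_hz}Hz]")
    return new


def rereference(epochs: EpochSet, scheme: str = "linked_mastoids") -> EpochSet:
    """Re-reference every channel to the linked mastoids or the spatial mean.

    Linked mastoids: subtract mean(A1, A2) per trial and sample. Average:
    subtract the mean over all channels. Idempotent for a given scheme.
    """
    if scheme == "linked_mastoids":
        missing = [n for n in ("A1", "A2") if n not in epochs.channel_names]
        if missing:
            raise ValueError(
                f"linked-mastoid re-reference needs channels {missing} "
                "which are not present"
            )
        ia1 = epochs.channel_index("A1")
        ia2 = epochs.channel_index("A2")
        ref = 0.5 * (epochs.data[:, ia1:ia1 + 1, :] + epochs.data[:, ia2:ia2 + 1, :])
    elif scheme == "average":
        ref = epochs.data.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown reference scheme {scheme!r}")
    new = epochs.copy_with(data=epochs.data - ref, reference=scheme)
    new.provenance.append(f"rereference[{scheme}]")
    return new


def epoch(recording: np.ndarray, events: pd.DataFrame, sampling_rate_hz: float,
          channel_names: list[str], cfg: PreprocessConfig | None = None,
          condition: str | None = None, reference: str = "nose") -> EpochSet:
    """Cut a continuous recording (channels x samples) into epochs.

    One trial per selected event, window [tmin, tmax) around the onset
    sample. In the pattern condition only triplet-initial events
    (``triplet_pos == 1``) are selected, so trials are time-locked to
    pattern onsets. Events whose window would leave the recording are
    dropped with a logged warning, not an error.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(sampling_rate_hz)
    recording = np.asarray(recording, dtype=float)
    if recording.ndim != 2 or recording.shape[0] != len(channel_names):
        raise ValueError("recording must be channels x samples")
    condition = condition or events.attrs.get("condition", "simple")

    sel = events
    if condition == "pattern":
        sel = events[events["triplet_pos"] == 1]

    n_pre, n_total = epoch_sample_counts(cfg, sampling_rate_hz)
    n_rec = recording.shape[1]
    starts = sel["onset_sample"].to_numpy(np.int64) - n_pre
    ok = (starts >= 0) & (starts + n_total <= n_rec)
    n_drop = int((~ok).sum())
    if n_drop:
        log.warning("dropping %d event(s) too close to the recording edge", n_drop)
    sel = sel[ok]
    starts = starts[ok]

    data = np.stack([recording[:, s:s + n_total] for s in starts]) \
        if len(starts) else np.empty((0, len(channel_names), n_total))
    es = EpochSet(
        data=data,
        sampling_rate_hz=sampling_rate_hz,
        tmin_ms=-n_pre * 1000.0 / sampling_rate_hz,
        channel_names=list(channel_names),
        condition=condition,
        stimulus=sel["code"].to_numpy(),
        reference=reference,
        triplet_pos=None,
        provenance=[f"epoch[{cfg.epoch_tmin_ms},{cfg.epoch_tmax_ms})"],
    )
    return es


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each trial's per-channel mean over the pre-stimulus window."""
    pre = epochs.times_ms < 0
    if not pre.any():
        raise ValueError("no pre-stimulus samples available for baseline")
    base = epochs.data[:, :, pre].mean(axis=2, keepdims=True)
    new = epochs.copy_with(data=epochs.data - base)
    new.provenance.append("baseline")
    return new


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 70.0,
                     mode: str = "absolute",
                     require_baseline: bool = True,
                     exclude_channels: tuple[str, ...] = NON_SCALP) -> EpochSet:
    """Mark trials whose amplitude exceeds the threshold on any EEG channel.

    ``absolute`` mode rejects a trial iff any scalp channel has a sample
    with |value| strictly greater than the threshold (a trial peaking at
    exactly the threshold is retained); ``peak_to_peak`` compares each
    channel's max-min range against the threshold. Mastoid/reference
    channels are excluded from the scan. Counts are logged.
    """
    if threshold_uv <= 0:
        raise ValueError("rejection threshold must be positive")
    if require_baseline and not any(p.startswith("baseline") for p in epochs.provenance):
        raise ValueError(
            "reject_artifacts expects baseline-corrected epochs "
            "(pass require_baseline=False to override)"
        )
    keep_ch = np.array([n not in exclude_channels for n in epochs.channel_names])
    scan = epochs.data[:, keep_ch, :]
    if mode == "absolute":
        extreme = np.abs(scan).max(axis=(1, 2)) > threshold_uv
    elif mode == "peak_to_peak":
        extreme = (scan.max(axis=2) - scan.min(axis=2)).max(axis=1) > threshold_uv
    else:
        raise ValueError(f"unknown rejection mode {mode!r}")
    new = epochs.copy_with(rejected=epochs.rejected | extreme)
    new.provenance.append(f"reject[±{threshold_uv}uV,{mode}]")
    log.info(
        "artifact rejection (%s, ±%g uV): %d/%d trials rejected",
        mode, threshold_uv, int(new.rejected.sum()), new.n_trials,
    )
    return new


def preprocess_epochs(epochs: EpochSet, cfg: PreprocessConfig | None = None) -> EpochSet:
    """Run the epoched part of the chain in canonical order.

    filter (optional) -> linked-mastoid re-reference -> baseline -> reject.
    Use :func:`epoch` first when starting from a continuous recording.
    """
    cfg = cfg or PreprocessConfig()
    out = epochs
    if cfg.apply_filter:
        out = filter_epochs(out, cfg)
    out = rereference(out, "linked_mastoids")
    out = baseline_correct(out)
    out = reject_artifacts(out, cfg.rejection_threshold_uv, cfg.rejection_mode)
    return out
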