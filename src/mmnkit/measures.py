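"""MMN derivation and per-subject measures.

The MMN is read off the difference wave (deviant evoked minus standard
evoked). Peak latency is the time of the most negative sample at a chosen
electrode (Fz by convention) within a closed search window, 100-250 ms by
default; ties resolve to the earliest sample. Mean amplitude is the mean of
the difference wave over a 50-ms window centred on the individual peak,
reported with the field's sign convention: a positive number denotes the
magnitude of the negativity (the raw signed mean is kept alongside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epochs import DifferenceWave, EpochSet, Evoked

DEFAULT_SEARCH_WINDOW_MS = (100.0, 250.0)
DEFAULT_MEAN_WIDTH_MS = 50.0
_EPS = 1e-9


@dataclass
class MMNMeasure:
    subject_id: str
    condition: str
    electrode: str
    peak_latency_ms: float
    mean_amplitude_uv: float  # magnitude of the negativity (positive number)
    signed_mean_uv: float
    window_ms: tuple[float, float]
    n_trials_standard: int
    n_trials_deviant: int
    flags: tuple[str, ...] = ()


def average_evoked(epochs: EpochSet, stimulus: str) -> Evoked:
    """Arithmetic mean over retained trials with the given stimulus label."""
    mask = (~epochs.rejected) & (epochs.stimulus == stimulus)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"no retained {stimulus!r} trials to average "
            f"(condition {epochs.condition!r})"
        )
    return Evoked(
        data=epochs.data[mask].mean(axis=0),
        sampling_rate_hz=epochs.sampling_rate_hz,
        tmin_ms=epochs.tmin_ms,
        channel_names=list(epochs.channel_names),
        condition=epochs.condition,
        stimulus=stimulus,
        n_trials_averaged=n,
    )


def _difference(standard: Evoked, deviant: Evoked) -> DifferenceWave:
    return DifferenceWave(standard=standard, deviant=deviant,
                          diff=deviant.data - standard.data)


def simple_mmn(standard: Evoked, deviant: Evoked) -> DifferenceWave:
    """Frequency-oddball MMN: deviant minus standard evoked response."""
    return _difference(standard, deviant)


def pattern_mmn(standard_first_tone: Evoked, deviant_first_tone: Evoked) -> DifferenceWave:
    """Pattern-oddball MMN: first tone of the deviant (falling) pattern
    minus first tone of the standard (rising) pattern.

    Both evokeds must come from triplet-initial epochs; responses to tones
    2-3, identical across patterns, superpose equally and cancel in the
    subtraction.
    """
    for ev in (standard_first_tone, deviant_first_tone):
        if ev.condition != "pattern":
            raise ValueError(
                "pattern_mmn expects evokeds from the pattern condition "
                f"(got {ev.condition!r})"
            )
    return _difference(standard_first_tone, deviant_first_tone)


def peak_latency(diff: DifferenceWave, electrode: str = "Fz",
                 window_ms: tuple[float, float] = DEFAULT_SEARCH_WINDOW_MS,
                 ) -> tuple[float, tuple[str, ...]]:
    """Latency (ms) of the most negative sample at ``electrode`` within the
    closed search window. Ties go to the earliest sample. A flat segment
    yields the window start plus a ``"no_unique_peak"`` flag.
    """
    ch = diff.channel_index(electrode)
    t = diff.times_ms
    lo, hi = window_ms
    mask = (t >= lo - _EPS) & (t <= hi + _EPS)
    if not mask.any():
        raise ValueError("search window lies outside the epoch")
    seg = diff.diff[ch, mask]
    tw = t[mask]
    flags: tuple[str, ...] = ()
    if np.ptp(seg) == 0:
        return float(tw[0]), ("no_unique_peak",)
    return float(tw[int(np.argmin(seg))]), flags


def mean_amplitude(diff: DifferenceWave, electrode: str,
                   peak_latency_ms: float,
                   width_ms: float = DEFAULT_MEAN_WIDTH_MS,
                   ) -> tuple[float, float, tuple[float, float], tuple[str, ...]]:
    """Mean of the difference wave over [peak - w/2, peak + w/2] (closed,
    at sample resolution) at ``electrode``.

    Returns (magnitude, signed_mean, actual_window, flags); the window is
    clamped to the epoch bounds and flagged ``"clamped_window"`` if cut.
    """
    ch = diff.channel_index(electrode)
    t = diff.times_ms
    half = width_ms / 2.0
    lo, hi = peak_latency_ms - half, peak_latency_ms + half
    flags: list[str] = []
    if lo < t[0] - _EPS or hi > t[-1] + _EPS:
        flags.append("clamped_window")
        lo, hi = max(lo, t[0]), min(hi, t[-1])
    mask = (t >= lo - _EPS) & (t <= hi + _EPS)
    signed = float(diff.diff[ch, mask].mean())
    return -signed, signed, (lo, hi), tuple(flags)


def window_mean(evoked: Evoked, electrode: str,
                window_ms: tuple[float, float]) -> float:
    """Signed mean of an evoked response over a closed time window."""
    ch = evoked.channel_index(electrode)
    t = evoked.times_ms
    mask = (t >= window_ms[0] - _EPS) & (t <= window_ms[1] + _EPS)
    if not mask.any():
        raise ValueError("window lies outside the epoch")
    return float(evoked.data[ch, mask].mean())


def measure_mmn(diff: DifferenceWave, subject_id: str,
                electrode: str = "Fz",
                search_window_ms: tuple[float, float] = DEFAULT_SEARCH_WINDOW_MS,
                width_ms: float = DEFAULT_MEAN_WIDTH_MS) -> MMNMeasure:
    """Individual peak latency and mean amplitude for one difference wave."""
    lat, f1 = peak_latency(diff, electrode, search_window_ms)
    mag, signed, window, f2 = mean_amplitude(diff, electrode, lat, width_ms)
    return MMNMeasure(
        subject_id=subject_id,
        condition=diff.standard.condition,
        electrode=electrode,
        peak_latency_ms=lat,
        mean_amplitude_uv=mag,
        signed_mean_uv=signed,
        window_ms=window,
        n_trials_standard=diff.standard.n_trials_averaged,
        n_trials_deviant=diff.deviant.n_trials_averaged,
        flags=f1 + f2,
    )


def measures_to_frame(measures: list[MMNMeasure],
                      genders: dict[str, str] | None = None) -> pd.DataFrame:
    """Tidy measures table: one row per subject x condition."""
    rows = []
    for m in measures:
        rows.append(
            {
                "subject_id": m.subject_id,
                "gender": (genders or {}).get(m.subject_id, ""),
                "condition": m.condition,
                "electrode": m.electrode,
                "peak_latency_ms": m.peak_latency_ms,
                "mean_amplitude_uv": m.mean_amplitude_uv,
                "signed_mean_uv": m.signed_mean_uv,
                "window_start_ms": m.window_ms[0],
                "window_end_ms": m.window_ms[1],
                "n_trials_standard": m.n_trials_standard,
                "n_trials_deviant": m.n_trials_deviant,
                "flags": ";".join(m.flags),
            }
        )
    return pd.DataFrame(rows)
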