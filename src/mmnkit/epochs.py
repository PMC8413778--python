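"""In-memory containers for epoched EEG, evoked averages and difference waves.

All voltages are microvolts; times are milliseconds relative to stimulus
onset; sample indices are 0-based and epoch windows half-open [tmin, tmax).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class EpochSet:
    """Trials x channels x samples with timing, labels and a rejection mask.

    ``tmin_ms`` is the time of the first sample relative to stimulus onset
    (an exact multiple of the sample period). ``stimulus`` labels each trial
    ``"standard"`` or ``"deviant"``; ``rejected`` marks trials excluded from
    averaging. ``provenance`` records the processing stages applied, in order.
    """

    data: np.ndarray
    sampling_rate_hz: float
    tmin_ms: float
    channel_names: list[str]
    condition: str  # "simple" | "pattern"
    stimulus: np.ndarray  # (n_trials,) of str
    rejected: np.ndarray | None = None
    reference: str = "nose"
    triplet_pos: np.ndarray | None = None  # (n_trials,) int, pattern only
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        self.stimulus = np.asarray(self.stimulus)
        if self.stimulus.shape[0] != self.data.shape[0]:
            raise ValueError("stimulus labels must match trial count")
        if self.rejected is None:
            self.rejected = np.zeros(self.data.shape[0], dtype=bool)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        if self.rejected.shape[0] != self.data.shape[0]:
            raise ValueError("rejection mask must match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        step = 1000.0 / self.sampling_rate_hz
        return self.tmin_ms + step * np.arange(self.n_samples)

    @property
    def n_retained(self) -> int:
        return int((~self.rejected).sum())

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None

    def copy_with(self, **changes) -> "EpochSet":
        """Shallow-copy with replaced fields; provenance list is copied."""
        changes.setdefault("provenance", list(self.provenance))
        return replace(self, **changes)

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset trials by boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        return self.copy_with(
            data=self.data[mask],
            stimulus=self.stimulus[mask],
            rejected=self.rejected[mask],
            triplet_pos=None if self.triplet_pos is None else self.triplet_pos[mask],
        )


@dataclass
class Evoked:
    """Average over retained trials: channels x samples."""

    data: np.ndarray
    sampling_rate_hz: float
    tmin_ms: float
    channel_names: list[str]
    condition: str
    stimulus: str
    n_trials_averaged: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.n_trials_averaged < 1:
            raise ValueError("an evoked average needs at least one trial")

    @property
    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate_hz
        return self.tmin_ms + step * np.arange(self.data.shape[1])

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None


@dataclass
class DifferenceWave:
    """Deviant minus standard evoked pair; ``diff`` is the MMN waveform."""

    standard: Evoked
    deviant: Evoked
    diff: np.ndarray

    def __post_init__(self) -> None:
        if self.standard.data.shape != self.deviant.data.shape:
            raise ValueError("standard and deviant evokeds differ in shape")
        if self.standard.channel_names != self.deviant.channel_names:
            raise ValueError("standard and deviant evokeds differ in channels")

    @property
    def times_ms(self) -> np.ndarray:
        return self.standard.times_ms

    @property
    def channel_names(self) -> list[str]:
        return self.standard.channel_names

    @property
    def sampling_rate_hz(self) -> float:
        return self.standard.sampling_rate_hz

    def channel_index(self, name: str) -> int:
        return self.standard.channel_index(name)
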