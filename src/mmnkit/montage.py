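"""Electrode montages: labels, planar positions and reference bookkeeping.

Positions are 2D top-view projections on a unit head (x toward the right
ear, y toward the nasion). They drive the simulator's spatial profiles and
spatially correlated noise; topographic statistics only need the labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 32 recording sites of the standard cap (10-20 system), in cap order.
CHANNELS_32 = [
    "FP1", "FPz", "FP2", "Fz", "F3", "F4", "F7", "F8",
    "FC1", "FC2", "FC5", "FC6", "Cz", "C3", "C4", "T7", "T8",
    "CP1", "CP2", "CP5", "CP6", "Pz", "P3", "P4", "P7", "P8",
    "POz", "Oz", "O1", "O2", "A1", "A2",
]

# Approximate 10-20 planar projection, unit head radius.
_POSITIONS_32 = {
    "FP1": (-0.278, 0.856), "FPz": (0.0, 0.9), "FP2": (0.278, 0.856),
    "Fz": (0.0, 0.45), "F3": (-0.34, 0.48), "F4": (0.34, 0.48),
    "F7": (-0.728, 0.529), "F8": (0.728, 0.529),
    "FC1": (-0.18, 0.23), "FC2": (0.18, 0.23),
    "FC5": (-0.59, 0.27), "FC6": (0.59, 0.27),
    "Cz": (0.0, 0.0), "C3": (-0.45, 0.0), "C4": (0.45, 0.0),
    "T7": (-0.9, 0.0), "T8": (0.9, 0.0),
    "CP1": (-0.18, -0.23), "CP2": (0.18, -0.23),
    "CP5": (-0.59, -0.27), "CP6": (0.59, -0.27),
    "Pz": (0.0, -0.45), "P3": (-0.34, -0.48), "P4": (0.34, -0.48),
    "P7": (-0.728, -0.529), "P8": (0.728, -0.529),
    "POz": (0.0, -0.675), "Oz": (0.0, -0.9),
    "O1": (-0.278, -0.856), "O2": (0.278, -0.856),
    "A1": (-1.0, -0.15), "A2": (1.0, -0.15),
}

#: Channels that never enter scalp/topographic statistics.
NON_SCALP = ("A1", "A2")


@dataclass
class Montage:
    """Ordered channel labels with planar positions and a reference tag."""

    names: list[str]
    positions: np.ndarray  # (n_channels, 2)
    reference: str = "nose"  # nose | linked_mastoids | average

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        if self.positions.shape != (len(self.names), 2):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.names)} channels"
            )

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def scalp_indices(self) -> np.ndarray:
        """Indices of scalp channels (mastoids A1/A2 excluded)."""
        return np.array([i for i, n in enumerate(self.names) if n not in NON_SCALP])

    @property
    def scalp_names(self) -> list[str]:
        return [n for n in self.names if n not in NON_SCALP]

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.names]
        if missing:
            raise ValueError(f"montage is missing required channels: {missing}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.names,
             "x": self.positions[:, 0],
             "y": self.positions[:, 1]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, reference: str = "nose") -> "Montage":
        return cls(list(df["name"]), df[["x", "y"]].to_numpy(float), reference)


def standard_montage_32(reference: str = "nose") -> Montage:
    """The 32-channel 10-20 cap used throughout (FP1...O2 plus mastoids)."""
    pos = np.array([_POSITIONS_32[n] for n in CHANNELS_32])
    return Montage(list(CHANNELS_32), pos, reference)
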