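"""Oddball stimulus-sequence generation.

Two designs are supported. In the *simple* (frequency) oddball a unit is a
single tone: standards at 1131 Hz, rare deviants at 1269 Hz. In the
*pattern* oddball a unit is a three-tone triplet: the standard is a rising
pitch pattern (1131, 1198, 1269 Hz) and the deviant the reversed falling
pattern. Deviant units are placed uniformly at random subject to a minimum
run of standard units between them (default 1, i.e. no two consecutive
deviant units), which keeps the regularity interpretable.

The output is an event table (one row per tone) with integer onset samples
spaced one stimulus-onset asynchrony apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STANDARD_HZ = 1131.0
MIDDLE_HZ = 1198.0
DEVIANT_HZ = 1269.0

RISING_TRIPLET = (STANDARD_HZ, MIDDLE_HZ, DEVIANT_HZ)
FALLING_TRIPLET = (DEVIANT_HZ, MIDDLE_HZ, STANDARD_HZ)


@dataclass
class SequenceConfig:
    """Stimulus-sequence parameters.

    Defaults follow the oddball design the package targets: 200 deviants at
    probability .16, 180 ms SOA, 50 ms tone bursts.
    """

    condition: str = "simple"  # "simple" | "pattern"
    n_deviants: int = 200
    p_deviant: float = 0.16
    soa_ms: float = 180.0
    tone_duration_ms: float = 50.0
    sampling_rate_hz: float = 512.0
    seed: int = 0
    min_standards_between_deviants: int = 1
    head_standards: int = 0  # force this many leading units to be standard

    def validate(self) -> None:
        if self.condition not in ("simple", "pattern"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 0.0 < self.p_deviant < 1.0:
            raise ValueError("p_deviant must lie strictly between 0 and 1")
        if self.n_deviants < 1:
            raise ValueError("n_deviants must be at least 1")
        if not self.soa_ms > self.tone_duration_ms >= 0:
            raise ValueError("need soa_ms > tone_duration_ms >= 0")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.condition == "simple" and self.p_deviant >= 0.5:
            raise ValueError(
                "p_deviant >= 0.5 violates oddball rarity in the simple condition"
            )
        if self.min_standards_between_deviants < 0 or self.head_standards < 0:
            raise ValueError("spacing constraints must be non-negative")

    @property
    def n_units(self) -> int:
        """Total unit count forced by n_deviants and p_deviant (rounded)."""
        return int(round(self.n_deviants / self.p_deviant))


def _place_deviants(rng: np.random.Generator, n_units: int, k: int,
                    gap: int, head: int) -> np.ndarray:
    """Uniform random deviant unit positions with >= gap standards between
    consecutive deviants and none in the first ``head`` units.

    Uses the classic bijection between spaced k-subsets of [0, m) and
    arbitrary k-subsets of [0, m - (k-1)*gap).
    """
    m = n_units - head
    slots = m - (k - 1) * gap
    if slots < k:
        raise ValueError(
            f"cannot place {k} deviants in {n_units} units with gap "
            f"{gap} and {head} leading standards"
        )
    base = np.sort(rng.choice(slots, size=k, replace=False))
    return head + base + gap * np.arange(k)


def generate_stimulus_sequence(cfg: SequenceConfig) -> pd.DataFrame:
    """Generate an event table for one oddball block set.

    Returns a DataFrame with columns ``onset_sample`` (int), ``code``
    ("standard"/"deviant", the code of the *unit* a tone belongs to),
    ``triplet_pos`` (1-3 in the pattern condition, <NA> otherwise) and
    ``frequency_hz``. Deterministic for a fixed config (seed included).

    The realized deviant probability ``n_deviants / n_units`` is recorded in
    ``df.attrs["realized_p"]``; it differs from ``cfg.p_deviant`` whenever
    ``n_deviants / p_deviant`` is not an integer.
    """
    cfg.validate()
    n_units = cfg.n_units
    rng = np.random.default_rng(cfg.seed)
    deviant_units = _place_deviants(
        rng, n_units, cfg.n_deviants,
        cfg.min_standards_between_deviants, cfg.head_standards,
    )
    is_deviant_unit = np.zeros(n_units, dtype=bool)
    is_deviant_unit[deviant_units] = True

    soa_samples = int(round(cfg.soa_ms / 1000.0 * cfg.sampling_rate_hz))
    tones_per_unit = 3 if cfg.condition == "pattern" else 1
    n_tones = n_units * tones_per_unit

    onset = np.arange(n_tones, dtype=np.int64) * soa_samples
    unit_of_tone = np.repeat(np.arange(n_units), tones_per_unit)
    code = np.where(is_deviant_unit[unit_of_tone], "deviant", "standard")

    if cfg.condition == "pattern":
        pos = np.tile(np.array([1, 2, 3]), n_units)
        freq = np.where(
            is_deviant_unit[unit_of_tone],
            np.tile(np.array(FALLING_TRIPLET), n_units),
            np.tile(np.array(RISING_TRIPLET), n_units),
        )
        triplet_pos = pd.array(pos, dtype="Int64")
    else:
        freq = np.where(is_deviant_unit[unit_of_tone], DEVIANT_HZ, STANDARD_HZ)
        triplet_pos = pd.array([pd.NA] * n_tones, dtype="Int64")

    df = pd.DataFrame(
        {
            "onset_sample": onset,
            "code": code,
            "triplet_pos": triplet_pos,
            "frequency_hz": freq,
        }
    )
    df.attrs.update(
        condition=cfg.condition,
        n_deviants=cfg.n_deviants,
        n_units=n_units,
        p_deviant=cfg.p_deviant,
        realized_p=cfg.n_deviants / n_units,
        soa_ms=cfg.soa_ms,
        soa_samples=soa_samples,
        tone_duration_ms=cfg.tone_duration_ms,
        sampling_rate_hz=cfg.sampling_rate_hz,
        seed=cfg.seed,
    )
    return df


def count_deviant_units(events: pd.DataFrame) -> int:
    """Number of deviant units (tones in simple, triplets in pattern)."""
    if events.attrs.get("condition") == "pattern":
        first = events["triplet_pos"] == 1
        return int(((events["code"] == "deviant") & first).sum())
    return int((events["code"] == "deviant").sum())
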