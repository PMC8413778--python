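"""Topographic statistics: global field power, DISS, and the randomization
test comparing scalp topographies between groups.

Global field power (GFP) is the spatial root-mean-square of an
average-referenced map — a reference-free measure of field strength:

    GFP = sqrt( (1/E) * sum_i (v_i - v_bar)^2 )

Global dissimilarity (DISS) between two maps is the root-mean-square
difference of their GFP-normalized, average-referenced values:

    DISS(u, v) = sqrt( (1/E) * sum_i (u_i/GFP_u - v_i/GFP_v)^2 )

so DISS is 0 for maps of identical shape, 2 for polarity-reversed maps, and
obeys DISS^2 = 2 * (1 - r) with r the spatial Pearson correlation. Strength
differences drop out: DISS compares shape only.

Group comparison uses a nonparametric randomization test: individual maps
are pooled and repeatedly reassigned to two groups of the original sizes;
the DISS between the permuted group-average maps forms the null
distribution, and the p-value is the proportion of permutations with DISS
at least as large as observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .epochs import DifferenceWave
from .measures import MMNMeasure
from .montage import NON_SCALP

_EPS = 1e-9


@dataclass
class TopoMap:
    """One scalp voltage map: a value per scalp electrode."""

    values: np.ndarray
    labels: list[str]
    subject_id: str = ""
    window_ms: tuple[float, float] | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels),):
            raise ValueError("one value per electrode label required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")


@dataclass
class DissResult:
    diss_observed: float
    p_value: float
    n_permutations: int
    null_distribution: np.ndarray
    seed: int | None
    n_a: int
    n_b: int

    def summary(self) -> str:
        return (
            f"DISS = {self.diss_observed:.3f}, p = {self.p_value:.3g} "
            f"({self.n_permutations} permutations, groups {self.n_a}/{self.n_b})"
        )


def subject_topomap(diff: DifferenceWave, measure: MMNMeasure,
                    mode: str = "window",
                    exclude: tuple[str, ...] = NON_SCALP) -> TopoMap:
    """Per-electrode MMN map for one subject.

    ``window`` mode (default) averages the difference wave over the
    subject's individual 50-ms MMN window — the same window as the
    amplitude measure; ``peak`` mode takes the single sample at the peak
    latency. Mastoid channels are excluded.
    """
    t = diff.times_ms
    if mode == "window":
        lo, hi = measure.window_ms
        mask = (t >= lo - _EPS) & (t <= hi + _EPS)
        vals = diff.diff[:, mask].mean(axis=1)
    elif mode == "peak":
        idx = int(np.argmin(np.abs(t - measure.peak_latency_ms)))
        vals = diff.diff[:, idx]
    else:
        raise ValueError(f"unknown topomap mode {mode!r}")
    keep = [i for i, n in enumerate(diff.channel_names) if n not in exclude]
    return TopoMap(
        values=vals[keep],
        labels=[diff.channel_names[i] for i in keep],
        subject_id=measure.subject_id,
        window_ms=measure.window_ms,
    )


def gfp(map_or_values: TopoMap | np.ndarray) -> float:
    """Global field power: spatial standard deviation of the map
    (root-mean-square about the spatial mean, 1/E normalization)."""
    v = map_or_values.values if isinstance(map_or_values, TopoMap) else np.asarray(map_or_values, float)
    if v.size < 2:
        raise ValueError("GFP needs at least two electrodes")
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


def _normalize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    g = np.sqrt(np.mean(v ** 2))
    if g == 0:
        raise ValueError("cannot GFP-normalize a spatially uniform map (GFP = 0)")
    return v / g


def diss(u: TopoMap | np.ndarray, v: TopoMap | np.ndarray) -> float:
    """Global dissimilarity between two maps on identical electrode sets.

    Both maps are average-referenced and divided by their GFP before the
    root-mean-square difference is taken; the result lies in [0, 2].
    """
    if isinstance(u, TopoMap) and isinstance(v, TopoMap):
        if u.labels != v.labels:
            raise ValueError("maps must share an identical ordered electrode set")
        uu, vv = u.values, v.values
    else:
        uu = u.values if isinstance(u, TopoMap) else np.asarray(u, float)
        vv = v.values if isinstance(v, TopoMap) else np.asarray(v, float)
        if uu.shape != vv.shape:
            raise ValueError("maps must have the same number of electrodes")
    return float(np.sqrt(np.mean((_normalize(uu) - _normalize(vv)) ** 2)))


def _stack(maps: list[TopoMap] | np.ndarray) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(maps, np.ndarray):
        return np.asarray(maps, float), None
    labels = maps[0].labels
    for m in maps[1:]:
        if m.labels != labels:
            raise ValueError("all maps must share an identical electrode set")
    return np.stack([m.values for m in maps]), labels


def diss_permutation_test(maps_a: list[TopoMap] | np.ndarray,
                          maps_b: list[TopoMap] | np.ndarray,
                          n_permutations: int = 10_000,
                          seed: int | None = None,
                          add_one: bool = False) -> DissResult:
    """Randomization test for a group difference in map shape.

    The observed statistic is the DISS between the two group-average maps.
    Each permutation reassigns the pooled individual maps uniformly at
    random into groups of the original sizes and recomputes the statistic;
    p is the proportion of permutations with DISS >= observed (ties count
    toward the null, a conservative convention). ``add_one`` switches to the
    (b+1)/(m+1) estimator. Reproducible for a fixed seed.
    """
    a, labels_a = _stack(maps_a)
    b, labels_b = _stack(maps_b)
    if labels_a is not None and labels_b is not None and labels_a != labels_b:
        raise ValueError("groups must share an identical electrode set")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 maps")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value",
                      stacklevel=2)
    n_a = a.shape[0]
    pooled = np.concatenate([a, b], axis=0)
    n = pooled.shape[0]
    observed = diss(a.mean(axis=0), b.mean(axis=0))

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        order = rng.permutation(n)
        ga = pooled[order[:n_a]].mean(axis=0)
        gb = pooled[order[n_a:]].mean(axis=0)
        null[i] = diss(ga, gb)

    count = int((null >= observed - 1e-12).sum())
    p = (count + 1) / (n_permutations + 1) if add_one else count / n_permutations
    return DissResult(
        diss_observed=observed,
        p_value=float(p),
        n_permutations=n_permutations,
        null_distribution=null,
        seed=seed,
        n_a=n_a,
        n_b=b.shape[0],
    )
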