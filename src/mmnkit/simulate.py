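"""Synthetic oddball-EEG study generator.

Emulates nose-referenced 32-channel epochs from a two-condition (simple /
pattern oddball), two-gender study so that every downstream stage can be
exercised without recordings. Each standard epoch is a fixed P1-N1-P2
template (sum of Gaussian kernels) times a broad spatial profile; each
deviant epoch additionally carries a negative Gaussian MMN kernel (default
FWHM 60 ms) peaking at the subject's configured latency, weighted by a
fronto-central spatial profile that is maximal around Fz/FC1/FC2/Cz and
tapers to zero at occipital and mastoid sites. In the pattern condition
epochs are time-locked to triplet-initial tones and the obligatory
responses to tones 2-3 are superposed linearly at +180 and +360 ms.

Noise is AR(1) in time (coefficient 0.95 at 512 Hz) with spatially
correlated channel loading (squared-exponential kernel over montage
distance), which gives EEG-like low-frequency-dominated spectra. Optional
artifact trials carry a >= 100 uV frontal excursion so the +/- 70 uV
rejection stage has something to catch.

Subject parameters are drawn per condition x gender cell from configured
means and between-subject SDs; the default study preset uses cell means of
173.55 / 142.58 ms (simple, female / male) and 150.11 / 158.08 ms (pattern)
for peak latency, 1.89 / 1.48 and 1.03 / 0.79 uV for mean amplitude, with
SDs reconstructed from the corresponding standard errors (SEM * sqrt(n),
n = 14 female / 15 male).

Note on amplitudes: the configured cell amplitudes are *measured* 50-ms
window mean amplitudes. The generator converts them to Gaussian kernel
peaks through the analytic window factor (about 0.86 for FWHM 60 ms /
50 ms window) so that the pipeline's measured mean amplitudes recover the
configured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sg
from scipy import special

from .epochs import EpochSet
from .montage import Montage, standard_montage_32
from .preprocess import PreprocessConfig, epoch_sample_counts
from .sequences import SequenceConfig, generate_stimulus_sequence

CONDITIONS = ("simple", "pattern")
GENDERS = ("female", "male")

#: Obligatory auditory response: (amplitude uV, latency ms, FWHM ms).
OBLIGATORY_COMPONENTS = ((1.2, 55.0, 40.0), (-2.0, 105.0, 55.0), (1.4, 185.0, 80.0))

MMN_CENTER = (0.0, 0.2)     # fronto-central, between Fz and Cz
MMN_RADIUS = 0.9            # taper reaches zero before occipital/mastoid sites
OBLIGATORY_CENTER = (0.0, 0.05)
OBLIGATORY_RADIUS = 1.4

AR_COEFF = 0.95
SPATIAL_NOISE_SCALE = 0.35

_SEED_MOD = 2 ** 31


def fwhm_to_sigma(fwhm_ms: float) -> float:
    return fwhm_ms / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def gaussian_kernel(t_ms: np.ndarray, latency_ms: float, fwhm_ms: float) -> np.ndarray:
    s = fwhm_to_sigma(fwhm_ms)
    return np.exp(-0.5 * ((t_ms - latency_ms) / s) ** 2)


def mean_window_factor(fwhm_ms: float = 60.0, width_ms: float = 50.0) -> float:
    """Ratio of a Gaussian's mean over a centred window to its peak.

    mean/peak = sigma*sqrt(2*pi)*erf(w / (2*sigma*sqrt(2))) / w — about
    0.860 for FWHM 60 ms and a 50 ms window. Used to convert configured
    window-mean amplitudes into kernel peaks and back.
    """
    s = fwhm_to_sigma(fwhm_ms)
    return float(s * math.sqrt(2.0 * math.pi)
                 * special.erf(width_ms / (2.0 * s * math.sqrt(2.0))) / width_ms)


def cosine_taper_weights(montage: Montage, center: tuple[float, float],
                         radius: float, unit_at: str = "Fz") -> np.ndarray:
    """Cosine-squared taper over montage distance from ``center``; zero at
    distance >= radius, rescaled so the weight at ``unit_at`` is exactly 1."""
    d = np.linalg.norm(montage.positions - np.asarray(center), axis=1)
    w = np.where(d < radius, np.cos(0.5 * np.pi * d / radius) ** 2, 0.0)
    ref = w[montage.index(unit_at)]
    if ref <= 0:
        raise ValueError(f"taper vanishes at reference channel {unit_at}")
    return w / ref


@dataclass
class SubjectProfile:
    """Per-subject simulation parameters.

    ``mmn_latency_ms`` / ``mmn_peak_uv`` map condition -> value;
    ``mmn_peak_uv`` is the (positive) magnitude of the negative Gaussian
    kernel's peak.
    """

    subject_id: str
    gender: str
    mmn_latency_ms: dict[str, float]
    mmn_peak_uv: dict[str, float]
    noise_sd_uv: float = 4.0
    artifact_trial_fraction: float = 0.0
    mmn_fwhm_ms: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}")
        for cond, lat in self.mmn_latency_ms.items():
            if not 100.0 <= lat <= 250.0:
                raise ValueError(
                    f"{self.subject_id}/{cond}: latency {lat} outside [100, 250] ms"
                )
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be non-negative")
        if not 0.0 <= self.artifact_trial_fraction < 1.0:
            raise ValueError("artifact_trial_fraction must lie in [0, 1)")


@dataclass
class CellStats:
    """Condition x gender cell: means and between-subject SDs of the
    measured quantities (latency in ms, 50-ms window mean amplitude in uV)."""

    latency_mean: float
    latency_sd: float
    amplitude_mean: float
    amplitude_sd: float

    def validate(self) -> None:
        if self.latency_sd < 0 or self.amplitude_sd < 0:
            raise ValueError("between-subject SDs must be non-negative")


@dataclass
class StudyConfig:
    n_female: int = 14
    n_male: int = 15
    cells: dict[tuple[str, str], CellStats] = field(default_factory=dict)
    montage: Montage = field(default_factory=standard_montage_32)
    sampling_rate_hz: float = 512.0
    seed: int = 0
    noise_sd_uv: float = 4.0
    artifact_trial_fraction: float = 0.05
    mmn_fwhm_ms: float = 60.0
    n_deviants: int = 200
    p_deviant: float = 0.16
    soa_ms: float = 180.0
    conditions: tuple[str, ...] = CONDITIONS

    def validate(self) -> None:
        if self.n_female + self.n_male < 2:
            raise ValueError("need at least 2 subjects in total")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        for cond in self.conditions:
            for g in GENDERS:
                if (cond, g) not in self.cells:
                    raise ValueError(f"missing cell parameters for ({cond}, {g})")
                self.cells[(cond, g)].validate()
        self.montage.require("Fz", "A1", "A2")


def study_preset(seed: int = 0, noise_sd_uv: float = 4.0,
                 artifact_trial_fraction: float = 0.05,
                 sampling_rate_hz: float = 512.0) -> StudyConfig:
    """The default study conditions the simulator targets.

    14 female / 15 male subjects, two oddball conditions, cell means for
    peak latency and window mean amplitude as in the study summary table,
    between-subject SDs reconstructed from the SEMs (SEM * sqrt(n)).
    """
    sems = {
        ("simple", "female"): (173.55, 9.06, 1.89, 0.25, 14),
        ("simple", "male"): (142.58, 6.76, 1.48, 0.23, 15),
        ("pattern", "female"): (150.11, 8.32, 1.03, 0.10, 14),
        ("pattern", "male"): (158.08, 7.49, 0.79, 0.22, 15),
    }
    cells = {
        key: CellStats(
            latency_mean=lm, latency_sd=lsem * math.sqrt(n),
            amplitude_mean=am, amplitude_sd=asem * math.sqrt(n),
        )
        for key, (lm, lsem, am, asem, n) in sems.items()
    }
    return StudyConfig(
        n_female=14, n_male=15, cells=cells,
        sampling_rate_hz=sampling_rate_hz, seed=seed,
        noise_sd_uv=noise_sd_uv,
        artifact_trial_fraction=artifact_trial_fraction,
    )


def _colored_noise(rng: np.random.Generator, n_trials: int, chol: np.ndarray,
                   n_samples: int, sd_uv: float, ar: float = AR_COEFF) -> np.ndarray:
    """AR(1)-in-time, spatially correlated noise with stationary SD sd_uv."""
    burn = 200
    n_ch = chol.shape[0]
    w = rng.standard_normal((n_trials, n_ch, n_samples + burn))
    w = np.einsum("ck,tks->tcs", chol, w)
    e = sg.lfilter([1.0], [1.0, -ar], w, axis=-1)[..., burn:]
    return e * (sd_uv * math.sqrt(1.0 - ar * ar))


def _noise_chol(montage: Montage, scale: float = SPATIAL_NOISE_SCALE) -> np.ndarray:
    pos = montage.positions
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    k = np.exp(-0.5 * d2 / scale ** 2) + 1e-6 * np.eye(len(pos))
    return np.linalg.cholesky(k)


def _inject_artifacts(rng: np.random.Generator, data: np.ndarray,
                      montage: Montage, fraction: float, fs: float,
                      n_pre: int) -> np.ndarray:
    """Add >= 100 uV frontal half-sine excursions to a fraction of trials.

    Returns the indices of the affected trials.
    """
    n_trials, _, n_samples = data.shape
    k = int(round(fraction * n_trials))
    if k == 0:
        return np.empty(0, dtype=int)
    trials = rng.choice(n_trials, size=k, replace=False)
    dur = max(int(round(0.1 * fs)), 4)
    blip = 150.0 * np.sin(np.pi * np.arange(dur) / (dur - 1))
    ifp1, ifp2 = montage.index("FP1"), montage.index("FP2")
    for tr in trials:
        start = int(rng.integers(n_pre, max(n_pre + 1, n_samples - dur)))
        sl = slice(start, start + dur)
        seg = blip[: data.shape[2] - start]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        data[tr, ifp1, sl] += sign * seg
        data[tr, ifp2, sl] += 0.8 * sign * seg
    return np.sort(trials)


def generate_subject_epochs(profile: SubjectProfile, sequence: pd.DataFrame,
                            study: StudyConfig,
                            prep: PreprocessConfig | None = None,
                            ) -> tuple[EpochSet, EpochSet]:
    """Simulate one subject's epochs for one condition.

    Returns (standard, deviant) epoch sets, nose-referenced, with the epoch
    window of ``prep`` (default [-100, 400) ms). Deterministic for a fixed
    profile seed.
    """
    profile.validate()
    prep = prep or PreprocessConfig()
    cond = sequence.attrs.get("condition")
    if cond not in profile.mmn_latency_ms or cond not in profile.mmn_peak_uv:
        raise ValueError(
            f"sequence condition {cond!r} has no parameters in profile "
            f"{profile.subject_id}"
        )
    montage = study.montage
    montage.require("Fz", "A1", "A2")
    fs = study.sampling_rate_hz
    n_pre, n_total = epoch_sample_counts(prep, fs)
    t = (np.arange(n_total) - n_pre) * 1000.0 / fs

    # obligatory P1-N1-P2 response, superposed for triplet tones 2-3
    shifts = (0.0, study.soa_ms, 2 * study.soa_ms) if cond == "pattern" else (0.0,)
    oblig = np.zeros(n_total)
    for shift in shifts:
        for amp, lat, fwhm in OBLIGATORY_COMPONENTS:
            oblig += amp * gaussian_kernel(t, lat + shift, fwhm)
    w_obl = cosine_taper_weights(montage, OBLIGATORY_CENTER, OBLIGATORY_RADIUS,
                                 unit_at="Cz")
    base = w_obl[:, None] * oblig[None, :]

    mmn = -profile.mmn_peak_uv[cond] * gaussian_kernel(
        t, profile.mmn_latency_ms[cond], profile.mmn_fwhm_ms
    )
    w_mmn = cosine_taper_weights(montage, MMN_CENTER, MMN_RADIUS, unit_at="Fz")
    mmn_map = w_mmn[:, None] * mmn[None, :]

    if cond == "pattern":
        events = sequence[sequence["triplet_pos"] == 1]
    else:
        events = sequence
    codes = events["code"].to_numpy()
    n_trials = len(codes)

    data = np.tile(base, (n_trials, 1, 1))
    data[codes == "deviant"] += mmn_map

    rng = np.random.default_rng(profile.seed)
    if profile.noise_sd_uv > 0:
        data += _colored_noise(rng, n_trials, _noise_chol(montage),
                               n_total, profile.noise_sd_uv)
    _inject_artifacts(rng, data, montage, profile.artifact_trial_fraction,
                      fs, n_pre)

    def make(mask: np.ndarray, label: str) -> EpochSet:
        return EpochSet(
            data=data[mask],
            sampling_rate_hz=fs,
            tmin_ms=-n_pre * 1000.0 / fs,
            channel_names=list(montage.names),
            condition=cond,
            stimulus=np.full(int(mask.sum()), label),
            reference="nose",
            triplet_pos=(np.ones(int(mask.sum()), dtype=int)
                         if cond == "pattern" else None),
            provenance=["simulated"],
        )

    return make(codes == "standard", "standard"), make(codes == "deviant", "deviant")


@dataclass
class StudyDataset:
    """A simulated study: subject profiles plus reproducible epoch access.

    Epochs are generated on demand per subject and condition (a full study
    held in memory at once would be several gigabytes); everything is
    reproducible from the study seed.
    """

    config: StudyConfig
    subjects: list[SubjectProfile]
    sequence_seeds: dict[tuple[str, str], int]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def genders(self) -> dict[str, str]:
        return {s.subject_id: s.gender for s in self.subjects}

    def profile(self, subject_id: str) -> SubjectProfile:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(f"unknown subject {subject_id!r}")

    def sequence(self, subject_id: str, condition: str) -> pd.DataFrame:
        cfg = SequenceConfig(
            condition=condition,
            n_deviants=self.config.n_deviants,
            p_deviant=self.config.p_deviant,
            soa_ms=self.config.soa_ms,
            sampling_rate_hz=self.config.sampling_rate_hz,
            seed=self.sequence_seeds[(subject_id, condition)],
        )
        return generate_stimulus_sequence(cfg)

    def subject_epochs(self, subject_id: str, condition: str,
                       prep: PreprocessConfig | None = None,
                       ) -> tuple[EpochSet, EpochSet]:
        return generate_subject_epochs(
            self.profile(subject_id), self.sequence(subject_id, condition),
            self.config, prep,
        )

    def profile_measures(self) -> pd.DataFrame:
        """The drawn subject parameters as a tidy measures table.

        Latency is the configured peak latency; amplitude is the target
        window-mean amplitude (kernel peak times the analytic window
        factor). This is what the epoch-level pipeline recovers, up to
        sample quantization and averaging noise.
        """
        factor = mean_window_factor(self.config.mmn_fwhm_ms)
        rows = []
        for s in self.subjects:
            for cond in self.config.conditions:
                rows.append({
                    "subject_id": s.subject_id,
                    "gender": s.gender,
                    "condition": cond,
                    "peak_latency_ms": s.mmn_latency_ms[cond],
                    "mean_amplitude_uv": s.mmn_peak_uv[cond] * factor,
                })
        return pd.DataFrame(rows)


def _draw_clipped(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    # single draw clipped to the valid range: keeps cell means nearly
    # unbiased (resampling out-of-range draws would shift them visibly)
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def generate_study(study: StudyConfig) -> StudyDataset:
    """Draw subject parameters for the whole study.

    Per-subject peak latencies are drawn from the configured cell normal
    distributions, clipped to the valid MMN range [100, 250] ms; window
    mean amplitudes are drawn likewise, floored at 0.05 uV, and converted
    to kernel peaks. Fully reproducible from ``study.seed``.
    """
    study.validate()
    rng = np.random.default_rng(study.seed)
    factor = mean_window_factor(study.mmn_fwhm_ms)
    subjects: list[SubjectProfile] = []
    sequence_seeds: dict[tuple[str, str], int] = {}

    roster = [("female", i) for i in range(study.n_female)] + \
             [("male", i) for i in range(study.n_male)]
    for gender, i in roster:
        sid = f"{gender[0]}{i + 1:02d}"
        lat = {}
        peak = {}
        for cond in study.conditions:
            cell = study.cells[(cond, gender)]
            lat[cond] = _draw_clipped(rng, cell.latency_mean,
                                      cell.latency_sd, 100.0, 250.0)
            amp = max(rng.normal(cell.amplitude_mean, cell.amplitude_sd), 0.05) \
                if cell.amplitude_sd > 0 else max(cell.amplitude_mean, 0.05)
            peak[cond] = amp / factor
        subjects.append(SubjectProfile(
            subject_id=sid, gender=gender,
            mmn_latency_ms=lat, mmn_peak_uv=peak,
            noise_sd_uv=study.noise_sd_uv,
            artifact_trial_fraction=study.artifact_trial_fraction,
            mmn_fwhm_ms=study.mmn_fwhm_ms,
            seed=int(rng.integers(_SEED_MOD)),
        ))
        for cond in study.conditions:
            sequence_seeds[(sid, cond)] = int(rng.integers(_SEED_MOD))
    return StudyDataset(config=study, subjects=subjects,
                        sequence_seeds=sequence_seeds)
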