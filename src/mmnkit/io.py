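"""Plain-text file formats: epochs (TSV matrix + JSON sidecar), events,
montages, measures tables. Everything round-trips bit-exactly.

Epoch layout: the trials x channels x samples array is flattened to a 2-D
matrix with one row per (trial, channel) pair — row index = trial *
n_channels + channel — and one column per sample, written as tab-separated
``%.17g`` floats (lossless for float64). The JSON sidecar carries shape,
timing, labels and the rejection mask.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .montage import Montage

SIDECAR_REQUIRED = (
    "n_trials", "n_channels", "n_samples", "sampling_rate_hz",
    "tmin_ms", "channel_names", "units", "condition", "stimulus",
    "rejected", "reference",
)


class FormatError(ValueError):
    """Raised when a file does not match the documented layout."""


def config_hash(obj) -> str:
    """Short sha256 over a canonical-JSON rendering of a config object."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return {k: v for k, v in vars(o).items()}
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_epochs(epochs: EpochSet, prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mat = epochs.data.reshape(epochs.n_trials * epochs.n_channels,
                              epochs.n_samples)
    data_path = prefix.with_suffix(".tsv")
    np.savetxt(data_path, mat, fmt="%.17g", delimiter="\t")
    sidecar = {
        "n_trials": epochs.n_trials,
        "n_channels": epochs.n_channels,
        "n_samples": epochs.n_samples,
        "sampling_rate_hz": epochs.sampling_rate_hz,
        "tmin_ms": epochs.tmin_ms,
        "channel_names": list(epochs.channel_names),
        "units": "uV",
        "condition": epochs.condition,
        "stimulus": [str(s) for s in epochs.stimulus],
        "rejected": [bool(r) for r in epochs.rejected],
        "reference": epochs.reference,
        "triplet_pos": (None if epochs.triplet_pos is None
                        else [int(p) for p in epochs.triplet_pos]),
        "provenance": list(epochs.provenance),
    }
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=1))
    return data_path, json_path


def read_epochs(prefix: str | Path) -> EpochSet:
    prefix = Path(prefix)
    json_path = prefix.with_suffix(".json")
    data_path = prefix.with_suffix(".tsv")
    meta = json.loads(json_path.read_text())
    for key in SIDECAR_REQUIRED:
        if key not in meta:
            raise FormatError(f"sidecar {json_path} is missing key {key!r}")
    mat = np.loadtxt(data_path, delimiter="\t", ndmin=2)
    expected = (meta["n_trials"] * meta["n_channels"], meta["n_samples"])
    if meta["n_trials"] == 0:
        mat = np.empty(expected)
    if mat.shape != expected:
        raise FormatError(
            f"{data_path}: matrix shape {mat.shape} does not match sidecar "
            f"(expected {expected} = trials*channels x samples)"
        )
    return EpochSet(
        data=mat.reshape(meta["n_trials"], meta["n_channels"], meta["n_samples"]),
        sampling_rate_hz=meta["sampling_rate_hz"],
        tmin_ms=meta["tmin_ms"],
        channel_names=list(meta["channel_names"]),
        condition=meta["condition"],
        stimulus=np.array(meta["stimulus"]),
        rejected=np.array(meta["rejected"], dtype=bool),
        reference=meta["reference"],
        triplet_pos=(None if meta.get("triplet_pos") is None
                     else np.array(meta["triplet_pos"], dtype=int)),
        provenance=list(meta.get("provenance", [])),
    )


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.to_csv(path, sep="\t", index=False)
    meta_path = path.with_suffix(".attrs.json")
    meta_path.write_text(json.dumps(events.attrs, indent=1))
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t",
                     dtype={"onset_sample": np.int64, "code": str},
                     )
    df["triplet_pos"] = df["triplet_pos"].astype("Int64")
    meta_path = path.with_suffix(".attrs.json")
    if meta_path.exists():
        df.attrs.update(json.loads(meta_path.read_text()))
    return df


def write_montage(montage: Montage, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    montage.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_montage(path: str | Path, reference: str = "nose") -> Montage:
    return Montage.from_frame(pd.read_csv(path, sep="\t"), reference)


@dataclass
class ManifestDataset:
    """Epoch files on disk described by a study manifest.

    ``manifest.json`` maps subjects to genders and per-condition epoch-file
    prefixes, e.g.::

        {"subjects": [{"id": "f01", "gender": "female",
                       "files": {"simple": {"standard": "f01_simple_standard",
                                            "deviant": "f01_simple_deviant"}}}],
         "conditions": ["simple"]}

    Prefixes are resolved relative to the manifest directory.
    """

    root: Path
    manifest: dict

    @classmethod
    def load(cls, path: str | Path) -> "ManifestDataset":
        path = Path(path)
        manifest = json.loads(path.read_text())
        ds = cls(root=path.parent, manifest=manifest)
        ds.validate()
        return ds

    def validate(self) -> None:
        for sub in self.manifest.get("subjects", []):
            if sub.get("gender") not in ("female", "male"):
                raise FormatError(
                    f"subject {sub.get('id')!r}: gender must be female or male"
                )
            for cond, files in sub.get("files", {}).items():
                for role in ("standard", "deviant"):
                    prefix = self.root / files[role]
                    for suffix in (".tsv", ".json"):
                        if not prefix.with_suffix(suffix).exists():
                            raise FormatError(
                                f"manifest references missing file "
                                f"{prefix.with_suffix(suffix)}"
                            )

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.manifest.get("conditions", []))

    @property
    def subject_ids(self) -> list[str]:
        return [s["id"] for s in self.manifest["subjects"]]

    def genders(self) -> dict[str, str]:
        return {s["id"]: s["gender"] for s in self.manifest["subjects"]}

    def subject_epochs(self, subject_id: str, condition: str,
                       prep=None) -> tuple[EpochSet, EpochSet]:
        for sub in self.manifest["subjects"]:
            if sub["id"] == subject_id:
                files = sub["files"][condition]
                return (read_epochs(self.root / files["standard"]),
                        read_epochs(self.root / files["deviant"]))
        raise KeyError(f"unknown subject {subject_id!r}")


def import_raw(path: str | Path):
    """Thin adapter for standard EEG formats (EDF/BrainVision/FIF).

    Returns (data_uV, sampling_rate_hz, channel_names). Requires the
    optional ``mne`` dependency; nothing is re-implemented here.
    """
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("importing standard EEG formats requires mne") from err
    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)
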