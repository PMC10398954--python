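"""Core data model and readers/writers for the resting-state EEG pipeline.

The pipeline's in-memory currency is the :class:`Recording` (continuous
multichannel scalp EEG in microvolts) and the :class:`EpochSet` (fixed-length
artifact-screened segments).  Two on-disk dialects are supported:

* ``edf`` — European Data Format, read through :mod:`mne` and written by a
  minimal 16-bit writer (:mod:`rseeg._edf`).  EDF quantizes samples to the
  physical range, so round trips are exact only to quantization precision.
* ``array+json`` — a raw little-endian float32 array (``<stem>.f32``) next to
  a JSON sidecar (``<stem>.json``) carrying sampling rate, channel labels,
  units and subject metadata.  Round trips are byte-identical at float32
  precision, which is what the deterministic tests rely on.

Cohorts are described by a tab-separated manifest with columns
``subject_id``, ``group`` and ``path``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "UnitError",
    "Band",
    "CANONICAL_BANDS",
    "Recording",
    "EpochSet",
    "CohortManifest",
    "TEN_TWENTY_32",
    "read_recording",
    "write_recording",
    "load_cohort",
    "write_manifest",
    "summarize_demographics",
    "load_patient_demographics",
]


class ValidationError(ValueError):
    """An object or file violates a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending field."""


class UnitError(ValueError):
    """A channel's physical unit cannot be converted to microvolts."""


GROUPS = ("patient", "control", "unknown")

#: Default 32-channel international 10/20 montage used throughout the package.
TEN_TWENTY_32: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FCz", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO3", "POz", "PO4", "O1", "Oz", "O2",
)

# Standard 10/20 + 10/10 scalp names used only to warn about unusual montages.
_STANDARD_NAMES = frozenset(
    TEN_TWENTY_32
    + (
        "Fpz", "AFz", "AF3", "AF4", "AF7", "AF8", "F1", "F2", "F5", "F6", "F9", "F10",
        "FT7", "FT8", "FT9", "FT10", "FC3", "FC4", "C1", "C2", "C5", "C6", "Cpz",
        "CPz", "CP3", "CP4", "TP7", "TP8", "TP9", "TP10", "P1", "P2", "P5", "P6",
        "P9", "P10", "PO7", "PO8", "Iz", "T3", "T4", "T5", "T6", "A1", "A2", "M1",
        "M2", "Nz",
    )
)


@dataclass(frozen=True)
class Band:
    """A frequency band ``[f1, f2]`` in Hz."""

    name: str
    f1: float
    f2: float

    def __post_init__(self) -> None:
        if not (0 < self.f1 < self.f2):
            raise ValidationError(f"band {self.name}: need 0 < f1 < f2, got [{self.f1}, {self.f2}]")


#: The five canonical bands partitioning 0.5-45 Hz.
CANONICAL_BANDS: tuple[Band, ...] = (
    Band("delta", 0.5, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 13.0),
    Band("beta", 13.0, 30.0),
    Band("gamma", 30.0, 45.0),
)

BAND_BY_NAME = {b.name: b for b in CANONICAL_BANDS}


@dataclass
class Recording:
    """Continuous multichannel EEG, channels x samples, in microvolts."""

    data: np.ndarray
    channel_labels: list[str]
    fs: float
    subject_id: str = "unknown"
    group: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_labels = list(self.channel_labels)
        if self.data.ndim != 2:
            raise ValidationError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains NaN or Inf")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("channel labels are not unique")
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group label {self.group!r}; expected one of {GROUPS}")
        odd = [c for c in self.channel_labels if c not in _STANDARD_NAMES]
        if odd:
            warnings.warn(f"non-standard channel labels: {odd}", stacklevel=2)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Fixed-length segments: ``epochs`` is n_epochs x channels x samples."""

    epochs: np.ndarray
    fs: float
    epoch_length_s: float
    channel_labels: list[str]
    source_subject: str = "unknown"
    group: str = "unknown"
    kept_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs)
        if self.epochs.ndim != 3:
            raise ValidationError("epochs must be 3-D (n_epochs x channels x samples)")
        want = round(self.epoch_length_s * self.fs)
        if self.epochs.shape[2] != want:
            raise ValidationError(
                f"samples_per_epoch {self.epochs.shape[2]} != round(epoch_length_s*fs) = {want}"
            )
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.epochs.shape[0], dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


@dataclass
class CohortManifest:
    """Subject roster: (subject_id, group, path) rows plus group counts."""

    subject_ids: list[str]
    groups: list[str]
    paths: list[Path]

    def __post_init__(self) -> None:
        if len(set(self.subject_ids)) != len(self.subject_ids):
            dupes = {s for s in self.subject_ids if self.subject_ids.count(s) > 1}
            raise ValidationError(f"duplicate subject ids: {sorted(dupes)}")
        bad = sorted({g for g in self.groups if g not in GROUPS})
        if bad:
            raise ValidationError(f"unknown group labels: {bad}")

    @property
    def n_patients(self) -> int:
        return sum(g == "patient" for g in self.groups)

    @property
    def n_controls(self) -> int:
        return sum(g == "control" for g in self.groups)

    def __len__(self) -> int:
        return len(self.subject_ids)

    def __iter__(self):
        return iter(zip(self.subject_ids, self.groups, self.paths))


# ---------------------------------------------------------------------------
# recording I/O


def _infer_format(path: Path) -> str:
    if path.suffix.lower() == ".edf":
        return "edf"
    return "array+json"


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from EDF or the native array+json dialect.

    ``format`` is inferred from the extension when omitted.  Data are always
    returned in microvolts.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "edf":
        from . import _edf

        return _edf.read_edf(path)
    if fmt == "array+json":
        return _read_array_json(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording; the file is readable back by :func:`read_recording`."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if not np.all(np.isfinite(rec.data)):  # pragma: no cover - Recording validates
        raise ValidationError("refusing to write non-finite data")
    if fmt == "edf":
        from . import _edf

        return _edf.write_edf(rec, path)
    if fmt == "array+json":
        return _write_array_json(rec, path)
    raise ValueError(f"unknown format {fmt!r}")


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".json"), stem.with_suffix(".f32")


def _write_array_json(rec: Recording, path: Path) -> Path:
    json_path, f32_path = _sidecar_paths(path)
    arr = np.ascontiguousarray(rec.data, dtype="<f4")
    f32_path.write_bytes(arr.tobytes())
    sidecar = {
        "format": "rseeg-array+json-v1",
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "units": "uV",
        "subject_id": rec.subject_id,
        "group": rec.group,
        "shape": list(arr.shape),
        "dtype": "<f4",
        "data_file": f32_path.name,
        "meta": _jsonable(rec.meta),
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return json_path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


_UNIT_TO_UV = {"uV": 1.0, "µV": 1.0, "mV": 1e3, "V": 1e6, "nV": 1e-3}


def _read_array_json(path: Path) -> Recording:
    json_path, _ = _sidecar_paths(path)
    try:
        sidecar = json.loads(json_path.read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"sidecar {json_path.name}: invalid JSON ({e})") from e
    for key in ("fs", "channel_labels", "shape", "data_file"):
        if key not in sidecar:
            raise ParseError(f"sidecar {json_path.name}: missing field {key!r}")
    units = sidecar.get("units", "uV")
    if units not in _UNIT_TO_UV:
        raise UnitError(f"cannot convert unit {units!r} to uV")
    f32_path = json_path.parent / sidecar["data_file"]
    raw = np.frombuffer(f32_path.read_bytes(), dtype=sidecar.get("dtype", "<f4"))
    shape = tuple(sidecar["shape"])
    if raw.size != int(np.prod(shape)):
        raise ParseError(
            f"{f32_path.name}: field 'shape' declares {int(np.prod(shape))} samples, "
            f"file holds {raw.size}"
        )
    data = raw.reshape(shape) * _UNIT_TO_UV[units]
    if len(sidecar["channel_labels"]) != shape[0]:
        raise ParseError(
            f"sidecar {json_path.name}: field 'channel_labels' has "
            f"{len(sidecar['channel_labels'])} entries for {shape[0]} channels"
        )
    return Recording(
        data=data,
        channel_labels=sidecar["channel_labels"],
        fs=float(sidecar["fs"]),
        subject_id=sidecar.get("subject_id", "unknown"),
        group=sidecar.get("group", "unknown"),
        meta=sidecar.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# cohort manifest


def load_cohort(manifest_path: str | Path, check_files: bool = True) -> CohortManifest:
    """Load a tab-separated ``subject_id / group / path`` manifest."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    required = {"subject_id", "group", "path"}
    if not required.issubset(df.columns):
        raise ParseError(f"manifest missing columns: {sorted(required - set(df.columns))}")
    if len(df) == 0:
        raise ValidationError("manifest is empty")
    paths = [
        p if (p := Path(str(raw))).is_absolute() else manifest_path.parent / p
        for raw in df["path"]
    ]
    manifest = CohortManifest(
        subject_ids=[str(s) for s in df["subject_id"]],
        groups=[str(g) for g in df["group"]],
        paths=paths,
    )
    if check_files:
        missing = [
            sid
            for sid, _, p in manifest
            if not (p.exists() or p.with_suffix(".json").exists())
        ]
        if missing:
            raise ValidationError(f"missing recording files for subjects: {missing}")
    return manifest


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "subject_id": manifest.subject_ids,
            "group": manifest.groups,
            "path": [str(p) for p in manifest.paths],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# demographics


def summarize_demographics(table: pd.DataFrame | Sequence[tuple[str, float]]) -> dict:
    """Summarize a (sex, age) table: female count, mean age, sample SD.

    The SD uses the n-1 (sample) denominator.  Requires n >= 2.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table, columns=["sex", "age"])
    if len(table) < 2:
        raise ValidationError("need at least 2 rows for a sample SD")
    ages = table["age"].to_numpy(dtype=float)
    return {
        "n": int(len(table)),
        "n_female": int((table["sex"].astype(str).str.upper() == "F").sum()),
        "mean_age": float(np.mean(ages)),
        "sd_age": float(np.std(ages, ddof=1)),
    }


def load_patient_demographics() -> pd.DataFrame:
    """The packaged demographics of the 18-patient convalescent cohort."""
    with resources.files("rseeg.data").joinpath("patient_demographics.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
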