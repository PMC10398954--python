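"""Minimal EDF (European Data Format) support.

Reading goes through :mod:`mne` after a light structural validation of the
ASCII header (so malformed files fail with a message naming the offending
field rather than an opaque reader error).  Writing is a small 16-bit EDF
writer: no installed library writes EDF, and the pipeline only needs plain
continuous EEG records (1 s data records, one physical range per channel).

EDF stores samples as 16-bit integers scaled into a per-channel physical
range, so round trips are exact to quantization (range / 65534), not to the
bit.  The native array+json dialect in :mod:`rseeg.io` is the byte-exact one.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .io import ParseError, Recording, UnitError

_DIGITAL_MAX = 32767

_DIM_TO_UV = {"uV": 1.0, "mV": 1e3, "V": 1e6}


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} > {width}")
    return b.ljust(width)


def write_edf(rec: Recording, path: str | Path, physical_dim: str = "uV") -> Path:
    """Write ``rec`` as EDF with 1-second data records.

    ``physical_dim`` labels the stored values; data are converted from the
    recording's microvolts into that unit before scaling.
    """
    path = Path(path)
    if physical_dim not in _DIM_TO_UV:
        raise UnitError(f"cannot express microvolt data in unit {physical_dim!r}")
    spr = rec.fs
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate (1 s records)")
    spr = int(round(spr))
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one 1 s EDF record")
    if n_records * spr != rec.n_samples:
        warnings.warn(
            f"truncating {rec.n_samples - n_records * spr} trailing samples "
            "to whole EDF records",
            stacklevel=2,
        )
    data = rec.data[:, : n_records * spr] / _DIM_TO_UV[physical_dim]
    ns = rec.n_channels

    # physical max must survive the 8-char ASCII field, so format first and
    # rescale against the formatted value to keep digital samples in range
    pmax = np.empty(ns)
    pmax_str = []
    for i, need in enumerate(np.maximum(np.abs(data).max(axis=1), 1e-9)):
        v, s = need * 1.001, ""
        for _ in range(60):
            # leave room for the '-' sign in the pmin field (7 chars max)
            s = next(
                (
                    c
                    for p in (4, 3, 2, 1)
                    if len(c := f"{v:.{p}g}") <= 7 and float(c) >= need
                ),
                "",
            )
            if s:
                break
            v *= 1.05
        if not s:
            raise ValueError(f"cannot format physical range {need} into EDF header")
        pmax[i] = float(s)
        pmax_str.append(s)
    digital = np.round(data / pmax[:, None] * _DIGITAL_MAX).astype("<i2")

    head = b"".join(
        [
            _field("0", 8),
            _field(rec.subject_id[:80], 80),
            _field(f"rseeg group={rec.group}", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (ns + 1)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(ns), 4),
        ]
    )

    def sig(fmt: str, width: int, values) -> bytes:
        return b"".join(_field(fmt.format(v), width) for v in values)

    head += sig("{}", 16, rec.channel_labels)
    head += sig("{}", 80, [""] * ns)
    head += sig("{}", 8, [physical_dim] * ns)
    head += sig("-{}", 8, pmax_str)
    head += sig("{}", 8, pmax_str)
    head += sig("{}", 8, [-_DIGITAL_MAX] * ns)
    head += sig("{}", 8, [_DIGITAL_MAX] * ns)
    head += sig("{}", 80, [""] * ns)
    head += sig("{}", 8, [spr] * ns)
    head += sig("{}", 32, [""] * ns)
    assert len(head) == 256 * (ns + 1)

    # data records: per record, channel blocks of spr int16 samples
    records = digital.reshape(ns, n_records, spr).transpose(1, 0, 2)
    path.write_bytes(head + records.tobytes())
    return path


def validate_edf_header(path: str | Path) -> dict:
    """Structural sanity check of an EDF header; raises ParseError on defects."""
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 256:
        raise ParseError("file shorter than the 256-byte EDF header")
    head = blob[:256]
    try:
        ns = int(head[252:256].decode("ascii").strip())
        header_bytes = int(head[184:192].decode("ascii").strip())
        n_records = int(head[236:244].decode("ascii").strip())
    except ValueError as e:
        raise ParseError(f"EDF header: non-numeric field ({e})") from e
    if header_bytes != 256 * (ns + 1):
        raise ParseError(
            f"EDF header: 'number of bytes in header' is {header_bytes}, "
            f"expected {256 * (ns + 1)} for {ns} signals"
        )
    if len(blob) < header_bytes:
        raise ParseError(
            f"EDF header: 'number of signals' declares {ns} signals but the "
            "signal header block is truncated"
        )
    spr_block = blob[256 + ns * 216 : 256 + ns * 224]
    try:
        spr = [
            int(spr_block[i * 8 : (i + 1) * 8].decode("ascii").strip()) for i in range(ns)
        ]
    except ValueError as e:
        raise ParseError(f"EDF header: bad 'samples per record' field ({e})") from e
    expected = header_bytes + n_records * sum(spr) * 2
    if len(blob) != expected:
        raise ParseError(
            f"EDF header: declared {ns} signals x {n_records} records "
            f"({expected} bytes) but file holds {len(blob)} bytes"
        )
    dims = [
        blob[256 + ns * 96 + i * 8 : 256 + ns * 96 + (i + 1) * 8].decode("ascii").strip()
        for i in range(ns)
    ]
    return {"ns": ns, "n_records": n_records, "samples_per_record": spr, "dims": dims}


def read_edf(path: str | Path) -> Recording:
    """Read an EDF recording into microvolts via mne."""
    path = Path(path)
    info = validate_edf_header(path)
    bad_dims = sorted({d for d in info["dims"] if d not in _DIM_TO_UV and d != ""})
    if bad_dims:
        raise UnitError(f"physical dimension(s) {bad_dims} not convertible to uV")

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns volts for recognized EEG units

    blob = path.read_bytes()
    subject_id = blob[8:88].decode("ascii").strip() or "unknown"
    rec_field = blob[88:168].decode("ascii").strip()
    group = "unknown"
    if "group=" in rec_field:
        candidate = rec_field.split("group=")[1].split()[0]
        if candidate in ("patient", "control"):
            group = candidate
    return Recording(
        data=data_uv,
        channel_labels=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        subject_id=subject_id,
        group=group,
    )
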