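"""Re-referencing, band-pass filtering, segmentation and artifact rejection.

The canonical order is rereference -> bandpass -> segment -> reject:
a neutral (average or REST) reference, zero-phase 0.5-45 Hz band-pass,
non-overlapping 5 s epochs, and rejection of any epoch whose absolute
amplitude exceeds 90 uV on any channel.  Filtering is forward-backward
(zero phase) so downstream phase estimates carry no filter delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import EpochSet, Recording, ValidationError

__all__ = [
    "EmptyAfterRejectionError",
    "rereference",
    "bandpass",
    "segment",
    "reject",
    "preprocess_recording",
]


class EmptyAfterRejectionError(RuntimeError):
    """Every epoch of a subject exceeded the amplitude threshold."""

    def __init__(self, subject_id: str, threshold_uv: float):
        self.subject_id = subject_id
        super().__init__(
            f"subject {subject_id!r}: no epochs survive +/-{threshold_uv} uV rejection"
        )


def rereference(rec: Recording, method: str = "average") -> Recording:
    """Re-reference to the common average or to REST (infinity reference).

    REST uses the packaged generic spherical-head lead field
    (:mod:`rseeg.leadfield`); it requires channels with standard 10/20-family
    names so electrode positions can be looked up.
    """
    if rec.n_channels < 2:
        raise ValidationError("re-referencing requires at least 2 channels")
    if method == "average":
        data = rec.data - rec.data.mean(axis=0, keepdims=True)
    elif method == "rest":
        from . import leadfield

        t = leadfield.rest_transform(tuple(rec.channel_labels))
        data = t @ (rec.data - rec.data.mean(axis=0, keepdims=True))
    else:
        raise ValueError(f"unknown reference method {method!r}")
    return Recording(
        data=data,
        channel_labels=rec.channel_labels,
        fs=rec.fs,
        subject_id=rec.subject_id,
        group=rec.group,
        meta={**rec.meta, "reference": method},
    )


def design_bandpass(f1: float, f2: float, fs: float, order: int = 5) -> np.ndarray:
    """Elliptic band-pass SOS shared by preprocessing and PLV filtering.

    The elliptic design (0.05 dB passband ripple, 40 dB stopband) keeps the
    passband flat to ~1% right up to the band edges — a Butterworth of any
    practical order sags several percent near 40-45 Hz once the forward-
    backward pass squares its response — while the squared 40 dB stopband
    comfortably exceeds 20 dB one octave outside the band.
    """
    if not (0 < f1 < f2):
        raise ValidationError(f"need 0 < f1 < f2, got [{f1}, {f2}]")
    if f2 >= fs / 2:
        raise ValidationError(f"f2 = {f2} Hz is not below Nyquist ({fs / 2} Hz)")
    return signal.ellip(order, 0.05, 40.0, [f1, f2], btype="bandpass", fs=fs, output="sos")


def bandpass(rec: Recording, f1: float = 0.5, f2: float = 45.0, order: int = 5) -> Recording:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    sos = design_bandpass(f1, f2, rec.fs, order)
    data = signal.sosfiltfilt(sos, rec.data, axis=-1)
    if data.dtype != rec.data.dtype and rec.data.dtype == np.float32:
        data = data.astype(np.float32)  # keep single precision through the chain
    return Recording(
        data=data,
        channel_labels=rec.channel_labels,
        fs=rec.fs,
        subject_id=rec.subject_id,
        group=rec.group,
        meta={**rec.meta, "bandpass": (f1, f2)},
    )


def segment(rec: Recording, epoch_length_s: float = 5.0) -> EpochSet:
    """Cut into consecutive non-overlapping epochs; the remainder is dropped."""
    spe = round(epoch_length_s * rec.fs)
    n_epochs = rec.n_samples // spe
    if n_epochs < 1:
        raise ValidationError(
            f"recording of {rec.duration_s:.2f} s is shorter than one "
            f"{epoch_length_s} s epoch"
        )
    cut = rec.data[:, : n_epochs * spe]
    epochs = np.moveaxis(cut.reshape(rec.n_channels, n_epochs, spe), 1, 0)
    return EpochSet(
        epochs=epochs,
        fs=rec.fs,
        epoch_length_s=epoch_length_s,
        channel_labels=rec.channel_labels,
        source_subject=rec.subject_id,
        group=rec.group,
    )


def reject(epochs: EpochSet, threshold_uv: float = 90.0) -> EpochSet:
    """Drop every epoch with any sample strictly beyond +/-threshold on any channel.

    Samples at exactly the threshold are kept (strict inequality).
    """
    if threshold_uv <= 0:
        raise ValidationError("threshold must be positive")
    peak = np.abs(epochs.epochs).max(axis=(1, 2))
    kept = peak <= threshold_uv
    if not kept.any():
        raise EmptyAfterRejectionError(epochs.source_subject, threshold_uv)
    return EpochSet(
        epochs=epochs.epochs[kept],
        fs=epochs.fs,
        epoch_length_s=epochs.epoch_length_s,
        channel_labels=epochs.channel_labels,
        source_subject=epochs.source_subject,
        group=epochs.group,
        kept_mask=kept,
    )


@dataclass(frozen=True)
class PreprocessParams:
    reference: str = "average"
    f1: float = 0.5
    f2: float = 45.0
    epoch_length_s: float = 5.0
    reject_uv: float = 90.0


def preprocess_recording(rec: Recording, params: PreprocessParams = PreprocessParams()) -> EpochSet:
    """The full fixed-order chain: rereference -> bandpass -> segment -> reject."""
    rec = rereference(rec, params.reference)
    rec = bandpass(rec, params.f1, params.f2)
    epochs = segment(rec, params.epoch_length_s)
    return reject(epochs, params.reject_uv)
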