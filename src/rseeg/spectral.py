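"""Welch power spectra and band-integrated absolute power (aPSD).

For each subject the PSD is estimated per epoch with Welch's method (2 s Hann
windows, 50% overlap by default, giving 0.5 Hz resolution — matching the
lower delta edge) and averaged across epochs.  Averaging the raw resting
epochs in the time domain before the spectral estimate would cancel
non-phase-locked activity, so the average is taken over per-epoch spectra.

The absolute power of a band is the sum of PSD bins inside the band:

    aPSD(band) = sum_{f1 <= f < f2} PSD(f)

with half-open bins so the shared edges (4, 8, 13, 30 Hz) are counted once;
the top band (gamma) closes at 45 Hz.  Under this convention the five
canonical bands exactly partition the total 0.5-45 Hz power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import Band, CANONICAL_BANDS, EpochSet, ValidationError

__all__ = ["BandSpectrum", "welch_psd", "band_power", "apsd_table", "grand_average_apsd"]


@dataclass
class BandSpectrum:
    """Per-channel PSD on a common frequency grid, in uV^2/Hz."""

    freqs: np.ndarray
    psd: np.ndarray  # channels x freqs
    fs: float
    channel_labels: list[str]
    welch_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValidationError("frequency grid must be strictly increasing")
        if np.any(self.psd < 0):
            raise ValidationError("PSD must be non-negative")
        if self.psd.shape != (len(self.channel_labels), len(self.freqs)):
            raise ValidationError("psd shape inconsistent with labels/freqs")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def welch_psd(
    epochs: EpochSet,
    window_s: float = 2.0,
    overlap: float = 0.5,
    taper: str = "hann",
) -> BandSpectrum:
    """Welch PSD per epoch and channel, averaged across epochs."""
    if epochs.n_epochs < 1:
        raise ValidationError("need at least one epoch")
    nperseg = round(window_s * epochs.fs)
    if nperseg > epochs.epochs.shape[2]:
        raise ValidationError(
            f"Welch window of {window_s} s exceeds the {epochs.epoch_length_s} s epoch"
        )
    freqs, psd = signal.welch(
        epochs.epochs,
        fs=epochs.fs,
        window=taper,
        nperseg=nperseg,
        noverlap=round(nperseg * overlap),
        axis=-1,
    )
    return BandSpectrum(
        freqs=freqs,
        psd=np.asarray(psd.mean(axis=0), dtype=float),
        fs=epochs.fs,
        channel_labels=epochs.channel_labels,
        welch_params={"window_s": window_s, "overlap": overlap, "taper": taper},
    )


def _band_bins(spec: BandSpectrum, band: Band) -> np.ndarray:
    if band.f1 < spec.freqs[0] - 1e-9 or band.f2 > spec.freqs[-1] + 1e-9:
        raise ValidationError(
            f"band {band.name} [{band.f1}, {band.f2}] outside spectral range "
            f"[{spec.freqs[0]}, {spec.freqs[-1]}]"
        )
    top = max(b.f2 for b in CANONICAL_BANDS)
    if band.f2 >= top:  # close the right edge of the top band
        return (spec.freqs >= band.f1 - 1e-9) & (spec.freqs <= band.f2 + 1e-9)
    return (spec.freqs >= band.f1 - 1e-9) & (spec.freqs < band.f2 - 1e-9)


def band_power(spec: BandSpectrum, band: Band) -> np.ndarray:
    """Absolute band power: sum of PSD bins in the band, one value per channel."""
    return spec.psd[:, _band_bins(spec, band)].sum(axis=1)


def apsd_table(spec: BandSpectrum, bands: tuple[Band, ...] = CANONICAL_BANDS) -> np.ndarray:
    """Channels x bands matrix of absolute band power."""
    return np.column_stack([band_power(spec, b) for b in bands])


def grand_average_apsd(apsd_per_channel: np.ndarray) -> float:
    """Mean absolute band power across all electrodes (one scalar per subject)."""
    return float(np.mean(apsd_per_channel))
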