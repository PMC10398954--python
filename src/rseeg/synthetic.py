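"""Synthetic two-group resting-state EEG cohorts with known ground truth.

Each subject is synthesized in the frequency domain as

* a 1/f^beta Gaussian background (beta = 1 by default, the standard
  resting-EEG surrogate), plus
* one narrowband Gaussian oscillator per canonical band and channel, with a
  Gaussian spectral envelope centered in the band.

Two group effects, mirroring the structure reported for convalescent
anti-NMDA-receptor-encephalitis patients versus healthy controls, are
injected:

* power enhancement — patients' delta and theta oscillator amplitudes on a
  designated middle/posterior channel set are scaled by ``delta_theta_gain``
  (band power scales with the square of the gain);
* coupling attenuation — channels of a designated fronto-temporo-parietal
  set share a common band oscillator mixed into each channel with weight
  ``coupling`` (kappa), normalized to preserve variance; for patients the
  effective weight is ``kappa * (1 - patient_coupling_drop)``.  At kappa = 1
  coupled channels carry identical band components, so their PLV is 1.

Subject-to-subject variability enters through independent spectral draws,
per-channel log-normal amplitude jitter and a small uniform jitter on kappa.
Per-subject seeds derive deterministically from the cohort seed as
``seed + subject_index`` (patients first, then controls); the full cohort is
byte-exact for a fixed configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import fft as sfft

from . import io as rio
from .io import Band, CANONICAL_BANDS, CohortManifest, Recording, ValidationError

__all__ = ["SimConfig", "generate_subject", "iter_cohort", "generate_cohort", "inject_artifacts"]

#: middle/posterior channels whose delta/theta power is enhanced in patients
POSTERIOR_CHANNELS: tuple[str, ...] = (
    "Cz", "CP1", "CP2", "Pz", "P3", "P4", "PO3", "POz", "PO4", "O1", "Oz", "O2",
)

#: fronto-temporo-parietal set sharing the coupled band oscillator
COUPLED_CHANNELS: tuple[str, ...] = (
    "F7", "F3", "Fz", "F4", "F8", "T7", "T8", "P3", "Pz", "P4",
)

#: occipital set whose coupling is preserved in patients (the attenuation is
#: spatially specific; preserved posterior synchrony anchors the weight scale)
ANCHOR_CHANNELS: tuple[str, ...] = ("O1", "Oz", "O2")

_DEFAULT_BAND_AMP = {"delta": 6.0, "theta": 4.0, "alpha": 3.5, "beta": 1.5, "gamma": 0.8}


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters (defaults are the study conditions)."""

    n_per_group: int = 18
    channel_labels: tuple[str, ...] = rio.TEN_TWENTY_32
    fs: float = 500.0
    duration_s: float = 300.0
    background_exponent: float = 1.0
    background_rms_uv: float = 2.0
    band_amp_uv: dict = field(default_factory=lambda: dict(_DEFAULT_BAND_AMP))
    amp_jitter_log_sd: float = 0.2
    delta_theta_gain: float = 1.5
    gain_channels: tuple[str, ...] = POSTERIOR_CHANNELS
    gain_bands: tuple[str, ...] = ("delta", "theta")
    coupling: float = 0.7
    coupling_jitter: float = 0.05
    patient_coupling_drop: float = 0.5
    coupled_channels: tuple[str, ...] = COUPLED_CHANNELS
    coupled_bands: tuple[str, ...] = ("delta", "theta")
    anchor_channels: tuple[str, ...] = ANCHOR_CHANNELS
    anchor_coupling: float = 0.8
    artifact_rate_per_min: float = 2.0
    artifact_amplitude_uv: float = 150.0
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be >= 1")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValidationError("fs and duration_s must be positive")
        if self.delta_theta_gain < 0 or self.background_rms_uv < 0:
            raise ValidationError("gains and amplitudes must be >= 0")
        if any(a < 0 for a in self.band_amp_uv.values()):
            raise ValidationError("band amplitudes must be >= 0")
        if not (0 <= self.coupling <= 1 and 0 <= self.patient_coupling_drop <= 1):
            raise ValidationError("coupling and patient_coupling_drop must lie in [0, 1]")
        if not (0 <= self.anchor_coupling <= 1):
            raise ValidationError("anchor_coupling must lie in [0, 1]")
        unknown = set(self.gain_channels) | set(self.coupled_channels)
        unknown |= set(self.anchor_channels)
        unknown -= set(self.channel_labels)
        if unknown:
            raise ValidationError(f"designated channels not in montage: {sorted(unknown)}")

    def subject_seed(self, index: int) -> int:
        """Per-subject seed rule (public contract): cohort seed + subject index."""
        return int(self.seed) + int(index)


def _band_envelope(freqs: np.ndarray, band: Band) -> np.ndarray:
    """Gaussian spectral amplitude envelope centered in the band."""
    center = (band.f1 + band.f2) / 2
    sigma_power = (band.f2 - band.f1) / 6  # +/-3 sigma of power at band edges
    power = np.exp(-((freqs - center) ** 2) / (2 * sigma_power**2))
    return np.sqrt(power)


def _unit_rms_scale(profile: np.ndarray, n: int) -> float:
    """Scale making irfft of CN(0,1)-weighted ``profile`` unit RMS in time."""
    var = 2.0 * np.sum(profile**2) / n**2
    return 1.0 / np.sqrt(var) if var > 0 else 0.0


def generate_subject(cfg: SimConfig, group: str, subject_seed: int) -> Recording:
    """Synthesize one subject. The draw sequence is independent of ``group``,
    so with neutral effect parameters (gain 1, drop 0) a patient and a control
    generated from the same seed are sample-identical."""
    cfg.validate()
    if group not in ("patient", "control"):
        raise ValidationError(f"group must be 'patient' or 'control', got {group!r}")
    rng = np.random.default_rng(subject_seed)
    n = round(cfg.duration_s * cfg.fs)
    nch = cfg.n_channels
    freqs = np.fft.rfftfreq(n, 1 / cfg.fs)
    nf = freqs.size
    is_patient = group == "patient"

    # 1/f^beta background, flattened below the 0.5 Hz high-pass corner
    bg_profile = np.zeros(nf)
    with np.errstate(divide="ignore"):
        bg_profile[1:] = np.maximum(freqs[1:], 0.5) ** (-cfg.background_exponent / 2)
    bg_profile *= _unit_rms_scale(bg_profile, n) * cfg.background_rms_uv
    spec = np.empty((nch, nf), dtype=np.complex64)
    spec.real = rng.standard_normal((nch, nf), dtype=np.float32)
    spec.imag = rng.standard_normal((nch, nf), dtype=np.float32)
    spec *= (bg_profile / np.sqrt(2)).astype(np.float32)

    coupled_idx = np.array([cfg.channel_labels.index(c) for c in cfg.coupled_channels])
    anchor_idx = np.array([cfg.channel_labels.index(c) for c in cfg.anchor_channels])
    gain_idx = np.array([cfg.channel_labels.index(c) for c in cfg.gain_channels])

    def _mix(dest: np.ndarray, idx: np.ndarray, shared: np.ndarray, kappa: float) -> None:
        kappa = float(np.clip(kappa, 0.0, 1.0))
        norm = np.sqrt(kappa**2 + (1 - kappa) ** 2)
        dest[idx] = (kappa * shared + (1 - kappa) * dest[idx]) / norm

    for band in CANONICAL_BANDS:
        amp = cfg.band_amp_uv.get(band.name, 0.0)
        envelope = _band_envelope(freqs, band)
        mask = envelope > 1e-3
        env = envelope[mask] * _unit_rms_scale(envelope, n) / np.sqrt(2)
        nm = int(mask.sum())
        z_own = rng.standard_normal((nch, nm)) + 1j * rng.standard_normal((nch, nm))
        z_shared = rng.standard_normal(nm) + 1j * rng.standard_normal(nm)
        z_anchor = rng.standard_normal(nm) + 1j * rng.standard_normal(nm)
        z_own = z_own.astype(np.complex64)
        z_shared = z_shared.astype(np.complex64)
        z_anchor = z_anchor.astype(np.complex64)
        jitter = np.exp(rng.normal(0.0, cfg.amp_jitter_log_sd, size=nch))
        kappa_jit = rng.uniform(-cfg.coupling_jitter, cfg.coupling_jitter)
        if amp == 0:
            continue
        amp_ch = np.full(nch, amp) * jitter
        if is_patient and band.name in cfg.gain_bands:
            amp_ch[gain_idx] *= cfg.delta_theta_gain
        z_band = z_own
        if band.name in cfg.coupled_bands:
            z_band = z_own.copy()
            if len(coupled_idx) >= 2:
                kappa = cfg.coupling
                if is_patient:
                    kappa *= 1.0 - cfg.patient_coupling_drop
                _mix(z_band, coupled_idx, z_shared, kappa + kappa_jit)
            if len(anchor_idx) >= 2:
                _mix(z_band, anchor_idx, z_anchor, cfg.anchor_coupling + kappa_jit)
        spec[:, mask] += (amp_ch[:, None] * env).astype(np.float32) * z_band

    data = sfft.irfft(spec, n=n, axis=-1)
    rec = Recording(
        data=data,
        channel_labels=list(cfg.channel_labels),
        fs=cfg.fs,
        subject_id=f"sim-{subject_seed}",
        group=group,
        meta={"seed": int(subject_seed)},
    )
    if cfg.artifact_rate_per_min > 0:
        rec = inject_artifacts(
            rec, cfg.artifact_rate_per_min, cfg.artifact_amplitude_uv, rng=rng
        )
    return rec


def iter_cohort(cfg: SimConfig):
    """Yield (subject_id, group, Recording): patients first, then controls."""
    cfg.validate()
    for i in range(cfg.n_per_group):
        rec = generate_subject(cfg, "patient", cfg.subject_seed(i))
        yield f"P{i + 1:02d}", "patient", replace_id(rec, f"P{i + 1:02d}")
    for i in range(cfg.n_per_group):
        rec = generate_subject(cfg, "control", cfg.subject_seed(cfg.n_per_group + i))
        yield f"C{i + 1:02d}", "control", replace_id(rec, f"C{i + 1:02d}")


def replace_id(rec: Recording, subject_id: str) -> Recording:
    rec.subject_id = subject_id
    return rec


def generate_cohort(cfg: SimConfig, out_dir: str | Path) -> CohortManifest:
    """Write the cohort via the array+json dialect and return its manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids, groups, paths = [], [], []
    for sid, group, rec in iter_cohort(cfg):
        path = rio.write_recording(rec, out_dir / f"{sid}.json")
        ids.append(sid)
        groups.append(group)
        paths.append(path)
    manifest = CohortManifest(subject_ids=ids, groups=groups, paths=paths)
    rio.write_manifest(manifest, out_dir / "manifest.tsv")
    return manifest


def inject_artifacts(
    rec: Recording,
    rate_per_min: float,
    amplitude_uv: float = 150.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    duration_s: float = 0.2,
) -> Recording:
    """Add Poisson-count high-amplitude half-sine transients.

    Each event hits one random channel at a random onset with a half-sine
    burst of the stated amplitude; counts and positions are recorded in the
    recording's provenance metadata.  Amplitudes at or below 90 uV would
    survive the standard rejection threshold, which triggers a warning.
    """
    if rate_per_min < 0:
        raise ValidationError("artifact rate must be >= 0")
    if rate_per_min == 0:
        return rec
    if amplitude_uv <= 90:
        warnings.warn(
            f"artifact amplitude {amplitude_uv} uV <= 90 uV rejection threshold; "
            "injected events will not be rejectable",
            stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    n_events = int(rng.poisson(rate_per_min * rec.duration_s / 60.0))
    burst_len = round(duration_s * rec.fs)
    burst = amplitude_uv * np.sin(np.pi * np.arange(burst_len) / max(burst_len - 1, 1))
    data = rec.data.copy()
    events = []
    for _ in range(n_events):
        ch = int(rng.integers(0, rec.n_channels))
        onset = int(rng.integers(0, max(rec.n_samples - burst_len, 1)))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        data[ch, onset : onset + burst_len] += sign * burst
        events.append({"channel": rec.channel_labels[ch], "onset_sample": onset})
    return Recording(
        data=data,
        channel_labels=rec.channel_labels,
        fs=rec.fs,
        subject_id=rec.subject_id,
        group=rec.group,
        meta={**rec.meta, "artifacts": {"n_events": n_events, "events": events}},
    )
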