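"""End-to-end orchestration: simulate -> preprocess -> spectra -> networks ->
group statistics -> classification.

The heavy lifting lives in the stage modules; this module streams subjects
through the chain, accumulates per-subject features into a
:class:`CohortData`, runs the group comparisons and the LOOCV classifier,
and (for :func:`run_pipeline`) writes every intermediate artifact plus a
provenance record so a run is reproducible from its config alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassificationReport, CohortFeatures, loocv_svm
from .io import BAND_BY_NAME, Band, CohortManifest, Recording, ValidationError, read_recording
from .network import build_network, network_metrics
from .preprocess import PreprocessParams, preprocess_recording
from .spectral import band_power, grand_average_apsd, welch_psd
from .stats import StatMap, compare_cohort, upper_triangle
from .synthetic import SimConfig, iter_cohort

__all__ = [
    "ConfigError",
    "CohortData",
    "subject_features",
    "collect_cohort",
    "group_statistics",
    "default_config",
    "validate_config",
    "run_pipeline",
]


class ConfigError(ValueError):
    """The run configuration violates the documented schema."""


@dataclass
class CohortData:
    """Per-subject feature arrays for a whole cohort, keyed by band name."""

    subject_ids: list[str]
    labels: np.ndarray  # 1 = patient, 0 = control
    channel_labels: list[str]
    bands: list[Band]
    apsd_channels: dict[str, np.ndarray]  # band -> subjects x channels
    adjacency: dict[str, np.ndarray]  # band -> subjects x ch x ch
    c: dict[str, np.ndarray]
    l: dict[str, np.ndarray]
    epochs_kept: list[int] = field(default_factory=list)

    @property
    def grand_apsd(self) -> dict[str, np.ndarray]:
        return {b: a.mean(axis=1) for b, a in self.apsd_channels.items()}

    def edge_values(self, band: str) -> tuple[np.ndarray, list[str]]:
        ids, iu, ju = upper_triangle(self.channel_labels)
        return self.adjacency[band][:, iu, ju], ids

    def to_features(self) -> CohortFeatures:
        return CohortFeatures(
            subject_ids=self.subject_ids,
            labels=self.labels,
            bands=self.bands,
            adjacency=self.adjacency,
            apsd=self.grand_apsd,
            c=self.c,
            l=self.l,
            channel_labels=self.channel_labels,
        )


def subject_features(
    rec: Recording,
    bands: list[Band],
    pre: PreprocessParams = PreprocessParams(),
    window_s: float = 2.0,
    overlap: float = 0.5,
    trim_s: float = 0.25,
    formula: str = "bct",
) -> dict:
    """Preprocess one recording and compute its spectra, networks and metrics."""
    epochs = preprocess_recording(rec, pre)
    spec = welch_psd(epochs, window_s=window_s, overlap=overlap)
    out = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "n_epochs_kept": epochs.n_epochs,
        "n_epochs_total": epochs.kept_mask.size,
        "apsd": {},
        "W": {},
        "C": {},
        "L": {},
    }
    for band in bands:
        out["apsd"][band.name] = band_power(spec, band)
        net = build_network(epochs, band, trim_s=trim_s)
        out["W"][band.name] = net.W
        c, l = network_metrics(net.W, formula=formula)
        out["C"][band.name] = c
        out["L"][band.name] = l
    return out


def collect_cohort(
    subjects,
    bands: list[Band],
    pre: PreprocessParams = PreprocessParams(),
    **feature_kw,
) -> CohortData:
    """Accumulate :func:`subject_features` over (sid, group, Recording) triples."""
    ids: list[str] = []
    labels: list[int] = []
    kept: list[int] = []
    per_band: dict[str, dict[str, list]] = {
        b.name: {"apsd": [], "W": [], "C": [], "L": []} for b in bands
    }
    channel_labels: list[str] | None = None
    for sid, group, rec in subjects:
        feats = subject_features(rec, bands, pre=pre, **feature_kw)
        if channel_labels is None:
            channel_labels = rec.channel_labels
        elif channel_labels != rec.channel_labels:
            raise ValidationError(f"subject {sid}: montage mismatch")
        ids.append(sid)
        labels.append(1 if group == "patient" else 0)
        kept.append(feats["n_epochs_kept"])
        for b in bands:
            per_band[b.name]["apsd"].append(feats["apsd"][b.name])
            per_band[b.name]["W"].append(feats["W"][b.name])
            per_band[b.name]["C"].append(feats["C"][b.name])
            per_band[b.name]["L"].append(feats["L"][b.name])
    if not ids:
        raise ValidationError("empty cohort")
    return CohortData(
        subject_ids=ids,
        labels=np.array(labels),
        channel_labels=list(channel_labels),
        bands=list(bands),
        apsd_channels={b: np.array(v["apsd"]) for b, v in per_band.items()},
        adjacency={b: np.array(v["W"]) for b, v in per_band.items()},
        c={b: np.array(v["C"]) for b, v in per_band.items()},
        l={b: np.array(v["L"]) for b, v in per_band.items()},
        epochs_kept=kept,
    )


def simulated_cohort(cfg: SimConfig):
    """Adapter: stream a synthetic cohort into :func:`collect_cohort`."""
    return iter_cohort(cfg)


def manifest_cohort(manifest: CohortManifest):
    for sid, group, path in manifest:
        rec = read_recording(path)
        rec.group = group
        rec.subject_id = sid
        yield sid, group, rec


def group_statistics(
    data: CohortData, alpha: float = 0.01, equal_var: bool = True
) -> dict[str, dict[str, StatMap]]:
    """Patient-vs-control maps per band: channels (aPSD), edges (PLV), metrics.

    Each (band x feature-kind) family is FDR-corrected jointly.
    """
    pat = data.labels == 1
    ctl = data.labels == 0
    out: dict[str, dict[str, StatMap]] = {}
    for band in data.bands:
        b = band.name
        apsd = data.apsd_channels[b]
        edges, edge_ids = data.edge_values(b)
        metrics = np.column_stack([data.c[b], data.l[b]])
        out[b] = {
            "channels": compare_cohort(
                apsd[pat], apsd[ctl], data.channel_labels, alpha=alpha, equal_var=equal_var
            ),
            "edges": compare_cohort(
                edges[pat], edges[ctl], edge_ids, alpha=alpha, equal_var=equal_var
            ),
            "metrics": compare_cohort(
                metrics[pat], metrics[ctl], ["C", "L"], alpha=alpha, equal_var=equal_var
            ),
        }
    return out


# ---------------------------------------------------------------------------
# declarative configuration


def default_config() -> dict:
    return {
        "seed": 0,
        "bands": ["delta", "theta"],
        "simulate": {"n_per_group": 18, "duration_s": 300.0},
        "preprocess": {
            "reference": "average",
            "f1": 0.5,
            "f2": 45.0,
            "epoch_length_s": 5.0,
            "reject_uv": 90.0,
        },
        "spectral": {"window_s": 2.0, "overlap": 0.5},
        "network": {"trim_s": 0.25, "formula": "bct"},
        "stats": {"alpha": 0.01, "welch": False},
        "classify": {"k": 1, "kernel": "linear", "svm_c": 1.0, "refit_per_fold": True},
    }


_SIM_FIELDS = {f.name for f in dc_fields(SimConfig)}


def load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        if str(config).endswith((".yaml", ".yml")):
            import yaml

            config = yaml.safe_load(text)
        else:
            config = json.loads(text)
    merged = default_config()
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key] = {**merged[key], **val}
        else:
            merged[key] = val
    return merged


def validate_config(config: dict | str | Path) -> dict:
    """Validate against the schema; raises ConfigError listing every violation."""
    cfg = load_config(config)
    errors: list[str] = []
    sim = cfg["simulate"]
    unknown = set(sim) - _SIM_FIELDS - {"seed"}
    if unknown:
        errors.append(f"simulate: unknown parameters {sorted(unknown)}")
    if sim.get("n_per_group", 18) < 2:
        errors.append("simulate.n_per_group: must be >= 2 for group statistics")
    if sim.get("duration_s", 300.0) <= 0:
        errors.append("simulate.duration_s: must be positive")
    fs = sim.get("fs", 500.0)
    pre = cfg["preprocess"]
    if not (0 < pre["f1"] < pre["f2"]):
        errors.append("preprocess: need 0 < f1 < f2")
    if pre["f2"] >= fs / 2:
        errors.append(f"preprocess.f2: {pre['f2']} Hz violates Nyquist ({fs / 2} Hz)")
    if pre["epoch_length_s"] <= 0:
        errors.append("preprocess.epoch_length_s: must be positive")
    if pre["reject_uv"] <= 0:
        errors.append("preprocess.reject_uv: must be positive")
    if pre["reference"] not in ("average", "rest"):
        errors.append(f"preprocess.reference: unknown method {pre['reference']!r}")
    for b in cfg["bands"]:
        if b not in BAND_BY_NAME:
            errors.append(f"bands: unknown band {b!r}")
    spect = cfg["spectral"]
    if spect["window_s"] > pre["epoch_length_s"]:
        errors.append("spectral.window_s: exceeds the epoch length")
    if not (0 < cfg["stats"]["alpha"] < 1):
        errors.append("stats.alpha: must lie in (0, 1)")
    if cfg["classify"]["k"] < 1:
        errors.append("classify.k: must be >= 1")
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def _sim_config(cfg: dict) -> SimConfig:
    sim = dict(cfg["simulate"])
    sim.setdefault("seed", cfg.get("seed", 0))
    return SimConfig(**{k: v for k, v in sim.items() if k in _SIM_FIELDS})


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute the full chain on a synthetic cohort and write all artifacts.

    Outputs under ``out_dir``: per-band adjacency CSVs and aPSD TSVs,
    statistic maps, the classification report, and ``provenance.json``.
    Identical config (including seed) produces identical numeric outputs.
    """
    t_start = time.time()
    cfg = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bands = [BAND_BY_NAME[b] for b in cfg["bands"]]
    pre = PreprocessParams(
        reference=cfg["preprocess"]["reference"],
        f1=cfg["preprocess"]["f1"],
        f2=cfg["preprocess"]["f2"],
        epoch_length_s=cfg["preprocess"]["epoch_length_s"],
        reject_uv=cfg["preprocess"]["reject_uv"],
    )
    sim = _sim_config(cfg)
    data = collect_cohort(
        simulated_cohort(sim),
        bands,
        pre=pre,
        window_s=cfg["spectral"]["window_s"],
        overlap=cfg["spectral"]["overlap"],
        trim_s=cfg["network"]["trim_s"],
        formula=cfg["network"]["formula"],
    )

    # per-subject artifacts
    for b in cfg["bands"]:
        band_dir = out_dir / "adjacency" / b
        band_dir.mkdir(parents=True, exist_ok=True)
        for i, sid in enumerate(data.subject_ids):
            pd.DataFrame(
                data.adjacency[b][i], index=data.channel_labels, columns=data.channel_labels
            ).to_csv(band_dir / f"{sid}.csv")
        pd.DataFrame(
            data.apsd_channels[b], index=data.subject_ids, columns=data.channel_labels
        ).to_csv(out_dir / f"apsd_{b}.tsv", sep="\t")
    pd.DataFrame(
        {
            "subject_id": data.subject_ids,
            "group": np.where(data.labels == 1, "patient", "control"),
            "epochs_kept": data.epochs_kept,
            **{f"C_{b}": data.c[b] for b in cfg["bands"]},
            **{f"L_{b}": data.l[b] for b in cfg["bands"]},
        }
    ).to_csv(out_dir / "graph_metrics.tsv", sep="\t", index=False)

    stat_maps = group_statistics(
        data, alpha=cfg["stats"]["alpha"], equal_var=not cfg["stats"]["welch"]
    )
    sig_counts: dict[str, dict[str, int]] = {}
    for b, kinds in stat_maps.items():
        sig_counts[b] = {}
        for kind, sm in kinds.items():
            sm.to_frame().to_csv(out_dir / f"stats_{b}_{kind}.tsv", sep="\t", index=False)
            sig_counts[b][kind] = sm.n_significant

    report: ClassificationReport = loocv_svm(
        data.to_features(),
        k=cfg["classify"]["k"],
        kernel=cfg["classify"]["kernel"],
        svm_c=cfg["classify"]["svm_c"],
        refit_per_fold=cfg["classify"]["refit_per_fold"],
    )
    (out_dir / "classification.json").write_text(json.dumps(report.to_dict(), indent=1))

    provenance = {
        "package_version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "subject_seeds": {
            sid: sim.subject_seed(i) for i, sid in enumerate(data.subject_ids)
        },
        "epochs_kept": dict(zip(data.subject_ids, data.epochs_kept)),
        "significant_features": sig_counts,
        "elapsed_s": round(time.time() - t_start, 2),
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return out_dir
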