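"""Synthetic cohort generator: determinism, effect injection, artifacts."""

import numpy as np
import pytest

from rseeg import io
from rseeg.io import BAND_BY_NAME
from rseeg.network import build_network
from rseeg.preprocess import preprocess_recording, reject, segment
from rseeg.spectral import band_power, welch_psd
from rseeg.synthetic import (
    COUPLED_CHANNELS,
    POSTERIOR_CHANNELS,
    SimConfig,
    generate_cohort,
    generate_subject,
    inject_artifacts,
    iter_cohort,
)

DELTA = BAND_BY_NAME["delta"]

FAST = dict(duration_s=30.0, artifact_rate_per_min=0.0)


class TestDeterminism:
    def test_same_seed_same_subject(self):
        cfg = SimConfig(**FAST)
        a = generate_subject(cfg, "patient", 17)
        b = generate_subject(cfg, "patient", 17)
        assert np.array_equal(a.data, b.data)

    def test_neutral_parameters_make_groups_identical(self):
        cfg = SimConfig(delta_theta_gain=1.0, patient_coupling_drop=0.0, **FAST)
        pat = generate_subject(cfg, "patient", 5)
        ctl = generate_subject(cfg, "control", 5)
        assert np.array_equal(pat.data, ctl.data)

    def test_effect_parameters_separate_groups(self):
        cfg = SimConfig(**FAST)
        pat = generate_subject(cfg, "patient", 5)
        ctl = generate_subject(cfg, "control", 5)
        assert not np.array_equal(pat.data, ctl.data)

    def test_invalid_group_rejected(self):
        with pytest.raises(io.ValidationError):
            generate_subject(SimConfig(**FAST), "sick", 0)


class TestEffectStructure:
    def test_full_coupling_locks_the_designated_pairs(self):
        cfg = SimConfig(
            background_rms_uv=0.0,
            band_amp_uv={"delta": 6.0},
            coupling=1.0,
            coupling_jitter=0.0,
            patient_coupling_drop=0.0,
            amp_jitter_log_sd=0.0,
            **FAST,
        )
        rec = generate_subject(cfg, "control", 3)
        net = build_network(segment(rec), DELTA)
        idx = [rec.channel_labels.index(c) for c in COUPLED_CHANNELS]
        pair_w = net.W[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)]
        assert pair_w.min() > 0.98

    def test_power_gain_squares_into_band_power(self):
        # patient/control mean delta aPSD ratio on designated channels ~ g^2
        cfg = SimConfig(duration_s=120.0, delta_theta_gain=2.0, artifact_rate_per_min=0.0)
        gi = [cfg.channel_labels.index(c) for c in POSTERIOR_CHANNELS]

        def group_mean(group):
            vals = []
            for s in range(20):
                ep = preprocess_recording(generate_subject(cfg, group, 9000 + s))
                vals.append(band_power(welch_psd(ep), DELTA)[gi].mean())
            return np.mean(vals)

        ratio = group_mean("patient") / group_mean("control")
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_group_plv_deficit_grows_with_coupling_drop(self):
        deficits = []
        for drop in (0.0, 0.4, 0.8):
            cfg = SimConfig(patient_coupling_drop=drop, coupling_jitter=0.0, **FAST)
            idx = [cfg.channel_labels.index(c) for c in COUPLED_CHANNELS]
            iu = np.triu_indices(len(idx), 1)

            def coupled_mean(group, cfg=cfg, idx=idx, iu=iu):
                w = 0.0
                for seed in (11, 12):
                    net = build_network(segment(generate_subject(cfg, group, seed)), DELTA)
                    w += net.W[np.ix_(idx, idx)][iu].mean() / 2
                return w

            deficits.append(coupled_mean("control") - coupled_mean("patient"))
        assert deficits[0] == pytest.approx(0.0, abs=0.02)
        assert deficits[0] < deficits[1] < deficits[2]


class TestCohort:
    def test_cohort_files_and_counts(self, tmp_path):
        cfg = SimConfig(n_per_group=2, **FAST)
        manifest = generate_cohort(cfg, tmp_path)
        assert manifest.n_patients == 2
        assert manifest.n_controls == 2
        assert len(list(tmp_path.glob("*.f32"))) == 4
        reloaded = io.load_cohort(tmp_path / "manifest.tsv")
        assert reloaded.subject_ids == manifest.subject_ids

    def test_cohort_generation_is_reproducible(self, tmp_path):
        cfg = SimConfig(n_per_group=2, **FAST)
        generate_cohort(cfg, tmp_path / "a")
        generate_cohort(cfg, tmp_path / "b")
        for f in sorted((tmp_path / "a").glob("*.f32")):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_subject_seed_rule_is_seed_plus_index(self):
        cfg = SimConfig(n_per_group=2, seed=40, **FAST)
        recs = {sid: rec for sid, _, rec in iter_cohort(cfg)}
        direct = generate_subject(cfg, "patient", 41)
        assert np.array_equal(recs["P02"].data, direct.data)

    def test_empty_cohort_rejected(self):
        with pytest.raises(io.ValidationError):
            list(iter_cohort(SimConfig(n_per_group=0, **FAST)))


class TestArtifacts:
    def test_zero_rate_is_identity(self, rng):
        rec = generate_subject(SimConfig(**FAST), "control", 1)
        out = inject_artifacts(rec, rate_per_min=0.0, seed=0)
        assert out is rec

    def test_counts_are_poisson_and_reproducible(self):
        rec = generate_subject(SimConfig(duration_s=60.0, artifact_rate_per_min=0.0), "control", 1)
        a = inject_artifacts(rec, rate_per_min=12.0, seed=7)
        b = inject_artifacts(rec, rate_per_min=12.0, seed=7)
        n = a.meta["artifacts"]["n_events"]
        assert n == np.random.default_rng(7).poisson(12.0)
        assert b.meta["artifacts"]["n_events"] == n
        assert np.array_equal(a.data, b.data)

    def test_injected_burst_is_rejected_downstream(self):
        cfg = SimConfig(duration_s=60.0, artifact_rate_per_min=0.0)
        rec = generate_subject(cfg, "control", 2)
        spiked = inject_artifacts(rec, rate_per_min=2.0, amplitude_uv=150.0, seed=4)
        n_events = spiked.meta["artifacts"]["n_events"]
        assert n_events >= 1
        epochs = preprocess_recording(spiked)
        hit = {e["onset_sample"] // 2500 for e in spiked.meta["artifacts"]["events"]}
        dropped = set(np.flatnonzero(~epochs.kept_mask))
        assert hit & dropped == {h for h in hit if h < epochs.kept_mask.size}

    def test_sub_threshold_amplitude_warns(self):
        rec = generate_subject(SimConfig(**FAST), "control", 1)
        with pytest.warns(UserWarning, match="90"):
            inject_artifacts(rec, rate_per_min=10.0, amplitude_uv=80.0, seed=0)
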