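"""SPN filters, feature fusion and LOOCV SVM classification."""

import numpy as np
import pytest

from rseeg.io import Band, ValidationError
from rseeg import classify

DELTA = Band("delta", 0.5, 4.0)
THETA = Band("theta", 4.0, 8.0)


def _random_adjacency(rng, n_subj, n_ch=6, boost=None, scale=0.05):
    ws = []
    for _ in range(n_subj):
        w = np.triu(0.2 + scale * rng.standard_normal((n_ch, n_ch)), 1)
        w = np.clip(w + w.T, 0.01, 1.0)
        np.fill_diagonal(w, 0.0)
        if boost is not None:
            i, j, amount = boost
            w[i, j] = w[j, i] = np.clip(w[i, j] + amount, 0.0, 1.0)
        ws.append(w)
    return np.array(ws)


class TestSpn:
    def test_equal_classes_have_no_discriminative_direction(self, rng):
        ws = _random_adjacency(rng, 4)
        model = classify.spn_fit(ws, ws.copy(), DELTA, k=2)
        assert np.allclose(model.eigenvalues, 0.5, atol=1e-9)

    def test_eigenvalues_pair_across_class_orderings(self, rng):
        pat = _random_adjacency(rng, 5, boost=(0, 1, 0.4))
        ctl = _random_adjacency(rng, 5)
        a = classify.spn_fit(pat, ctl, DELTA, k=3)
        b = classify.spn_fit(ctl, pat, DELTA, k=3)
        assert np.allclose(np.sort(a.eigenvalues), np.sort(1.0 - b.eigenvalues), atol=1e-8)

    def test_leading_filter_localizes_the_differing_node(self, rng):
        # classes differ only through node 2's couplings
        pat = _random_adjacency(rng, 8, scale=0.01)
        ctl = _random_adjacency(rng, 8, scale=0.01)
        pat[:, 2, :] += 0.35
        pat[:, :, 2] += 0.35
        pat[:, 2, 2] = 0.0
        pat = np.clip((pat + pat.transpose(0, 2, 1)) / 2, 0, 1)
        model = classify.spn_fit(pat, ctl, DELTA, k=1)
        assert int(np.argmax(np.abs(model.filters[0]))) == 2

    def test_filters_are_unit_norm(self, rng):
        model = classify.spn_fit(
            _random_adjacency(rng, 4, boost=(1, 3, 0.3)), _random_adjacency(rng, 4), DELTA
        )
        assert np.allclose(np.linalg.norm(model.filters, axis=1), 1.0)
        assert model.eigenvalues.min() >= 0.0 and model.eigenvalues.max() <= 1.0

    def test_montage_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            classify.spn_fit(
                _random_adjacency(rng, 3, n_ch=6), _random_adjacency(rng, 3, n_ch=5), DELTA
            )


def _toy_cohort(rng, n_per_group=6, separation=3.0):
    n = 2 * n_per_group
    labels = np.r_[np.ones(n_per_group, int), np.zeros(n_per_group, int)]
    adjacency = {}
    apsd, c, l = {}, {}, {}
    for band in (DELTA, THETA):
        pat = _random_adjacency(rng, n_per_group, boost=(0, 1, 0.3 * separation / 3))
        ctl = _random_adjacency(rng, n_per_group)
        adjacency[band.name] = np.concatenate([pat, ctl])
        apsd[band.name] = rng.standard_normal(n) + separation * labels
        c[band.name] = rng.standard_normal(n) * 0.1 - 0.2 * separation / 3 * labels
        l[band.name] = rng.standard_normal(n) * 0.1 + 0.2 * separation / 3 * labels
    return classify.CohortFeatures(
        subject_ids=[f"s{i}" for i in range(n)],
        labels=labels,
        bands=[DELTA, THETA],
        adjacency=adjacency,
        apsd=apsd,
        c=c,
        l=l,
    )


class TestFusion:
    def test_two_bands_with_one_filter_pair_give_10_features(self, rng):
        cohort = _toy_cohort(rng)
        models = {
            b.name: classify.spn_fit(
                cohort.adjacency[b.name][cohort.labels == 1],
                cohort.adjacency[b.name][cohort.labels == 0],
                b,
                k=1,
            )
            for b in cohort.bands
        }
        x, names = classify.fuse_features(cohort, models)
        assert x.shape == (cohort.n_subjects, 10)
        assert names[:3] == ["delta:apsd", "delta:C", "delta:L"]
        assert names[3:5] == ["delta:spn0", "delta:spn1"]


class TestReportMetrics:
    def test_one_misclassified_control_of_36(self):
        acc, sens, spec = classify.report_metrics(18, 17, 18, 18)
        assert (acc, sens, spec) == (97.22, 100.0, 94.44)

    def test_all_correct_and_all_wrong(self):
        assert classify.report_metrics(10, 12, 10, 12) == (100.0, 100.0, 100.0)
        assert classify.report_metrics(0, 0, 10, 12) == (0.0, 0.0, 0.0)

    def test_accuracy_is_count_weighted_mean_of_sens_and_spec(self, rng):
        for _ in range(25):
            n_p, n_h = int(rng.integers(1, 30)), int(rng.integers(1, 30))
            c_p, c_h = int(rng.integers(0, n_p + 1)), int(rng.integers(0, n_h + 1))
            acc, sens, spec = classify.report_metrics(c_p, c_h, n_p, n_h)
            blended = (sens * n_p + spec * n_h) / (n_p + n_h)
            assert acc == pytest.approx(blended, abs=0.011)  # both sides 2 dp

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            classify.report_metrics(5, 0, 4, 10)
        with pytest.raises(ValidationError):
            classify.report_metrics(0, 0, 0, 10)


class TestLoocv:
    def test_separable_cohort_classifies_perfectly(self, rng):
        report = classify.loocv_svm(_toy_cohort(rng, separation=6.0))
        assert report.accuracy == 100.0
        assert len(report.y_pred) == report.n_pas_total + report.n_hcs_total

    def test_report_counts_are_consistent(self, rng):
        report = classify.loocv_svm(_toy_cohort(rng, separation=1.0))
        acc, sens, spec = classify.report_metrics(
            report.n_pas, report.n_hcs, report.n_pas_total, report.n_hcs_total
        )
        assert (report.accuracy, report.sensitivity, report.specificity) == (acc, sens, spec)

    def test_deterministic_given_inputs(self, rng):
        cohort = _toy_cohort(rng, separation=1.5)
        a = classify.loocv_svm(cohort)
        b = classify.loocv_svm(cohort)
        assert np.array_equal(a.y_pred, b.y_pred)

    def test_constant_feature_dropped_with_warning(self, rng):
        cohort = _toy_cohort(rng, separation=6.0)
        cohort.c["delta"] = np.zeros(cohort.n_subjects)  # zero variance
        with pytest.warns(UserWarning, match="zero-variance"):
            report = classify.loocv_svm(cohort)
        assert report.accuracy == 100.0

    def test_tiny_class_cannot_support_fold_refits(self, rng):
        cohort = _toy_cohort(rng, n_per_group=2)
        with pytest.raises(ValidationError):
            classify.loocv_svm(cohort)
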