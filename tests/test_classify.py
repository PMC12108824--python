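import numpy as np
import pytest

from pillowflux.classify import (
    ClassifierSpec,
    CurveImageCNN,
    build_dataset,
    render_window_image,
    train_and_evaluate,
    _class_weights,
)
from pillowflux.benchmarks import make_imbalanced_sessions
from pillowflux.simulate import PostureSchedule, SensorArrayConfig, simulate_session

from conftest import make_session


class TestRendering:
    def test_shape_and_value_range(self, short_session):
        img = render_window_image(short_session, window=(0.0, 600.0))
        assert img.shape == (224, 224, 3)
        assert img.dtype == np.uint8

    def test_identical_windows_render_identically(self, short_session):
        a = render_window_image(short_session, window=(0.0, 600.0))
        b = render_window_image(short_session, window=(0.0, 600.0))
        assert np.array_equal(a, b)

    def test_constant_window_distinguishable_from_step_window(self):
        flat = make_session(np.full((60, 3), 50.0))
        H = np.full((60, 3), 50.0)
        H[30:, 0] = 80.0
        stepped = make_session(H)
        a = render_window_image(flat, window=(0.0, 600.0))
        b = render_window_image(stepped, window=(0.0, 600.0))
        assert np.abs(a.astype(int) - b.astype(int)).sum() > 0

    def test_window_with_too_few_samples_rejected(self, short_session):
        with pytest.raises(ValueError, match="two samples"):
            render_window_image(short_session, window=(0.0, 10.0))

    def test_custom_size(self, short_session):
        img = render_window_image(short_session, window=(0.0, 600.0), size=96)
        assert img.shape == (96, 96, 3)


class TestBuildDataset:
    def test_class_weights_from_imbalanced_counts(self):
        """528 windows split 438/66/24 give inverse-frequency weights
        528/(3*438), 528/(3*66), 528/(3*24)."""
        labels = np.array(["supine"] * 438 + ["left"] * 66 + ["right"] * 24)
        counts, weights = _class_weights(labels)
        assert counts == {"left": 66, "right": 24, "supine": 438}
        assert weights["supine"] == pytest.approx(0.4018, abs=1e-4)
        assert weights["left"] == pytest.approx(2.6667, abs=1e-4)
        assert weights["right"] == pytest.approx(7.3333, abs=1e-4)

    def test_balanced_counts_give_unit_weights(self):
        labels = np.array(["left", "right", "supine"] * 10)
        _, weights = _class_weights(labels)
        assert all(w == pytest.approx(1.0) for w in weights.values())

    def test_windows_tiled_and_labeled(self):
        cfg = SensorArrayConfig(noise_sd_rh=0.0)
        sched = PostureSchedule([(0.0, "supine"), (1200.0, "left")], 2400.0)
        session = simulate_session(cfg, sched, seed=0)
        ds = build_dataset([session], window_s=600.0, size=64)
        assert len(ds.images) == 4
        assert list(ds.labels) == ["supine", "supine", "left", "left"]

    def test_majority_label_with_tie_goes_to_later_posture(self):
        cfg = SensorArrayConfig(noise_sd_rh=0.0)
        sched = PostureSchedule([(0.0, "supine"), (300.0, "left")], 1200.0)
        session = simulate_session(cfg, sched, seed=0)
        ds = build_dataset([session], window_s=600.0, size=64)
        # window [0, 600): 30 supine samples vs 30 left samples -> left
        assert ds.labels[0] == "left"

    def test_untruthed_session_rejected(self):
        session = make_session(np.full((120, 3), 50.0))
        with pytest.raises(ValueError, match="no ground-truth"):
            build_dataset([session], window_s=600.0)


def small_dataset(counts, seed, noise=0.5, size=64):
    sessions = make_imbalanced_sessions(
        counts, windows_per_session=20, noise_sd_rh=noise, seed=seed
    )
    return build_dataset(sessions, window_s=600.0, size=size)


class TestCurveImageCNN:
    def test_separable_dataset_reaches_perfect_validation(self):
        """Noise-free renders of the three postures are fully separable; a
        short training run must classify the held-out fold perfectly."""
        ds = small_dataset({"supine": 40, "left": 30, "right": 20}, seed=0, noise=0.0)
        report = train_and_evaluate(
            ds, ClassifierSpec(input_size=48, max_epochs=15, seed=0)
        )
        assert report.accuracy == 1.0

    def test_training_is_deterministic_given_seed(self):
        ds = small_dataset({"supine": 20, "left": 14, "right": 6}, seed=1)
        a = CurveImageCNN(input_size=32, max_epochs=2, random_state=5).fit(
            ds.images, ds.labels
        )
        b = CurveImageCNN(input_size=32, max_epochs=2, random_state=5).fit(
            ds.images, ds.labels
        )
        for k in a.params_:
            assert np.array_equal(a.params_[k], b.params_[k])

    def test_predict_proba_rows_sum_to_one(self):
        ds = small_dataset({"supine": 20, "left": 14, "right": 6}, seed=1)
        clf = CurveImageCNN(input_size=32, max_epochs=2).fit(ds.images, ds.labels)
        probs = clf.predict_proba(ds.images[:10])
        assert probs.shape == (10, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_single_class_rejected(self):
        ds = small_dataset({"supine": 20, "left": 14, "right": 6}, seed=1)
        mask = ds.labels == "supine"
        with pytest.raises(ValueError, match="two classes"):
            CurveImageCNN(input_size=32).fit(ds.images[mask], ds.labels[mask])

    def test_sklearn_params_round_trip(self):
        clf = CurveImageCNN(input_size=48, lr=0.02)
        params = clf.get_params()
        assert params["input_size"] == 48
        clone = CurveImageCNN(**params)
        assert clone.get_params() == params


class TestReports:
    def test_confusion_matrix_consistency(self):
        ds = small_dataset({"supine": 40, "left": 30, "right": 20}, seed=2, noise=0.0)
        report = train_and_evaluate(
            ds, ClassifierSpec(input_size=48, max_epochs=10, seed=2)
        )
        cm = report.confusion
        assert cm.sum() == report.n_validation
        assert report.accuracy == pytest.approx(np.trace(cm) / cm.sum())
        for i, lab in enumerate(report.label_order):
            assert report.per_class[lab]["support"] == cm[i].sum()

    def test_binary_metric_arithmetic(self):
        """Metrics recomputed from a fixed 2x2 table: [[50, 0], [5, 45]]
        (rows = true) gives accuracy 0.95, precision 1.0, recall 0.9."""
        tn, fp, fn, tp = 50, 0, 5, 45
        true_pairs = [False] * (tn + fp) + [True] * (fn + tp)
        pred_pairs = [False] * tn + [True] * fp + [False] * fn + [True] * tp
        from sklearn.metrics import confusion_matrix

        cm = confusion_matrix(true_pairs, pred_pairs, labels=[False, True])
        assert cm.tolist() == [[50, 0], [5, 45]]
        acc = np.trace(cm) / cm.sum()
        prec = cm[1, 1] / cm[:, 1].sum()
        rec = cm[1, 1] / cm[1].sum()
        assert acc == pytest.approx(0.95)
        assert prec == pytest.approx(1.0)
        assert rec == pytest.approx(0.9)

    def test_random_labels_give_chance_level_auc(self):
        rng = np.random.default_rng(0)
        ds = small_dataset({"supine": 30, "left": 30}, seed=3)
        shuffled = ds.labels[rng.permutation(len(ds.labels))]
        clf = CurveImageCNN(input_size=32, max_epochs=3, random_state=0).fit(
            ds.images, shuffled
        )
        probs = clf.predict_proba(ds.images)
        from sklearn.metrics import roc_auc_score

        auc = roc_auc_score((shuffled == "left").astype(int), probs[:, 0])
        assert 0.25 < auc < 0.75

    def test_class_weighting_lifts_minority_recall(self):
        """Under heavy imbalance and a tiny epoch budget, inverse-frequency
        weighting must recover more of the rare class than unweighted
        training (averaged over seeds)."""
        rec_w, rec_u = [], []
        for seed in (0, 1, 2):
            ds = small_dataset(
                {"supine": 60, "left": 8, "right": 4}, seed=seed, noise=2.0
            )
            for weighted, out in ((True, rec_w), (False, rec_u)):
                spec = ClassifierSpec(
                    input_size=32, max_epochs=3, seed=seed, class_weighting=weighted
                )
                rep = train_and_evaluate(ds, spec)
                minority = rep.per_class.get("right", {"recall": 0.0})
                out.append(minority["recall"])
        assert np.mean(rec_w) > np.mean(rec_u)
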