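"""NIPALS PLS-2 discriminant analysis: decomposition, LV selection,
prediction, thresholds, persistence."""

import numpy as np
import pytest

import nirleaf as nl
from nirleaf.exceptions import RankError, ValidationError
from nirleaf.plsda import fit_pls2


def _spectra(values, labels, kind="derivative"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return nl.SpectraSet(
        values=values, axis=np.arange(p, dtype=float)[::-1],
        labels=np.asarray(labels),
        sample_id=np.array([f"s{i}" for i in range(n)]),
        sample_type="dried", kind=kind,
    )


class TestDummyCode:
    def test_six_class_block(self):
        labels = ["c1", "c2", "c3", "c4", "c5", "c6"] * 2
        order = ("c1", "c2", "c3", "c4", "c5", "c6")
        dummy = nl.dummy_code(labels, order)
        assert dummy.matrix.shape == (12, 6)
        assert np.allclose(dummy.matrix.sum(axis=1), 1.0)
        assert dummy.matrix[2, 2] == 1.0 and dummy.matrix[2].sum() == 1.0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            nl.dummy_code(["a", "zzz"], ("a", "b"))


class TestFitPLS2:
    def test_rank_one_x(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=10)
        p = rng.normal(size=6)
        X = np.outer(t, p)
        X -= X.mean(axis=0)
        Y = rng.normal(size=(10, 2))
        Y -= Y.mean(axis=0)
        d = fit_pls2(X, Y, 1)
        explained = np.outer(d.x_scores[:, 0], d.x_loadings[:, 0])
        assert np.allclose(explained, X, atol=1e-10)
        with pytest.raises(RankError):
            fit_pls2(X, Y, 2)

    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 4))
        X -= X.mean(axis=0)
        Y = rng.normal(size=(12, 2))
        Y -= Y.mean(axis=0)
        d = fit_pls2(X, Y, 4)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        assert np.allclose(X @ d.coef, X @ beta, atol=1e-6)

    def test_single_response_matches_sklearn_pls1(self):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 8))
        X -= X.mean(axis=0)
        y = rng.normal(size=(10, 1))
        y -= y.mean(axis=0)
        d = fit_pls2(X, y, 3)
        ref = sklearn_pls.PLSRegression(n_components=3, scale=False).fit(X, y)
        # scores agree up to per-component sign
        assert np.allclose(np.abs(d.x_scores), np.abs(ref.x_scores_),
                           atol=1e-8)

    def test_score_orthogonality(self, small_leaves):
        pre, _ = nl.preprocess_chain(small_leaves, nl.PreprocessConfig())
        dummy = nl.dummy_code(pre.labels, tuple(pre.classes()))
        Yc = dummy.matrix - dummy.matrix.mean(axis=0)
        d = fit_pls2(pre.values, Yc, 8)
        gram = d.x_scores.T @ d.x_scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(gram)).max()

    def test_excessive_lv_request_rejected(self):
        with pytest.raises(RankError):
            fit_pls2(np.zeros((5, 3)), np.zeros((5, 2)), 5)


class TestPredict:
    def test_separable_training_set_fully_recovered(self, separable_spectra):
        model = nl.fit_plsda(separable_spectra, n_lv=2)
        pred = nl.predict(model, separable_spectra)
        assert np.array_equal(pred.assigned, separable_spectra.labels)
        # scores sit near the dummy rows for near-noiseless data
        members = pred.y_hat[separable_spectra.labels == "A", 0]
        assert np.all(np.abs(members - 1.0) < 0.2)

    def test_identical_samples_identical_predictions(self, separable_spectra):
        model = nl.fit_plsda(separable_spectra, n_lv=2)
        dup = separable_spectra.subset([0, 0])
        pred = nl.predict(model, dup)
        assert np.array_equal(pred.y_hat[0], pred.y_hat[1])

    def test_axis_mismatch_rejected(self, separable_spectra):
        model = nl.fit_plsda(separable_spectra, n_lv=2)
        shrunk = separable_spectra.with_values(
            separable_spectra.values[:, :-1],
            axis=separable_spectra.axis[:-1],
        )
        with pytest.raises(ValidationError):
            nl.predict(model, shrunk)

    def test_constant_shift_of_training_absorbed_by_centering(
        self, separable_spectra
    ):
        model = nl.fit_plsda(separable_spectra, n_lv=2)
        shifted = separable_spectra.with_values(separable_spectra.values + 3.7)
        model2 = nl.fit_plsda(shifted, n_lv=2)
        probe = separable_spectra.subset(np.arange(5))
        probe_shifted = probe.with_values(probe.values + 3.7)
        assert np.allclose(nl.predict(model, probe).y_hat,
                           nl.predict(model2, probe_shifted).y_hat, atol=1e-8)

    def test_training_error_monotone_in_n_lv(self, small_leaves):
        pre, _ = nl.preprocess_chain(
            small_leaves, nl.PreprocessConfig(mean_center=False)
        )
        errors = []
        for n_lv in (1, 3, 5, 8, 12):
            model = nl.fit_plsda(pre, n_lv=n_lv)
            pred = nl.predict(model, pre)
            errors.append(np.mean(pred.assigned != pre.labels))
        assert all(a >= b for a, b in zip(errors, errors[1:]))


class TestSelectNLV:
    def test_separable_data_reaches_zero_cv_error(self, separable_spectra):
        folds = nl.venetian_blinds(list(separable_spectra.sample_id), 6, 1)
        sel = nl.select_n_lv(separable_spectra, folds, max_lv=6)
        assert sel.errors[sel.n_lv - 1] == 0.0
        # smallest LV count attaining the minimum is returned
        assert np.all(sel.errors[: sel.n_lv - 1] > 0.0)

    def test_max_lv_one_returns_one(self, separable_spectra):
        folds = nl.venetian_blinds(list(separable_spectra.sample_id), 6, 1)
        assert nl.select_n_lv(separable_spectra, folds, max_lv=1).n_lv == 1

    def test_uninformative_labels_give_chance_error(self):
        """Random labels: CV error near 1 - 1/n_classes across seeds."""
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 25))
            labels = np.array(["c1", "c2", "c3"] * 20)
            rng.shuffle(labels)
            s = _spectra(X, labels)
            folds = nl.venetian_blinds(list(s.sample_id), 6, 1)
            sel = nl.select_n_lv(s, folds, max_lv=5)
            errs.append(sel.errors.mean())
        mean_err = float(np.mean(errs))
        assert abs(mean_err - 2 / 3) < 0.12


class TestThresholds:
    def test_separable_scores_give_midpoint(self):
        model = _fake_model_with_classes(("in", "out"))
        pred = nl.Prediction(
            y_hat=np.array([[0.8, 0.2], [0.9, 0.1], [0.1, 0.9], [0.2, 0.8]]),
            assigned=np.array(["in", "in", "out", "out"]),
            class_order=("in", "out"),
        )
        thr = nl.estimate_thresholds(
            model, pred, ["in", "in", "out", "out"]
        )
        assert thr[0] == pytest.approx(0.5)

    def test_overlapping_scores_match_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        member = rng.random(40) < 0.4
        labels = np.where(member, "in", "out")
        model = _fake_model_with_classes(("in", "out"))
        pred = nl.Prediction(
            y_hat=np.column_stack([scores, -scores]),
            assigned=labels, class_order=("in", "out"),
        )
        thr = nl.estimate_thresholds(model, pred, labels)[0]

        def n_errors(t):
            return np.sum(member & (scores < t)) + np.sum(~member & (scores >= t))

        # exhaustive scan over a fine grid cannot beat the chosen threshold
        grid = np.linspace(scores.min(), scores.max(), 5000)
        assert n_errors(thr) <= min(n_errors(t) for t in grid)

    def test_thresholds_strictly_inside_score_range(self, separable_spectra):
        model = nl.fit_plsda(separable_spectra, n_lv=2)
        pred = nl.predict(model, separable_spectra)
        thr = nl.estimate_thresholds(model, pred, separable_spectra.labels)
        for j in range(len(model.class_order)):
            assert pred.y_hat[:, j].min() < thr[j] < pred.y_hat[:, j].max()

    def test_class_absent_from_calibration_rejected(self):
        model = _fake_model_with_classes(("in", "out"))
        pred = nl.Prediction(
            y_hat=np.array([[0.5, 0.5], [0.4, 0.6]]),
            assigned=np.array(["in", "in"]),
            class_order=("in", "out"),
        )
        with pytest.raises(ValidationError):
            nl.estimate_thresholds(model, pred, ["in", "in"])


def _fake_model_with_classes(class_order):
    from nirleaf.plsda import PLSDAModel, PLSDecomposition

    p, c = 3, len(class_order)
    return PLSDAModel(
        decomposition=PLSDecomposition(
            x_weights=np.zeros((p, 1)), x_loadings=np.zeros((p, 1)),
            x_scores=np.zeros((2, 1)), y_loadings=np.zeros((c, 1)),
            coef=np.zeros((p, c)),
        ),
        n_lv=1, class_order=tuple(class_order),
        centering=nl.CenteringModel(axis=np.arange(p, dtype=float)[::-1],
                                    column_means=np.zeros(p)),
        y_means=np.zeros(c), axis=np.arange(p, dtype=float)[::-1],
    )


class TestPersistence:
    def test_save_load_round_trip(self, separable_spectra, tmp_path):
        model = nl.fit_plsda(separable_spectra, n_lv=2)
        pred = nl.predict(model, separable_spectra)
        nl.estimate_thresholds(model, pred, separable_spectra.labels)
        nl.save_model(model, tmp_path / "model")
        back = nl.load_model(tmp_path / "model")
        assert back.n_lv == model.n_lv
        assert back.class_order == model.class_order
        assert np.allclose(nl.predict(back, separable_spectra).y_hat,
                           pred.y_hat, atol=1e-10)
        assert np.allclose(nl.vip_scores(back), nl.vip_scores(model),
                           atol=1e-8)
        assert np.allclose(back.thresholds, model.thresholds)
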