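"""Morphological features and the 1-NN PVC/other classifier."""

import numpy as np
import pytest

from pwavedet.io_formats import EcgRecord
from pwavedet.pvc_classifier import (
    FEATURE_NAMES,
    PvcClassifier,
    classify,
    extract_features,
    load_model,
    save_model,
    train,
)
from pwavedet.qrs_detection import BeatSet
from pwavedet.synthetic_ecg import generate_record
from tests.conftest import clean_preset

FS = 360.0


def identical_beats_record(n_beats=6, rr_s=0.8):
    t = np.arange(int((n_beats + 1) * rr_s * FS)) / FS
    x = np.zeros_like(t)
    r = []
    for i in range(n_beats):
        c = (i + 0.5) * rr_s
        x += np.exp(-((t - c) ** 2) / (2 * 0.012**2))
        r.append(int(round(c * FS)))
    return EcgRecord(samples=x, fs=FS), np.array(r)


class TestExtractFeatures:
    def test_identical_beats_have_zero_deltas(self):
        rec, r = identical_beats_record()
        X, idx = extract_features(rec, BeatSet(r_samples=r))
        names = list(FEATURE_NAMES)
        assert idx == list(range(2, len(r)))
        assert np.allclose(X[:, names.index("d_auc")], 0.0, atol=1e-9)
        assert np.allclose(X[:, names.index("d_u_qrs")], 0.0, atol=1e-9)
        assert np.allclose(X[:, names.index("d_rr")], 0.0, atol=1e-9)

    def test_rectangular_pulse_area(self):
        """1 mV x 100 ms pulse centred at R -> AUC close to 100 mV*ms.

        The baseline high-pass subtracts the pulse's own running-mean
        contribution (~9 % over its 1.1 s window), so the area is asserted
        to the analytic value within that bias.
        """
        n = int(20 * FS)
        x = np.zeros(n)
        r = []
        for c in (5.0, 10.0, 15.0):
            s = int(c * FS)
            x[s - 18 : s + 18] = 1.0  # 36 samples = 100 ms
            r.append(s)
        rec = EcgRecord(samples=x, fs=FS)
        X, idx = extract_features(rec, BeatSet(r_samples=np.array(r)))
        auc = X[0, list(FEATURE_NAMES).index("auc")]
        assert auc == pytest.approx(100.0, rel=0.15)

    def test_pvc_beats_have_larger_area_and_altitude(self, bigeminy):
        rec, truth = bigeminy
        beats = BeatSet(
            r_samples=truth.r_samples, labels=list(truth.beat_labels)
        )
        X, idx = extract_features(rec, beats)
        names = list(FEATURE_NAMES)
        lab = np.array([truth.beat_labels[i] for i in idx])
        for feat in ("auc", "u_qrs"):
            col = X[:, names.index(feat)]
            assert col[lab == "PVC"].mean() > col[lab == "other"].mean()

    def test_out_of_bounds_window_skipped_with_warning(self):
        rec, r = identical_beats_record()
        r = np.concatenate([r, [rec.samples.size - 2]])
        with pytest.warns(UserWarning, match="skipped"):
            X, idx = extract_features(rec, BeatSet(r_samples=r))
        assert len(r) - 1 not in idx

    def test_needs_three_beats(self):
        rec, r = identical_beats_record()
        with pytest.raises(ValueError):
            extract_features(rec, BeatSet(r_samples=r[:2]))


class TestPvcClassifier:
    def rand_set(self, rng, n=40):
        X = rng.normal(size=(n, 7))
        y = np.where(rng.random(n) < 0.3, "PVC", "other")
        if len(set(y)) < 2:
            y[0] = "PVC"
        return X, y

    def test_memorises_training_set(self, rng):
        X, y = self.rand_set(rng)
        model = train(X, y)
        assert np.array_equal(classify(model, X), y)

    def test_label_permutation_invariance(self, rng):
        X, y = self.rand_set(rng)
        perm = rng.permutation(len(y))
        a = classify(train(X, y), X[perm])
        b = y[perm]
        assert np.array_equal(a, b)

    def test_tie_resolves_to_lowest_training_index(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 5.0]])
        y = ["PVC", "other", "other"]
        model = train(X, y, feature_names=("auc", "rr_i"))
        assert classify(model, np.array([[1.0, 0.0]]))[0] == "PVC"

    def test_matches_sklearn_on_generic_data(self, rng):
        """Independent cross-check against sklearn's 1-NN (no ties)."""
        from sklearn.neighbors import KNeighborsClassifier
        from sklearn.preprocessing import StandardScaler

        X, y = self.rand_set(rng, n=80)
        Q = rng.normal(size=(50, 7))
        model = train(X, y)
        scaler = StandardScaler().fit(X)
        sk = KNeighborsClassifier(n_neighbors=1).fit(scaler.transform(X), y)
        assert np.array_equal(
            classify(model, Q), sk.predict(scaler.transform(Q))
        )

    def test_class_imbalance_trains(self, rng):
        X = rng.normal(size=(100, 7))
        y = ["other"] * 95 + ["PVC"] * 5
        assert train(X, y) is not None

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 7))
        with pytest.raises(ValueError):
            train(X, ["other"] * 10)

    def test_nonfinite_query_labelled_other(self, rng):
        X, y = self.rand_set(rng)
        model = train(X, y)
        q = np.full((1, 7), np.nan)
        with pytest.warns(UserWarning):
            assert classify(model, q)[0] == "other"

    def test_sklearn_protocol(self):
        model = PvcClassifier()
        params = model.get_params()
        assert "feature_names" in params
        model.set_params(feature_names=("auc", "rr_i"))
        assert model.feature_names == ("auc", "rr_i")
        with pytest.raises(ValueError):
            model.predict(np.zeros((1, 2)))  # not fitted

    def test_json_round_trip(self, rng, tmp_path):
        X, y = self.rand_set(rng)
        model = train(X, y)
        path = tmp_path / "model.json"
        save_model(model, path)
        clone = load_model(path)
        Q = rng.normal(size=(20, 7))
        assert np.array_equal(classify(model, Q), classify(clone, Q))


class TestOnSyntheticRhythms:
    def test_bigeminy_train_test_accuracy(self):
        """>= 90 % beat-label accuracy across independently seeded records."""

        def feats(seed):
            rec, truth = generate_record(
                clean_preset("bigeminy", seed=seed, duration=60.0)
            )
            bs = BeatSet(r_samples=truth.r_samples)
            X, idx = extract_features(rec, bs)
            return X, [truth.beat_labels[i] for i in idx]

        Xtr, ytr = feats(101)
        Xte, yte = feats(202)
        pred = classify(train(Xtr, ytr), Xte)
        acc = float(np.mean(pred == np.asarray(yte, dtype=object)))
        assert acc >= 0.90
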