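"""Morphological beat features and 1-NN PVC/other classification.

Premature ventricular contractions carry no preceding P wave, so knowing
which beats are PVCs tells the P-wave stage where *not* to search.  Each QRS
complex is summarised by seven morphological features:

========  ==================================================================
auc       area under |signal| over R(i) +- 50 ms, in mV*ms
d_auc     auc(i) - auc(i-1)
rr_i      RR(i) in ms
rr_prev   RR(i-1) in ms
d_rr      rr_i - rr_prev
u_qrs     max |signal| over R(i) +- 50 ms, in mV (the QRS altitude U_QRS(i))
d_u_qrs   u_qrs(i) - u_qrs(i-1)
========  ==================================================================

where "signal" is the baseline-removed (0.67 Hz high-passed) ECG — a raw DC
offset would otherwise dominate the area measure.  Feature vectors exist for
beats with index >= 2 (the deltas need RR(i-1)); the first two beats of a
record default to "other".

Classification is 1-nearest-neighbour in z-scored feature space
(features mix mV and ms scales; unscaled Euclidean distance would be
RR-dominated).  The estimator follows the scikit-learn protocol; the
neighbour search itself is a direct distance computation so that the
documented tie rule — equidistant training points resolve to the lowest
training index — holds exactly.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .io_formats import EcgRecord
from .preprocess import FilterSpec, ms_to_samples, remove_baseline
from .qrs_detection import BeatSet

__all__ = [
    "FEATURE_NAMES",
    "extract_features",
    "PvcClassifier",
    "train",
    "classify",
    "save_model",
    "load_model",
]

FEATURE_NAMES = ("auc", "d_auc", "rr_i", "rr_prev", "d_rr", "u_qrs", "d_u_qrs")
_AUC_HALF_MS = 50.0


def extract_features(
    record: EcgRecord,
    beats: BeatSet,
    filter_spec: FilterSpec | None = None,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> tuple[np.ndarray, list[int]]:
    """Extract per-beat morphological feature vectors.

    Returns ``(X, beat_indices)`` where row k of X describes beat
    ``beat_indices[k]``.  Vectors start at beat index 2; beats whose
    +-50 ms window would leave the record are skipped with a warning.
    """
    if len(beats) < 3:
        raise ValueError("feature extraction needs at least 3 beats")
    unknown = set(feature_names) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature names {sorted(unknown)}")
    fs = record.fs
    hp = remove_baseline(record, filter_spec)
    half = ms_to_samples(_AUC_HALF_MS, fs)
    dt_ms = 1000.0 / fs

    def window_measures(r: int) -> tuple[float, float] | None:
        lo, hi = r - half, r + half + 1
        if lo < 0 or hi > hp.size:
            return None
        seg = np.abs(hp[lo:hi])
        return float(seg.sum() * dt_ms), float(seg.max())

    per_beat = [window_measures(int(r)) for r in beats.r_samples]
    rows, idx = [], []
    for i in range(2, len(beats)):
        cur, prev = per_beat[i], per_beat[i - 1]
        if cur is None or prev is None:
            warnings.warn(
                f"beat {i}: feature window exceeds record bounds; skipped",
                stacklevel=2,
            )
            continue
        rr_i = beats.rr(i) * dt_ms
        rr_prev = beats.rr(i - 1) * dt_ms
        full = {
            "auc": cur[0],
            "d_auc": cur[0] - prev[0],
            "rr_i": rr_i,
            "rr_prev": rr_prev,
            "d_rr": rr_i - rr_prev,
            "u_qrs": cur[1],
            "d_u_qrs": cur[1] - prev[1],
        }
        rows.append([full[name] for name in feature_names])
        idx.append(i)
    return np.asarray(rows, dtype=float), idx


class PvcClassifier(BaseEstimator, ClassifierMixin):
    """1-nearest-neighbour PVC/other beat classifier with z-scoring.

    Parameters
    ----------
    feature_names : tuple of str
        Which features the classifier consumes (any subset of
        :data:`FEATURE_NAMES`); only used for bookkeeping/serialisation.

    Attributes (after :meth:`fit`)
    ------------------------------
    X_ : ndarray       standardized training matrix
    y_ : ndarray       training labels ("PVC"/"other")
    mean_, scale_ : ndarray   per-feature standardisation parameters
    classes_ : ndarray
    """

    def __init__(self, feature_names: tuple[str, ...] = FEATURE_NAMES):
        self.feature_names = tuple(feature_names)

    def fit(self, X: np.ndarray, y) -> "PvcClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(list(y), dtype=object)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per label")
        if not np.all(np.isfinite(X)):
            raise ValueError("training features must be finite")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training set must contain both classes")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        self.scale_[self.scale_ == 0.0] = 1.0
        self.X_ = (X - self.mean_) / self.scale_
        self.y_ = y
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "X_"):
            raise ValueError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0], dtype=object)
        for k, row in enumerate(X):
            if not np.all(np.isfinite(row)):
                warnings.warn(
                    "non-finite feature vector labelled 'other'", stacklevel=2
                )
                out[k] = "other"
                continue
            z = (row - self.mean_) / self.scale_
            d2 = np.sum((self.X_ - z) ** 2, axis=1)
            # np.argmin returns the first minimum: ties resolve to the
            # lowest training index, and duplicate conflicting training
            # points resolve to the earlier sample
            out[k] = self.y_[int(np.argmin(d2))]
        return out


def train(features: np.ndarray, labels, **kwargs) -> PvcClassifier:
    """Fit a :class:`PvcClassifier` (functional wrapper)."""
    return PvcClassifier(**kwargs).fit(features, labels)


def classify(model: PvcClassifier, features: np.ndarray) -> np.ndarray:
    """Predict beat labels with a trained classifier (functional wrapper)."""
    return model.predict(features)


def save_model(model: PvcClassifier, path) -> None:
    """Serialise a fitted classifier to a documented JSON file."""
    payload = {
        "feature_names": list(model.feature_names),
        "mean": model.mean_.tolist(),
        "scale": model.scale_.tolist(),
        "X_standardized": model.X_.tolist(),
        "labels": model.y_.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> PvcClassifier:
    with open(path) as fh:
        payload = json.load(fh)
    model = PvcClassifier(feature_names=tuple(payload["feature_names"]))
    model.mean_ = np.asarray(payload["mean"], dtype=float)
    model.scale_ = np.asarray(payload["scale"], dtype=float)
    model.X_ = np.asarray(payload["X_standardized"], dtype=float)
    model.y_ = np.asarray(payload["labels"], dtype=object)
    model.classes_ = np.unique(model.y_)
    return model


def train_default_classifier(seed: int = 12345) -> PvcClassifier:
    """Train on synthetic presets (bigeminy, trigeminy, sinus, SVES mix).

    Ground-truth R positions and labels from the generator are used, so the
    classifier is available without any external recording.  Deterministic
    for a given seed.
    """
    from .synthetic_ecg import generate_record, preset

    rows, labels = [], []
    for k, name in enumerate(("bigeminy", "trigeminy", "normal_sinus", "sves_mix")):
        script = preset(name, duration=60.0, fs=360.0, seed=seed + k)
        record, truth = generate_record(script)
        beats = BeatSet(r_samples=truth.r_samples, labels=list(truth.beat_labels))
        X, idx = extract_features(record, beats)
        rows.append(X)
        labels.extend(truth.beat_labels[i] for i in idx)
    return train(np.vstack(rows), labels)
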