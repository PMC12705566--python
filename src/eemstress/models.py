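"""Training front-ends: attention classifiers and KNN / random-forest baselines.

Three data views feed the same attention architecture: full 2-D EEMs (image
patches), 1-D emission spectra at one excitation wavelength (windows), and
short feature vectors — 7 peak intensities or 5 PARAFAC scores — as a single
token. Baselines (KNN, RF) consume flattened vectors. Every trained model
exposes the same contract: ``predict_proba`` returns per-class probability
vectors summing to 1, ordered by ``classes``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from .attention import AttentionConfig, ViTClassifier, patchify

__all__ = [
    "TrainedClassifier",
    "train_attention_classifier",
    "train_baseline",
]

ModelKind = Literal["ATTENTION_1D", "ATTENTION_2D", "ATTENTION_FEATURES", "KNN", "RF"]


@dataclass
class TrainedClassifier:
    """A fitted classifier with a uniform probability-prediction contract."""

    kind: str
    classes: np.ndarray
    training_log: list[float] = field(default_factory=list)
    _predict_proba: object = None

    def predict_proba(self, X) -> np.ndarray:
        P = self._predict_proba(np.asarray(X, dtype=float))
        return np.asarray(P, dtype=float)

    def predict(self, X) -> np.ndarray:
        P = self.predict_proba(X)
        return self.classes[np.argmax(P, axis=1)]

    @property
    def smoothed_loss(self) -> list[float]:
        """Exponentially smoothed training loss (alpha = 0.3)."""
        out, s = [], None
        for v in self.training_log:
            s = v if s is None else 0.7 * s + 0.3 * v
            out.append(s)
        return out


def _infer_view(X: np.ndarray, config: AttentionConfig) -> str:
    if X.ndim == 3:
        return "image"
    if X.ndim == 2:
        return "features" if X.shape[1] <= config.patch_size_1d else "sequence"
    raise ValueError(f"expected (n, ...) input with 2 or 3 dims, got {X.ndim}")


def _patch_batch(X: np.ndarray, view: str, config: AttentionConfig) -> np.ndarray:
    if view == "features":
        return X[:, None, :]
    return np.stack([patchify(x, config) for x in X])


def train_attention_classifier(
    X,
    labels,
    config: AttentionConfig | None = None,
    view: str = "auto",
) -> TrainedClassifier:
    """Train the patch-attention classifier on one data view.

    ``X`` is (n, n_ex, n_em) EEMs, (n, n_em) emission slices, or (n, p)
    feature vectors; ``view`` may force "image" / "sequence" / "features".
    Inputs are standardized with statistics of the training data. Training is
    cross-entropy with Adam and dropout, deterministic given ``config.seed``;
    optional early stopping monitors loss on an internal stratified hold-out.
    """
    config = config or AttentionConfig()
    X = np.asarray(X, dtype=float)
    y_raw = np.asarray(labels)
    classes, y = np.unique(y_raw, return_inverse=True)
    if classes.size < 2:
        raise ValueError("training requires at least two classes")
    if classes.size != config.n_classes:
        config = AttentionConfig(**{**config.__dict__, "n_classes": int(classes.size)})
    if view == "auto":
        view = _infer_view(X, config)

    mu = float(X.mean())
    sd = float(X.std()) or 1.0
    if view == "features":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd
    Xp = _patch_batch(Xs, view, config)
    n, n_patches, patch_dim = Xp.shape

    counts = np.bincount(y)
    use_es = config.early_stopping and counts.min() >= 5 and n >= 20
    if use_es:
        tr, va = train_test_split(
            np.arange(n),
            test_size=config.val_fraction,
            stratify=y,
            random_state=config.seed,
        )
    else:
        tr, va = np.arange(n), None

    net = ViTClassifier(patch_dim, n_patches, config)
    rng = np.random.default_rng(config.seed + 2)
    log: list[float] = []
    best_val, best_snap, since_best = np.inf, None, 0
    for _ in range(config.epochs):
        order = rng.permutation(len(tr))
        epoch_losses = []
        for start in range(0, len(tr), config.batch_size):
            idx = tr[order[start : start + config.batch_size]]
            loss, grads = net.loss_and_grads(Xp[idx], y[idx])
            net.adam_step(grads, config.learning_rate)
            epoch_losses.append(loss)
        log.append(float(np.mean(epoch_losses)))
        if use_es:
            logits, _ = net.forward(Xp[va], train=False)
            p = np.exp(logits - logits.max(1, keepdims=True))
            p /= p.sum(1, keepdims=True)
            vloss = float(-np.log(np.clip(p[np.arange(len(va)), y[va]], 1e-12, None)).mean())
            if vloss < best_val - 1e-6:
                best_val, best_snap, since_best = vloss, net.snapshot(), 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    if use_es and best_snap is not None:
        net.restore(best_snap)

    kind = {"image": "ATTENTION_2D", "sequence": "ATTENTION_1D", "features": "ATTENTION_FEATURES"}[view]

    def predict_proba(Xnew: np.ndarray) -> np.ndarray:
        Xn = (np.asarray(Xnew, dtype=float) - mu) / sd
        return net.predict_proba(_patch_batch(Xn, view, config))

    clf = TrainedClassifier(kind=kind, classes=classes, training_log=log)
    clf._predict_proba = predict_proba
    clf.net = net  # fitted network kept accessible for inspection
    return clf


def train_baseline(
    features,
    labels,
    kind: str = "KNN",
    hyperparams: dict | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit a KNN or random-forest baseline on a flat feature table.

    EEMs must be unfolded to vectors by the caller (``X.reshape(n, -1)``).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("baselines expect a flat (n, p) feature matrix")
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training requires at least two classes")
    hyperparams = dict(hyperparams or {})
    if kind.upper() == "KNN":
        est = KNeighborsClassifier(n_neighbors=hyperparams.pop("n_neighbors", 5), **hyperparams)
    elif kind.upper() == "RF":
        est = RandomForestClassifier(
            n_estimators=hyperparams.pop("n_estimators", 200),
            random_state=seed,
            **hyperparams,
        )
    else:
        raise ValueError(f"unknown baseline kind {kind!r} (use 'KNN' or 'RF')")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)

    def predict_proba(Xnew: np.ndarray) -> np.ndarray:
        return est.predict_proba(Xnew.reshape(len(Xnew), -1))

    clf = TrainedClassifier(kind=kind.upper(), classes=est.classes_)
    clf._predict_proba = predict_proba
    clf.estimator = est
    return clf
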