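"""Kernel naive Bayes classifier (from scratch) and comparators.

The primary model treats each band-power feature as conditionally
independent given the class and estimates each class-conditional feature
density with a Gaussian-kernel KDE (Silverman bandwidth per class/feature).
Posteriors are accumulated in log space. A Gaussian-density variant and
from-scratch QDA and k-NN comparators are included; SVM is delegated to
scikit-learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .states import VigilanceState, parse_state

__all__ = [
    "TrainedNBC",
    "fit_kernel_nbc",
    "predict_proba",
    "predict",
    "silverman_bandwidth",
    "fit_predict_comparators",
]

_LOG_DENSITY_FLOOR = np.log(1e-300)


def silverman_bandwidth(x: np.ndarray, floor: float = 0.0) -> float:
    """Silverman's rule: 0.9 · min(SD, IQR/1.34) · n^(−1/5), floored."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    spread_candidates = [v for v in (sd, iqr / 1.34) if v > 0]
    spread = min(spread_candidates) if spread_candidates else 0.0
    h = 0.9 * spread * n ** (-0.2)
    return max(h, floor)


@dataclass
class TrainedNBC:
    """Fitted naive Bayes model.

    ``mode="kernel"`` stores the training points and one bandwidth per
    class/feature; ``mode="gaussian"`` stores means and SDs instead.
    """

    classes: list  # ordered VigilanceState (or arbitrary hashables)
    log_priors: np.ndarray
    mode: str = "kernel"
    train_points: dict = field(default_factory=dict)  # class -> (n_c, d) array
    bandwidths: dict = field(default_factory=dict)  # class -> (d,) array
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    feature_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.log_priors = np.asarray(self.log_priors, dtype=float)
        total = np.exp(logsumexp(self.log_priors))
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"priors must sum to 1, got {total}")
        if self.mode == "kernel":
            for c in self.classes:
                if c in self.bandwidths and np.any(self.bandwidths[c] <= 0):
                    raise ValueError("bandwidths must be positive")

    @property
    def n_features(self) -> int:
        if self.mode == "kernel":
            return next(iter(self.train_points.values())).shape[1]
        return len(next(iter(self.means.values())))

    def to_json(self) -> str:
        def key(c):
            return c.value if isinstance(c, VigilanceState) else str(c)

        payload = {
            "classes": [key(c) for c in self.classes],
            "log_priors": self.log_priors.tolist(),
            "mode": self.mode,
            "feature_names": list(self.feature_names),
        }
        if self.mode == "kernel":
            payload["train_points"] = {key(c): self.train_points[c].tolist()
                                       for c in self.classes}
            payload["bandwidths"] = {key(c): self.bandwidths[c].tolist()
                                     for c in self.classes}
        else:
            payload["means"] = {key(c): self.means[c].tolist() for c in self.classes}
            payload["sds"] = {key(c): self.sds[c].tolist() for c in self.classes}
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "TrainedNBC":
        d = json.loads(text)
        classes = [parse_state(c) for c in d["classes"]]
        kw = dict(
            classes=classes,
            log_priors=np.array(d["log_priors"]),
            mode=d["mode"],
            feature_names=d.get("feature_names", []),
        )
        if d["mode"] == "kernel":
            kw["train_points"] = {c: np.array(d["train_points"][c.value]) for c in classes}
            kw["bandwidths"] = {c: np.array(d["bandwidths"][c.value]) for c in classes}
        else:
            kw["means"] = {c: np.array(d["means"][c.value]) for c in classes}
            kw["sds"] = {c: np.array(d["sds"][c.value]) for c in classes}
        return cls(**kw)


def fit_kernel_nbc(
    X,
    y,
    mode: str = "kernel",
    priors: str = "empirical",
    bandwidth: float | None = None,
    feature_names=None,
) -> TrainedNBC:
    """Fit the naive Bayes model.

    priors: "empirical" (class frequencies) or "uniform". ``bandwidth``
    overrides the Silverman rule with one global value.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=object)
    classes = sorted(set(y.tolist()), key=str)
    if len(classes) < 2:
        raise ValueError("need at least two classes to fit a classifier")
    for c in classes:
        if np.sum(y == c) < 2:
            raise ValueError(f"class {c} has fewer than 2 training samples")

    if priors == "empirical":
        log_priors = np.log([np.mean(y == c) for c in classes])
    elif priors == "uniform":
        log_priors = np.full(len(classes), -np.log(len(classes)))
    else:
        raise ValueError(f"unknown priors mode: {priors!r}")

    model = TrainedNBC(classes=classes, log_priors=log_priors, mode=mode,
                       feature_names=list(feature_names or []))
    # bandwidth floor guards zero-variance features within a class
    ranges = X.max(axis=0) - X.min(axis=0)
    floors = np.maximum(1e-6 * ranges, 1e-12)
    for c in classes:
        Xc = X[y == c]
        if mode == "kernel":
            model.train_points[c] = Xc.copy()
            if bandwidth is not None:
                model.bandwidths[c] = np.full(X.shape[1], float(bandwidth))
            else:
                model.bandwidths[c] = np.array(
                    [silverman_bandwidth(Xc[:, j], floors[j])
                     for j in range(X.shape[1])]
                )
        elif mode == "gaussian":
            model.means[c] = Xc.mean(axis=0)
            model.sds[c] = np.maximum(Xc.std(ddof=1, axis=0), floors)
        else:
            raise ValueError(f"unknown NBC mode: {mode!r}")
    return model


def _kde_log_density(x_col: np.ndarray, train: np.ndarray, h: float,
                     chunk: int = 512) -> np.ndarray:
    """log KDE density of each x under a Gaussian kernel on train points.

    Kernel terms are bounded by 1, so a plain exp-sum is numerically safe;
    a fully underflowed sum yields -inf, which the caller floors.
    """
    n = len(train)
    out = np.empty(len(x_col))
    log_norm = np.log(n * h * np.sqrt(2.0 * np.pi))
    with np.errstate(divide="ignore"):
        for a in range(0, len(x_col), chunk):
            b = min(a + chunk, len(x_col))
            z = (x_col[a:b, None] - train[None, :]) / h
            np.multiply(z, z, out=z)
            z *= -0.5
            np.exp(z, out=z)
            out[a:b] = np.log(z.sum(axis=1)) - log_norm
    return out


def predict_proba(model: TrainedNBC, X) -> np.ndarray:
    """Posterior class probabilities, rows summing to 1.

    Log posterior ∝ log prior + Σ_j log density_{c,j}(x_j), normalized with
    log-sum-exp; per-feature log densities are floored at log(1e-300) so a
    single far-out feature cannot force −inf.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature count mismatch: model has {model.n_features}, got {X.shape[1]}"
        )
    if np.isnan(X).any():
        i, j = np.argwhere(np.isnan(X))[0]
        raise ValueError(f"NaN feature value at epoch {i}, feature {j}")
    log_post = np.tile(model.log_priors, (X.shape[0], 1))
    for k, c in enumerate(model.classes):
        for j in range(X.shape[1]):
            if model.mode == "kernel":
                ld = _kde_log_density(X[:, j], model.train_points[c][:, j],
                                      model.bandwidths[c][j])
            else:
                mu, sd = model.means[c][j], model.sds[c][j]
                z = (X[:, j] - mu) / sd
                ld = -0.5 * z * z - np.log(sd * np.sqrt(2.0 * np.pi))
            log_post[:, k] += np.maximum(ld, _LOG_DENSITY_FLOOR)
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    return np.exp(log_post)


def predict(model: TrainedNBC, X) -> np.ndarray:
    """Argmax class labels from :func:`predict_proba`."""
    proba = predict_proba(model, X)
    idx = np.argmax(proba, axis=1)
    out = np.empty(len(idx), dtype=object)
    out[:] = [model.classes[i] for i in idx]
    return out


# ---------------------------------------------------------------------------
# comparators


def _qda_fit_predict(X_train, y_train, X_test, ridge: float = 1e-8):
    classes = sorted(set(y_train.tolist()), key=str)
    d = X_train.shape[1]
    scores = np.empty((len(X_test), len(classes)))
    for k, c in enumerate(classes):
        Xc = X_train[y_train == c]
        mu = Xc.mean(axis=0)
        cov = np.cov(Xc, rowvar=False).reshape(d, d)
        # ridge-regularize singular covariances
        eps = 0.0
        while True:
            try:
                chol = np.linalg.cholesky(cov + eps * np.eye(d))
                break
            except np.linalg.LinAlgError:
                eps = max(eps * 10.0, ridge * max(np.trace(cov) / d, 1.0))
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        diff = X_test - mu
        sol = np.linalg.solve(chol, diff.T)
        maha = np.sum(sol * sol, axis=0)
        prior = np.log(np.mean(y_train == c))
        scores[:, k] = prior - 0.5 * (logdet + maha)
    idx = np.argmax(scores, axis=1)
    post = np.exp(scores - logsumexp(scores, axis=1, keepdims=True))
    labels = np.empty(len(idx), dtype=object)
    labels[:] = [classes[i] for i in idx]
    return labels, post, classes


def _knn_fit_predict(X_train, y_train, X_test, k: int = 5):
    classes = sorted(set(y_train.tolist()), key=str)
    k = min(k, len(X_train))
    labels = np.empty(len(X_test), dtype=object)
    post = np.zeros((len(X_test), len(classes)))
    class_idx = {c: i for i, c in enumerate(classes)}
    chunk = 256
    for a in range(0, len(X_test), chunk):
        b = min(a + chunk, len(X_test))
        d2 = ((X_test[a:b, None, :] - X_train[None, :, :]) ** 2).sum(axis=-1)
        # stable argsort: distance ties resolved by lower training index
        order = np.argsort(d2, axis=1, kind="stable")[:, :k]
        for r in range(b - a):
            votes = y_train[order[r]]
            counts = {c: int(np.sum(votes == c)) for c in classes}
            top = max(counts.values())
            winners = [c for c in classes if counts[c] == top]
            if len(winners) == 1:
                lab = winners[0]
            else:  # vote tie -> nearest neighbour's label
                lab = votes[0]
            labels[a + r] = lab
            for c in classes:
                post[a + r, class_idx[c]] = counts[c] / k
    return labels, post, classes


def fit_predict_comparators(X_train, y_train, X_test, method: str, k: int = 5):
    """Train a comparator and predict the test set.

    Returns (labels, posteriors, classes); posteriors may be None for SVM.
    QDA and k-NN are implemented here; SVM is delegated to scikit-learn.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_train.ndim == 1:
        X_train = X_train[:, None]
    if X_test.ndim == 1:
        X_test = X_test[:, None]
    y_train = np.asarray(y_train, dtype=object)
    if method == "qda":
        return _qda_fit_predict(X_train, y_train, X_test)
    if method == "knn":
        return _knn_fit_predict(X_train, y_train, X_test, k=k)
    if method == "svm":
        from sklearn.svm import SVC

        classes = sorted(set(y_train.tolist()), key=str)
        clf = SVC(kernel="rbf", gamma="scale")
        clf.fit(X_train, [str(c) for c in y_train])
        by_name = {str(c): c for c in classes}
        raw = clf.predict(X_test)
        labels = np.empty(len(raw), dtype=object)
        labels[:] = [by_name[r] for r in raw]
        # decision-function scores stand in for posteriors in ROC use
        scores = clf.decision_function(X_test)
        return labels, scores, classes
    raise ValueError(f"unsupported comparator method: {method!r}")
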