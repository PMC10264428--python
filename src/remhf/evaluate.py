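"""Evaluation protocol: repeated shuffled 75/25 splits, confusion-matrix
metrics, ROC/AUC, single-band ablation by false-negative ratio, hourly
Pearson correlations, and the nonparametric tests.

REM is the positive class throughout: TP counts epochs correctly scored as
REM, TN epochs correctly rejected.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from . import classify
from .features import BandTable, FeatureMatrix, HourlySummary
from .states import VigilanceState

__all__ = [
    "ConfusionMatrix",
    "ClassifierSpec",
    "EvaluationReport",
    "confusion_matrix",
    "metrics",
    "repeated_evaluation",
    "roc_and_auc",
    "band_ablation_fnr",
    "hourly_correlation",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "binary_wake_rem",
]

WAKE, REM = VigilanceState.WAKE, VigilanceState.REM


@dataclass(frozen=True)
class ConfusionMatrix:
    """Epoch counts with REM as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_matrix(y_true, y_pred, positive=REM) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise ValueError("label arrays differ in length")
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def metrics(cm: ConfusionMatrix):
    """(accuracy %, sensitivity %, specificity %).

    Undefined ratios (zero denominator) are returned as None, never 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    sensitivity = 100.0 * cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    specificity = 100.0 * cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else None
    return accuracy, sensitivity, specificity


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to run and with what options."""

    method: str = "kernel_nbc"  # kernel_nbc | gaussian_nbc | qda | knn | svm
    priors: str = "empirical"  # empirical | uniform (NBC only)
    bandwidth: float | None = None
    k: int = 5

    def __post_init__(self) -> None:
        allowed = {"kernel_nbc", "gaussian_nbc", "qda", "knn", "svm"}
        if self.method not in allowed:
            raise ValueError(f"method must be one of {sorted(allowed)}")


def _fit_predict(spec: ClassifierSpec, X_tr, y_tr, X_te):
    """Returns (predicted labels, positive-class scores or None)."""
    if spec.method in ("kernel_nbc", "gaussian_nbc"):
        mode = "kernel" if spec.method == "kernel_nbc" else "gaussian"
        model = classify.fit_kernel_nbc(
            X_tr, y_tr, mode=mode, priors=spec.priors, bandwidth=spec.bandwidth
        )
        proba = classify.predict_proba(model, X_te)
        idx = np.argmax(proba, axis=1)
        labels = np.empty(len(idx), dtype=object)
        labels[:] = [model.classes[i] for i in idx]
        pos = model.classes.index(REM) if REM in model.classes else None
        scores = proba[:, pos] if pos is not None else None
        return labels, scores
    labels, post, classes = classify.fit_predict_comparators(
        X_tr, y_tr, X_te, method=spec.method, k=spec.k
    )
    scores = None
    if spec.method in ("qda", "knn") and REM in classes:
        scores = np.asarray(post)[:, classes.index(REM)]
    elif spec.method == "svm" and REM in classes:
        sign = 1.0 if classes.index(REM) == 1 else -1.0
        scores = sign * np.asarray(post, dtype=float)
    return labels, scores


@dataclass
class EvaluationReport:
    """Per-shuffle metrics plus summary statistics and protocol metadata."""

    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: np.ndarray | None
    confusion_total: ConfusionMatrix
    metadata: dict = field(default_factory=dict)

    @property
    def fnr(self) -> np.ndarray:
        return 100.0 - self.sensitivity

    def summary(self) -> dict:
        out = {}
        for name in ("accuracy", "sensitivity", "specificity"):
            arr = getattr(self, name)
            out[name] = {"mean": float(np.mean(arr)), "sd": float(np.std(arr, ddof=1))
                         if len(arr) > 1 else 0.0}
        out["fnr"] = {"mean": float(np.mean(self.fnr)),
                      "sd": float(np.std(self.fnr, ddof=1)) if len(self.fnr) > 1 else 0.0}
        if self.auc is not None and len(self.auc):
            out["auc"] = {"mean": float(np.mean(self.auc)),
                          "sd": float(np.std(self.auc, ddof=1)) if len(self.auc) > 1 else 0.0}
        return out

    def to_dict(self) -> dict:
        return {
            "per_shuffle": {
                "accuracy": self.accuracy.tolist(),
                "sensitivity": self.sensitivity.tolist(),
                "specificity": self.specificity.tolist(),
                "auc": self.auc.tolist() if self.auc is not None else None,
            },
            "summary": self.summary(),
            "confusion_total": {
                "tp": self.confusion_total.tp, "fp": self.confusion_total.fp,
                "tn": self.confusion_total.tn, "fn": self.confusion_total.fn,
            },
            "metadata": self.metadata,
        }


def binary_wake_rem(features: FeatureMatrix):
    """Restrict a feature matrix to the WAKE/REM binary task -> (X, y)."""
    mask = np.array([s in (WAKE, REM) for s in features.labels])
    return features.values[mask], features.labels[mask]


def repeated_evaluation(
    X,
    y,
    classifier_spec: ClassifierSpec | None = None,
    n_shuffles: int = 1000,
    train_fraction: float = 0.75,
    seed: int | None = 0,
) -> EvaluationReport:
    """The shuffled-split protocol: ``n_shuffles`` random 75/25 splits, each
    fitted and tested, with mean ± SD of accuracy/sensitivity/specificity.

    Splits are unstratified; a split leaving either side without both
    classes is re-drawn (count recorded in metadata).
    """
    spec = classifier_spec or ClassifierSpec()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=object)
    keep = np.array([s in (WAKE, REM) for s in y])
    X, y = X[keep], y[keep]
    if not ((y == WAKE).any() and (y == REM).any()):
        raise ValueError("both WAKE and REM must be present")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    n = len(y)
    n_train = int(round(train_fraction * n))
    if not 0 < n_train < n:
        raise ValueError("train fraction leaves an empty train or test set")

    children = np.random.SeedSequence(seed).spawn(n_shuffles)
    acc = np.empty(n_shuffles)
    sens = np.empty(n_shuffles)
    spec_ = np.empty(n_shuffles)
    aucs = []
    redraws = 0
    tot = np.zeros(4, dtype=np.int64)
    for i in range(n_shuffles):
        rng = np.random.default_rng(children[i])
        while True:
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            # train needs >= 2 per class (fit requirement), test >= 1
            ok = all(
                np.sum(y[tr] == c) >= 2 and (y[te] == c).any()
                for c in (WAKE, REM)
            )
            if ok:
                break
            redraws += 1
        labels, scores = _fit_predict(spec, X[tr], y[tr], X[te])
        cm = confusion_matrix(y[te], labels)
        a, s, p = metrics(cm)
        acc[i], sens[i], spec_[i] = a, s, p
        tot += (cm.tp, cm.fp, cm.tn, cm.fn)
        if scores is not None:
            _, _, auc = roc_and_auc(scores, y[te])
            aucs.append(auc)
    report = EvaluationReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec_,
        auc=np.array(aucs) if aucs else None,
        confusion_total=ConfusionMatrix(*[int(v) for v in tot]),
        metadata={
            "classifier": spec.method,
            "priors": spec.priors,
            "n_shuffles": n_shuffles,
            "train_fraction": train_fraction,
            "seed": seed,
            "n_epochs": int(n),
            "redraws": redraws,
        },
    )
    return report


def roc_and_auc(scores, y, positive=REM):
    """ROC points and trapezoid AUC from positive-class scores.

    Returns (fpr, tpr, auc); fpr/tpr are swept over every distinct score
    threshold. The AUC equals the positive/negative pair concordance
    probability (ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=object)
    pos = y == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    pos_sorted = pos[order].astype(float)
    # collapse tied scores into single threshold steps
    distinct = np.concatenate([np.flatnonzero(np.diff(s_sorted)), [len(s_sorted) - 1]])
    tp = np.cumsum(pos_sorted)[distinct]
    fp = np.cumsum(1.0 - pos_sorted)[distinct]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def band_ablation_fnr(
    X,
    y,
    bands: BandTable,
    classifier_spec: ClassifierSpec | None = None,
    n_shuffles: int = 50,
    train_fraction: float = 0.75,
    seed: int | None = 0,
) -> dict:
    """Feed the classifier one band at a time; report the mean FNR per band.

    Returns {band name: {"fnr_mean", "fnr_sd", "fnr_per_shuffle"}}.
    """
    X = np.asarray(X, dtype=float)
    bands = bands if isinstance(bands, BandTable) else BandTable(tuple(bands))
    if X.shape[1] != len(bands):
        raise ValueError("feature column count must match the band table")
    out = {}
    for j, name in enumerate(bands.names):
        rep = repeated_evaluation(
            X[:, j], y, classifier_spec, n_shuffles=n_shuffles,
            train_fraction=train_fraction, seed=seed,
        )
        out[name] = {
            "fnr_mean": float(np.mean(rep.fnr)),
            "fnr_sd": float(np.std(rep.fnr, ddof=1)) if n_shuffles > 1 else 0.0,
            "fnr_per_shuffle": rep.fnr.tolist(),
        }
    return out


def pearson_correlation(x, y, alpha: float = 0.05):
    """Product-moment r with Fisher-z CI and two-tailed t-test p.

    Returns dict with r, ci_low, ci_high, r2, p, n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("series lengths differ")
    if n < 3:
        raise ValueError("correlation needs at least 3 points")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("correlation undefined for zero-variance series")
    xm, ym = x - x.mean(), y - y.mean()
    r = float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sstats.t.sf(abs(t), n - 2))
    if n > 3 and abs(r) < 1.0:
        z = math.atanh(r)
        se = 1.0 / math.sqrt(n - 3)
        zcrit = float(sstats.norm.ppf(1.0 - alpha / 2.0))
        lo, hi = math.tanh(z - zcrit * se), math.tanh(z + zcrit * se)
    else:
        lo, hi = r, r
    return {"r": r, "ci_low": lo, "ci_high": hi, "r2": r * r, "p": p, "n": n}


def hourly_correlation(summary: HourlySummary, shapiro_alpha: float = 0.05) -> dict:
    """Pearson correlation of hourly band power vs %WAKE and %REM.

    A Shapiro-Wilk normality check runs first on each series; failures emit
    a warning but do not block the correlation. Returns
    {band name: {"wake": {...}, "rem": {...}}}.
    """
    n = len(summary.hours)
    if n < 3:
        raise ValueError("need at least 3 hourly bins")
    for name, series in (("percent_wake", summary.percent_wake),
                         ("percent_rem", summary.percent_rem)):
        if np.std(series) > 0:
            w, p = sstats.shapiro(series)
            if p < shapiro_alpha:
                warnings.warn(
                    f"Shapiro-Wilk normality check failed for {name} (p={p:.3g})",
                    stacklevel=2,
                )
    out = {}
    for j, band_name in enumerate(summary.bands.names):
        col = summary.band_means[:, j]
        out[band_name] = {
            "wake": pearson_correlation(col, summary.percent_wake),
            "rem": pearson_correlation(col, summary.percent_rem),
        }
    return out


# ---------------------------------------------------------------------------
# nonparametric tests


def _midranks(values: np.ndarray) -> np.ndarray:
    return sstats.rankdata(values, method="average")


def mann_whitney_u(x, y, exact_max_n: int = 10):
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration of group assignments when both groups have
    at most ``exact_max_n`` observations (two-sided as deviation of U from
    its mean); otherwise the tie-corrected normal approximation with
    continuity correction. Returns dict with u (statistic of the first
    group), p, method.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    if n1 <= exact_max_n and n2 <= exact_max_n:
        obs_dev = abs(u1 - mu)
        count = 0
        total = 0
        idx_all = range(n1 + n2)
        for combo in itertools.combinations(idx_all, n1):
            r = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(r - mu) >= obs_dev - 1e-12:
                count += 1
        return {"u": u1, "p": count / total, "method": "exact"}
    n = n1 + n2
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(t_counts**3 - t_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return {"u": u1, "p": 1.0, "method": "normal"}
    z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
    p = 2.0 * float(sstats.norm.sf(max(z, 0.0)))
    return {"u": u1, "p": min(p, 1.0), "method": "normal"}


def wilcoxon_signed_rank(x, hypothetical_median: float = 100.0,
                         exact_max_n: int = 12):
    """One-sample Wilcoxon signed-rank test against a hypothetical median.

    Zero differences are discarded; if every difference is zero the
    statistic is undefined and an error is raised. Exact p by sign-flip
    enumeration for small n, else normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    d = x - hypothetical_median
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValueError(
            "Wilcoxon statistic undefined: all values equal the hypothetical median"
        )
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    if n <= exact_max_n:
        obs_dev = abs(w_plus - mu)
        count = 0
        for mask in range(1 << n):
            w = sum(ranks[i] for i in range(n) if mask >> i & 1)
            if abs(w - mu) >= obs_dev - 1e-12:
                count += 1
        return {"w": w_plus, "p": count / (1 << n), "method": "exact"}
    _, t_counts = np.unique(np.abs(d), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - float(np.sum(t_counts**3 - t_counts)) / 48.0
    z = (abs(w_plus - mu) - 0.5) / math.sqrt(sigma2)
    p = 2.0 * float(sstats.norm.sf(max(z, 0.0)))
    return {"w": w_plus, "p": min(p, 1.0), "method": "normal"}
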