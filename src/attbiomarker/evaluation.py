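"""Resampling, classification metrics, and DeLong comparison of AUCs.

The evaluation protocol mirrors the classifier study: a stratified 80/20
train/test split, five-fold cross-validation on the training portion,
metrics AUC / ACC / F1 / PRE / REC per fold and on the held-out test
set, and DeLong's nonparametric test for the difference of two
correlated AUCs computed on the same samples. AUC is the Mann-Whitney
probability of correct pair ordering with ties counted one half;
thresholded metrics use "probability >= threshold predicts positive"
with the case class (label 1) positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn import metrics as _skm
from sklearn.model_selection import StratifiedKFold

from attbiomarker.expression_io import LabeledExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    """Stratified holdout plus k-fold folds over the training portion."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int


@dataclass
class MetricsRow:
    """One evaluation's metric vector; ``auc`` is NaN when undefined."""

    auc: float
    acc: float
    f1: float
    pre: float
    rec: float

    def as_dict(self) -> dict[str, float]:
        return {"auc": self.auc, "acc": self.acc, "f1": self.f1,
                "pre": self.pre, "rec": self.rec}


@dataclass
class EvalReport:
    """Per-fold metrics, their mean/sd aggregates, and held-out test metrics."""

    per_fold: list[MetricsRow]
    aggregate: dict[str, dict[str, float]]
    test_set: MetricsRow | None
    test_scores: np.ndarray | None = None
    test_labels: np.ndarray | None = None


@dataclass
class DeLongResult:
    """AUC difference with its DeLong standardization."""

    delta_auc: float
    z: float
    p: float


# ---------------------------------------------------------------------------
# splits


def stratified_holdout(
    labels: np.ndarray, test_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled holdout; test counts round half to even.

    Returns (train_indices, test_indices).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
        n_test = int(np.round(test_fraction * len(idx)))  # round half to even
        if n_test == 0 or n_test == len(idx):
            raise ValueError(
                f"class {c} would be absent from one partition "
                f"(size {len(idx)}, test fraction {test_fraction})"
            )
        perm = rng.permutation(idx)
        test.append(perm[:n_test])
        train.append(perm[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def stratified_kfold(
    labels: np.ndarray, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition; class counts per fold differ by <= 1."""
    labels = np.asarray(labels)
    for c in np.unique(labels):
        if (labels == c).sum() < k:
            raise ValueError(f"class {c} has fewer than k={k} samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (tr, va) for tr, va in skf.split(np.zeros(len(labels)), labels)
    ]


def make_split_plan(
    labels: np.ndarray, test_fraction: float = 0.2, k: int = 5, seed: int = 0
) -> SplitPlan:
    """Holdout plus k-fold CV folds over the training indices."""
    train_idx, test_idx = stratified_holdout(labels, test_fraction, seed)
    inner = stratified_kfold(np.asarray(labels)[train_idx], k=k, seed=seed)
    folds = [(train_idx[tr], train_idx[va]) for tr, va in inner]
    return SplitPlan(train_indices=train_idx, test_indices=test_idx,
                     folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# metrics


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC (ties count one half)."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(_skm.roc_auc_score(y_true, scores))


def binary_metrics(
    y_true: np.ndarray, y_prob: np.ndarray, threshold: float = 0.5
) -> MetricsRow:
    """ACC/PRE/REC/F1 at a probability threshold plus threshold-free AUC.

    Predicts positive when probability >= threshold. With a single-class
    ``y_true`` the AUC is NaN (warning); the thresholded metrics are
    still returned.
    """
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape != y_prob.shape:
        raise ValueError("y_true and y_prob must have equal length")
    y_pred = (y_prob >= threshold).astype(int)
    acc = float(_skm.accuracy_score(y_true, y_pred))
    pre = float(_skm.precision_score(y_true, y_pred, zero_division=0))
    rec = float(_skm.recall_score(y_true, y_pred, zero_division=0))
    f1 = float(_skm.f1_score(y_true, y_pred, zero_division=0))
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class y_true: AUC undefined (NaN)", stacklevel=2)
        auc = float("nan")
    else:
        auc = roc_auc(y_true, y_prob)
    return MetricsRow(auc=auc, acc=acc, f1=f1, pre=pre, rec=rec)


# ---------------------------------------------------------------------------
# DeLong


def _structural_components(y: np.ndarray, s: np.ndarray):
    """AUC and its positive/negative midrank structural components."""
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (r_all[:m] - r_pos) / n          # one component per positive
    v01 = 1.0 - (r_all[m:] - r_neg) / m    # one per negative
    return auc, v10, v01


def delong_test(
    y_true: np.ndarray, scores_a: np.ndarray, scores_b: np.ndarray
) -> DeLongResult:
    """DeLong test for two correlated AUCs measured on the same samples.

    Uses the midrank structural-component estimator of the covariance of
    the paired AUCs; z = dAUC / sqrt(var), two-sided normal p. A zero
    variance with zero dAUC (e.g. identical score vectors) gives z=0,
    p=1; zero variance with a nonzero difference is an error.
    """
    y = np.asarray(y_true)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (y.shape == a.shape == b.shape):
        raise ValueError("score vectors must cover the same samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    auc_a, v10_a, v01_a = _structural_components(y, a)
    auc_b, v10_b, v01_b = _structural_components(y, b)
    delta = float(auc_a - auc_b)
    m, n = len(v10_a), len(v01_a)

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        if abs(delta) < 1e-12:
            return DeLongResult(delta_auc=0.0, z=0.0, p=1.0)
        raise ValueError("degenerate variance with nonzero AUC difference")
    z = delta / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongResult(delta_auc=delta, z=float(z), p=p)


# ---------------------------------------------------------------------------
# cross-validated harness


def crossval_evaluate(
    model_builder,
    m: LabeledExpressionMatrix,
    plan: SplitPlan,
) -> EvalReport:
    """Per-fold CV metrics plus final held-out test metrics.

    ``model_builder(fold_seed)`` must return an estimator adapter with
    ``fit(X, y)`` and ``predict_proba_1d(X) -> probabilities``. After
    CV, the model is refit on the full training split and scored on the
    held-out test indices (the headline metrics).
    """
    X, y = m.values, m.labels
    per_fold: list[MetricsRow] = []
    for i, (tr, va) in enumerate(plan.folds):
        try:
            est = model_builder(plan.seed + i)
            est.fit(X[tr], y[tr])
            prob = est.predict_proba_1d(X[va])
            per_fold.append(binary_metrics(y[va], prob))
        except Exception as exc:  # noqa: BLE001 - fold id added for diagnosis
            raise RuntimeError(f"training failed in fold {i}") from exc

    est = model_builder(plan.seed + len(plan.folds))
    est.fit(X[plan.train_indices], y[plan.train_indices])
    test_prob = est.predict_proba_1d(X[plan.test_indices])
    test_row = binary_metrics(y[plan.test_indices], test_prob)

    agg = {}
    for name in ("auc", "acc", "f1", "pre", "rec"):
        vals = np.array([getattr(r, name) for r in per_fold])
        agg[name] = {"mean": float(np.nanmean(vals)), "sd": float(np.nanstd(vals, ddof=1))
                     if len(vals) > 1 else 0.0}
    return EvalReport(
        per_fold=per_fold,
        aggregate=agg,
        test_set=test_row,
        test_scores=test_prob,
        test_labels=y[plan.test_indices],
    )


def compare_classifiers(
    m: LabeledExpressionMatrix,
    plan: SplitPlan,
    classifiers: dict[str, object],
) -> tuple[dict[str, EvalReport], list[dict]]:
    """Evaluate several classifiers on identical splits; DeLong per pair.

    Returns (reports_by_name, pairwise_delong_rows); a classifier whose
    evaluation fails is recorded with its error and skipped from the
    pairwise comparisons.
    """
    if not classifiers:
        raise ValueError("need at least one classifier")
    reports: dict[str, EvalReport] = {}
    failures: dict[str, str] = {}
    for name, builder in classifiers.items():
        try:
            reports[name] = crossval_evaluate(builder, m, plan)
        except Exception as exc:  # noqa: BLE001 - record and continue
            logger.warning("classifier %s failed: %s", name, exc)
            failures[name] = str(exc)

    pairwise: list[dict] = []
    names = list(reports)
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            ra, rb = reports[na], reports[nb]
            res = delong_test(ra.test_labels, ra.test_scores, rb.test_scores)
            pairwise.append(
                {"model_a": na, "model_b": nb, "delta_auc": res.delta_auc,
                 "z": res.z, "p": res.p}
            )
    for name, err in failures.items():
        pairwise.append({"model_a": name, "model_b": None, "error": err})
    return reports, pairwise


# ---------------------------------------------------------------------------
# estimator adapters


class SklearnAdapter:
    """Wrap an sklearn classifier into the fit/predict_proba_1d surface."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        self.estimator.fit(X, y)
        return self

    def predict_proba_1d(self, X):
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(X)[:, 1]
        s = est.decision_function(X)
        return 1.0 / (1.0 + np.exp(-s))


class AttCnnAdapter:
    """Adapter training an AttCNN spec with an internal validation carve-out.

    When ``fit`` receives no explicit validation data, a stratified 15%
    of the training samples is held out for early stopping.
    """

    def __init__(self, spec, cfg, val_fraction: float = 0.15):
        from attbiomarker import attcnn as _attcnn

        self._attcnn = _attcnn
        self.spec = spec
        self.cfg = cfg
        self.val_fraction = val_fraction
        self.model = None

    def fit(self, X, y, X_val=None, y_val=None):
        if X_val is None:
            tr, va = stratified_holdout(y, self.val_fraction, seed=self.cfg.seed)
            X, X_val, y, y_val = X[tr], X[va], y[tr], y[va]
        self.model = self._attcnn.train(self.spec, self.cfg, X, y, X_val, y_val)
        return self

    def predict_proba_1d(self, X):
        return self._attcnn.predict_proba(self.model, X)
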