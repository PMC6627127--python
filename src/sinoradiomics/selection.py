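"""RBF-SVM outcome classification with backward sequential feature
elimination under nested 9-fold cross-validation.

Protocol per outer fold (32 training / 4 validation patients):

1. z-score standardization fitted on the 32 training rows only;
2. (gamma, C) grid search — exhaustive over gamma = 2^-20..2^10,
   C = 2^-10..2^10 (integer exponents) — scored by inner 4-fold CV
   accuracy on the training rows;
3. backward sequential elimination starting from all 27 features: each
   iteration drops the feature whose removal gives the best (highest)
   inner-CV accuracy, i.e. the least-contributing feature; the rank of a
   feature is the iteration at which it was eliminated (survivors rank
   highest);
4. the selected subset is the prefix of the ranking with maximal inner-CV
   accuracy (smallest subset on ties); (gamma, C) are re-tuned on that
   subset and the final model refit on all 32 training rows;
5. the five confusion metrics (sensitivity, specificity, PPV, NPV,
   accuracy) are reported on the training rows (resubstitution) and the 4
   held-out patients.

Held-out rows never touch the scaler, the elimination, or the tuning.

The SVM engine is libsvm via scikit-learn.  The hot loop (tens of
thousands of tiny fits per experiment) calls scikit-learn's low-level
libsvm binding directly when available, which skips per-call estimator
validation; a public ``SVC`` fallback is used otherwise and a test pins
prediction-identity between the two paths.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, OUTCOME_COLUMN, standardize

try:  # fast path: low-level libsvm binding (same engine as SVC)
    from sklearn.svm import _libsvm as _llsvm
    _llsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - exercised only on exotic builds
    _llsvm = None
from sklearn.svm import SVC

__all__ = [
    "SvmConfig",
    "ConfusionMetrics",
    "EliminationTrace",
    "FoldResult",
    "CVExperimentResult",
    "make_folds",
    "grid_search",
    "backward_eliminate",
    "run_fold",
    "run_experiment",
    "confusion_metrics",
    "svm_predict",
]

POSITIVE_LABEL_DEFAULT = "control"


@dataclass(frozen=True)
class SvmConfig:
    """Hyperparameter grids and protocol knobs."""

    gamma_exponents: tuple[int, ...] = tuple(range(-20, 11))
    c_exponents: tuple[int, ...] = tuple(range(-10, 11))
    inner_folds: int = 4
    inner_repeats: int = 3  # repeated inner CV smooths the 1/32-grained score
    elimination_scoring: str = "inner_cv"  # or "resubstitution"
    positive_label: str = POSITIVE_LABEL_DEFAULT
    stratified: bool = False
    class_weighted: bool = False

    def __post_init__(self) -> None:
        if not self.gamma_exponents or not self.c_exponents:
            raise ValueError("hyperparameter grids must be nonempty")
        if self.elimination_scoring not in ("inner_cv", "resubstitution"):
            raise ValueError("elimination_scoring must be inner_cv or resubstitution")

    @property
    def gammas(self) -> np.ndarray:
        return 2.0 ** np.asarray(self.gamma_exponents, dtype=float)

    @property
    def cs(self) -> np.ndarray:
        return 2.0 ** np.asarray(self.c_exponents, dtype=float)


# --------------------------------------------------------------------------
# SVM engine
# --------------------------------------------------------------------------

def _svm_predict_fast(x_train: np.ndarray, y_train: np.ndarray,
                      x_test: np.ndarray, gamma: float, c: float,
                      class_weighted: bool) -> np.ndarray:
    if class_weighted:
        counts = np.bincount(y_train.astype(int), minlength=2).astype(float)
        weight = y_train.size / (2.0 * np.maximum(counts, 1.0))
    else:
        weight = np.ones(2)
    (support, sv, n_sv, coef, icpt, prob_a, prob_b,
     _status, _n_iter) = _llsvm.fit(
        x_train, y_train, svm_type=0, kernel="rbf", C=c, gamma=gamma,
        class_weight=weight)
    return _llsvm.predict(x_test, support, sv, n_sv, coef, icpt, prob_a, prob_b,
                          svm_type=0, kernel="rbf", gamma=gamma)


def svm_predict(x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray,
                gamma: float, c: float, class_weighted: bool = False,
                engine: str = "auto") -> np.ndarray:
    """Fit an RBF-SVM and predict labels for ``x_test``.

    ``y_train`` is a 0/1 vector.  A single-class training set degenerates
    to the constant predictor.  ``engine='svc'`` forces the public
    scikit-learn estimator (used for cross-checking the fast path).
    """
    x_train = np.ascontiguousarray(x_train, dtype=np.float64)
    x_test = np.ascontiguousarray(x_test, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.float64)
    classes = np.unique(y_train)
    if classes.size == 1:
        return np.full(x_test.shape[0], classes[0])
    if engine == "auto" and _llsvm is not None:
        return _svm_predict_fast(x_train, y_train, x_test, gamma, c,
                                 class_weighted)
    model = SVC(kernel="rbf", C=c, gamma=gamma,
                class_weight="balanced" if class_weighted else None)
    return model.fit(x_train, y_train).predict(x_test)


# --------------------------------------------------------------------------
# folds and metrics
# --------------------------------------------------------------------------

def make_folds(n: int, k: int, seed: int, stratified: bool = False,
               labels: np.ndarray | None = None) -> list[np.ndarray]:
    """Random partition of ``range(n)`` into k equal disjoint index sets.

    Stratified mode deals each class round-robin across folds so outcome
    labels are as balanced as the counts allow.
    """
    if n % k != 0:
        raise ValueError(f"k={k} does not divide n={n}")
    rng = np.random.default_rng(seed)
    if stratified:
        if labels is None:
            raise ValueError("stratified folds need labels")
        order = []
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            order.extend(rng.permutation(idx))
        folds: list[list[int]] = [[] for _ in range(k)]
        for pos, idx in enumerate(order):
            folds[pos % k].append(int(idx))
        return [np.sort(np.array(f)) for f in folds]
    perm = rng.permutation(n)
    return [np.sort(perm[i::k]) for i in range(k)]


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {"sensitivity": self.sensitivity, "specificity": self.specificity,
                "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy}


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """The five threshold metrics; zero-denominator ratios are NaN-flagged."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int, name: str, flags: list[str]) -> float:
        if den == 0:
            flags.append(name)
            return math.nan
        return num / den

    flags: list[str] = []
    return ConfusionMetrics(
        sensitivity=ratio(tp, tp + fn, "sensitivity", flags),
        specificity=ratio(tn, tn + fp, "specificity", flags),
        ppv=ratio(tp, tp + fp, "ppv", flags),
        npv=ratio(tn, tn + fn, "npv", flags),
        accuracy=(tp + tn) / total,
        degenerate=tuple(flags),
    )


def _counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return tp, fp, tn, fn


# --------------------------------------------------------------------------
# inner scoring
# --------------------------------------------------------------------------

def _inner_cv_accuracy(x: np.ndarray, y: np.ndarray,
                       splits: list[tuple[np.ndarray, np.ndarray]],
                       gamma: float, c: float, class_weighted: bool) -> float:
    correct = 0
    total = 0
    for tr, te in splits:
        pred = svm_predict(x[tr], y[tr], x[te], gamma, c, class_weighted)
        correct += int((pred == y[te]).sum())
        total += te.size
    return correct / total


def _resubstitution_accuracy(x: np.ndarray, y: np.ndarray,
                             gamma: float, c: float, class_weighted: bool) -> float:
    pred = svm_predict(x, y, x, gamma, c, class_weighted)
    return float((pred == y).mean())


def _make_inner_splits(n: int, k: int, rng: np.random.Generator,
                       repeats: int = 1) -> list[tuple[np.ndarray, np.ndarray]]:
    splits = []
    for _ in range(repeats):
        perm = rng.permutation(n)
        parts = [np.sort(perm[i::k]) for i in range(k)]
        for i in range(k):
            te = parts[i]
            tr = np.sort(np.concatenate([parts[j] for j in range(k) if j != i]))
            splits.append((tr, te))
    return splits


# --------------------------------------------------------------------------
# grid search
# --------------------------------------------------------------------------

def grid_search(x: np.ndarray, y: np.ndarray, cfg: SvmConfig,
                splits: list[tuple[np.ndarray, np.ndarray]],
                ) -> tuple[float, float, np.ndarray]:
    """Exhaustive (gamma, C) search scored by inner-CV accuracy.

    Returns the best pair and the full score surface, shaped
    (len(gamma grid), len(C grid)).  Ties break toward smaller C, then
    smaller gamma.
    """
    if np.unique(y).size < 2:
        raise ValueError("degenerate single-class training set")
    surface = np.empty((len(cfg.gamma_exponents), len(cfg.c_exponents)))
    for gi, gamma in enumerate(cfg.gammas):
        for ci, c in enumerate(cfg.cs):
            surface[gi, ci] = _inner_cv_accuracy(x, y, splits, gamma, c,
                                                 cfg.class_weighted)
    best = surface.max()
    ties = np.argwhere(surface == best)
    # smallest C first, then smallest gamma
    ci, gi = min((c, g) for g, c in ties)
    return float(cfg.gammas[gi]), float(cfg.cs[ci]), surface


# --------------------------------------------------------------------------
# backward sequential elimination
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EliminationTrace:
    """Record of one backward-elimination run.

    ``removed`` lists (iteration, feature, score-of-surviving-subset) in
    elimination order.  ``ranking`` orders all features best-first: the
    last survivor first, the first-eliminated feature last (its rank is
    the iteration at which it was removed).  ``selected`` is the prefix of
    the ranking with the best score (smallest on ties).
    """

    removed: tuple[tuple[int, str, float], ...]
    ranking: tuple[str, ...]
    subset_scores: dict[int, float] = field(repr=False, default_factory=dict)
    selected: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        eliminated = {f for _, f, _ in self.removed}
        if len(set(self.ranking)) != len(self.ranking) or \
                not eliminated <= set(self.ranking):
            raise ValueError("ranking must be a permutation of the feature set")
        if self.removed and len(self.ranking) != len(self.removed) + 1:
            raise ValueError("ranking must cover every feature exactly once")


def backward_eliminate(x: np.ndarray, y: np.ndarray, feature_names: list[str],
                       cfg: SvmConfig, gamma: float, c: float,
                       splits: list[tuple[np.ndarray, np.ndarray]] | None,
                       ) -> EliminationTrace:
    """Backward sequential elimination down to a single feature.

    Each iteration scores every candidate one-feature-removal and drops
    the feature whose removal leaves the highest score — the feature with
    the least impact on performance.  Ties break toward the earliest
    feature in the fixed roster order.  Scoring is inner-CV accuracy (or
    resubstitution when configured).  The selected subset is the
    best-scoring prefix of the resulting ranking.

    ``gamma`` is the width tuned on the full feature set; a subset of k of
    the k0 starting features is scored with gamma * k0 / k.  For
    standardized features the expected squared distance between points
    grows linearly with the feature count, so this keeps the effective
    kernel bandwidth constant along the elimination path instead of
    letting small subsets collapse to a nearly-flat kernel.
    """
    if len(feature_names) != x.shape[1]:
        raise ValueError("feature_names must match the design matrix")
    if len(feature_names) < 2:
        raise ValueError("need at least 2 features to eliminate")
    k0 = x.shape[1]

    def score(cols: list[int]) -> float:
        xs = x[:, cols]
        g = gamma * k0 / len(cols)
        if cfg.elimination_scoring == "inner_cv" and splits is not None:
            val = _inner_cv_accuracy(xs, y, splits, g, c, cfg.class_weighted)
        else:
            val = _resubstitution_accuracy(xs, y, g, c, cfg.class_weighted)
        if not math.isfinite(val):
            raise ValueError("non-finite elimination score")
        return val

    alive = list(range(len(feature_names)))
    subset_scores = {len(alive): score(alive)}
    removed: list[tuple[int, str, float]] = []
    iteration = 0
    while len(alive) > 1:
        iteration += 1
        best_score, best_pos = -np.inf, 0
        for pos in range(len(alive)):
            cand = alive[:pos] + alive[pos + 1:]
            s = score(cand)
            if s > best_score:  # strict: ties keep the earliest-roster drop
                best_score, best_pos = s, pos
        dropped = alive.pop(best_pos)
        removed.append((iteration, feature_names[dropped], best_score))
        subset_scores[len(alive)] = best_score

    ranking = [feature_names[alive[0]]] + [f for _, f, _ in reversed(removed)]
    best_size = max(subset_scores, key=lambda size: (subset_scores[size], -size))
    return EliminationTrace(
        removed=tuple(removed),
        ranking=tuple(ranking),
        subset_scores=subset_scores,
        selected=tuple(ranking[:best_size]),
    )


# --------------------------------------------------------------------------
# nested cross-validation
# --------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold: int
    train_counts: tuple[int, int, int, int]  # TP, FP, TN, FN
    val_counts: tuple[int, int, int, int]
    train_metrics: ConfusionMetrics
    val_metrics: ConfusionMetrics
    trace: EliminationTrace
    gamma: float
    c: float
    val_index: np.ndarray
    val_predictions: np.ndarray


@dataclass
class CVExperimentResult:
    folds: list[FoldResult]
    mean_train: dict[str, float]
    mean_val: dict[str, float]
    selection_frequency: dict[str, int]

    def as_report(self) -> dict:
        return {
            "mean_train": self.mean_train,
            "mean_validation": self.mean_val,
            "selection_frequency": self.selection_frequency,
            "folds": [
                {
                    "fold": f.fold,
                    "gamma": f.gamma,
                    "C": f.c,
                    "train_counts": list(f.train_counts),
                    "val_counts": list(f.val_counts),
                    "train_metrics": f.train_metrics.as_dict(),
                    "val_metrics": f.val_metrics.as_dict(),
                    "ranking": list(f.trace.ranking),
                    "selected": list(f.trace.selected),
                }
                for f in self.folds
            ],
        }


def _encode_labels(outcomes: pd.Series, positive_label: str) -> np.ndarray:
    return (outcomes == positive_label).to_numpy().astype(float)


def run_fold(table: pd.DataFrame, train_idx: np.ndarray, val_idx: np.ndarray,
             cfg: SvmConfig, rng: np.random.Generator, fold_id: int = 0,
             ) -> FoldResult:
    """Train and evaluate one outer fold; touches only training labels
    during standardization, tuning and elimination."""
    feats = [c for c in FEATURE_NAMES if c in table.columns]
    std_table, _ = standardize(table, train_idx)
    x_all = std_table[feats].to_numpy(dtype=float)
    y_all = _encode_labels(table[OUTCOME_COLUMN], cfg.positive_label)
    x_tr, y_tr = x_all[train_idx], y_all[train_idx]
    x_val = x_all[val_idx]

    splits = _make_inner_splits(len(train_idx), cfg.inner_folds, rng,
                                cfg.inner_repeats)
    gamma, c, _ = grid_search(x_tr, y_tr, cfg, splits)
    trace = backward_eliminate(x_tr, y_tr, feats, cfg, gamma, c, splits)

    sel = [feats.index(f) for f in trace.selected]
    gamma_sel, c_sel, _ = grid_search(x_tr[:, sel], y_tr, cfg, splits)

    pred_tr = svm_predict(x_tr[:, sel], y_tr, x_tr[:, sel], gamma_sel, c_sel,
                          cfg.class_weighted)
    pred_val = svm_predict(x_tr[:, sel], y_tr, x_val[:, sel], gamma_sel, c_sel,
                           cfg.class_weighted)

    y_val = y_all[val_idx]
    tr_counts = _counts(y_tr, pred_tr)
    val_counts = _counts(y_val, pred_val)
    return FoldResult(
        fold=fold_id,
        train_counts=tr_counts,
        val_counts=val_counts,
        train_metrics=confusion_metrics(*tr_counts),
        val_metrics=confusion_metrics(*val_counts),
        trace=trace,
        gamma=gamma_sel,
        c=c_sel,
        val_index=np.asarray(val_idx),
        val_predictions=pred_val,
    )


def run_experiment(table: pd.DataFrame, cfg: SvmConfig = SvmConfig(),
                   seed: int = 0, k: int = 9) -> CVExperimentResult:
    """Full nested cross-validation over a complete feature table."""
    n = len(table)
    labels = _encode_labels(table[OUTCOME_COLUMN], cfg.positive_label)
    if np.unique(labels).size < 2:
        raise ValueError("need both outcome classes")
    folds = make_folds(n, k, seed, stratified=cfg.stratified, labels=labels)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(k)

    results: list[FoldResult] = []
    for i, val_idx in enumerate(folds):
        train_idx = np.sort(np.setdiff1d(np.arange(n), val_idx))
        rng = np.random.default_rng(child_seeds[i])
        try:
            results.append(run_fold(table, train_idx, val_idx, cfg, rng, fold_id=i))
        except Exception as e:
            raise RuntimeError(f"fold {i} failed: {e}") from e

    def mean_side(side: str) -> dict[str, float]:
        out = {}
        for m in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            vals = np.array([getattr(getattr(f, side), m) for f in results])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[m] = float(np.nanmean(vals))
        return out

    freq: dict[str, int] = {name: 0 for name in FEATURE_NAMES
                            if name in table.columns}
    for f in results:
        for name in f.trace.selected:
            freq[name] += 1

    return CVExperimentResult(
        folds=results,
        mean_train=mean_side("train_metrics"),
        mean_val=mean_side("val_metrics"),
        selection_frequency=freq,
    )
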