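"""SVM engine: fold bookkeeping, confusion metrics, grid-search identity,
backward elimination behavior and leakage instrumentation."""

import numpy as np
import pandas as pd
import pytest

from sinoradiomics import selection as sel
from sinoradiomics.features import FEATURE_NAMES, OUTCOME_COLUMN


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def test_make_folds_partition():
    folds = sel.make_folds(36, 9, seed=1)
    assert len(folds) == 9
    assert all(len(f) == 4 for f in folds)
    union = np.sort(np.concatenate(folds))
    np.testing.assert_array_equal(union, np.arange(36))  # disjoint cover


def test_make_folds_reproducible_and_seed_sensitive():
    a = sel.make_folds(36, 9, seed=2)
    b = sel.make_folds(36, 9, seed=2)
    c = sel.make_folds(36, 9, seed=3)
    assert all(np.array_equal(x, y) for x, y in zip(a, b))
    assert any(not np.array_equal(x, y) for x, y in zip(a, c))


def test_make_folds_rejects_non_divisor():
    with pytest.raises(ValueError):
        sel.make_folds(36, 7, seed=0)


def test_stratified_folds_balance_labels():
    labels = np.array([1.0] * 22 + [0.0] * 14)
    folds = sel.make_folds(36, 9, seed=0, stratified=True, labels=labels)
    per_fold = [labels[f].sum() for f in folds]
    assert max(per_fold) - min(per_fold) <= 1.0


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

def test_published_training_fold_metrics():
    """(TP=19, FP=1, TN=12, FN=0) reproduces the published first training
    fold: sensitivity 1, specificity 0.92, PPV 0.95, NPV 1, accuracy 0.97.
    Brute force over all confusion matrices at n=32 finds exactly two
    integer solutions, (19,1,12,0) and (20,1,11,0) — the two possible
    control counts (19 or 20 of 32) after holding out 4 of 22 controls."""
    m = sel.confusion_metrics(19, 1, 12, 0)
    assert round(m.sensitivity, 2) == 1.0
    assert round(m.specificity, 2) == 0.92
    assert round(m.ppv, 2) == 0.95
    assert round(m.npv, 2) == 1.0
    assert round(m.accuracy, 2) == 0.97

    solutions = []
    for tp in range(33):
        for fp in range(33 - tp):
            for tn in range(33 - tp - fp):
                fn = 32 - tp - fp - tn
                c = sel.confusion_metrics(tp, fp, tn, fn)
                if c.degenerate:
                    continue
                if (round(c.sensitivity, 2), round(c.specificity, 2),
                        round(c.ppv, 2), round(c.npv, 2),
                        round(c.accuracy, 2)) == (1.0, 0.92, 0.95, 1.0, 0.97):
                    solutions.append((tp, fp, tn, fn))
    assert solutions == [(19, 1, 12, 0), (20, 1, 11, 0)]


def test_metric_edge_cases():
    perfect = sel.confusion_metrics(10, 0, 5, 0)
    assert perfect.as_dict() == {k: 1.0 for k in perfect.as_dict()}
    miss = sel.confusion_metrics(0, 0, 5, 3)
    assert miss.sensitivity == 0.0
    no_pos = sel.confusion_metrics(0, 0, 5, 0)
    assert "sensitivity" in no_pos.degenerate
    assert np.isnan(no_pos.sensitivity)
    with pytest.raises(ValueError):
        sel.confusion_metrics(-1, 0, 0, 1)
    with pytest.raises(ValueError):
        sel.confusion_metrics(0, 0, 0, 0)


# ---------------------------------------------------------------------------
# SVM engine equivalence
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(6))
def test_fast_engine_matches_svc(seed):
    """The low-level libsvm path predicts identically to the public SVC
    estimator across random problems and hyperparameters."""
    rng = np.random.default_rng(seed)
    x_tr = rng.normal(size=(24, 7))
    y_tr = rng.integers(0, 2, 24).astype(float)
    if len(np.unique(y_tr)) < 2:
        y_tr[0] = 1 - y_tr[0]
    x_te = rng.normal(size=(10, 7))
    gamma = float(2.0 ** rng.integers(-12, 4))
    c = float(2.0 ** rng.integers(-6, 8))
    fast = sel.svm_predict(x_tr, y_tr, x_te, gamma, c)
    ref = sel.svm_predict(x_tr, y_tr, x_te, gamma, c, engine="svc")
    np.testing.assert_array_equal(fast, ref)


def test_single_class_train_predicts_constant():
    x = np.zeros((5, 2))
    pred = sel.svm_predict(x, np.ones(5), np.zeros((3, 2)), 0.1, 1.0)
    assert np.all(pred == 1.0)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def _toy_problem(rng, n=32, k=5, shift=1.5):
    y = np.array([1.0] * (n // 2) + [0.0] * (n - n // 2))
    x = rng.normal(size=(n, k)) + shift * y[:, None]
    return x, y


def test_grid_search_single_point_grid(rng):
    x, y = _toy_problem(rng)
    cfg = sel.SvmConfig(gamma_exponents=(-3,), c_exponents=(2,))
    splits = sel._make_inner_splits(len(y), 4, rng)
    g, c, surface = sel.grid_search(x, y, cfg, splits)
    assert (g, c) == (2.0 ** -3, 2.0 ** 2)
    assert surface.shape == (1, 1)


def test_grid_search_default_surface_dimensions(rng):
    x, y = _toy_problem(rng)
    cfg = sel.SvmConfig()
    splits = sel._make_inner_splits(len(y), 4, rng, 1)
    _, _, surface = sel.grid_search(x, y, cfg, splits)
    assert surface.shape == (31, 21)


def test_grid_search_matches_brute_force_oracle(rng):
    """The returned pair and surface equal an independent enumeration of
    the grid through the public SVC estimator."""
    x, y = _toy_problem(rng, k=3)
    cfg = sel.SvmConfig(gamma_exponents=tuple(range(-6, -1)),
                        c_exponents=tuple(range(-2, 3)))
    splits = sel._make_inner_splits(len(y), 4, rng, 1)
    g, c, surface = sel.grid_search(x, y, cfg, splits)

    oracle = np.empty_like(surface)
    for gi, ge in enumerate(cfg.gamma_exponents):
        for ci, ce in enumerate(cfg.c_exponents):
            correct = 0
            for tr, te in splits:
                pred = sel.svm_predict(x[tr], y[tr], x[te], 2.0 ** ge, 2.0 ** ce,
                                       engine="svc")
                correct += (pred == y[te]).sum()
            oracle[gi, ci] = correct / len(y)
    np.testing.assert_array_equal(surface, oracle)
    best = oracle.max()
    ties = [(ce, ge) for gi, ge in enumerate(cfg.gamma_exponents)
            for ci, ce in enumerate(cfg.c_exponents) if oracle[gi, ci] == best]
    ce, ge = min(ties)
    assert (g, c) == (2.0 ** ge, 2.0 ** ce)


def test_grid_search_single_class_raises(rng):
    x = rng.normal(size=(8, 2))
    with pytest.raises(ValueError, match="single-class"):
        sel.grid_search(x, np.ones(8), sel.SvmConfig(),
                        sel._make_inner_splits(8, 4, rng))


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------

def test_constant_feature_eliminated_first(rng):
    x, y = _toy_problem(rng, k=1)
    x = np.hstack([x, np.zeros((len(y), 1))])  # constant second feature
    splits = sel._make_inner_splits(len(y), 4, rng)
    trace = sel.backward_eliminate(x, y, ["informative", "constant"],
                                   sel.SvmConfig(), 0.25, 4.0, splits)
    assert trace.removed[0][1] == "constant"
    assert trace.ranking == ("informative", "constant")


def test_trace_lengths(rng):
    x, y = _toy_problem(rng, k=6)
    names = [f"f{i}" for i in range(6)]
    splits = sel._make_inner_splits(len(y), 4, rng)
    trace = sel.backward_eliminate(x, y, names, sel.SvmConfig(), 0.1, 2.0, splits)
    assert len(trace.removed) == 5          # down to a single survivor
    assert sorted(trace.ranking) == sorted(names)
    assert set(trace.selected) <= set(names)
    assert len(trace.subset_scores) == 6    # sizes 6..1


def test_informative_features_outrank_noise():
    """Three strongly informative features (effect 1.5 SD each) rank above
    three pure-noise features in >= 90% of 50 seeded runs.  The sample
    size (200) is chosen so the marginal contribution of the weakest
    informative feature clears the sampling fluctuation of a noise
    feature's spurious separation; at a few dozen samples those
    fluctuations overlap and no ranking scheme can separate them."""
    wins = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        n = 200
        y = np.array([1.0] * (n // 2) + [0.0] * (n // 2))
        info = rng.normal(size=(n, 3)) + 1.5 * y[:, None]
        noise = rng.normal(size=(n, 3))
        x = np.hstack([info, noise])
        names = ["i0", "i1", "i2", "n0", "n1", "n2"]
        splits = sel._make_inner_splits(n, 4, rng, repeats=4)
        trace = sel.backward_eliminate(x, y, names, sel.SvmConfig(),
                                       1.0 / 6.0, 10.0, splits)
        top3 = set(trace.ranking[:3])
        wins += top3 == {"i0", "i1", "i2"}
    assert wins >= 45


# ---------------------------------------------------------------------------
# nested experiment
# ---------------------------------------------------------------------------

def _clean_table(seed=11):
    from sinoradiomics import cohort as co
    recs = co.sample_cohort(seed=seed)
    rows = [{"id": r["id"], **{f: r[f] for f in FEATURE_NAMES},
             OUTCOME_COLUMN: r["outcome"]} for r in recs]
    return pd.DataFrame(rows, columns=["id", *FEATURE_NAMES, OUTCOME_COLUMN])


def test_run_experiment_bookkeeping():
    table = _clean_table()
    res = sel.run_experiment(table, sel.SvmConfig(), seed=1)
    assert len(res.folds) == 9
    validated = np.sort(np.concatenate([f.val_index for f in res.folds]))
    np.testing.assert_array_equal(validated, np.arange(36))  # each patient once
    for f in res.folds:
        assert sum(f.train_counts) == 32
        assert sum(f.val_counts) == 4
        # metrics recomputable from counts
        assert f.val_metrics.accuracy == pytest.approx(
            (f.val_counts[0] + f.val_counts[2]) / 4)
    # mean metrics equal the nan-mean of per-fold metrics
    accs = [f.val_metrics.accuracy for f in res.folds]
    assert res.mean_val["accuracy"] == pytest.approx(np.nanmean(accs))
    # selection frequencies sum to the total of subset sizes
    assert sum(res.selection_frequency.values()) == sum(
        len(f.trace.selected) for f in res.folds)


def test_no_leakage_from_validation_rows():
    """Poisoning the held-out labels (and features) must not change the
    trained model: predictions, trace and hyperparameters are identical."""
    table = _clean_table()
    n = len(table)
    val_idx = np.arange(4)
    train_idx = np.arange(4, n)
    cfg = sel.SvmConfig()

    poisoned = table.copy()
    flip = {"control": "failure", "failure": "control"}
    poisoned.loc[poisoned.index[:4], OUTCOME_COLUMN] = [
        flip[v] for v in poisoned[OUTCOME_COLUMN][:4]]

    a = sel.run_fold(table, train_idx, val_idx, cfg, np.random.default_rng(5))
    b = sel.run_fold(poisoned, train_idx, val_idx, cfg, np.random.default_rng(5))
    np.testing.assert_array_equal(a.val_predictions, b.val_predictions)
    assert a.trace.ranking == b.trace.ranking
    assert (a.gamma, a.c) == (b.gamma, b.c)
    assert a.train_counts == b.train_counts


def test_experiment_deterministic():
    table = _clean_table()
    a = sel.run_experiment(table, sel.SvmConfig(), seed=3)
    b = sel.run_experiment(table, sel.SvmConfig(), seed=3)
    assert a.mean_val == b.mean_val
    assert all(x.trace.ranking == y.trace.ranking for x, y in zip(a.folds, b.folds))


def test_experiment_rejects_single_class():
    table = _clean_table()
    table[OUTCOME_COLUMN] = "control"
    with pytest.raises(ValueError):
        sel.run_experiment(table, sel.SvmConfig(), seed=0)
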