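"""Decoder tests: fold integrity, probing, subset manipulations and
independent oracles (nearest-centroid; exhaustive max-margin separator)."""

import numpy as np
import pytest

from icdecode import decode
from icdecode.decode import (holo_psth_contrast, nonphoto_mask, probe,
                             train_cv_decoder, train_subset, tre_inference,
                             validate_targets, xre_inference, zero_out)


def _gaussian_classes(rng, means, n_per=40, sd=1.0):
    X, y = [], []
    for lab, mu in means.items():
        X.append(rng.normal(0, sd, (n_per, len(mu))) + np.asarray(mu))
        y += [lab] * n_per
    return np.vstack(X), np.array(y)


def test_orthogonal_patterns_decode_perfectly(rng):
    means = {c: list(np.eye(4)[i] * 5) for i, c in
             enumerate(["I_C1", "I_C2", "L_C1", "L_C2"])}
    X, y = _gaussian_classes(rng, means, sd=0.05)
    _, res = train_cv_decoder(X, y, seed=0)
    assert res.cv_accuracy == 1.0


def test_fold_integrity(rng):
    X, y = _gaussian_classes(rng, {"a": [0, 0], "b": [1, 1]}, n_per=25)
    model, _ = train_cv_decoder(X, y, seed=1)
    all_test = np.concatenate([f.test_idx for f in model.folds])
    assert sorted(all_test) == list(range(len(y)))      # disjoint + cover
    for f in model.folds:
        assert set(f.train_idx).isdisjoint(f.test_idx)  # no leakage
        assert np.allclose(f.mean, X[f.train_idx].mean(axis=0))


def test_class_with_too_few_trials_raises(rng):
    X = rng.normal(size=(15, 3))
    y = np.array(["a"] * 12 + ["b"] * 3)
    with pytest.raises(ValueError, match="trials"):
        train_cv_decoder(X, y, k=10)


def test_confusion_rows_and_probe_fractions_are_distributions(rng):
    X, y = _gaussian_classes(rng, {"a": [1, 0], "b": [0, 1], "c": [1, 1]})
    model, res = train_cv_decoder(X, y, seed=2)
    assert np.allclose(res.confusion.sum(axis=1), 1.0)
    fr = probe(model, rng.normal(size=(30, 2)))
    assert fr.sum() == pytest.approx(1.0)


def test_probe_with_class_mean_pattern(rng):
    means = {"a": [3.0, 0.0], "b": [0.0, 3.0]}
    X, y = _gaussian_classes(rng, means)
    model, _ = train_cv_decoder(X, y, seed=3)
    fr = probe(model, np.tile(means["a"], (50, 1)))
    assert fr["a"] > 0.99


def test_null_probe_fraction_near_uniform(rng):
    """A pure-noise probe lands on each class about a quarter of the time
    on average over realizations (single sessions fluctuate)."""
    means = {c: list(mu) for c, mu in zip("abcd", 3 * np.eye(4))}
    fr = np.zeros(4)
    n_rep = 6
    for k in range(n_rep):
        X, y = _gaussian_classes(rng, means, n_per=50)
        model, _ = train_cv_decoder(X, y, seed=k)
        fr += probe(model, rng.normal(0, 1, (400, 4))).to_numpy()
    assert np.all(np.abs(fr / n_rep - 0.25) < 0.08)


def test_agreement_with_nearest_centroid_oracle(rng):
    """Held-out accuracy within +/-0.05 of an independent nearest-centroid
    oracle on overlapping Gaussian classes."""
    means = {c: list(mu) for c, mu in zip("abcd", 1.5 * np.eye(4))}
    X, y = _gaussian_classes(rng, means, n_per=100)
    _, res = train_cv_decoder(X, y, seed=5)
    # oracle: leave-one-out nearest centroid, written independently
    correct = 0
    for i in range(len(y)):
        cents = {}
        for lab in means:
            m = (y == lab)
            m[i] = False
            cents[lab] = X[m].mean(axis=0)
        pred = min(cents, key=lambda l: np.sum((X[i] - cents[l]) ** 2))
        correct += pred == y[i]
    assert res.cv_accuracy == pytest.approx(correct / len(y), abs=0.05)


def _enumerated_max_margin(X, y):
    """Brute-force maximum-margin linear separator on 2D data: scan the
    boundary angle densely; for each direction take the midpoint threshold
    maximizing the margin."""
    best = (-np.inf, None, None)
    for ang in np.linspace(0, np.pi, 3600, endpoint=False):
        w = np.array([np.cos(ang), np.sin(ang)])
        p = X @ w
        lo, hi = p[y == 0], p[y == 1]
        for sign in (1.0, -1.0):
            a, b = (lo, hi) if sign > 0 else (hi, lo)
            margin = b.min() - a.max()
            if margin > best[0]:
                thr = (a.max() + b.min()) / 2.0
                best = (margin, sign * w, sign * thr)
    _, w, thr = best
    return lambda Z: (Z @ w > thr).astype(int)


def test_two_neuron_separable_matches_margin_oracle(rng):
    X0 = rng.normal(0, 0.4, (30, 2)) + [0.0, 0.0]
    X1 = rng.normal(0, 0.4, (30, 2)) + [3.0, 2.0]
    X = np.vstack([X0, X1])
    y01 = np.array([0] * 30 + [1] * 30)
    y = np.array(["n", "p"])[y01]
    model, _ = train_cv_decoder(X, y, k=5, seed=6)
    oracle = _enumerated_max_margin(
        (X - X.mean(0)) / X.std(0), y01)  # oracle on comparable scaling
    grid = rng.normal(1.5, 1.5, (300, 2))
    fr_grid = []
    for fold in model.folds:
        Z = fold.standardize(grid)
        pred = decode._fold_predict(fold, model.classes, Z)
        fr_grid.append(pred)
    got = np.round(np.mean(fr_grid, axis=0)).astype(int)  # majority of folds
    want = oracle((grid - X.mean(0)) / X.std(0))
    assert np.mean(got == want) > 0.97


def test_permutation_equivariance(rng):
    means = {"a": [2, 0, 1], "b": [0, 2, 0]}
    X, y = _gaussian_classes(rng, means)
    model, res = train_cv_decoder(X, y, seed=7)
    perm = np.array([2, 0, 1])
    model_p, res_p = train_cv_decoder(X[:, perm], y, seed=7)
    assert res_p.cv_accuracy == pytest.approx(res.cv_accuracy)
    Z = rng.normal(size=(40, 3))
    assert np.allclose(probe(model, Z).to_numpy(),
                       probe(model_p, Z[:, perm]).to_numpy())


def test_zero_out_empty_subset_is_identity(rng):
    means = {"a": [2, 0], "b": [0, 2]}
    X, y = _gaussian_classes(rng, means)
    model, res = train_cv_decoder(X, y, seed=8)
    res0 = zero_out(model, X, y, np.array([], dtype=int))
    assert res0.cv_accuracy == res.cv_accuracy
    assert np.allclose(res0.confusion, res.confusion)


def test_zero_out_everything_destroys_information(rng):
    means = {c: list(mu) for c, mu in zip("abcd", 4 * np.eye(4))}
    X, y = _gaussian_classes(rng, means, n_per=30)
    model, res = train_cv_decoder(X, y, seed=9)
    assert res.cv_accuracy > 0.9
    res0 = zero_out(model, X, y, np.arange(4))
    assert res0.cv_accuracy <= 0.5  # at or below constant-class levels


def test_train_subset_all_equals_full(rng):
    means = {"a": [2, 0], "b": [0, 2]}
    X, y = _gaussian_classes(rng, means)
    _, full = train_cv_decoder(X, y, seed=10)
    _, sub = train_subset(X, y, np.arange(2), seed=10)
    assert sub.cv_accuracy == full.cv_accuracy


def test_zero_variance_column_floored(rng):
    X, y = _gaussian_classes(rng, {"a": [2, 0], "b": [0, 2]})
    X = np.hstack([X, np.ones((len(y), 1))])  # constant neuron
    model, res = train_cv_decoder(X, y, seed=11)
    assert np.isfinite(res.cv_accuracy)
    assert res.cv_accuracy > 0.9


def test_xre_requires_binary_xre_decoder(rng):
    X, y = _gaussian_classes(rng, {"a": [1, 0], "b": [0, 1]})
    model, _ = train_cv_decoder(X, y, seed=12)
    with pytest.raises(ValueError, match="X_RE"):
        xre_inference(model, X, X)


def test_xre_on_training_stimuli_tracks_cv_accuracy(rng):
    means = {"X_RE1": [1.5, 0.0], "X_RE2": [0.0, 1.5]}
    X, y = _gaussian_classes(rng, means, n_per=80)
    model, res = train_cv_decoder(X, y, seed=13)
    score = xre_inference(model, X[y == "X_RE1"], X[y == "X_RE2"])
    assert score == pytest.approx(res.cv_accuracy, abs=0.1)


def test_tre_inference_signs(rng):
    means = {"I_C1": [3, 0, 0, 0], "I_C2": [0, 3, 0, 0],
             "L_C1": [0, 0, 3, 0], "L_C2": [0, 0, 0, 3]}
    X, y = _gaussian_classes(rng, means, n_per=40)
    model, _ = train_cv_decoder(X, y, seed=14)
    tre1 = rng.normal(0, 0.5, (40, 4)) + means["I_C1"]
    tre2 = rng.normal(0, 0.5, (40, 4)) + means["I_C2"]
    sc = tre_inference(model, tre1, tre2)
    assert sc.frac_ic > 0.95 and sc.frac_lc < 0.05
    assert sc.score == pytest.approx(sc.frac_ic - sc.frac_lc)
    assert sc.frac_ic + sc.frac_lc <= 1.0


# ---------------------------------------------------------------------------
# holography geometry helpers

def test_nonphoto_mask_distance_rule():
    import pandas as pd

    neurons = pd.DataFrame({"id": [0, 1, 2],
                            "x_um": [0.0, 49.0, 200.0],
                            "y_um": [0.0, 0.0, 0.0]})
    mask = nonphoto_mask(neurons, np.array([[0.0, 0.0]]), min_dist_um=50.0)
    assert list(mask) == [False, False, True]  # 49 um is excluded


def test_validate_targets_rule():
    import pandas as pd

    neurons = pd.DataFrame({"id": [0], "x_um": [0.0], "y_um": [0.0]})
    targets = np.array([[5.0, 0.0], [11.0, 0.0]])
    valid = validate_targets(targets, neurons, tolerance_um=10.0)
    assert list(valid) == [True, False]


def test_holo_psth_contrast_identical_groups(rng):
    t = np.linspace(-1.0, 2.0, 24)
    frames = rng.normal(size=(20, 10, 24))
    ens = np.array(["e1"] * 10 + ["e2"] * 10, dtype=object)
    ic_resp = {"e1": np.arange(10) < 5, "e2": np.arange(10) < 5}
    # make the two neuron groups exchangeable: zero planted signal
    table, p = holo_psth_contrast(frames, t, ens, ic_resp)
    assert np.all(np.abs(table["difference"]) < 0.2)


def test_holo_psth_contrast_planted_drive(rng):
    t = np.linspace(-1.0, 2.0, 24)
    win = (t >= 0) & (t < 1)
    frames = rng.normal(size=(20, 10, 24))
    ic_mask = np.arange(10) < 5
    frames[np.ix_(np.arange(10), np.flatnonzero(ic_mask), np.flatnonzero(win))] += 3.0
    ens = np.array(["e1"] * 10 + ["e2"] * 10, dtype=object)
    table, p = holo_psth_contrast(frames, t, ens,
                                  {"e1": ic_mask, "e2": ic_mask})
    d = dict(zip(table["ensemble"], table["difference"]))
    assert d["e1"] > 2.0
    assert abs(d["e2"]) < 0.5
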