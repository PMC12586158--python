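"""Cross-validated multiclass linear decoding and inference decoding.

The central procedure: a linear support vector machine is trained to
classify trial-wise population responses to the four training images
(I_C1 / L_C1 / L_C2 / I_C2) with stratified 10-fold cross-validation; each
fold standardizes the response matrix by its *training* trials only. The
trained fold models are then probed with held-out stimulus types:

* **T_RE inference**: probe trials from the real-edge images with equal
  pixel overlap with an I_C and an L_C image. The inference score is the
  fraction of T_RE trials classified as the corresponding I_C minus the
  fraction classified as the corresponding L_C (averaged across the two
  image sets). Chance is 0 for a population faithful to the pixels.
* **X_RE inference**: a binary decoder trained on X_RE1 vs X_RE2 is probed
  with I_C trials; the score is the average probability that I_C1 is
  decoded as X_RE1 and I_C2 as X_RE2 (chance 0.5).
* **Subset manipulations**: zeroing out a neuron subset in the decoder
  input after training (columns zeroed after per-fold standardization), or
  training only on a subset.
* **Holography cross-decoding**: fold models trained on visual activity
  classify holography-evoked activity (normalized per neuron across all
  holography trials) and the expected-label fraction per targeted ensemble
  is compared to chance 0.25.

The multiclass scheme is one-vs-one with majority vote; ties break by
summed decision-function margins, then by lowest class index. C = 1 by
default. Zero-variance training columns have their SD floored at a
machine-epsilon-scaled constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "DecoderModel",
    "DecodeResult",
    "InferenceScore",
    "train_cv_decoder",
    "probe",
    "tre_inference",
    "xre_inference",
    "zero_out",
    "train_subset",
    "holo_cross_decode",
    "nonphoto_mask",
    "validate_targets",
    "holo_psth_contrast",
]

_SD_FLOOR = 1e4 * np.finfo(float).eps


@dataclass
class _Fold:
    train_idx: np.ndarray
    test_idx: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    clfs: dict[tuple[int, int], SVC]  # (class index a, b) -> binary SVM

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


@dataclass
class DecoderModel:
    folds: list[_Fold]
    classes: np.ndarray           # sorted label set
    n_neurons: int
    neuron_subset: np.ndarray | None = None  # ids, when trained on a subset

    @property
    def k(self) -> int:
        return len(self.folds)


@dataclass
class DecodeResult:
    cv_accuracy: float
    fold_accuracies: np.ndarray
    confusion: pd.DataFrame       # rows = true label, row-normalized
    classes: np.ndarray


@dataclass
class InferenceScore:
    frac_ic: float
    frac_lc: float
    fractions: pd.DataFrame       # probe label x training label

    @property
    def score(self) -> float:
        return self.frac_ic - self.frac_lc


def _fold_predict(fold: _Fold, classes: np.ndarray, Xs: np.ndarray
                  ) -> np.ndarray:
    """One-vs-one majority vote with margin then lowest-index tie-breaks."""
    n = Xs.shape[0]
    k = len(classes)
    votes = np.zeros((n, k))
    margins = np.zeros((n, k))
    for (a, b), clf in fold.clfs.items():
        dec = clf.decision_function(Xs)  # > 0 -> class b (fit with y = 1[b])
        bwin = dec > 0
        votes[bwin, b] += 1
        votes[~bwin, a] += 1
        margins[:, b] += dec
        margins[:, a] -= dec
    pred = np.empty(n, dtype=int)
    top = votes.max(axis=1)
    for i in range(n):
        tied = np.flatnonzero(votes[i] == top[i])
        if len(tied) == 1:
            pred[i] = tied[0]
        else:
            pred[i] = tied[np.argmax(margins[i, tied])]
    return pred


def train_cv_decoder(X: np.ndarray, y: np.ndarray, k: int = 10,
                     seed: int = 0, C: float = 1.0
                     ) -> tuple[DecoderModel, DecodeResult]:
    """Stratified k-fold linear-SVM decoder with train-set standardization.

    The k test sets are disjoint and cover all trials; every class needs at
    least k trials. Returns the fold models and the cross-validated result
    (mean held-out accuracy and the row-normalized confusion matrix).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    counts = np.bincount(y_idx)
    if counts.min() < k:
        raise ValueError(f"every class needs >= {k} trials "
                         f"(smallest has {counts.min()})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[_Fold] = []
    fold_acc = np.empty(k)
    conf = np.zeros((len(classes), len(classes)))
    for fi, (tr, te) in enumerate(skf.split(X, y_idx)):
        mean = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd = np.where(sd < _SD_FLOOR, _SD_FLOOR, sd)
        fold = _Fold(train_idx=tr, test_idx=te, mean=mean, sd=sd, clfs={})
        Xtr = fold.standardize(X[tr])
        for a, b in combinations(range(len(classes)), 2):
            m = (y_idx[tr] == a) | (y_idx[tr] == b)
            clf = SVC(kernel="linear", C=C)
            clf.fit(Xtr[m], (y_idx[tr][m] == b).astype(int))
            fold.clfs[(a, b)] = clf
        pred = _fold_predict(fold, classes, fold.standardize(X[te]))
        fold_acc[fi] = float(np.mean(pred == y_idx[te]))
        np.add.at(conf, (y_idx[te], pred), 1.0)
        folds.append(fold)
    conf = conf / conf.sum(axis=1, keepdims=True)
    model = DecoderModel(folds=folds, classes=classes, n_neurons=X.shape[1])
    result = DecodeResult(cv_accuracy=float(fold_acc.mean()),
                          fold_accuracies=fold_acc,
                          confusion=pd.DataFrame(conf, index=classes,
                                                 columns=classes),
                          classes=classes)
    return model, result


def probe(model: DecoderModel, X_probe: np.ndarray,
          zero_subset: np.ndarray | None = None,
          pre_standardized: bool = False) -> pd.Series:
    """Fraction of probe trials assigned to each training label.

    Every fold model classifies every probe trial after applying that
    fold's training standardization (probe trials never influence the
    standardization); fractions are averaged over folds. ``zero_subset``
    columns are zeroed *after* standardization.
    """
    fracs = np.zeros(len(model.classes))
    for fold in model.folds:
        Xs = X_probe.copy() if pre_standardized else fold.standardize(X_probe)
        if zero_subset is not None:
            Xs[:, zero_subset] = 0.0
        pred = _fold_predict(fold, model.classes, Xs)
        fracs += np.bincount(pred, minlength=len(model.classes)) / len(pred)
    return pd.Series(fracs / model.k, index=model.classes)


def evaluate(model: DecoderModel, X: np.ndarray, y: np.ndarray,
             zero_subset: np.ndarray | None = None) -> DecodeResult:
    """Re-evaluate held-out accuracy, optionally zeroing a neuron subset
    (after per-fold standardization) in the decoder input."""
    y = np.asarray(y)
    y_idx = np.searchsorted(model.classes, y)
    fold_acc = np.empty(model.k)
    conf = np.zeros((len(model.classes),) * 2)
    for fi, fold in enumerate(model.folds):
        Xs = fold.standardize(X[fold.test_idx])
        if zero_subset is not None:
            Xs[:, zero_subset] = 0.0
        pred = _fold_predict(fold, model.classes, Xs)
        fold_acc[fi] = float(np.mean(pred == y_idx[fold.test_idx]))
        np.add.at(conf, (y_idx[fold.test_idx], pred), 1.0)
    conf = conf / np.maximum(conf.sum(axis=1, keepdims=True), 1.0)
    return DecodeResult(cv_accuracy=float(fold_acc.mean()),
                        fold_accuracies=fold_acc,
                        confusion=pd.DataFrame(conf, index=model.classes,
                                               columns=model.classes),
                        classes=model.classes)


def zero_out(model: DecoderModel, X: np.ndarray, y: np.ndarray,
             subset: np.ndarray) -> DecodeResult:
    """Decoder performance when zeroing out ``subset`` neurons in the input
    after training (columns zeroed after per-fold standardization, so a
    zeroed column sits at the training mean in raw units)."""
    return evaluate(model, X, y, zero_subset=np.asarray(subset))


def train_subset(X: np.ndarray, y: np.ndarray, subset: np.ndarray,
                 k: int = 10, seed: int = 0, C: float = 1.0
                 ) -> tuple[DecoderModel, DecodeResult]:
    """Train a fresh decoder using only the ``subset`` columns of X."""
    subset = np.asarray(subset)
    model, result = train_cv_decoder(X[:, subset], y, k=k, seed=seed, C=C)
    model.neuron_subset = subset
    return model, result


# ---------------------------------------------------------------------------
# inference decoding

def tre_inference(model: DecoderModel, tre1: np.ndarray, tre2: np.ndarray,
                  zero_subset: np.ndarray | None = None) -> InferenceScore:
    """T_RE inference score.

    ``frac_IC`` is the mean over image sets of the fraction of T_REk probe
    trials classified as I_Ck; ``frac_LC`` analogously for L_Ck; the score
    is their difference.
    """
    f1 = probe(model, tre1, zero_subset=zero_subset)
    f2 = probe(model, tre2, zero_subset=zero_subset)
    fractions = pd.DataFrame([f1, f2], index=["T_RE1", "T_RE2"])
    frac_ic = 0.5 * (f1["I_C1"] + f2["I_C2"])
    frac_lc = 0.5 * (f1["L_C1"] + f2["L_C2"])
    return InferenceScore(frac_ic=float(frac_ic), frac_lc=float(frac_lc),
                          fractions=fractions)


def xre_inference(model: DecoderModel, ic1: np.ndarray, ic2: np.ndarray
                  ) -> float:
    """X_RE inference score: average probability that I_C1 trials are
    decoded as X_RE1 and I_C2 trials as X_RE2 (chance 0.5)."""
    if set(model.classes) != {"X_RE1", "X_RE2"}:
        raise ValueError("xre_inference expects a decoder trained on "
                         "X_RE1 vs X_RE2")
    f1 = probe(model, ic1)
    f2 = probe(model, ic2)
    return float(0.5 * (f1["X_RE1"] + f2["X_RE2"]))


def session_signed_rank(frac_ic: np.ndarray, frac_lc: np.ndarray
                        ) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-session
    (frac_IC, frac_LC)."""
    return float(stats.wilcoxon(frac_ic, frac_lc).pvalue)


# ---------------------------------------------------------------------------
# holography cross-decoding

def nonphoto_mask(neurons: pd.DataFrame, target_xy_um: np.ndarray,
                  min_dist_um: float = 50.0) -> np.ndarray:
    """Neurons strictly farther than ``min_dist_um`` from every target
    (the non-photoactivated population; 50 um for the standard setup,
    25 um for the mesoscope)."""
    xy = neurons[["x_um", "y_um"]].to_numpy()
    target_xy_um = np.atleast_2d(np.asarray(target_xy_um, dtype=float))
    d = np.linalg.norm(xy[:, None, :] - target_xy_um[None, :, :], axis=2)
    return d.min(axis=1) > min_dist_um


def validate_targets(target_xy_um: np.ndarray, neurons: pd.DataFrame,
                     tolerance_um: float = 10.0) -> np.ndarray:
    """A target coordinate is valid iff the closest neuron lies within
    ``tolerance_um``. Returns the boolean validity mask."""
    xy = neurons[["x_um", "y_um"]].to_numpy()
    target_xy_um = np.atleast_2d(np.asarray(target_xy_um, dtype=float))
    d = np.linalg.norm(target_xy_um[:, None, :] - xy[None, :, :], axis=2)
    return d.min(axis=1) <= tolerance_um


def holo_cross_decode(model: DecoderModel, holo_X: np.ndarray,
                      holo_ensembles: np.ndarray,
                      expected_label: dict[str, str],
                      standardize: str = "holo"
                      ) -> tuple[pd.DataFrame, float]:
    """Classify holography-evoked activity with a visually trained decoder.

    ``holo_X`` is (holography trials x neurons), column-matched to the
    decoder's input population. With ``standardize="holo"`` (the default)
    each neuron is z-scored across all holography trials and fed to the
    fold classifiers directly; with ``"fold"`` each fold's visual training
    standardization is applied instead.

    Returns a per-ensemble table with the fraction of its trials assigned
    the expected visual label (fold-averaged) and the one-tailed Wilcoxon
    signed-rank p-value of those fractions against chance 0.25.
    """
    holo_ensembles = np.asarray(holo_ensembles, dtype=object)
    if holo_X.shape[1] != model.n_neurons:
        raise ValueError("holography matrix does not match the decoder's "
                         "neuron population")
    if standardize == "holo":
        mean = holo_X.mean(axis=0)
        sd = holo_X.std(axis=0)
        sd = np.where(sd < _SD_FLOOR, _SD_FLOOR, sd)
        Xn = (holo_X - mean) / sd
        pre = True
    elif standardize == "fold":
        Xn = holo_X
        pre = False
    else:
        raise ValueError(f"unknown standardization {standardize!r}")
    rows = []
    for name, exp_label in expected_label.items():
        m = holo_ensembles == name
        if not m.any():
            continue
        fr = probe(model, Xn[m], pre_standardized=pre)
        rows.append({"ensemble": name, "expected_label": exp_label,
                     "n_trials": int(m.sum()),
                     "expected_fraction": float(fr[exp_label])})
    table = pd.DataFrame(rows)
    vals = table["expected_fraction"].to_numpy() - 0.25
    if len(vals) >= 2 and np.any(vals != 0):
        pval = float(stats.wilcoxon(vals, alternative="greater").pvalue)
    else:
        pval = np.nan
    return table, pval


def holo_psth_contrast(frames: np.ndarray, frame_t_s: np.ndarray,
                       holo_ensembles: np.ndarray,
                       ic_responsive: dict[str, np.ndarray],
                       neuron_mask: np.ndarray | None = None,
                       baseline_s: tuple[float, float] = (-1.0, 0.0),
                       window_s: tuple[float, float] = (0.0, 1.0)
                       ) -> tuple[pd.DataFrame, float]:
    """Mean holography-evoked activity of I_C-responsive vs non-responsive
    neurons among the analyzed population.

    ``frames`` is (holography trials x neurons x frames); baseline activity
    (-1 to 0 s by default) is subtracted per neuron and trial before
    averaging the stimulation window. ``ic_responsive`` maps ensemble name
    to the boolean mask of neurons visually responsive to the corresponding
    I_C image. Returns the per-ensemble mean difference and a one-tailed
    signed-rank p-value across ensembles.
    """
    holo_ensembles = np.asarray(holo_ensembles, dtype=object)
    bm = (frame_t_s >= baseline_s[0]) & (frame_t_s < baseline_s[1])
    wm = (frame_t_s >= window_s[0]) & (frame_t_s < window_s[1])
    resp = frames[:, :, wm].mean(axis=2) - frames[:, :, bm].mean(axis=2)
    if neuron_mask is None:
        neuron_mask = np.ones(frames.shape[1], dtype=bool)
    rows = []
    for name, ic_mask in ic_responsive.items():
        m = holo_ensembles == name
        if not m.any():
            continue
        pos = resp[np.ix_(m, neuron_mask & ic_mask)].mean()
        neg = resp[np.ix_(m, neuron_mask & ~ic_mask)].mean()
        rows.append({"ensemble": name, "ic_responsive_mean": float(pos),
                     "non_responsive_mean": float(neg),
                     "difference": float(pos - neg)})
    table = pd.DataFrame(rows)
    diffs = table["difference"].to_numpy()
    if len(diffs) >= 2 and np.any(diffs != 0):
        pval = float(stats.wilcoxon(diffs, alternative="greater").pvalue)
    else:
        pval = np.nan
    return table, pval
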