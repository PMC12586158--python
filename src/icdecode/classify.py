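"""Functional-ensemble classification.

Implements the univariate cell-type definitions used throughout the
analyses:

* **exclusively center-responsive** neurons: respond to the central RF-
  mapping grating patch (the illusory gap region) and to none of the eight
  surrounding positions (rank-sum vs gray trials, Holm correction over the
  nine positions);
* **IC-encoders**: respond to exactly one of the two illusory-bar images
  and to neither recombined control image (Kruskal-Wallis omnibus over
  blank / I_C1 / L_C1 / L_C2 / I_C2 followed by a Tukey-Kramer-style
  multiple comparison on mean ranks);
* **LC-encoders**: the mirror definition with I_C and L_C roles swapped;
* **segment responders**: respond more to the inward- than to the outward-
  pointing inducer segment in one quadrant (one-sided rank-sum);
* orientation-preference matching between illusory and real bars, and
  AUROC-based balancing of segment-responder ensembles for holography.

The Tukey-Kramer emulation compares mean ranks with pooled rank variance
(tie-corrected) against the studentized range critical value, mirroring the
kruskalwallis -> multcompare chain; a pairwise rank-sum + Holm fallback is
available via ``method="holm"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "find_center_exclusive",
    "find_ic_encoders",
    "find_lc_encoders",
    "find_segment_responders",
    "preferred_orientation_match",
    "auroc",
    "balance_segment_ensembles",
    "classify_session",
]

QUADRANTS = ("BR", "BL", "TL", "TR")


def _check_trials(groups: dict[str, np.ndarray], min_trials: int = 2) -> None:
    for name, arr in groups.items():
        if arr.shape[0] < min_trials:
            raise ValueError(f"condition {name!r} has fewer than "
                             f"{min_trials} trials")


# ---------------------------------------------------------------------------
# center-exclusive neurons

def find_center_exclusive(position_responses: list[np.ndarray],
                          gray_responses: np.ndarray,
                          alpha: float = 0.05
                          ) -> tuple[np.ndarray, pd.DataFrame]:
    """Mask of neurons responding exclusively at the center RF position.

    ``position_responses`` holds nine (trials x neurons) arrays, center
    first. Each position is compared to gray trials with a two-sided
    rank-sum test, Holm-corrected over the nine positions per neuron; a
    neuron is kept iff the center position is significant with a positive
    sign and all eight others are non-significant.
    """
    if len(position_responses) != 9:
        raise ValueError("expected nine RF-mapping positions (center first)")
    _check_trials({f"pos{i}": a for i, a in enumerate(position_responses)})
    _check_trials({"gray": gray_responses})
    n_neurons = gray_responses.shape[1]
    pvals = np.empty((9, n_neurons))
    sign = np.empty((9, n_neurons))
    for i, arr in enumerate(position_responses):
        res = stats.ranksums(arr, gray_responses, axis=0)
        pvals[i] = res.pvalue
        sign[i] = np.sign(res.statistic)
    reject = np.empty_like(pvals, dtype=bool)
    for j in range(n_neurons):
        reject[:, j] = multipletests(pvals[:, j], alpha=alpha,
                                     method="holm")[0]
    mask = reject[0] & (sign[0] > 0) & ~reject[1:].any(axis=0)
    table = pd.DataFrame({
        "p_center": pvals[0],
        "center_sign": sign[0],
        "n_other_significant": reject[1:].sum(axis=0),
        "is_center_exclusive": mask,
    })
    return mask, table


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Tukey-Kramer emulation on mean ranks

@dataclass
class _RankComparison:
    groups: list[str]
    mean_ranks: np.ndarray
    sizes: np.ndarray
    crit: float
    tie_var: float

    def significant(self, a: str, b: str) -> bool:
        ia, ib = self.groups.index(a), self.groups.index(b)
        se = np.sqrt(self.tie_var * (1.0 / self.sizes[ia] + 1.0 / self.sizes[ib]))
        return abs(self.mean_ranks[ia] - self.mean_ranks[ib]) > self.crit * se

    def greater(self, a: str, b: str) -> bool:
        ia, ib = self.groups.index(a), self.groups.index(b)
        return self.mean_ranks[ia] > self.mean_ranks[ib]


def _studentized_range_crit(alpha: float, k: int) -> float:
    # df -> inf is what the named MATLAB chain uses; scipy needs finite df
    return stats.studentized_range.ppf(1.0 - alpha, k, 1e6) / np.sqrt(2.0)


def _rank_comparison(samples: dict[str, np.ndarray], crit: float
                     ) -> _RankComparison:
    names = list(samples)
    sizes = np.array([len(samples[g]) for g in names])
    pooled = np.concatenate([samples[g] for g in names])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    # pooled rank variance with tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_adj = np.sum(counts ** 3 - counts) / (12.0 * (n - 1))
    tie_var = n * (n + 1) / 12.0 - tie_adj
    mean_ranks = np.empty(len(names))
    off = 0
    for i, g in enumerate(names):
        mean_ranks[i] = ranks[off:off + sizes[i]].mean()
        off += sizes[i]
    return _RankComparison(groups=names, mean_ranks=mean_ranks, sizes=sizes,
                           crit=crit, tie_var=tie_var)


def _encoder_classes(responses: dict[str, np.ndarray], targets: tuple[str, str],
                     controls: tuple[str, str], class_names: tuple[str, str],
                     alpha: float, method: str) -> tuple[np.ndarray, pd.DataFrame]:
    """Shared IC/LC-encoder logic.

    A neuron is labeled ``class_names[k]`` iff the omnibus Kruskal-Wallis
    over the five conditions is significant, ``targets[k]`` vs blank is
    significant with positive sign, the other target vs blank is not, and
    neither control vs blank is.
    """
    order = ["blank", *targets, *controls]
    missing = [k for k in order if k not in responses]
    if missing:
        raise ValueError(f"missing conditions {missing}")
    _check_trials(responses)
    n_neurons = responses["blank"].shape[1]
    classes = np.array(["none"] * n_neurons, dtype=object)
    crit = _studentized_range_crit(alpha, len(order))
    p_omni = np.empty(n_neurons)
    sig = {name: np.zeros(n_neurons, dtype=bool) for name in order[1:]}
    for j in range(n_neurons):
        samples = {name: responses[name][:, j] for name in order}
        try:
            p_omni[j] = stats.kruskal(*samples.values()).pvalue
        except ValueError:  # all values identical
            p_omni[j] = 1.0
        if p_omni[j] >= alpha:
            continue
        if method == "tukey":
            cmpres = _rank_comparison(samples, crit)
            for name in order[1:]:
                sig[name][j] = (cmpres.significant(name, "blank")
                                and cmpres.greater(name, "blank"))
        elif method == "holm":
            pv, greater = [], []
            for name in order[1:]:
                r = stats.ranksums(samples[name], samples["blank"])
                pv.append(r.pvalue)
                greater.append(r.statistic > 0)
            rej = multipletests(pv, alpha=alpha, method="holm")[0]
            for name, rj, gt in zip(order[1:], rej, greater):
                sig[name][j] = bool(rj and gt)
        else:
            raise ValueError(f"unknown method {method!r}")
        t0, t1 = targets
        c0, c1 = controls
        if sig[t0][j] and not sig[t1][j] and not sig[c0][j] and not sig[c1][j]:
            classes[j] = class_names[0]
        elif sig[t1][j] and not sig[t0][j] and not sig[c0][j] and not sig[c1][j]:
            classes[j] = class_names[1]
    table = pd.DataFrame({"p_omnibus": p_omni, "class": classes})
    for name in order[1:]:
        table[f"sig_{name}"] = sig[name]
    return classes, table


def find_ic_encoders(responses: dict[str, np.ndarray], alpha: float = 0.05,
                     method: str = "tukey") -> tuple[np.ndarray, pd.DataFrame]:
    """Label neurons IC1/IC2/none.

    ``responses`` maps ``blank`` (four circles), ``I_C1``, ``L_C1``,
    ``L_C2``, ``I_C2`` to (trials x neurons) arrays. A neuron is an
    IC-encoder iff exactly one I_C image is significantly above blank and
    neither L_C image is.
    """
    return _encoder_classes(responses, targets=("I_C1", "I_C2"),
                            controls=("L_C1", "L_C2"),
                            class_names=("IC1", "IC2"),
                            alpha=alpha, method=method)


def find_lc_encoders(responses: dict[str, np.ndarray], alpha: float = 0.05,
                     method: str = "tukey") -> tuple[np.ndarray, pd.DataFrame]:
    """Mirror of :func:`find_ic_encoders` with I_C and L_C roles swapped."""
    return _encoder_classes(responses, targets=("L_C1", "L_C2"),
                            controls=("I_C1", "I_C2"),
                            class_names=("LC1", "LC2"),
                            alpha=alpha, method=method)


# ---------------------------------------------------------------------------
# segment responders

def auroc(positives: np.ndarray, negatives: np.ndarray) -> np.ndarray:
    """Ideal-observer AUROC discriminating the two trial groups
    (Mann-Whitney U / (n1*n2))."""
    u = stats.mannwhitneyu(positives, negatives, alternative="two-sided",
                           axis=0).statistic
    return u / (positives.shape[0] * negatives.shape[0])


def find_segment_responders(responses: dict[str, np.ndarray],
                            alpha: float = 0.05
                            ) -> tuple[np.ndarray, pd.DataFrame]:
    """Label neurons by the inducer quadrant they respond to.

    ``responses`` maps ``In_q`` / ``Out_q`` for q in BR, BL, TL, TR to
    (trials x neurons) arrays. Per quadrant a one-sided rank-sum tests
    inward > outward; a neuron's class is the significant quadrant with the
    smallest p-value, ties broken by larger AUROC.
    """
    _check_trials(responses)
    n_neurons = responses["In_BR"].shape[1]
    pvals = np.empty((4, n_neurons))
    effect = np.empty((4, n_neurons))
    for i, q in enumerate(QUADRANTS):
        inw, outw = responses[f"In_{q}"], responses[f"Out_{q}"]
        res = stats.ranksums(inw, outw, alternative="greater", axis=0)
        pvals[i] = res.pvalue
        effect[i] = auroc(inw, outw)
    classes = np.array(["none"] * n_neurons, dtype=object)
    for j in range(n_neurons):
        sig = np.flatnonzero(pvals[:, j] < alpha)
        if len(sig) == 0:
            continue
        best = sig[np.lexsort((-effect[sig, j], pvals[sig, j]))[0]]
        classes[j] = QUADRANTS[best]
    table = pd.DataFrame({"segment_class": classes})
    for i, q in enumerate(QUADRANTS):
        table[f"p_{q}"] = pvals[i]
        table[f"auroc_{q}"] = effect[i]
    return classes, table


# ---------------------------------------------------------------------------
# orientation preference and ensemble balancing

def preferred_orientation_match(ic_responses: dict[float, np.ndarray],
                                ire_responses: dict[float, np.ndarray]
                                ) -> pd.DataFrame:
    """Preferred illusory vs real bar orientations per neuron.

    Preference is the orientation evoking the strongest mean response in
    each battery; ``match`` marks equality of the two argmaxes. The
    population match fraction is ``result["match"].mean()``.
    """
    ic_oris = sorted(ic_responses)
    ire_oris = sorted(ire_responses)
    ic_means = np.stack([ic_responses[o].mean(axis=0) for o in ic_oris])
    ire_means = np.stack([ire_responses[o].mean(axis=0) for o in ire_oris])
    pref_ic = np.array(ic_oris)[np.argmax(ic_means, axis=0)]
    pref_ire = np.array(ire_oris)[np.argmax(ire_means, axis=0)]
    return pd.DataFrame({"pref_ic_deg": pref_ic, "pref_ire_deg": pref_ire,
                         "match": pref_ic == pref_ire})


def balance_segment_ensembles(segment_class: np.ndarray,
                              responses: dict[str, np.ndarray],
                              neuron_ids: np.ndarray | None = None
                              ) -> dict[str, list[int]]:
    """Equal-size target lists per quadrant.

    N is the size of the smallest quadrant group; in larger groups the
    top-N neurons by inward-vs-outward AUROC are kept.
    """
    segment_class = np.asarray(segment_class, dtype=object)
    if neuron_ids is None:
        neuron_ids = np.arange(len(segment_class))
    groups = {q: np.flatnonzero(segment_class == q) for q in QUADRANTS}
    sizes = [len(v) for v in groups.values()]
    if min(sizes) == 0:
        raise ValueError("every quadrant needs at least one segment responder")
    n_keep = min(sizes)
    out = {}
    for q, idx in groups.items():
        if len(idx) > n_keep:
            a = auroc(responses[f"In_{q}"][:, idx], responses[f"Out_{q}"][:, idx])
            idx = idx[np.argsort(-a, kind="stable")[:n_keep]]
        out[q] = [int(neuron_ids[i]) for i in idx]
    return out


# ---------------------------------------------------------------------------
# session-level wrapper

def classify_session(session, alpha: float = 0.05,
                     method: str = "tukey") -> pd.DataFrame:
    """EnsembleLabels table for a synthetic session.

    Runs IC-encoder, LC-encoder and segment-responder classification (and,
    when the session contains an RF-mapping block, the center-exclusive
    test) and returns one row per neuron.
    """
    def grp(label):
        return session.responses[session.trial_mask(label)]

    battery = {"blank": grp("blank_circles"), "I_C1": grp("I_C1"),
               "L_C1": grp("L_C1"), "L_C2": grp("L_C2"), "I_C2": grp("I_C2")}
    ic_class, ic_table = find_ic_encoders(battery, alpha=alpha, method=method)
    lc_class, _ = find_lc_encoders(battery, alpha=alpha, method=method)
    seg_resp = {}
    for q in QUADRANTS:
        seg_resp[f"In_{q}"] = grp(f"In_{q}")
        seg_resp[f"Out_{q}"] = grp(f"Out_{q}")
    seg_class, seg_table = find_segment_responders(seg_resp, alpha=alpha)
    out = pd.DataFrame({
        "id": session.neurons["id"].to_numpy(),
        "ic_class": ic_class,
        "lc_class": lc_class,
        "segment_class": seg_class,
        "p_omnibus": ic_table["p_omnibus"].to_numpy(),
    })
    for q in QUADRANTS:
        out[f"auroc_{q}"] = seg_table[f"auroc_{q}"].to_numpy()
    has_rf = session.trials["label"].str.startswith("rf_pos").any()
    if has_rf:
        positions = [session.responses[session.trial_mask(f"rf_pos{i}")]
                     for i in range(1, 10)]
        mask, _ = find_center_exclusive(positions, grp("gray"), alpha=alpha)
        out["is_center_exclusive"] = mask
    return out
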