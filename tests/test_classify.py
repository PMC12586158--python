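"""Functional-ensemble classification tests.

Synthetic trial groups are generated directly from the rank-test
hypotheses; planted-session tests check recovery of the generator's
ground-truth classes.
"""

import numpy as np
import pytest

from icdecode import classify
from icdecode.classify import (auroc, balance_segment_ensembles,
                               find_center_exclusive, find_ic_encoders,
                               find_lc_encoders, find_segment_responders,
                               preferred_orientation_match)


def _battery_responses(rng, n_trials=60, blank=0.0, ic1=0.0, lc1=0.0,
                       lc2=0.0, ic2=0.0, n_neurons=1):
    mk = lambda mu: rng.normal(mu, 1.0, (n_trials, n_neurons))
    return {"blank": mk(blank), "I_C1": mk(ic1), "L_C1": mk(lc1),
            "L_C2": mk(lc2), "I_C2": mk(ic2)}


@pytest.mark.parametrize("method", ["tukey", "holm"])
def test_ic_encoder_detection(rng, method):
    resp = _battery_responses(rng, ic1=3.0)
    cls, table = find_ic_encoders(resp, method=method)
    assert cls[0] == "IC1"
    assert table.loc[0, "p_omnibus"] < 0.05


def test_segment_like_responder_is_not_ic_encoder(rng):
    # equal I_C1 / L_C1 response: the L_C condition is significant too
    resp = _battery_responses(rng, ic1=3.0, lc1=3.0)
    cls, _ = find_ic_encoders(resp)
    assert cls[0] == "none"


def test_flat_responder_fails_omnibus(rng):
    resp = _battery_responses(rng)
    cls, table = find_ic_encoders(resp)
    assert cls[0] == "none"


def test_both_ic_images_significant_is_excluded(rng):
    resp = _battery_responses(rng, ic1=3.0, ic2=3.0)
    cls, _ = find_ic_encoders(resp)
    assert cls[0] == "none"


def test_negative_response_not_labeled(rng):
    resp = _battery_responses(rng, ic1=-3.0)
    cls, _ = find_ic_encoders(resp)
    assert cls[0] == "none"


def test_lc_encoder_mirror(rng):
    resp = _battery_responses(rng, lc2=3.0)
    lc_cls, _ = find_lc_encoders(resp)
    assert lc_cls[0] == "LC2"
    ic_cls, _ = find_ic_encoders(resp)
    assert ic_cls[0] == "none"


def test_missing_condition_raises(rng):
    resp = _battery_responses(rng)
    del resp["L_C2"]
    with pytest.raises(ValueError, match="missing"):
        find_ic_encoders(resp)


def test_too_few_trials_raises(rng):
    resp = _battery_responses(rng, n_trials=1)
    with pytest.raises(ValueError, match="fewer than"):
        find_ic_encoders(resp)


# ---------------------------------------------------------------------------
# segment responders

def _segment_responses(rng, effects, n_trials=60, n_neurons=1):
    out = {}
    for q in classify.QUADRANTS:
        inw, outw = effects.get(q, (0.0, 0.0))
        out[f"In_{q}"] = rng.normal(inw, 1.0, (n_trials, n_neurons))
        out[f"Out_{q}"] = rng.normal(outw, 1.0, (n_trials, n_neurons))
    return out


def test_segment_responder_detection(rng):
    resp = _segment_responses(rng, {"BR": (2.0, 0.0)})
    cls, _ = find_segment_responders(resp)
    assert cls[0] == "BR"


def test_equal_in_out_is_none(rng):
    resp = _segment_responses(rng, {"BR": (2.0, 2.0)})
    cls, _ = find_segment_responders(resp)
    assert cls[0] == "none"


def test_two_quadrant_responder_takes_smaller_p(rng):
    resp = _segment_responses(rng, {"BR": (0.8, 0.0), "TL": (4.0, 0.0)})
    cls, table = find_segment_responders(resp)
    assert cls[0] == "TL"
    assert table.loc[0, "p_TL"] <= table.loc[0, "p_BR"]


# ---------------------------------------------------------------------------
# center-exclusive

def _position_responses(rng, center=0.0, others=None, n_trials=12,
                        n_neurons=1):
    others = others or {}
    out = [rng.normal(center, 1.0, (n_trials, n_neurons))]
    for i in range(1, 9):
        out.append(rng.normal(others.get(i, 0.0), 1.0, (n_trials, n_neurons)))
    return out


def test_center_exclusive_detection(rng):
    pos = _position_responses(rng, center=4.0)
    gray = rng.normal(0.0, 1.0, (12, 1))
    mask, _ = find_center_exclusive(pos, gray)
    assert mask[0]


def test_center_plus_surround_excluded(rng):
    pos = _position_responses(rng, center=4.0, others={2: 4.0})
    gray = rng.normal(0.0, 1.0, (12, 1))
    mask, _ = find_center_exclusive(pos, gray)
    assert not mask[0]


def test_null_neurons_rarely_center_exclusive(rng):
    pos = _position_responses(rng, n_neurons=200, n_trials=15)
    gray = rng.normal(0.0, 1.0, (15, 200))
    mask, _ = find_center_exclusive(pos, gray)
    assert mask.mean() <= 0.06  # about the one-sided nominal level


def test_wrong_position_count_raises(rng):
    with pytest.raises(ValueError, match="nine"):
        find_center_exclusive([rng.normal(size=(5, 1))] * 8,
                              rng.normal(size=(5, 1)))


# ---------------------------------------------------------------------------
# orientation match and balancing

def test_orientation_match_trivial():
    ic = {45.0: np.array([[1.0, 3.0]] * 10), 135.0: np.array([[3.0, 1.0]] * 10)}
    ire = {45.0: np.array([[0.0, 0.0]] * 10), 135.0: np.array([[4.0, 4.0]] * 10)}
    out = preferred_orientation_match(ic, ire)
    assert out.loc[0, "match"]        # 135 in both batteries
    assert not out.loc[1, "match"]    # 45 illusory vs 135 real: orthogonal


def test_orientation_match_fraction_recovers_planted(rng):
    n, p_match = 500, 0.8
    match_flag = rng.random(n) < p_match
    pref_ic = rng.choice([45.0, 135.0], size=n)
    pref_ire = np.where(match_flag, pref_ic, 180.0 - pref_ic)
    ic = {o: rng.normal(0, 0.1, (40, n)) + 2.0 * (pref_ic == o)
          for o in (45.0, 135.0)}
    ire = {o: rng.normal(0, 0.1, (40, n)) + 2.0 * (pref_ire == o)
           for o in (45.0, 135.0)}
    out = preferred_orientation_match(ic, ire)
    assert out["match"].mean() == pytest.approx(p_match, abs=0.05)


def test_auroc_against_rank_count_oracle(rng):
    pos = rng.normal(1.0, 1.0, (40, 5))
    neg = rng.normal(0.0, 1.0, (30, 5))
    got = auroc(pos, neg)
    # brute-force pair counting (Mann-Whitney U identity)
    for j in range(5):
        wins = sum(1.0 * (a > b) + 0.5 * (a == b)
                   for a in pos[:, j] for b in neg[:, j])
        assert got[j] == pytest.approx(wins / (40 * 30))


def test_auroc_perfect_separation():
    pos = np.arange(10.0, 20.0).reshape(-1, 1)
    neg = np.arange(0.0, 10.0).reshape(-1, 1)
    assert auroc(pos, neg)[0] == 1.0


def test_balance_segment_ensembles(rng):
    # 6 BR, 3 TL, 4 BL, 5 TR -> all trimmed to 3 by AUROC rank
    cls = np.array(["BR"] * 6 + ["TL"] * 3 + ["BL"] * 4 + ["TR"] * 5,
                   dtype=object)
    n = len(cls)
    resp = {}
    sep = np.linspace(0.5, 3.0, n)  # increasing separability with index
    for q in classify.QUADRANTS:
        resp[f"In_{q}"] = rng.normal(0, 1, (40, n)) + sep
        resp[f"Out_{q}"] = rng.normal(0, 1, (40, n))
    out = balance_segment_ensembles(cls, resp)
    assert all(len(v) == 3 for v in out.values())
    assert set(out["TL"]) == {6, 7, 8}  # smallest group kept unchanged
    assert set(out["BR"]) == {3, 4, 5}  # top-3 AUROC among the six BR


def test_balance_empty_quadrant_raises(rng):
    cls = np.array(["BR", "TL", "BL"], dtype=object)
    resp = {f"{p}_{q}": rng.normal(size=(10, 3))
            for p in ("In", "Out") for q in classify.QUADRANTS}
    with pytest.raises(ValueError):
        balance_segment_ensembles(cls, resp)


# ---------------------------------------------------------------------------
# session-level

def test_planted_session_recovery(small_sessions):
    sess = small_sessions["planted"]
    labels = classify.classify_session(sess)
    truth = small_sessions["planted_neurons"]["emergent_class"].to_numpy()
    planted = truth != "none"
    recovered = (labels["ic_class"].to_numpy() == truth)[planted]
    assert recovered.mean() >= 0.9
    seg_truth = np.zeros(len(truth), dtype=bool)
    seg_truth[12:44] = True  # planted segment responders
    assert (labels.loc[seg_truth, "segment_class"] != "none").mean() >= 0.8


def test_labels_stable_under_trial_permutation(small_sessions, rng):
    sess = small_sessions["planted"]
    labels = classify.classify_session(sess)
    perm = rng.permutation(len(sess.trials))
    import copy

    shuffled = copy.copy(sess)
    shuffled.trials = sess.trials.iloc[perm].reset_index(drop=True)
    shuffled.responses = sess.responses[perm]
    labels2 = classify.classify_session(shuffled)
    assert (labels["ic_class"] == labels2["ic_class"]).all()
    assert (labels["segment_class"] == labels2["segment_class"]).all()
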