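"""Generative-model tests: determinism, closed-form means, planted
connectivity and spike-train structure."""

import numpy as np
import pandas as pd
import pytest

from icdecode import ccg, synthdata
from icdecode.synthdata import (Comodulation, Connectivity, HolographyPlan,
                                build_connectivity, build_trial_table,
                                compute_stimulus_drive, make_population,
                                simulate_holography, simulate_population,
                                simulate_spike_trains)


def _single_neuron(rf_xy, pref=135.0, eclass="none", amp=0.0, sigma=3.0,
                   gain=4.0, noise=1.0):
    return pd.DataFrame([dict(
        id=0, x_um=0.0, y_um=0.0, area="V1", layer="L2/3",
        rf_x_deg=rf_xy[0], rf_y_deg=rf_xy[1], rf_sigma_deg=sigma,
        pref_ori_deg=pref, tuning_kappa=2.0, gain=gain, baseline=1.0,
        emergent_class=eclass, emergent_amp=amp, noise_sd=noise)])


def test_simulation_is_deterministic(battery):
    neurons = make_population(5, n_v1=30, n_ic_encoders=4, n_segment=8,
                              n_center=4)
    trials = build_trial_table({"I_C1": 20, "gray": 20}, seed=6)
    a = simulate_population(neurons, battery, trials, seed=7)
    b = simulate_population(neurons, battery, trials, seed=7)
    assert np.array_equal(a.responses, b.responses)
    c = simulate_population(neurons, battery, trials, seed=8)
    assert not np.array_equal(a.responses, c.responses)


def test_trial_table_randomized_and_complete():
    reps = {"I_C1": 30, "L_C1": 30, "gray": 10}
    t = build_trial_table(reps, seed=3)
    assert t["label"].value_counts().to_dict() == reps
    assert not (t["label"].to_numpy()[:30] == "I_C1").all()
    assert np.all(t["t_off"] > t["t_on"])


def test_segment_neuron_sees_shared_inducer_only(battery):
    """With zero noise and no emergent drive, a neuron whose RF covers only
    the BR inducer responds identically to I_C1, L_C1 and T_RE1."""
    neurons = _single_neuron((11.3, -11.3), noise=0.0)
    drives = compute_stimulus_drive(neurons, battery)
    assert drives.loc["I_C1", 0] == pytest.approx(drives.loc["L_C1", 0])
    assert drives.loc["I_C1", 0] == pytest.approx(drives.loc["T_RE1", 0])
    assert drives.loc["I_C1", 0] > drives.loc["blank_circles", 0]
    assert drives.loc["I_C2", 0] == pytest.approx(
        drives.loc["blank_circles", 0])


def test_planted_ic_neuron_closed_form_mean(battery):
    """Planted IC1 neuron with RF in the gap: mean(I_C1) - mean(L_C1) = c
    and mean(I_C1) - mean(I_C2) = c, recovered within 3 sigma/sqrt(n)."""
    c = 2.5
    n_reps = 200
    neurons = _single_neuron((0.5, -0.5), eclass="IC1", amp=c)
    trials = build_trial_table(
        {"I_C1": n_reps, "L_C1": n_reps, "I_C2": n_reps}, seed=9)
    sess = simulate_population(neurons, battery, trials, seed=10)
    tol = 3.0 / np.sqrt(n_reps) * np.sqrt(2)
    m = {lab: sess.responses[sess.trial_mask(lab), 0].mean()
         for lab in ("I_C1", "L_C1", "I_C2")}
    assert m["I_C1"] - m["L_C1"] == pytest.approx(c, abs=tol)
    assert m["I_C1"] - m["I_C2"] == pytest.approx(c, abs=tol)


def test_blank_trials_recover_baseline(battery):
    neurons = _single_neuron((0.0, 0.0))
    trials = build_trial_table({"blank_circles": 400}, seed=11)
    sess = simulate_population(neurons, battery, trials, seed=12)
    assert sess.responses[:, 0].mean() == pytest.approx(
        1.0, abs=3.0 / np.sqrt(400))


def test_emergent_real_edge_switch(battery):
    neurons = _single_neuron((0.0, 0.0), eclass="IC1", amp=3.0, noise=0.0)
    on = compute_stimulus_drive(neurons, battery,
                                emergent_drives_real_edges=True)
    off = compute_stimulus_drive(neurons, battery,
                                 emergent_drives_real_edges=False)
    assert on.loc["T_RE1", 0] - off.loc["T_RE1", 0] == pytest.approx(3.0)
    assert on.loc["I_C1", 0] == pytest.approx(off.loc["I_C1", 0])


def test_rf_outside_canvas_warns(battery):
    neurons = _single_neuron((500.0, 0.0), eclass="IC1", amp=3.0)
    with pytest.warns(UserWarning, match="outside canvas"):
        d = compute_stimulus_drive(neurons, battery)
    assert d.loc["blank_circles", 0] == pytest.approx(1.0)  # baseline only
    assert d.loc["I_C1", 0] == pytest.approx(4.0)  # emergent term survives


# ---------------------------------------------------------------------------
# holography

def _holo_setup(battery, like=0.0, ff=0.0, s=0.3):
    neurons = make_population(13, n_v1=80, n_hva=40, n_ic_encoders=12,
                              n_segment=32, n_center=8)
    drives = compute_stimulus_drive(neurons, battery)
    conn = build_connectivity(neurons, drives, like_to_like_weight=like,
                              feedforward_weight=ff, suppression=s)
    ids = neurons["id"].to_numpy()
    cls = neurons["emergent_class"].to_numpy()
    plan = HolographyPlan(
        ensembles={"IC1": [int(i) for i in ids[cls == "IC1"]]},
        n_reps=60, min_targets=5)
    return neurons, drives, conn, plan


def test_holography_suppression_only(battery):
    neurons, drives, conn, plan = _holo_setup(battery, like=0.0, s=0.4)
    holo = simulate_holography(neurons, conn, plan, seed=14)
    targets = set(plan.ensembles["IC1"])
    non = ~neurons["id"].isin(targets).to_numpy()
    assert holo.responses[:, non].mean() == pytest.approx(
        -0.4, abs=3.0 / np.sqrt(non.sum() * len(holo.trials)))


def test_like_to_like_drives_responsive_nontargets(battery):
    w, d = 0.5, 5.0
    neurons, drives, conn, plan = _holo_setup(battery, like=w, s=0.0)
    plan.direct_drive = d
    holo = simulate_holography(neurons, conn, plan, seed=15)
    targets = set(plan.ensembles["IC1"])
    blank = drives.loc["blank_circles"].to_numpy()
    responsive = (drives.loc["I_C1"].to_numpy() - blank) > 0.5
    non = ~neurons["id"].isin(targets).to_numpy()
    v1 = (neurons["area"] == "V1").to_numpy()
    got = holo.responses[:, non & v1 & responsive].mean() - \
        holo.responses[:, non & v1 & ~responsive].mean()
    # summed like-to-like input approximates w * d
    assert got == pytest.approx(w * d, rel=0.2)


def test_feedforward_routes_to_hva(battery):
    neurons = make_population(16, n_v1=80, n_hva=40, n_ic_encoders=12,
                              n_segment=32, n_center=8)
    drives = compute_stimulus_drive(neurons, battery)
    conn = build_connectivity(neurons, drives, feedforward_weight=0.5,
                              suppression=0.3)
    segq = neurons["emergent_class"].to_numpy() == "none"
    blank = drives.loc["blank_circles"].to_numpy()
    br = (drives.loc["In_BR"].to_numpy() - blank) > 0.5
    tl = (drives.loc["In_TL"].to_numpy() - blank) > 0.5
    v1 = (neurons["area"] == "V1").to_numpy()
    members = neurons["id"].to_numpy()[v1 & segq & (br | tl)]
    plan = HolographyPlan(ensembles={"BRTL": [int(i) for i in members]},
                          n_reps=60, min_targets=5)
    holo = simulate_holography(neurons, conn, plan, seed=17)
    hva_resp = ~v1 & (br | tl)
    assert holo.responses[:, hva_resp].mean() > 0.5
    non_target_v1 = v1 & ~neurons["id"].isin(set(plan.ensembles["BRTL"])).to_numpy()
    assert holo.responses[:, non_target_v1].mean() == pytest.approx(-0.3,
                                                                    abs=0.1)


def test_unknown_ensemble_member_raises(battery):
    neurons, drives, conn, plan = _holo_setup(battery)
    plan.ensembles["bad"] = [99999]
    with pytest.raises(ValueError, match="unknown ids"):
        simulate_holography(neurons, conn, plan, seed=18)


def test_connectivity_invariants(battery):
    neurons, drives, conn, _ = _holo_setup(battery, like=0.5, ff=0.5)
    assert np.all(np.diag(conn.W) == 0)
    with pytest.raises(ValueError):
        Connectivity(W=np.zeros((2, 2)), FF=np.zeros((2, 2)),
                     FB=np.zeros((2, 2)), suppression=-1.0)


def test_holography_plan_min_targets():
    plan = HolographyPlan(ensembles={"a": list(range(12)),
                                     "b": list(range(5))})
    assert list(plan.analyzable()) == ["a"]


# ---------------------------------------------------------------------------
# spike trains

def test_independent_pair_coincidences(spike_fixture):
    """transfer_p = 0 pair (units 2, 3): coincidence counts match the
    independent-Poisson expectation."""
    s = spike_fixture
    x2, x3 = s.spikes[2], s.spikes[3]
    lam2, lam3 = len(x2), len(x3)
    pair = ccg.SpikeTrainPair(x2, x3, s.n_bins)
    res = ccg.compute_ccg(pair)
    expected = lam2 * lam3 / s.n_bins / np.sqrt(lam2 * lam3)
    assert res.raw.mean() == pytest.approx(expected, rel=0.15)


def test_planted_synapse_excess_coincidences(spike_fixture):
    """Excess coincidences at the planted 3-ms lag approximate
    lambda_pre * transfer_p, spread over the +/-1 ms jitter."""
    s = spike_fixture
    pair = ccg.SpikeTrainPair(s.spikes[0], s.spikes[1], s.n_bins)
    res = ccg.compute_ccg(pair)
    lam_pre = len(s.spikes[0])
    norm = np.sqrt(len(s.spikes[0]) * len(s.spikes[1]))
    base = res.raw[np.abs(res.lags_ms) > 20].mean()
    excess = (res.raw[(res.lags_ms >= 2) & (res.lags_ms <= 4)] - base).sum()
    assert excess * norm == pytest.approx(lam_pre * 0.25, rel=0.15)


def test_out_of_window_lag_warns():
    with pytest.warns(UserWarning, match="undetectable"):
        simulate_spike_trains({0: 5.0, 1: 5.0}, [(0, 1, 15.0, 0.2)],
                              duration_s=10.0, seed=3)


def test_comodulation_raises_rate_covariance():
    s = simulate_spike_trains(
        {0: 10.0, 1: 10.0}, [], duration_s=300.0, seed=4,
        comodulation=Comodulation(units=(0, 1), depth=0.8, freq_hz=1.0))
    pair = ccg.SpikeTrainPair(s.spikes[0], s.spikes[1], s.n_bins)
    res = ccg.compute_ccg(pair)
    lam = np.sqrt(len(s.spikes[0]) * len(s.spikes[1]))
    independent_level = len(s.spikes[0]) * len(s.spikes[1]) / s.n_bins / lam
    # raw CCG broadly elevated above the independent-rate expectation
    assert res.raw.mean() > 1.15 * independent_level
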