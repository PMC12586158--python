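"""End-to-end orchestration: simulate -> preprocess -> classify -> decode ->
holography -> CCG, as one reproducible run.

A run is a pure function of ``(RunConfig, seed)``: the master seed expands
into per-stage child seeds through a fixed affine counter scheme
(``stage_seed = (seed * 1000003 + stage_index) mod 2^31``), so any single
stage can be re-run reproducibly. Every output table embeds the
configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ccg as ccg_mod
from . import classify as classify_mod
from . import decode as decode_mod
from . import preprocess, stimgen, synthdata

__all__ = ["RunConfig", "run_pipeline", "make_fixtures", "stage_seed"]


def stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage child seed (documented counter scheme)."""
    return (int(seed) * 1000003 + stage) % (2 ** 31)


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    # stimulus
    stimulus: dict = field(default_factory=dict)
    # population / simulator
    n_v1: int = 200
    n_hva: int = 80
    n_ic_encoders: int = 24
    n_segment: int = 80
    n_center: int = 20
    emergent_amp: float = 3.0
    noise_sd: float = 1.0
    emergent_drives_real_edges: bool = True
    n_train_reps: int = 100
    n_other_reps: int = 50
    # analysis constants
    alpha: float = 0.05
    k_folds: int = 10
    svm_c: float = 1.0
    gaze_threshold_deg: float = 8.0
    excursion_fraction: float = 0.02
    # holography
    like_to_like_weight: float = 0.4
    feedforward_weight: float = 0.4
    suppression: float = 0.3
    direct_drive: float = 5.0
    holo_reps: int = 50
    min_targets: int = 10
    nonphoto_dist_um: float = 50.0
    # ccg demo block
    ccg_duration_s: float = 1200.0
    ccg_rate_hz: float = 10.0
    ccg_transfer_p: float = 0.25
    # output
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls(**(yaml.safe_load(f) or {}))

    def config_hash(self, seed: int) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # output location is not part of the run
        payload = yaml.safe_dump({"config": d, "seed": seed}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _decode_stage(session, labels_df, cfg: RunConfig, seed: int) -> dict:
    X, y = session.response_matrix(*stimgen.TRAINING_LABELS)
    model, cv = decode_mod.train_cv_decoder(X, y, k=cfg.k_folds, seed=seed,
                                            C=cfg.svm_c)
    tre1 = session.responses[session.trial_mask("T_RE1")]
    tre2 = session.responses[session.trial_mask("T_RE2")]
    tre = decode_mod.tre_inference(model, tre1, tre2)

    Xx, yx = session.response_matrix("X_RE1", "X_RE2")
    xmodel, xcv = decode_mod.train_cv_decoder(Xx, yx, k=cfg.k_folds,
                                              seed=seed, C=cfg.svm_c)
    ic1 = session.responses[session.trial_mask("I_C1")]
    ic2 = session.responses[session.trial_mask("I_C2")]
    xre_score = decode_mod.xre_inference(xmodel, ic1, ic2)

    ic_idx = np.flatnonzero(labels_df["ic_class"].to_numpy() != "none")
    # segment responders *per se*: exclude neurons that also carry an
    # encoder label, so the subset isolates bottom-up segment information
    seg_idx = np.flatnonzero(
        (labels_df["segment_class"].to_numpy() != "none")
        & (labels_df["ic_class"].to_numpy() == "none")
        & (labels_df["lc_class"].to_numpy() == "none"))
    out = {
        "cv_accuracy": cv.cv_accuracy,
        "confusion": cv.confusion,
        "tre_frac_ic": tre.frac_ic,
        "tre_frac_lc": tre.frac_lc,
        "tre_score": tre.score,
        "xre_cv_accuracy": xcv.cv_accuracy,
        "xre_score": xre_score,
        "model": model,
    }
    if len(ic_idx):
        zo = decode_mod.zero_out(model, X, y, ic_idx)
        tre_zo = decode_mod.tre_inference(model, tre1, tre2,
                                          zero_subset=ic_idx)
        _, sub_cv = decode_mod.train_subset(X, y, ic_idx, k=cfg.k_folds,
                                            seed=seed, C=cfg.svm_c)
        sub_model, _ = decode_mod.train_subset(X, y, ic_idx, k=cfg.k_folds,
                                               seed=seed, C=cfg.svm_c)
        tre_sub = decode_mod.tre_inference(sub_model, tre1[:, ic_idx],
                                           tre2[:, ic_idx])
        out.update(zero_ic_cv=zo.cv_accuracy, zero_ic_tre=tre_zo.score,
                   subset_ic_cv=sub_cv.cv_accuracy, subset_ic_tre=tre_sub.score)
    if len(seg_idx):
        zo = decode_mod.zero_out(model, X, y, seg_idx)
        tre_zo = decode_mod.tre_inference(model, tre1, tre2,
                                          zero_subset=seg_idx)
        sub_model, sub_cv = decode_mod.train_subset(X, y, seg_idx,
                                                    k=cfg.k_folds, seed=seed,
                                                    C=cfg.svm_c)
        tre_sub = decode_mod.tre_inference(sub_model, tre1[:, seg_idx],
                                           tre2[:, seg_idx])
        out.update(zero_seg_cv=zo.cv_accuracy, zero_seg_tre=tre_zo.score,
                   subset_seg_cv=sub_cv.cv_accuracy,
                   subset_seg_tre=tre_sub.score)
    return out


def _holography_stage(session, labels_df, drives, cfg: RunConfig,
                      seed: int) -> dict:
    neurons = session.neurons
    ids = neurons["id"].to_numpy()
    ic_class = labels_df["ic_class"].to_numpy()
    seg_class = labels_df["segment_class"].to_numpy().copy()
    # targeted segment ensembles are segment responders per se
    seg_class[(ic_class != "none")
              | (labels_df["lc_class"].to_numpy() != "none")] = "none"
    ensembles: dict[str, list[int]] = {
        "IC1_encoders": [int(i) for i in ids[ic_class == "IC1"]],
        "IC2_encoders": [int(i) for i in ids[ic_class == "IC2"]],
    }
    seg_resp = {f"{pre}_{q}": session.responses[session.trial_mask(f"{pre}_{q}")]
                for pre in ("In", "Out") for q in classify_mod.QUADRANTS}
    try:
        balanced = classify_mod.balance_segment_ensembles(seg_class, seg_resp,
                                                          neuron_ids=ids)
        ensembles["BR_TL_segment"] = balanced["BR"] + balanced["TL"]
        ensembles["BL_TR_segment"] = balanced["BL"] + balanced["TR"]
    except ValueError:
        pass
    expected = {"IC1_encoders": "I_C1", "IC2_encoders": "I_C2",
                "BR_TL_segment": "I_C1", "BL_TR_segment": "I_C2"}
    plan = synthdata.HolographyPlan(ensembles=ensembles, n_reps=cfg.holo_reps,
                                    direct_drive=cfg.direct_drive,
                                    min_targets=cfg.min_targets)
    conn = synthdata.build_connectivity(
        neurons, drives, like_to_like_weight=cfg.like_to_like_weight,
        feedforward_weight=cfg.feedforward_weight,
        suppression=cfg.suppression)
    holo = synthdata.simulate_holography(neurons, conn, plan, seed=seed)
    analyzable = plan.analyzable()
    X, y = session.response_matrix(*stimgen.TRAINING_LABELS)
    ens_col = holo.trials["holo_ensemble"].to_numpy()
    is_v1 = neurons["area"].to_numpy() == "V1"
    v1_nontarget = {}
    hva_only = {}
    for name in analyzable:
        members = plan.ensembles[name]
        target_xy = neurons.set_index("id").loc[members, ["x_um", "y_um"]]
        nonphoto = decode_mod.nonphoto_mask(neurons, target_xy.to_numpy(),
                                            cfg.nonphoto_dist_um)
        for store, mask in ((v1_nontarget, nonphoto & is_v1),
                            (hva_only, nonphoto & ~is_v1)):
            sub = np.flatnonzero(mask)
            if len(sub) == 0:
                continue
            model, _ = decode_mod.train_subset(X, y, sub, k=cfg.k_folds,
                                               seed=seed, C=cfg.svm_c)
            # normalization spans all holography trials; fractions are
            # computed on this ensemble's trials only
            table, _ = decode_mod.holo_cross_decode(
                model, holo.responses[:, sub], ens_col,
                {name: expected[name]})
            store[name] = float(table["expected_fraction"].iloc[0])
    return {"nontarget_expected_fraction": v1_nontarget,
            "hva_expected_fraction": hva_only,
            "holo_session": holo, "plan": plan, "connectivity": conn}


def run_pipeline(config: RunConfig | None = None, seed: int = 0) -> dict:
    """Run every stage and return the results bundle.

    With ``config.out_dir`` set, tidy CSV results and a JSON summary (with
    the config hash) are also written there.
    """
    cfg = config or RunConfig()
    spec = stimgen.StimulusSpec.from_dict(cfg.stimulus) if cfg.stimulus \
        else stimgen.StimulusSpec()
    stim = stimgen.render_battery(spec)

    neurons = synthdata.make_population(
        stage_seed(seed, 1), n_v1=cfg.n_v1, n_hva=cfg.n_hva,
        n_ic_encoders=cfg.n_ic_encoders, n_segment=cfg.n_segment,
        n_center=cfg.n_center, emergent_amp=cfg.emergent_amp,
        noise_sd=cfg.noise_sd)
    reps = synthdata.default_ic_block_reps(cfg.n_train_reps, cfg.n_other_reps)
    trials = synthdata.build_trial_table(reps, stage_seed(seed, 2))
    rf_trials = synthdata.build_trial_table(
        synthdata.default_rf_block_reps(), stage_seed(seed, 3),
        block="rf_mapping", t_start=float(trials["t_off"].max()) + 10.0)
    all_trials = pd.concat([trials, rf_trials], ignore_index=True)
    drives = synthdata.compute_stimulus_drive(
        neurons, stim, emergent_drives_real_edges=cfg.emergent_drives_real_edges,
        include_rf_block=True)
    pupil = synthdata.simulate_pupil(all_trials, stage_seed(seed, 4),
                                     excursion_fraction=cfg.excursion_fraction)
    session = synthdata.simulate_population(
        neurons, stim, all_trials, stage_seed(seed, 5), drives=drives,
        pupil=pupil)

    keep = preprocess.fixed_gaze_filter(pupil, session.trials,
                                        cfg.gaze_threshold_deg)
    session.trials = session.trials[keep].reset_index(drop=True)
    session.responses = session.responses[keep]

    labels_df = classify_mod.classify_session(session, alpha=cfg.alpha)
    dec = _decode_stage(session, labels_df, cfg, stage_seed(seed, 6))
    holo = _holography_stage(session, labels_df, drives, cfg,
                             stage_seed(seed, 7))

    # small CCG demonstration block: one planted synapse + one null pair
    spikes = synthdata.simulate_spike_trains(
        {0: cfg.ccg_rate_hz, 1: cfg.ccg_rate_hz, 2: cfg.ccg_rate_hz,
         3: cfg.ccg_rate_hz},
        [(0, 1, 3.0, cfg.ccg_transfer_p)], cfg.ccg_duration_s,
        seed=stage_seed(seed, 8))
    graph = ccg_mod.build_connection_graph(spikes, pairs=[(0, 1), (2, 3)])

    bundle = {
        "config_hash": cfg.config_hash(seed),
        "stimulus_set": stim,
        "session": session,
        "labels": labels_df,
        "gaze_kept_fraction": float(keep.mean()),
        "decode": dec,
        "holography": holo,
        "ccg_graph": graph,
        "support_ratio": stimgen.support_ratio(spec),
    }
    if cfg.out_dir:
        _write_outputs(bundle, cfg, seed)
    return bundle


def _tidy_rows(bundle: dict) -> pd.DataFrame:
    rows = []

    def add(mode, metric, value, subset="all"):
        rows.append({"config_hash": bundle["config_hash"], "mode": mode,
                     "subset": subset, "metric": metric,
                     "value": float(value)})

    dec = bundle["decode"]
    add("cv", "accuracy", dec["cv_accuracy"])
    add("tre", "score", dec["tre_score"])
    add("tre", "frac_ic", dec["tre_frac_ic"])
    add("tre", "frac_lc", dec["tre_frac_lc"])
    add("xre", "score", dec["xre_score"])
    add("xre", "cv_accuracy", dec["xre_cv_accuracy"])
    for key in ("zero_ic_cv", "zero_ic_tre", "subset_ic_cv", "subset_ic_tre",
                "zero_seg_cv", "zero_seg_tre", "subset_seg_cv",
                "subset_seg_tre"):
        if key in dec:
            add("manipulation", key, dec[key])
    for name, frac in bundle["holography"]["nontarget_expected_fraction"].items():
        add("holo_v1_nontarget", "expected_fraction", frac, subset=name)
    for name, frac in bundle["holography"]["hva_expected_fraction"].items():
        add("holo_hva", "expected_fraction", frac, subset=name)
    add("stimuli", "support_ratio", bundle["support_ratio"])
    add("preprocess", "gaze_kept_fraction", bundle["gaze_kept_fraction"])
    return pd.DataFrame(rows)


def _write_outputs(bundle: dict, cfg: RunConfig, seed: int) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tidy = _tidy_rows(bundle)
    tidy.to_csv(out / "results.csv", index=False)
    bundle["labels"].to_csv(out / "ensemble_labels.csv", index=False)
    bundle["ccg_graph"].to_csv(out / "ccg_edges.csv", index=False)
    summary = {
        "seed": seed,
        "config_hash": bundle["config_hash"],
        "metrics": {f"{r.mode}/{r.metric}" if r.subset == "all"
                    else f"{r.mode}/{r.subset}/{r.metric}": r.value
                    for r in tidy.itertuples(index=False)},
    }
    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)


def make_fixtures(seed: int = 0) -> dict:
    """Small deterministic bundles used by the test suite.

    Returns a null session (no emergent drive), a planted session, a
    holography bundle and a short spike-train set with one planted synapse.
    """
    spec = stimgen.StimulusSpec()
    stim = stimgen.render_battery(spec)
    common = dict(n_v1=60, n_hva=0, n_ic_encoders=10, n_segment=24,
                  n_center=8)
    reps = synthdata.default_ic_block_reps(40, 30)
    trials = synthdata.build_trial_table(reps, stage_seed(seed, 21))

    null_neurons = synthdata.make_population(stage_seed(seed, 22),
                                             emergent_amp=0.0, **common)
    null_session = synthdata.simulate_population(null_neurons, stim, trials,
                                                 stage_seed(seed, 23))
    planted_neurons = synthdata.make_population(stage_seed(seed, 24),
                                                emergent_amp=3.0, **common)
    planted_session = synthdata.simulate_population(
        planted_neurons, stim, trials, stage_seed(seed, 25))

    drives = synthdata.compute_stimulus_drive(planted_neurons, stim)
    conn = synthdata.build_connectivity(planted_neurons, drives,
                                        like_to_like_weight=0.4,
                                        suppression=0.3)
    ids = planted_neurons["id"].to_numpy()
    cls = planted_neurons["emergent_class"].to_numpy()
    plan = synthdata.HolographyPlan(
        ensembles={"IC1_encoders": [int(i) for i in ids[cls == "IC1"]]},
        n_reps=30, min_targets=5)
    holo = synthdata.simulate_holography(planted_neurons, conn, plan,
                                         stage_seed(seed, 26))

    spikes = synthdata.simulate_spike_trains(
        {0: 10.0, 1: 10.0, 2: 10.0, 3: 10.0}, [(0, 1, 3.0, 0.25)],
        600.0, seed=stage_seed(seed, 27))
    return {"stimulus_set": stim, "null_session": null_session,
            "planted_session": planted_session, "holography": holo,
            "plan": plan, "connectivity": conn, "spikes": spikes}
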