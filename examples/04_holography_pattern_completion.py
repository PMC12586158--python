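"""Holographic photostimulation and cross-decoding of evoked activity.

With like-to-like recurrence planted (IC-encoders project to neurons
visually responsive to their I_C image), photoactivating an IC-encoder
ensemble recreates a decodable image representation in the *non-target*
V1 population; with feedforward weights, segment-responder ensembles (but
not IC-encoder ensembles) drive the representation in the higher visual
area. Decoders are trained on visual trials and classify the
holography-evoked activity normalized across all holography trials.
"""

import numpy as np

from icdecode import classify, decode, render_battery, synthdata
from icdecode.stimgen import TRAINING_LABELS

battery = render_battery()
neurons = synthdata.make_population(seed=1, n_hva=80)
trials = synthdata.build_trial_table(synthdata.default_ic_block_reps(),
                                     seed=2)
drives = synthdata.compute_stimulus_drive(neurons, battery)
session = synthdata.simulate_population(neurons, battery, trials, seed=3,
                                        drives=drives)
labels = classify.classify_session(session)

ids = neurons["id"].to_numpy()
icc = labels["ic_class"].to_numpy()
ensembles = {"IC1_encoders": [int(i) for i in ids[icc == "IC1"]],
             "IC2_encoders": [int(i) for i in ids[icc == "IC2"]]}
expected = {"IC1_encoders": "I_C1", "IC2_encoders": "I_C2"}

plan = synthdata.HolographyPlan(ensembles=ensembles, n_reps=50)
conn = synthdata.build_connectivity(neurons, drives,
                                    like_to_like_weight=0.4,
                                    feedforward_weight=0.4,
                                    suppression=0.3)
holo = synthdata.simulate_holography(neurons, conn, plan, seed=4)

X, y = session.response_matrix(*TRAINING_LABELS)
ecol = holo.trials["holo_ensemble"].to_numpy()
is_v1 = (neurons["area"] == "V1").to_numpy()

for name, members in plan.analyzable().items():
    txy = neurons.set_index("id").loc[members, ["x_um", "y_um"]].to_numpy()
    nonphoto = decode.nonphoto_mask(neurons, txy, min_dist_um=50.0)
    sub = np.flatnonzero(nonphoto & is_v1)
    model, _ = decode.train_subset(X, y, sub, seed=0)
    table, p = decode.holo_cross_decode(model, holo.responses[:, sub], ecol,
                                        {name: expected[name]})
    frac = table["expected_fraction"].iloc[0]
    print(f"{name}: non-target V1 trials decoded as {expected[name]} on "
          f"{frac:.2%} of trials (chance 25%) -> pattern completion")
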