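"""Synthetic neural sessions with planted emergent structure.

The simulator produces everything the downstream analyses consume:

* trial-aligned response matrices for the stimulus battery, generated from a
  bottom-up receptive-field (RF) model plus a planted *emergent* term:

  ``r_i(trial) = b_i + g_i * B_i(stim) * O_i(stim) + c_i * T_i(stim) + eps``

  where ``B_i`` is the RF-weighted local-contrast (edge-energy) drive of
  the stimulus (luminance-contrast coverage for the RF-mapping grating
  patches), ``O_i`` a von Mises orientation-tuning factor on the dominant
  local edge orientation inside the RF (1 when the RF sees no oriented ink),
  ``T_i`` the indicator that the stimulus carries the neuron's emergent
  feature and ``eps ~ N(0, sigma_i^2)`` i.i.d. trial noise;
* holography-block responses with planted recurrent (like-to-like),
  feedforward (V1 -> higher visual area) and feedback connectivity plus a
  global suppression of the non-photoactivated population;
* millisecond spike trains with planted monosynaptic connections and
  optional slow shared rate comodulation, for the cross-correlogram
  analyses;
* pupil-position traces with configurable gaze excursions.

Emergent classes: an ``IC1`` neuron responds (with amplitude ``c``) to every
stimulus that contains its illusory/real 135-deg bar feature --
``{I_C1, T_RE1, X_RE1, I_RE_135}`` -- and analogously ``IC2`` at 45 deg;
``LC1``/``LC2`` neurons respond only to the matching ``L_C`` image. The
inclusion of the real-edge stimuli is the generative hypothesis under which
inference decoding is positive; it can be switched off with
``emergent_drives_real_edges=False`` to simulate the null.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
seed and configuration give bit-identical sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimgen import StimulusSet, rf_mapping_grid

__all__ = [
    "EMERGENT_FEATURE_SETS",
    "SessionData",
    "Connectivity",
    "HolographyPlan",
    "SpikeTrainSet",
    "PupilTrace",
    "make_population",
    "build_trial_table",
    "compute_stimulus_drive",
    "simulate_population",
    "build_connectivity",
    "simulate_holography",
    "simulate_spike_trains",
    "simulate_pupil",
]

HVA_AREAS = ("LM", "RL", "AL", "PM", "AM")

#: stimuli that carry each emergent feature (bar orientation in the image)
EMERGENT_FEATURE_SETS = {
    "IC1": ("I_C1", "T_RE1", "X_RE1", "I_RE_135"),
    "IC2": ("I_C2", "T_RE2", "X_RE2", "I_RE_45"),
    "LC1": ("L_C1",),
    "LC2": ("L_C2",),
}

_QUADRANT_RF = {  # quadrant -> RF center on the inward inducer midpoint (deg)
    "BR": (11.3, -11.3), "TL": (-11.3, 11.3), "TR": (11.3, 11.3),
    "BL": (-11.3, -11.3),
}

RF_POSITION_LABELS = tuple(f"rf_pos{i}" for i in range(1, 10))


# ---------------------------------------------------------------------------
# containers

@dataclass
class SpikeTrainSet:
    """Spike trains at 1-ms resolution, stored as sorted bin indices."""

    spikes: dict[int, np.ndarray]
    n_bins: int
    bin_ms: float = 1.0

    def binary(self, unit: int) -> np.ndarray:
        x = np.zeros(self.n_bins, dtype=np.int64)
        x[self.spikes[unit]] = 1
        return x

    def times_s(self, unit: int) -> np.ndarray:
        return self.spikes[unit] * self.bin_ms / 1000.0


@dataclass
class PupilTrace:
    t_s: np.ndarray
    xy_deg: np.ndarray  # frames x 2


@dataclass
class SessionData:
    """One synthetic recording session.

    ``responses`` holds the per-trial scalar response (mean over the
    stimulus window); ``frames``/``frame_t_s`` optionally hold a coarse
    within-trial time course (trials x neurons x frames).
    """

    trials: pd.DataFrame
    responses: np.ndarray
    neurons: pd.DataFrame
    spike_trains: SpikeTrainSet | None = None
    pupil: PupilTrace | None = None
    frames: np.ndarray | None = None
    frame_t_s: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[1]

    def trial_mask(self, *labels: str) -> np.ndarray:
        return self.trials["label"].isin(labels).to_numpy()

    def response_matrix(self, *labels: str) -> tuple[np.ndarray, np.ndarray]:
        """Responses and labels restricted to the given stimulus labels."""
        m = self.trial_mask(*labels)
        return self.responses[m], self.trials.loc[m, "label"].to_numpy()

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            t = f.create_group("trials")
            t.create_dataset("label",
                             data=self.trials["label"].fillna("").astype("S"))
            t.create_dataset("block", data=self.trials["block"].astype("S"))
            t.create_dataset("t_on", data=self.trials["t_on"].to_numpy())
            t.create_dataset("t_off", data=self.trials["t_off"].to_numpy())
            if "holo_ensemble" in self.trials:
                t.create_dataset(
                    "holo_ensemble",
                    data=self.trials["holo_ensemble"].fillna("").astype("S"))
            f.create_dataset("responses", data=self.responses,
                             compression="gzip")
            n = f.create_group("neurons")
            for col in self.neurons.columns:
                v = self.neurons[col].to_numpy()
                if v.dtype == object:
                    v = v.astype("S")
                n.create_dataset(col, data=v)
            if self.spike_trains is not None:
                g = f.create_group("spikes")
                g.attrs["n_bins"] = self.spike_trains.n_bins
                g.attrs["bin_ms"] = self.spike_trains.bin_ms
                for uid, s in self.spike_trains.spikes.items():
                    g.create_dataset(str(uid), data=s)
            if self.pupil is not None:
                g = f.create_group("pupil")
                g.create_dataset("t_s", data=self.pupil.t_s)
                g.create_dataset("xy_deg", data=self.pupil.xy_deg)


# ---------------------------------------------------------------------------
# population

def make_population(seed: int,
                    n_v1: int = 200,
                    n_hva: int = 0,
                    hva_area: str = "LM",
                    n_ic_encoders: int = 24,
                    n_lc_encoders: int = 0,
                    n_segment: int = 80,
                    n_center: int = 20,
                    n_hva_segment: int | None = None,
                    emergent_amp: float = 3.0,
                    noise_sd: float = 1.0,
                    gain: float = 4.0,
                    baseline: float = 1.0,
                    rf_sigma_deg: float = 3.0,
                    tuning_kappa: float = 2.0) -> pd.DataFrame:
    """Build a neuron metadata table with planted functional structure.

    The V1 population contains (in order) IC-encoders (half IC1, half IC2,
    RFs mostly in the gap region, preferred orientation matching their
    illusory bar), optional LC-encoders, segment responders (RFs on the four
    inward inducer positions), exclusively-center neurons and background
    neurons with random RFs. Higher-visual-area (HVA) neurons, when
    requested, are mostly segment-driven with RFs on the inducer positions.

    Defaults put the session at a desk-scale version of the study
    conditions: 200 V1 neurons, emergent amplitude 3x the unit trial noise.
    """
    rng = np.random.default_rng(seed)
    if n_ic_encoders + n_lc_encoders + n_segment + n_center > n_v1:
        raise ValueError("V1 subgroup sizes exceed n_v1")
    rows = []

    def add(area, layer, rf, sigma, pref, eclass, amp, x_um, y_um):
        rows.append(dict(
            id=len(rows), x_um=float(x_um), y_um=float(y_um), area=area,
            layer=layer, rf_x_deg=float(rf[0]), rf_y_deg=float(rf[1]),
            rf_sigma_deg=float(sigma), pref_ori_deg=float(pref % 180.0),
            tuning_kappa=float(tuning_kappa), gain=float(gain),
            baseline=float(baseline), emergent_class=eclass,
            emergent_amp=float(amp if eclass != "none" else 0.0),
            noise_sd=float(noise_sd)))

    def v1_pos():
        return rng.uniform(0.0, 1000.0, size=2)

    def disk_jitter(radius):
        # bounded jitter keeps gap-region RFs (with their 2-sigma extent)
        # inside the illusory gap
        r = radius * np.sqrt(rng.uniform())
        a = rng.uniform(0, 2 * np.pi)
        return np.array([r * np.cos(a), r * np.sin(a)])

    quads = ("BR", "TL", "BL", "TR")
    # IC-encoders: IC1 tuned 135 deg, IC2 tuned 45 deg, RFs in the gap
    for k in range(n_ic_encoders):
        cls = "IC1" if k < n_ic_encoders // 2 else "IC2"
        pref = 135.0 if cls == "IC1" else 45.0
        rf = disk_jitter(1.5)
        add("V1", "L2/3", rf, rf_sigma_deg, pref + rng.normal(0, 5),
            cls, emergent_amp, *v1_pos())
    for k in range(n_lc_encoders):
        cls = "LC1" if k < n_lc_encoders // 2 else "LC2"
        rf = disk_jitter(1.5)
        add("V1", "L2/3", rf, rf_sigma_deg, rng.uniform(0, 180),
            cls, emergent_amp, *v1_pos())
    def rot90cw(p):
        return np.array([p[1], -p[0]])

    # segment responders: RF on an inward inducer, orientation-matched.
    # Jitter and tuning scatter are paired under 90-deg rotation between
    # the two diagonals so the population is symmetric between the two
    # image configurations by construction.
    seg_jit: list = []
    for k in range(n_segment):
        q = quads[k % 4]
        cx, cy = _QUADRANT_RF[q]
        if k % 4 in (0, 1):
            jit, dori = disk_jitter(1.5), rng.normal(0, 10)
            seg_jit.append((jit, dori))
        else:
            jit, dori = seg_jit[-2]
            jit = rot90cw(jit)
        rf = np.array([cx, cy]) + jit
        ori = 135.0 if q in ("BR", "TL") else 45.0
        add("V1", "L2/3", rf, rf_sigma_deg, ori + dori,
            "none", 0.0, *v1_pos())
    # exclusively-center neurons: RF in the gap, no emergent drive
    for _ in range(n_center):
        rf = disk_jitter(1.5)
        add("V1", "L2/3", rf, rf_sigma_deg, rng.uniform(0, 180),
            "none", 0.0, *v1_pos())
    # background neurons: random RFs across the field, generated in
    # 90-deg-rotation pairs (RF rotated, preferred orientation +90) for the
    # same configuration symmetry
    n_bg = n_v1 - n_ic_encoders - n_lc_encoders - n_segment - n_center
    for k in range(n_bg):
        if k % 2 == 0:
            rf = rng.uniform(-30.0, 30.0, size=2)
            pref = rng.uniform(0, 180)
        else:
            rf, pref = rot90cw(rf), pref + 90.0
        add("V1", "L2/3", rf, rf_sigma_deg, pref, "none", 0.0, *v1_pos())
    # HVA population, spatially offset from V1 by 2 mm
    if n_hva:
        if n_hva_segment is None:
            n_hva_segment = int(round(0.6 * n_hva))
        hva_jit: list = []
        for k in range(n_hva):
            x, y = rng.uniform(0.0, 1000.0, size=2)
            x += 2500.0
            if k < n_hva_segment:
                q = quads[k % 4]
                cx, cy = _QUADRANT_RF[q]
                if k % 4 in (0, 1):
                    jit, dori = disk_jitter(1.5), rng.normal(0, 10)
                    hva_jit.append((jit, dori))
                else:
                    jit, dori = hva_jit[-2]
                    jit = rot90cw(jit)
                rf = np.array([cx, cy]) + jit
                ori = 135.0 if q in ("BR", "TL") else 45.0
                add(hva_area, "L2/3", rf, rf_sigma_deg, ori + dori,
                    "none", 0.0, x, y)
            else:
                if (k - n_hva_segment) % 2 == 0:
                    rf = rng.uniform(-30.0, 30.0, size=2)
                    pref = rng.uniform(0, 180)
                else:
                    rf, pref = rot90cw(rf), pref + 90.0
                add(hva_area, "L2/3", rf, rf_sigma_deg, pref,
                    "none", 0.0, x, y)
    df = pd.DataFrame(rows)
    bad = (df["rf_sigma_deg"] <= 0) | (df["noise_sd"] < 0)
    if bad.any():
        raise ValueError("invalid neuron parameters")
    return df


# ---------------------------------------------------------------------------
# trial tables

def build_trial_table(label_reps: dict[str, int], seed: int,
                      block: str = "visual",
                      stim_s: float = 1.0, iti_s: float = 0.0,
                      t_start: float = 0.0) -> pd.DataFrame:
    """Randomized-order trial table for one block."""
    rng = np.random.default_rng(seed)
    labels = np.concatenate([[lab] * n for lab, n in label_reps.items()])
    rng.shuffle(labels)
    t_on = t_start + np.arange(len(labels)) * (stim_s + iti_s)
    return pd.DataFrame({
        "label": labels, "block": block, "holo_ensemble": None,
        "t_on": t_on, "t_off": t_on + stim_s,
    })


def default_ic_block_reps(n_train: int = 100, n_other: int = 100) -> dict[str, int]:
    """Per-image repeat counts for the visual battery block.

    Training images (I_C/L_C) get ``n_train`` repeats, probe/control images
    ``n_other`` -- a desk-scale version of the study conditions (400 and
    >=50 repeats respectively).
    """
    reps = {lab: n_train for lab in ("I_C1", "L_C1", "L_C2", "I_C2")}
    for lab in ("T_RE1", "T_RE2", "X_RE1", "X_RE2",
                "I_RE_0", "I_RE_45", "I_RE_90", "I_RE_135",
                "In_BR", "In_BL", "In_TL", "In_TR",
                "Out_BR", "Out_BL", "Out_TL", "Out_TR",
                "blank_circles", "gray"):
        reps[lab] = n_other
    return reps


def default_rf_block_reps(n_reps: int = 10, n_gray: int = 10) -> dict[str, int]:
    reps = {lab: n_reps for lab in RF_POSITION_LABELS}
    reps["gray"] = n_gray
    return reps


# ---------------------------------------------------------------------------
# bottom-up drive model

def _orientation_energy(img: np.ndarray, n_bins: int = 8
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel gradient energy binned by edge orientation.

    Returns ``(energy, bin_centers_deg)`` where ``energy`` has shape
    (n_bins, H, W). Edge orientation is measured clockwise from vertical,
    modulo 180 deg.
    """
    gy_row, gx = np.gradient(img)
    gy = -gy_row  # rows run top->bottom, visual y runs bottom->top
    mag2 = gx * gx + gy * gy
    theta = np.degrees(np.arctan2(gy, -gx)) % 180.0  # edge dir = grad rot -90
    width = 180.0 / n_bins
    idx = np.floor((theta + width / 2.0) / width).astype(int) % n_bins
    energy = np.zeros((n_bins,) + img.shape)
    for b in range(n_bins):
        energy[b][idx == b] = mag2[idx == b]
    centers = np.arange(n_bins) * width
    return energy, centers


#: classical-RF extent: Gaussian weights are truncated at this many sigma
RF_TRUNCATION_SIGMA = 2.0

#: scaling of raster edge energy into contrast-drive units; chosen so a bar
#: or outline crossing an RF yields B*gain of a few noise SDs at the
#: default gain, comparable to the luminance drive of a grating patch
EDGE_CONTRAST_SCALE = 10.0


def _rf_window(x_deg, y_deg, rf_x, rf_y, sigma,
               half_extent=RF_TRUNCATION_SIGMA):
    jx = np.flatnonzero(np.abs(x_deg - rf_x) <= half_extent * sigma)
    iy = np.flatnonzero(np.abs(y_deg - rf_y) <= half_extent * sigma)
    return iy, jx


def compute_stimulus_drive(neurons: pd.DataFrame, stim_set: StimulusSet,
                           labels: list[str] | None = None,
                           emergent_drives_real_edges: bool = True,
                           include_rf_block: bool = False,
                           rf_patch_level: float = 1.0) -> pd.DataFrame:
    """Noiseless per-neuron drive for every stimulus label.

    Returns a DataFrame (index = stimulus label, columns = neuron ids) of
    ``b + g*B*O + c*T``. This is the closed-form mean of the generative
    model and is used both by the simulator and by closed-form tests.

    The bottom-up term ``B`` is local-contrast drive: for the battery
    images it is the RF-weighted mean gradient magnitude (edge energy) of
    the raster, so the shared white-circle *fill* -- identical across
    images and not an oriented feature -- contributes nothing away from its
    rim, while bars and outlines drive neurons whose RF covers their edges.
    For the RF-mapping block (grating patch on a plain gray background,
    cycling through all drift directions) ``B`` is the RF-weighted mean
    luminance contrast |pixel - background| (patch coverage) and the
    orientation factor is 1. Neurons whose RF falls outside the canvas get
    ``B = 0`` with a warning.
    """
    labels = list(labels) if labels is not None else stim_set.labels
    x_deg, y_deg = stim_set.x_deg, stim_set.y_deg
    rf_labels: set[str] = set()
    contrast = {}
    energies = {}
    for lab in labels:
        img = stim_set[lab].pixels
        gy, gx = np.gradient(img)
        contrast[lab] = EDGE_CONTRAST_SCALE * np.sqrt(gx * gx + gy * gy)
        energies[lab] = _orientation_energy(img)
    if include_rf_block:
        centers, diam = rf_mapping_grid(stim_set.spec)
        X, Y = np.meshgrid(x_deg, y_deg)
        for i, (cx, cy) in enumerate(centers, start=1):
            patch = np.full(X.shape, 0.5)
            patch[(X - cx) ** 2 + (Y - cy) ** 2 <= (diam / 2) ** 2] = rf_patch_level
            lab = f"rf_pos{i}"
            contrast[lab] = np.abs(patch - 0.5)
            labels.append(lab)
            rf_labels.add(lab)

    out = np.zeros((len(labels), len(neurons)))
    xmin, xmax = x_deg.min(), x_deg.max()
    ymin, ymax = y_deg.min(), y_deg.max()
    for jn, nr in enumerate(neurons.itertuples(index=False)):
        if not (xmin <= nr.rf_x_deg <= xmax and ymin <= nr.rf_y_deg <= ymax):
            warnings.warn(f"RF of neuron {nr.id} outside canvas; B=0")
            for il, lab in enumerate(labels):
                drive = nr.baseline
                if nr.emergent_class != "none":
                    feats = EMERGENT_FEATURE_SETS[nr.emergent_class]
                    if not emergent_drives_real_edges:
                        feats = feats[:1]
                    if lab in feats:
                        drive += nr.emergent_amp
                out[il, jn] = drive
            continue
        iy, jx = _rf_window(x_deg, y_deg, nr.rf_x_deg, nr.rf_y_deg,
                            nr.rf_sigma_deg)
        dx = (x_deg[jx] - nr.rf_x_deg) / nr.rf_sigma_deg
        dy = (y_deg[iy] - nr.rf_y_deg) / nr.rf_sigma_deg
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        # classical RF: Gaussian truncated at RF_TRUNCATION_SIGMA
        w = np.exp(-0.5 * d2)
        w[d2 > RF_TRUNCATION_SIGMA ** 2] = 0.0
        wsum = w.sum()
        if wsum == 0.0:
            wsum = 1.0
        for il, lab in enumerate(labels):
            crop = contrast[lab][np.ix_(iy, jx)]
            B = float((w * crop).sum() / wsum)
            if lab in rf_labels:
                O = 1.0  # patch gratings cycle through all directions
            else:
                energy, centers = energies[lab]
                e = energy[:, iy][:, :, jx] * w[None]
                bin_tot = e.reshape(e.shape[0], -1).sum(axis=1)
                tot = bin_tot.sum()
                if tot < 1e-9:
                    O = 1.0
                else:
                    dom = centers[int(np.argmax(bin_tot))]
                    d = np.radians(2.0 * (nr.pref_ori_deg - dom))
                    O = float(np.exp(nr.tuning_kappa * (np.cos(d) - 1.0)))
            drive = nr.baseline + nr.gain * B * O
            if nr.emergent_class != "none":
                feats = EMERGENT_FEATURE_SETS[nr.emergent_class]
                if not emergent_drives_real_edges:
                    feats = feats[:1]
                if lab in feats:
                    drive += nr.emergent_amp
            out[il, jn] = drive
    return pd.DataFrame(out, index=labels, columns=neurons["id"].to_numpy())


def simulate_population(neurons: pd.DataFrame, stim_set: StimulusSet,
                        trial_table: pd.DataFrame, seed: int,
                        emergent_drives_real_edges: bool = True,
                        drives: pd.DataFrame | None = None,
                        time_resolved: bool = False,
                        frame_hz: float = 7.715,
                        pupil: PupilTrace | None = None) -> SessionData:
    """Generate trial responses from the generative model.

    ``drives`` may carry a precomputed :func:`compute_stimulus_drive` table
    (it must cover every label in the trial table). With ``time_resolved``
    a coarse within-trial time course from -1 s to t_off+1 s is attached;
    frames inside the stimulus window carry the drive, frames outside carry
    only baseline + noise, and the per-trial scalar response equals the
    mean of the in-window frames.
    """
    rng = np.random.default_rng(seed)
    needed = sorted(set(trial_table["label"]))
    if drives is None:
        battery = [l for l in needed if l in stim_set.images]
        drives = compute_stimulus_drive(
            neurons, stim_set, labels=battery,
            emergent_drives_real_edges=emergent_drives_real_edges,
            include_rf_block=any(l.startswith("rf_pos") for l in needed))
    missing = [l for l in needed if l not in drives.index]
    if missing:
        raise ValueError(f"no drive available for labels {missing}")

    sd = neurons["noise_sd"].to_numpy()
    n_tr, n_nr = len(trial_table), len(neurons)
    drive_mat = drives.loc[trial_table["label"]].to_numpy()
    if not time_resolved:
        responses = drive_mat + rng.normal(0.0, 1.0, (n_tr, n_nr)) * sd
        return SessionData(trials=trial_table.reset_index(drop=True),
                           responses=responses, neurons=neurons.copy(),
                           pupil=pupil)
    stim_s = float((trial_table["t_off"] - trial_table["t_on"]).iloc[0])
    t = np.arange(-1.0, stim_s + 1.0, 1.0 / frame_hz)
    in_win = (t >= 0.0) & (t < stim_s)
    n_f = len(t)
    base = neurons["baseline"].to_numpy()
    frames = np.empty((n_tr, n_nr, n_f))
    frames[:] = base[None, :, None]
    frames[:, :, in_win] = drive_mat[:, :, None]
    frames += rng.normal(0.0, 1.0, frames.shape) * (
        sd[None, :, None] * np.sqrt(in_win.sum()))
    responses = frames[:, :, in_win].mean(axis=2)
    return SessionData(trials=trial_table.reset_index(drop=True),
                       responses=responses, neurons=neurons.copy(),
                       frames=frames, frame_t_s=t, pupil=pupil)


# ---------------------------------------------------------------------------
# connectivity + holography

@dataclass
class Connectivity:
    """Directed weights: local (within V1), feedforward (V1 -> HVA) and
    feedback (HVA -> V1), plus a global suppression scalar."""

    W: np.ndarray
    FF: np.ndarray
    FB: np.ndarray
    suppression: float = 0.3

    def __post_init__(self):
        for M in (self.W, self.FF, self.FB):
            np.fill_diagonal(M, 0.0)
        if self.suppression < 0:
            raise ValueError("suppression must be >= 0")

    @property
    def total(self) -> np.ndarray:
        return self.W + self.FF + self.FB


@dataclass
class HolographyPlan:
    """Named target ensembles and stimulation metadata.

    Pulse metadata follows the study protocol (10 pulses at 10 Hz, 10 ms
    pulse width); ensembles are analyzed downstream only when they have at
    least ``min_targets`` (10) members.
    """

    ensembles: dict[str, list[int]]
    n_reps: int = 50
    direct_drive: float = 5.0
    n_pulses: int = 10
    pulse_hz: float = 10.0
    pulse_width_ms: float = 10.0
    min_targets: int = 10

    def analyzable(self) -> dict[str, list[int]]:
        return {k: v for k, v in self.ensembles.items()
                if len(v) >= self.min_targets}


def build_connectivity(neurons: pd.DataFrame, drives: pd.DataFrame,
                       like_to_like_weight: float = 0.0,
                       feedforward_weight: float = 0.0,
                       feedback_weight: float = 0.0,
                       suppression: float = 0.3,
                       responsive_sd_units: float = 0.5) -> Connectivity:
    """Planted circuit: like-to-like recurrence, segment feedforward, and
    optional feedback.

    * Local: each IC-encoder of class k projects to every other V1 neuron
      whose visual drive to the matching I_C image exceeds baseline by
      ``responsive_sd_units`` noise SDs; per-source weight is
      ``like_to_like_weight / n_class_encoders`` so that targeting the whole
      class delivers a summed drive of about ``like_to_like_weight * d``.
    * Feedforward: non-emergent V1 neurons that are segment-driven project
      to HVA neurons responsive to the same quadrant segment (the circuit
      hypothesis that bottom-up information is relayed forward).
    * Feedback: HVA neurons responsive to an I_C image project to the
      matching IC-encoders.
    """
    n = len(neurons)
    W = np.zeros((n, n))
    FF = np.zeros((n, n))
    FB = np.zeros((n, n))
    area = neurons["area"].to_numpy()
    eclass = neurons["emergent_class"].to_numpy()
    is_v1 = area == "V1"
    blank = drives.loc["blank_circles"].to_numpy()
    sd = neurons["noise_sd"].to_numpy()

    def responsive(label):
        return (drives.loc[label].to_numpy() - blank) > responsive_sd_units * sd

    if like_to_like_weight:
        for k, ic_label in (("IC1", "I_C1"), ("IC2", "I_C2"),
                            ("LC1", "L_C1"), ("LC2", "L_C2")):
            src = np.flatnonzero(is_v1 & (eclass == k))
            if len(src) == 0:
                continue
            tgt = np.flatnonzero(is_v1 & responsive(ic_label))
            w = like_to_like_weight / len(src)
            for i in src:
                W[i, tgt] = w
    if feedforward_weight:
        for q in ("BR", "BL", "TL", "TR"):
            resp_q = responsive(f"In_{q}")
            src = np.flatnonzero(is_v1 & resp_q & (eclass == "none"))
            tgt = np.flatnonzero(~is_v1 & resp_q)
            if len(src) == 0:
                continue
            w = feedforward_weight / len(src)
            for i in src:
                FF[i, tgt] = w
    if feedback_weight:
        for k, ic_label in (("IC1", "I_C1"), ("IC2", "I_C2")):
            src = np.flatnonzero(~is_v1 & responsive(ic_label))
            tgt = np.flatnonzero(is_v1 & (eclass == k))
            if len(src) == 0:
                continue
            w = feedback_weight / len(src)
            for i in src:
                FB[i, tgt] = w
    return Connectivity(W=W, FF=FF, FB=FB, suppression=suppression)


def simulate_holography(neurons: pd.DataFrame, connectivity: Connectivity,
                        plan: HolographyPlan, seed: int,
                        time_resolved: bool = False,
                        frame_hz: float = 7.525,
                        t_start: float = 0.0,
                        iti_s: float = 4.5
                        ) -> SessionData:
    """Holography-block responses.

    Per trial targeting ensemble S: targets receive the direct drive ``d``;
    every neuron j additionally receives ``sum_{i in S} M[i, j] * d`` routed
    through the planted connectivity, minus the global suppression ``s``,
    plus i.i.d. noise. With zero connectivity the non-target population
    carries only ``-s``.
    """
    rng = np.random.default_rng(seed)
    ids = neurons["id"].to_numpy()
    id_to_idx = {int(i): k for k, i in enumerate(ids)}
    n = len(neurons)
    M = connectivity.total
    rows = []
    drive_rows = []
    for name, members in plan.ensembles.items():
        missing = [m for m in members if int(m) not in id_to_idx]
        if missing:
            raise ValueError(f"ensemble {name!r} references unknown ids {missing}")
        sel = np.zeros(n)
        sel[[id_to_idx[int(m)] for m in members]] = 1.0
        d = plan.direct_drive
        drive = d * sel + (M.T @ sel) * d - connectivity.suppression
        for _ in range(plan.n_reps):
            rows.append(name)
            drive_rows.append(drive)
    order = rng.permutation(len(rows))
    stim_s = plan.n_pulses / plan.pulse_hz
    t_on = t_start + np.arange(len(rows)) * (stim_s + iti_s)
    trials = pd.DataFrame({
        "label": None, "block": "holography",
        "holo_ensemble": np.array(rows, dtype=object)[order],
        "t_on": t_on, "t_off": t_on + stim_s,
    })
    drive_mat = np.asarray(drive_rows)[order]
    sd = neurons["noise_sd"].to_numpy()
    if not time_resolved:
        responses = drive_mat + rng.normal(0.0, 1.0, drive_mat.shape) * sd
        return SessionData(trials=trials, responses=responses,
                           neurons=neurons.copy())
    t = np.arange(-1.0, stim_s + 1.0, 1.0 / frame_hz)
    in_win = (t >= 0.0) & (t < stim_s)
    frames = np.zeros((len(rows), n, len(t)))
    frames[:, :, in_win] = drive_mat[:, :, None]
    frames += rng.normal(0.0, 1.0, frames.shape) * (
        sd[None, :, None] * np.sqrt(in_win.sum()))
    responses = frames[:, :, in_win].mean(axis=2)
    return SessionData(trials=trials, responses=responses,
                       neurons=neurons.copy(), frames=frames, frame_t_s=t)


# ---------------------------------------------------------------------------
# spike trains

@dataclass
class Comodulation:
    """Shared slow sinusoidal rate modulation (timescale >= 100 ms)."""

    units: tuple[int, ...] = ()
    depth: float = 0.5
    freq_hz: float = 1.0
    phase: float = 0.0


def simulate_spike_trains(base_rates_hz: dict[int, float],
                          connections: list[tuple[int, int, float, float]],
                          duration_s: float, seed: int,
                          comodulation: Comodulation | None = None
                          ) -> SpikeTrainSet:
    """Poisson spike trains at 1-ms bins with planted synapses.

    ``connections`` is a list of ``(pre, post, lag_ms, transfer_p)``: each
    pre spike independently inserts a post spike at ``lag_ms`` plus a +/-1 ms
    jitter with probability ``transfer_p``. Comodulated units share a slow
    sinusoidal rate modulation, exercising the smoothing correction of the
    cross-correlogram analysis.
    """
    rng = np.random.default_rng(seed)
    L = int(round(duration_s * 1000.0))
    spikes: dict[int, np.ndarray] = {}
    for uid, rate in base_rates_hz.items():
        p = np.full(L, rate / 1000.0)
        if comodulation is not None and uid in comodulation.units:
            t = np.arange(L) / 1000.0
            p = p * (1.0 + comodulation.depth * np.sin(
                2 * np.pi * comodulation.freq_hz * t + comodulation.phase))
            np.clip(p, 0.0, 1.0, out=p)
        spikes[uid] = np.flatnonzero(rng.random(L) < p)
    for pre, post, lag_ms, transfer_p in connections:
        if not (0.0 < lag_ms <= 10.0):
            warnings.warn(f"connection lag {lag_ms} ms outside (0, 10] ms is "
                          "undetectable by the 1-10 ms peak window")
        src = spikes[pre]
        hit = src[rng.random(len(src)) < transfer_p]
        jit = rng.integers(-1, 2, size=len(hit))
        ins = hit + int(round(lag_ms)) + jit
        ins = ins[(ins >= 0) & (ins < L)]
        spikes[post] = np.unique(np.concatenate([spikes[post], ins]))
    return SpikeTrainSet(spikes=spikes, n_bins=L)


# ---------------------------------------------------------------------------
# pupil

def simulate_pupil(trial_table: pd.DataFrame, seed: int,
                   excursion_trials: list[int] | None = None,
                   excursion_fraction: float = 0.0,
                   excursion_deg: float = 10.0,
                   jitter_deg: float = 0.3,
                   frame_hz: float = 30.0) -> PupilTrace:
    """Pupil-position trace with its mode at (0, 0).

    Selected trials (explicit list, or a random fraction) carry a gaze
    excursion of ``excursion_deg`` for their whole duration.
    """
    rng = np.random.default_rng(seed)
    t_end = float(trial_table["t_off"].max()) + 1.0
    t = np.arange(0.0, t_end, 1.0 / frame_hz)
    xy = rng.normal(0.0, jitter_deg, size=(len(t), 2))
    if excursion_trials is None:
        n_exc = int(round(excursion_fraction * len(trial_table)))
        excursion_trials = list(rng.choice(len(trial_table), size=n_exc,
                                           replace=False))
    for ti in excursion_trials:
        row = trial_table.iloc[int(ti)]
        ang = rng.uniform(0, 2 * np.pi)
        off = excursion_deg * np.array([np.cos(ang), np.sin(ang)])
        # strictly interior samples: boundary frames are shared with the
        # neighboring trials at zero ITI
        m = (t > row["t_on"]) & (t < row["t_off"])
        xy[m] += off
    return PupilTrace(t_s=t, xy_deg=xy)
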