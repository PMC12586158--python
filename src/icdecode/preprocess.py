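"""Trace normalization and trial/unit filters applied before analysis.

Calcium traces: neuropil-corrected fluorescence ``Fc = F_roi - 0.7 * F_neu``,
z-scored per continuous recording block (Z-F), and baseline-subtracted
responses (dZ-F). Ephys units: regular-spiking (putative excitatory) filter
by spike trough-to-peak width >= 0.4 ms. Trials: fixed-gaze filter keeping
trials whose pupil position stays within 8 visual degrees of the resting
(modal) position.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthdata import PupilTrace, SessionData

__all__ = [
    "neuropil_correct",
    "zscore_trace",
    "delta_zf",
    "build_response_matrix",
    "fixed_gaze_filter",
    "rs_filter",
    "pupil_mode",
]


def neuropil_correct(f_roi: np.ndarray, f_neu: np.ndarray,
                     coeff: float = 0.7) -> np.ndarray:
    """``Fc = F_roi - coeff * F_neu`` elementwise."""
    f_roi = np.asarray(f_roi, dtype=float)
    f_neu = np.asarray(f_neu, dtype=float)
    if f_roi.shape != f_neu.shape:
        raise ValueError("F_roi and F_neu must have the same shape")
    return f_roi - coeff * f_neu


def zscore_trace(fc: np.ndarray,
                 block_bounds: list[tuple[int, int]] | None = None
                 ) -> np.ndarray:
    """Z-score a trace independently over each continuous recording block.

    ``block_bounds`` are half-open ``(start, stop)`` sample ranges; by
    default the whole trace is one block. A zero-variance block raises.
    """
    fc = np.asarray(fc, dtype=float)
    if block_bounds is None:
        block_bounds = [(0, fc.shape[-1])]
    out = np.empty_like(fc)
    for start, stop in block_bounds:
        seg = fc[..., start:stop]
        sd = seg.std(axis=-1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError(f"zero-variance block [{start}, {stop})")
        out[..., start:stop] = (seg - seg.mean(axis=-1, keepdims=True)) / sd
    return out


def delta_zf(zf: np.ndarray, baseline_window: tuple[int, int]) -> np.ndarray:
    """Subtract the mean Z-F over the baseline (gray-screen) sample window."""
    zf = np.asarray(zf, dtype=float)
    b0, b1 = baseline_window
    return zf - zf[..., b0:b1].mean(axis=-1, keepdims=True)


def build_response_matrix(session: SessionData,
                          window_s: tuple[float, float] | None = None
                          ) -> np.ndarray:
    """Trials x neurons matrix of mean responses over the stated window.

    For time-resolved sessions the window is relative to stimulus onset
    (e.g. (0, 1) for the 1-s presentations, (0, 0.4) for the 0.4-s ephys
    presentations); otherwise the precomputed per-trial scalar responses
    are returned and the window, if given, is validated against the trial
    duration.
    """
    if session.frames is None:
        if window_s is not None:
            dur = float((session.trials["t_off"] - session.trials["t_on"]).max())
            if window_s[0] < -1.0 - 1e-9 or window_s[1] > dur + 1.0 + 1e-9:
                raise ValueError("window outside the simulated trial extent")
        return session.responses.copy()
    if window_s is None:
        window_s = (0.0, float(
            (session.trials["t_off"] - session.trials["t_on"]).iloc[0]))
    t = session.frame_t_s
    m = (t >= window_s[0]) & (t < window_s[1])
    if not m.any():
        raise ValueError("window contains no frames")
    return session.frames[:, :, m].mean(axis=2)


def pupil_mode(pupil: PupilTrace, bin_deg: float = 1.0) -> np.ndarray:
    """Resting pupil position: mode of a 2D histogram of pupil positions.

    The histogram uses ``bin_deg`` bins; ties break toward the earliest bin
    in row-major order. Returns the (x, y) bin center.
    """
    xy = pupil.xy_deg
    x0 = np.floor(xy.min(axis=0) / bin_deg) * bin_deg
    idx = np.floor((xy - x0) / bin_deg).astype(int)
    nb = idx.max(axis=0) + 1
    flat = idx[:, 0] * nb[1] + idx[:, 1]
    counts = np.bincount(flat, minlength=nb[0] * nb[1])
    best = int(np.argmax(counts))  # argmax takes the earliest maximal bin
    bi = np.array([best // nb[1], best % nb[1]])
    return x0 + (bi + 0.5) * bin_deg


def fixed_gaze_filter(pupil: PupilTrace, trials: pd.DataFrame,
                      threshold_deg: float = 8.0) -> np.ndarray:
    """Keep trials whose pupil stays within ``threshold_deg`` of the mode.

    A trial passes only if every pupil sample inside its [t_on, t_off]
    window lies within the threshold of the resting (modal) position.
    """
    mode = pupil_mode(pupil)
    dist = np.linalg.norm(pupil.xy_deg - mode[None, :], axis=1)
    keep = np.empty(len(trials), dtype=bool)
    for k, row in enumerate(trials.itertuples(index=False)):
        m = (pupil.t_s >= row.t_on) & (pupil.t_s <= row.t_off)
        keep[k] = bool(np.all(dist[m] <= threshold_deg)) if m.any() else True
    return keep


def read_nwb_spikes_and_trials(path) -> tuple[dict[int, np.ndarray], pd.DataFrame]:
    """Minimal NWB reader: per-unit spike times and the trial table.

    Reads only the ``units`` (spike_times + ragged index) and
    ``intervals/trials`` groups of an NWB HDF5 file; everything else in the
    file is ignored. Returns spike times in seconds keyed by unit id and a
    trial DataFrame with at least ``t_on`` / ``t_off``.
    """
    import h5py

    with h5py.File(path, "r") as f:
        units = f["units"]
        times = units["spike_times"][()]
        index = units["spike_times_index"][()]
        ids = units["id"][()] if "id" in units else np.arange(len(index))
        spikes = {}
        start = 0
        for uid, stop in zip(ids, index):
            spikes[int(uid)] = times[start:int(stop)]
            start = int(stop)
        tr = f["intervals/trials"]
        data = {"t_on": tr["start_time"][()], "t_off": tr["stop_time"][()]}
        for key in tr:
            if key not in ("start_time", "stop_time", "id"):
                col = tr[key][()]
                if col.dtype.kind == "S":
                    col = col.astype(str)
                if col.ndim == 1 and len(col) == len(data["t_on"]):
                    data[key] = col
        return spikes, pd.DataFrame(data)


def rs_filter(trough_to_peak_ms, min_ms: float = 0.4) -> np.ndarray:
    """Regular-spiking (putative excitatory) unit mask: width >= 0.4 ms."""
    widths = np.asarray(trough_to_peak_ms, dtype=float)
    if np.any(widths <= 0):
        raise ValueError("trough-to-peak widths must be positive")
    return widths >= min_ms
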