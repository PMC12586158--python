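"""Parametric construction of the illusory-contour stimulus battery.

The battery is built from four "inducer" circles placed on the diagonals of
the visual field. Black bars drawn on the circles (inward-pointing inducer
segments) induce an illusory bar across the central gap when two diagonally
opposed segments are aligned (Kanizsa-type configuration):

* ``I_C1`` / ``I_C2`` -- illusory-bar images (135 deg and 45 deg bars; 0 deg
  is vertical, orientation increases clockwise).
* ``L_C1`` / ``L_C2`` -- recombinations of the top and bottom halves of the
  two ``I_C`` images; every local segment is preserved but no illusory bar
  is formed.
* ``T_RE1`` / ``T_RE2`` -- real-edge probes with *equal* ink overlap with the
  corresponding ``I_C`` and ``L_C`` image.
* ``X_RE1`` / ``X_RE2`` -- real-edge probes with equal ink overlap with both
  ``I_C`` images (full-length outlined bar over all four inward inducers).
* ``I_RE_<ori>`` -- outlined real bars at four orientations.
* ``In_<q>`` / ``Out_<q>`` -- single inward / outward inducer segments per
  quadrant (BR, BL, TL, TR).
* ``blank_circles`` / ``gray`` -- the shared circle layer alone, and a blank
  gray field.

Geometry is expressed in idealized visual degrees; the default parameters
are circle diameter 30 deg, diagonal center distance 46 deg (16 deg gap),
inducer bar length 16 deg (support ratio 2/3) and outline thickness 2 deg.
Gray levels: background 0.5, circles 1.0 and ink 0.0 (white-on-black
polarity), inverted for black-on-white. The ``ink_mask`` of an image marks
bar/outline pixels only -- the circle layer is shared by every image and
carries no discriminative information.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Configuration",
    "Polarity",
    "StimulusSpec",
    "StimulusImage",
    "StimulusSet",
    "render_battery",
    "support_ratio",
    "pixel_overlap",
    "rf_mapping_grid",
]

QUADRANTS = ("BR", "BL", "TL", "TR")

#: quadrant -> (diagonal orientation in degrees clockwise from vertical,
#:              sign of the radial direction along that orientation's axis)
_QUADRANT_AXIS = {"BR": (135.0, +1.0), "TL": (135.0, -1.0),
                  "TR": (45.0, +1.0), "BL": (45.0, -1.0)}

I_RE_ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)

TRAINING_LABELS = ("I_C1", "L_C1", "L_C2", "I_C2")


class Configuration(str, enum.Enum):
    """cfg1 is the canonical layout; cfg0 is cfg1 rotated 315 deg clockwise."""

    cfg1 = "cfg1"
    cfg0 = "cfg0"


class Polarity(str, enum.Enum):
    white_on_black = "white_on_black"
    black_on_white = "black_on_white"


def _orient_vec(theta_deg: float) -> np.ndarray:
    """Unit vector of a bar axis at ``theta_deg`` clockwise from vertical."""
    t = math.radians(theta_deg)
    return np.array([math.sin(t), math.cos(t)])


def _rot_cw(p: np.ndarray, beta_deg: float) -> np.ndarray:
    """Rotate a 2D point clockwise by ``beta_deg`` about the origin."""
    b = math.radians(beta_deg)
    c, s = math.cos(b), math.sin(b)
    return np.array([p[0] * c + p[1] * s, -p[0] * s + p[1] * c])


@dataclass(frozen=True)
class StimulusSpec:
    """Geometric parameters of the battery, in visual degrees."""

    circle_diameter_deg: float = 30.0
    diag_center_dist_deg: float = 46.0
    inducer_bar_len_deg: float = 16.0
    bar_outline_thickness_deg: float = 2.0
    bar_width_deg: float = 8.0
    configuration: Configuration = Configuration.cfg1
    polarity: Polarity = Polarity.white_on_black
    raster_ppd: float = 4.0
    canvas_deg: tuple[float, float] = (96.0, 96.0)

    def __post_init__(self) -> None:
        if self.diag_center_dist_deg < self.circle_diameter_deg:
            raise ValueError(
                "diag_center_dist_deg must be at least circle_diameter_deg "
                "(circles must not overlap across the gap)")
        if self.inducer_bar_len_deg < 0:
            raise ValueError("inducer_bar_len_deg must be non-negative")
        if self.bar_outline_thickness_deg * self.raster_ppd < 2.0:
            raise ValueError(
                f"raster_ppd={self.raster_ppd} is too coarse to represent a "
                f"{self.bar_outline_thickness_deg} deg outline (needs >= 2 px)")

    @property
    def gap_deg(self) -> float:
        """Gap between diagonally opposed circles along their diagonal."""
        return self.diag_center_dist_deg - self.circle_diameter_deg

    @property
    def illusory_bar_len_deg(self) -> float:
        """End-to-end extent of the (illusory or real) bar: 2 segments + gap."""
        return 2.0 * self.inducer_bar_len_deg + self.gap_deg

    @property
    def rotation_deg(self) -> float:
        return 315.0 if self.configuration is Configuration.cfg0 else 0.0

    def replace(self, **kw) -> "StimulusSpec":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["configuration"] = self.configuration.value
        d["polarity"] = self.polarity.value
        d["canvas_deg"] = list(self.canvas_deg)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "StimulusSpec":
        d = dict(d)
        if "configuration" in d:
            d["configuration"] = Configuration(d["configuration"])
        if "polarity" in d:
            d["polarity"] = Polarity(d["polarity"])
        if "canvas_deg" in d:
            d["canvas_deg"] = tuple(d["canvas_deg"])
        return cls(**d)


# ---------------------------------------------------------------------------
# geometric primitives

@dataclass(frozen=True)
class _Disk:
    cx: float
    cy: float
    r: float

    def mask(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        return (X - self.cx) ** 2 + (Y - self.cy) ** 2 <= self.r ** 2

    def rotated(self, beta: float) -> "_Disk":
        c = _rot_cw(np.array([self.cx, self.cy]), beta)
        return _Disk(c[0], c[1], self.r)


@dataclass(frozen=True)
class _RotRect:
    """Filled rectangle centered at (cx, cy), long axis at ``theta`` deg
    clockwise from vertical."""

    cx: float
    cy: float
    length: float
    width: float
    theta: float

    def mask(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        u = _orient_vec(self.theta)
        dx, dy = X - self.cx, Y - self.cy
        along = dx * u[0] + dy * u[1]
        across = dx * u[1] - dy * u[0]
        return (np.abs(along) <= self.length / 2) & (np.abs(across) <= self.width / 2)

    def rotated(self, beta: float) -> "_RotRect":
        c = _rot_cw(np.array([self.cx, self.cy]), beta)
        return _RotRect(c[0], c[1], self.length, self.width, self.theta + beta)


@dataclass(frozen=True)
class _OutlineRect:
    """Rectangle outline (frame) of the given edge thickness."""

    cx: float
    cy: float
    length: float
    width: float
    theta: float
    thickness: float

    def mask(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        outer = _RotRect(self.cx, self.cy, self.length, self.width, self.theta)
        inner = _RotRect(self.cx, self.cy,
                         max(self.length - 2 * self.thickness, 0.0),
                         max(self.width - 2 * self.thickness, 0.0), self.theta)
        return outer.mask(X, Y) & ~inner.mask(X, Y)

    def rotated(self, beta: float) -> "_OutlineRect":
        c = _rot_cw(np.array([self.cx, self.cy]), beta)
        return _OutlineRect(c[0], c[1], self.length, self.width,
                            self.theta + beta, self.thickness)


def _circle_primitives(spec: StimulusSpec) -> list[_Disk]:
    r = spec.circle_diameter_deg / 2.0
    rad = spec.diag_center_dist_deg / 2.0
    disks = []
    for q in QUADRANTS:
        theta, sign = _QUADRANT_AXIS[q]
        c = sign * rad * _orient_vec(theta)
        disks.append(_Disk(c[0], c[1], r))
    return disks


def _inducer_bar(spec: StimulusSpec, quadrant: str, inward: bool) -> _RotRect:
    """Inducer segment in ``quadrant``.

    Inward bars run from the circle's inner edge (gap/2 from center) outward
    over ``inducer_bar_len_deg``; outward bars are flush with the circle's
    outer edge and extend the same length inward.
    """
    theta, sign = _QUADRANT_AXIS[quadrant]
    L = spec.inducer_bar_len_deg
    if inward:
        r0 = spec.gap_deg / 2.0
        r1 = r0 + L
    else:
        r1 = spec.diag_center_dist_deg / 2.0 + spec.circle_diameter_deg / 2.0
        r0 = r1 - L
    mid = sign * (r0 + r1) / 2.0
    c = mid * _orient_vec(theta)
    return _RotRect(c[0], c[1], L, spec.bar_width_deg, theta)


def _tre_outline_bar(spec: StimulusSpec, theta: float, sign: float
                     ) -> _OutlineRect:
    """Real-edge bar of a T_RE image: spans from the shared inducer's inner
    edge to the canvas center.

    Ending at the center keeps the bar equidistant from the two inducer
    positions that distinguish the matched I_C and L_C images, so both the
    pixel overlap and the local-contrast drive are balanced between them.
    """
    half = spec.gap_deg / 2.0
    c = sign * (half / 2.0) * _orient_vec(theta)
    return _OutlineRect(c[0], c[1], half, spec.bar_width_deg, theta,
                        spec.bar_outline_thickness_deg)


def _full_outline_bar(spec: StimulusSpec, theta: float) -> _OutlineRect:
    return _OutlineRect(0.0, 0.0, spec.illusory_bar_len_deg,
                        spec.bar_width_deg, theta,
                        spec.bar_outline_thickness_deg)


# ---------------------------------------------------------------------------
# rendered image containers

@dataclass
class StimulusImage:
    label: str
    pixels: np.ndarray        # float raster in [0, 1]
    ink_mask: np.ndarray      # bool raster, non-background non-circle pixels

    @property
    def ink_count(self) -> int:
        return int(self.ink_mask.sum())


def pixel_overlap(a: StimulusImage, b: StimulusImage) -> float:
    """Normalized ink overlap (Jaccard index of the two ink masks).

    The shared circle layer is excluded because it is identical across
    images; only bar/outline ink is compared.
    """
    if a.ink_mask.shape != b.ink_mask.shape:
        raise ValueError("stimulus images are on different raster grids")
    inter = int((a.ink_mask & b.ink_mask).sum())
    union = int((a.ink_mask | b.ink_mask).sum())
    if union == 0:
        return 1.0 if a.label == b.label else 0.0
    return inter / union


@dataclass
class StimulusSet:
    spec: StimulusSpec
    images: dict[str, StimulusImage]
    x_deg: np.ndarray = field(repr=False)   # pixel-center x coords (deg)
    y_deg: np.ndarray = field(repr=False)   # pixel-center y coords (deg)

    def __getitem__(self, label: str) -> StimulusImage:
        return self.images[label]

    def __contains__(self, label: str) -> bool:
        return label in self.images

    @property
    def labels(self) -> list[str]:
        return list(self.images)

    def overlap_matrix(self, labels: Iterable[str] | None = None
                       ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Pairwise ink intersection counts and Jaccard fractions.

        Returns ``(counts, fractions, labels)``; ``fractions`` is symmetric
        with unit diagonal.
        """
        labels = list(labels) if labels is not None else self.labels
        n = len(labels)
        counts = np.zeros((n, n), dtype=int)
        frac = np.zeros((n, n))
        for i, la in enumerate(labels):
            for j, lb in enumerate(labels):
                if j < i:
                    counts[i, j] = counts[j, i]
                    frac[i, j] = frac[j, i]
                    continue
                ma, mb = self.images[la].ink_mask, self.images[lb].ink_mask
                counts[i, j] = int((ma & mb).sum())
                frac[i, j] = pixel_overlap(self.images[la], self.images[lb])
        return counts, frac, labels

    # -- IO ------------------------------------------------------------
    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("stimuli")
            for k, v in self.spec.to_dict().items():
                g.attrs[k] = v if not isinstance(v, list) else np.asarray(v)
            g.create_dataset("x_deg", data=self.x_deg)
            g.create_dataset("y_deg", data=self.y_deg)
            labels = self.labels
            g.create_dataset("labels", data=np.array(labels, dtype="S"))
            g.create_dataset(
                "pixels", data=np.stack([self.images[l].pixels for l in labels]),
                compression="gzip")
            g.create_dataset(
                "ink_mask", data=np.stack([self.images[l].ink_mask for l in labels]),
                compression="gzip")
            counts, frac, _ = self.overlap_matrix()
            g.create_dataset("overlap_counts", data=counts)
            g.create_dataset("overlap_fractions", data=frac)

    def save_pngs(self, outdir) -> None:
        from pathlib import Path

        from PIL import Image

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for label, img in self.images.items():
            arr = np.round(img.pixels * 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(outdir / f"{label}.png")


# ---------------------------------------------------------------------------
# operations

def support_ratio(spec: StimulusSpec) -> float:
    """Fraction of the illusory bar physically supported by inducer ink:
    ``2 L / (2 L + gap)`` with the default geometry = 2/3."""
    L = spec.inducer_bar_len_deg
    denom = 2.0 * L + spec.gap_deg
    if denom == 0:
        raise ValueError("support ratio undefined for zero bar and zero gap")
    return 2.0 * L / denom


def rf_mapping_grid(spec: StimulusSpec | None = None,
                    eccentricity_deg: float = 16.0,
                    patch_diameter_deg: float = 16.0
                    ) -> tuple[list[tuple[float, float]], float]:
    """Centers of the 9 receptive-field-mapping grating patches.

    Position 1 is the canvas center (the illusory gap region); positions
    2-9 sit at 16 deg eccentricity at clock positions
    6 / 4.5 / 3 / 1.5 / 12 / 10.5 / 9 / 7.5.
    """
    centers = [(0.0, 0.0)]
    for clock in (6.0, 4.5, 3.0, 1.5, 12.0, 10.5, 9.0, 7.5):
        ang = math.radians(clock * 30.0)  # clockwise from 12 o'clock
        centers.append((eccentricity_deg * math.sin(ang),
                        eccentricity_deg * math.cos(ang)))
    return centers, patch_diameter_deg


def _battery_primitives(spec: StimulusSpec) -> dict[str, list]:
    """Ink primitives per label, in the canonical (cfg1) frame."""
    inward = {q: _inducer_bar(spec, q, inward=True) for q in QUADRANTS}
    outward = {q: _inducer_bar(spec, q, inward=False) for q in QUADRANTS}
    prims: dict[str, list] = {
        "I_C1": [inward["BR"], inward["TL"]],
        "I_C2": [inward["BL"], inward["TR"]],
        # L_C images: half-swapped recombinations about the horizontal
        # midline -- bottom half of I_C1 + top half of I_C2 and vice versa.
        "L_C1": [inward["BR"], inward["TR"]],
        "L_C2": [inward["TL"], inward["BL"]],
        "T_RE1": [inward["BR"], _tre_outline_bar(spec, 135.0, +1.0)],
        "T_RE2": [inward["BL"], _tre_outline_bar(spec, 45.0, -1.0)],
        "X_RE1": [*inward.values(), _full_outline_bar(spec, 135.0)],
        "X_RE2": [*inward.values(), _full_outline_bar(spec, 45.0)],
        "blank_circles": [],
        "gray": [],
    }
    for ori in I_RE_ORIENTATIONS:
        prims[f"I_RE_{int(ori)}"] = [_full_outline_bar(spec, ori)]
    for q in QUADRANTS:
        prims[f"In_{q}"] = [inward[q]]
        prims[f"Out_{q}"] = [outward[q]]
    return prims


def render_battery(spec: StimulusSpec | None = None) -> StimulusSet:
    """Rasterize the full labeled battery at the spec's resolution.

    Every image except ``gray`` shares the identical four-circle layer; the
    configuration rotation (cfg0) is applied to the geometric primitives
    before rasterization, so no image resampling is involved.
    """
    spec = spec or StimulusSpec()
    w, h = spec.canvas_deg
    nx = int(round(w * spec.raster_ppd))
    ny = int(round(h * spec.raster_ppd))
    x = (np.arange(nx) + 0.5) / spec.raster_ppd - w / 2.0
    y = h / 2.0 - (np.arange(ny) + 0.5) / spec.raster_ppd
    X, Y = np.meshgrid(x, y)

    beta = spec.rotation_deg
    circles = [d.rotated(beta) if beta else d for d in _circle_primitives(spec)]
    circle_mask = np.zeros((ny, nx), dtype=bool)
    for d in circles:
        circle_mask |= d.mask(X, Y)

    if spec.polarity is Polarity.white_on_black:
        circle_level, ink_level = 1.0, 0.0
    else:
        circle_level, ink_level = 0.0, 1.0

    images: dict[str, StimulusImage] = {}
    for label, prims in _battery_primitives(spec).items():
        ink = np.zeros((ny, nx), dtype=bool)
        for p in prims:
            p = p.rotated(beta) if beta else p
            ink |= p.mask(X, Y)
        px = np.full((ny, nx), 0.5)
        if label != "gray":
            px[circle_mask] = circle_level
        px[ink] = ink_level
        images[label] = StimulusImage(label=label, pixels=px, ink_mask=ink)
    return StimulusSet(spec=spec, images=images, x_deg=x, y_deg=y)
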