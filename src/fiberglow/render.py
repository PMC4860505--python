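"""Render simulated fibers as multi-channel fluorescence microscopy fields.

Each field is a three-channel 16-bit image: CldU (whole-fiber prelabel),
IdU (replication tracts) and qdot (quantum-dot Dig-TMP adduct signals).
Fibers are laid out as smooth, bounded-curvature curves in horizontal lanes
with a guaranteed minimum separation, so ground truth stays unambiguous;
an optional noise model adds shot noise and Gaussian read noise on top of a
constant background. Ground-truth pixel coordinates of every fiber path and
every spot are emitted alongside the images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import ConfigError, RenderConfig
from .simulate import Fiber

CHANNELS = ("cldU", "idU", "qdot")


@dataclass
class ImageSet:
    """Registered multi-channel field with pixel-scale metadata."""

    channels: dict[str, np.ndarray]
    pixel_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ConfigError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class FiberLayout:
    """Ground-truth geometry of one rendered fiber."""

    fiber_id: int
    field_index: int
    path: np.ndarray  # (N, 2) float, (row, col) at 1-px arc steps
    arc_px: np.ndarray  # (N,) cumulative arc length
    length_px: float


@dataclass
class RenderedField:
    """One rendered field plus the ground truth needed to score it."""

    image_set: ImageSet
    layouts: list[FiberLayout]
    spots: pd.DataFrame  # fiber_id, position_kb, row, col


def _smooth_path(
    start: tuple[float, float],
    length_px: float,
    band_halfwidth: float,
    rc: RenderConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Random smooth curve of exact arc length, confined to a horizontal band.

    The heading performs a clamped random walk with a restoring pull toward
    the band center, so curvature stays bounded and the fiber never leaves
    its lane. Returns (path, cumulative arc length); steps are 1 px with a
    fractional final step.
    """
    n_full = int(np.floor(length_px))
    frac = length_px - n_full
    steps = [1.0] * n_full + ([frac] if frac > 1e-9 else [])
    y0, x0 = start
    pts = [(y0, x0)]
    theta = float(rng.normal(0.0, rc.curvature_sd * 3))
    y, x = y0, x0
    for ds in steps:
        dev = (y - y0) / max(band_halfwidth, 1e-6)
        target = -np.clip(dev, -1.0, 1.0) * 0.2
        theta = 0.92 * theta + 0.08 * target + rng.normal(0.0, rc.curvature_sd)
        theta = float(np.clip(theta, -rc.max_heading_rad, rc.max_heading_rad))
        x += ds * np.cos(theta)
        y += ds * np.sin(theta)
        pts.append((y, x))
    path = np.asarray(pts, dtype=float)
    seg = np.sqrt(((np.diff(path, axis=0)) ** 2).sum(axis=1))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return path, arc


def _deposit_line(img: np.ndarray, path: np.ndarray, arc: np.ndarray, arc_lo: float, arc_hi: float, amplitude: float) -> None:
    """Bilinearly deposit ``amplitude`` per px of arc over [arc_lo, arc_hi]."""
    ds = 0.25
    total = arc[-1]
    lo, hi = max(0.0, arc_lo), min(total, arc_hi)
    if hi <= lo:
        return
    s = np.arange(lo, hi, ds)
    ys = np.interp(s, arc, path[:, 0])
    xs = np.interp(s, arc, path[:, 1])
    _deposit_points(img, ys, xs, np.full(s.size, amplitude * ds))


def _deposit_points(img: np.ndarray, ys: np.ndarray, xs: np.ndarray, amps: np.ndarray) -> None:
    h, w = img.shape
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    fy = ys - y0
    fx = xs - x0
    for dy, dx, wgt in (
        (0, 0, (1 - fy) * (1 - fx)),
        (0, 1, (1 - fy) * fx),
        (1, 0, fy * (1 - fx)),
        (1, 1, fy * fx),
    ):
        yy = y0 + dy
        xx = x0 + dx
        ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        np.add.at(img, (yy[ok], xx[ok]), amps[ok] * wgt[ok])


def arc_kb_to_xy(layout: FiberLayout, position_kb: float, rc: RenderConfig) -> tuple[float, float]:
    """Map a kb arc position on a fiber to (row, col) image coordinates."""
    s = position_kb * rc.px_per_kb
    y = float(np.interp(s, layout.arc_px, layout.path[:, 0]))
    x = float(np.interp(s, layout.arc_px, layout.path[:, 1]))
    return y, x


def render_images(
    fibers: Sequence[Fiber],
    rc: RenderConfig,
    rng: np.random.Generator,
) -> list[RenderedField]:
    """Render fibers into as many fields as needed; never overlaps fibers.

    Fibers are packed greedily into horizontal lanes (``row_height_px``
    tall, ``min_gap_px`` apart along a lane); when a field is full a new one
    is started. A fiber too long for the usable field width raises a
    ``ConfigError`` asking for a larger image or shorter fibers.
    """
    h, w = rc.image_shape
    usable_w = w - 2 * rc.margin_px
    lane_h = rc.row_height_px
    n_lanes = (h - 2 * rc.margin_px) // lane_h
    if n_lanes < 1 or usable_w < 10:
        raise ConfigError("image_shape too small for the configured margins")

    fields: list[dict] = []

    def new_field() -> dict:
        f = {
            "signal": {ch: np.zeros((h, w)) for ch in CHANNELS},
            "layouts": [],
            "spot_rows": [],
            "lane": 0,
            "x": float(rc.margin_px),
        }
        fields.append(f)
        return f

    fld = new_field()
    for fb in fibers:
        length_px = fb.length_kb * rc.px_per_kb
        if length_px > usable_w:
            raise ConfigError(
                f"fiber {fb.id} ({fb.length_kb:.0f} kb = {length_px:.0f} px) exceeds the usable field "
                f"width ({usable_w} px); enlarge image_shape or truncate fiber lengths"
            )
        # horizontal extent never exceeds arc length, so this fit test is safe
        if fld["x"] + length_px > w - rc.margin_px:
            fld["lane"] += 1
            fld["x"] = float(rc.margin_px)
        if fld["lane"] >= n_lanes:
            fld = new_field()
        y_center = rc.margin_px + fld["lane"] * lane_h + lane_h / 2.0
        band = lane_h / 2.0 - 3.0
        path, arc = _smooth_path((y_center, fld["x"]), length_px, max(band, 1.0), rc, rng)
        fld["x"] = float(path[:, 1].max()) + rc.min_gap_px

        layout = FiberLayout(
            fiber_id=fb.id,
            field_index=len(fields) - 1,
            path=path,
            arc_px=arc,
            length_px=float(arc[-1]),
        )
        fld["layouts"].append(layout)

        gains = rc.channel_gains
        _deposit_line(fld["signal"]["cldU"], path, arc, 0.0, arc[-1], gains["cldU"])
        for t in fb.idu_tracts:
            _deposit_line(
                fld["signal"]["idU"], path, arc, t.start_kb * rc.px_per_kb, t.end_kb * rc.px_per_kb, gains["idU"]
            )
        for ad in fb.adducts:
            y, x = arc_kb_to_xy(layout, ad.position_kb, rc)
            _deposit_points(
                fld["signal"]["qdot"], np.array([y]), np.array([x]), np.array([gains["qdot"]])
            )
            fld["spot_rows"].append(
                {"fiber_id": fb.id, "position_kb": ad.position_kb, "row": y, "col": x, "kind": ad.kind}
            )

    out: list[RenderedField] = []
    for idx, fld in enumerate(fields):
        channels: dict[str, np.ndarray] = {}
        for ch in CHANNELS:
            img = fld["signal"][ch]
            if rc.psf_sigma_px > 0:
                img = gaussian_filter(img, rc.psf_sigma_px)
            img = img + rc.background_level
            if rc.shot_noise:
                img = rng.poisson(np.maximum(img, 0.0) * rc.photon_gain) / rc.photon_gain
            if rc.read_noise_sd > 0:
                img = img + rng.normal(0.0, rc.read_noise_sd, img.shape)
            channels[ch] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
        spots = pd.DataFrame(fld["spot_rows"], columns=["fiber_id", "position_kb", "row", "col", "kind"])
        out.append(
            RenderedField(
                image_set=ImageSet(
                    channels=channels,
                    pixel_um=rc.pixel_um,
                    meta={"field_index": idx, "kb_per_um": rc.kb_per_um},
                ),
                layouts=fld["layouts"],
                spots=spots,
            )
        )
    return out
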