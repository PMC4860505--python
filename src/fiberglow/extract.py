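"""Quantum-dot spot detection, spot-to-fiber assignment and IdU tract
segmentation.

The quantum-dot channel reports every Dig-TMP adduct — interstrand
crosslinks and monoadducts alike, since the immunotag cannot distinguish
them — as a bright diffraction-limited spot. Detection thresholds are
expressed in multiples of the robust background SD so they are invariant
to channel gain. Replication tracts are recovered from the IdU intensity
profile sampled along each traced fiber.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from .trace import FiberTrace

log = logging.getLogger(__name__)


@dataclass
class SpotParams:
    threshold_k: float = 5.0  # background SD multiples
    min_separation_px: int = 3
    centroid_window_px: int = 2  # half-width of the sub-pixel centroid window
    smooth_sigma: float = 1.0


@dataclass(frozen=True)
class Spot:
    row: float
    col: float
    peak_intensity: float
    snr: float


@dataclass(frozen=True)
class DetectedSignal:
    """A quantum-dot spot assigned to a fiber at arc position ``arc_kb``."""

    fiber_id: int
    arc_kb: float
    row: float
    col: float
    peak_intensity: float
    snr: float
    dist_px: float


@dataclass(frozen=True)
class TractInterval:
    """A replication tract on a fiber, half-open in kb."""

    fiber_id: int
    start_kb: float
    end_kb: float
    label: str = "IdU"
    mean_intensity: float = 0.0


@dataclass
class AssignmentResult:
    signals: list[DetectedSignal]
    n_unassigned: int = 0
    n_ties: int = 0


def detect_spots(qdot_channel: np.ndarray, params: SpotParams | None = None) -> list[Spot]:
    """Detect point-like quantum-dot signals in one channel.

    Local maxima of the lightly smoothed channel exceeding
    ``background + threshold_k * SD`` (robust median/MAD estimates) are
    accepted; maxima closer than ``min_separation_px`` collapse to the
    brighter one; centroids are refined to sub-pixel precision by an
    intensity-weighted mean in a small window. Zero detections is a valid
    outcome.
    """
    params = params or SpotParams()
    img = np.asarray(qdot_channel, dtype=float)
    sm = ndimage.gaussian_filter(img, params.smooth_sigma) if params.smooth_sigma > 0 else img
    bg = float(np.median(sm))
    sd = 1.4826 * float(np.median(np.abs(sm - bg)))
    thr = bg + max(params.threshold_k * sd, 1e-6)
    coords = peak_local_max(sm, min_distance=params.min_separation_px, threshold_abs=thr, exclude_border=False)
    spots: list[Spot] = []
    win = params.centroid_window_px
    h, w = sm.shape
    for r, c in coords:
        r0, r1 = max(0, r - win), min(h, r + win + 1)
        c0, c1 = max(0, c - win), min(w, c + win + 1)
        patch = np.clip(sm[r0:r1, c0:c1] - bg, 0.0, None)
        total = patch.sum()
        if total <= 0:
            continue
        ys, xs = np.mgrid[r0:r1, c0:c1]
        cy = float((patch * ys).sum() / total)
        cx = float((patch * xs).sum() / total)
        peak = float(sm[r, c])
        snr = (peak - bg) / sd if sd > 0 else np.inf
        spots.append(Spot(row=cy, col=cx, peak_intensity=peak, snr=float(snr)))
    return spots


def _point_to_polyline(point: np.ndarray, poly: np.ndarray, arc: np.ndarray) -> tuple[float, float]:
    """Minimum distance from a point to a polyline, and the arc position of
    the closest approach (px)."""
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    seg_len2 = (ab**2).sum(axis=1)
    seg_len2 = np.where(seg_len2 == 0, 1e-12, seg_len2)
    t = np.clip(((point - a) * ab).sum(axis=1) / seg_len2, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d2 = ((point - proj) ** 2).sum(axis=1)
    i = int(np.argmin(d2))
    arc_at = arc[i] + t[i] * np.sqrt(seg_len2[i])
    return float(np.sqrt(d2[i])), float(arc_at)


def assign_spots_to_fibers(
    spots: Sequence[Spot],
    traces: Sequence[FiberTrace],
    max_dist_px: float = 3.0,
    kb_per_px: float = 0.16 * 2.59,
    tie_eps_px: float = 1e-6,
) -> AssignmentResult:
    """Assign each spot to the nearest fiber trace by perpendicular distance.

    Spots farther than ``max_dist_px`` from every trace, or exactly
    equidistant between two traces, are left unassigned (ties are counted
    and logged). Arc positions come from orthogonal projection onto the
    polyline, converted to kb and clamped to the fiber length.
    """
    result = AssignmentResult(signals=[])
    if not traces:
        result.n_unassigned = len(spots)
        return result
    arcs = []
    for tr in traces:
        seg = np.sqrt((np.diff(tr.polyline, axis=0) ** 2).sum(axis=1))
        arcs.append(np.concatenate([[0.0], np.cumsum(seg)]))
    bboxes = [
        (tr.polyline[:, 0].min(), tr.polyline[:, 0].max(), tr.polyline[:, 1].min(), tr.polyline[:, 1].max())
        for tr in traces
    ]
    for sp in spots:
        pt = np.array([sp.row, sp.col])
        best = (np.inf, -1, 0.0)
        second = np.inf
        for idx, tr in enumerate(traces):
            y0, y1, x0, x1 = bboxes[idx]
            if not (y0 - max_dist_px <= sp.row <= y1 + max_dist_px and x0 - max_dist_px <= sp.col <= x1 + max_dist_px):
                continue
            d, arc_at = _point_to_polyline(pt, tr.polyline, arcs[idx])
            if d < best[0]:
                second = best[0]
                best = (d, idx, arc_at)
            elif d < second:
                second = d
        if best[1] < 0 or best[0] > max_dist_px:
            result.n_unassigned += 1
            continue
        if abs(best[0] - second) <= tie_eps_px:
            result.n_ties += 1
            result.n_unassigned += 1
            log.info("spot at (%.1f, %.1f) equidistant between two fibers; discarded", sp.row, sp.col)
            continue
        tr = traces[best[1]]
        arc_kb = float(np.clip(best[2] * kb_per_px, 0.0, tr.length_kb))
        result.signals.append(
            DetectedSignal(
                fiber_id=tr.id,
                arc_kb=arc_kb,
                row=sp.row,
                col=sp.col,
                peak_intensity=sp.peak_intensity,
                snr=sp.snr,
                dist_px=best[0],
            )
        )
    return result


def segment_tracts(
    arc_kb: np.ndarray,
    profile: np.ndarray,
    threshold: float | str = "otsu",
    gap_close_kb: float = 2.0,
    min_tract_kb: float = 1.0,
    fiber_id: int = -1,
    otsu_contrast_k: float = 4.0,
) -> list[TractInterval]:
    """Segment supra-threshold runs of an IdU profile into tract intervals.

    Runs separated by sub-threshold gaps shorter than ``gap_close_kb`` are
    merged; merged runs shorter than ``min_tract_kb`` are dropped. Each run
    of samples maps to the half-open interval [first - step/2, last + step/2)
    clipped to the fiber, so an n-sample run has width n*step.

    ``threshold='otsu'`` thresholds the profile by Otsu's method, guarded by
    a contrast test (the above-threshold mean must exceed the
    below-threshold mean by ``otsu_contrast_k`` below-threshold SDs) so that
    a tract-free noise profile yields no tracts.
    """
    arc = np.asarray(arc_kb, dtype=float)
    prof = np.asarray(profile, dtype=float)
    if arc.size == 0 or prof.size != arc.size:
        return []
    step = float(np.median(np.diff(arc))) if arc.size > 1 else 1.0
    if threshold == "otsu":
        if float(np.ptp(prof)) <= 1e-9:
            return []
        thr = float(threshold_otsu(prof))
        below = prof[prof < thr]
        above = prof[prof >= thr]
        if below.size == 0 or above.size == 0:
            return []
        if above.mean() - below.mean() < otsu_contrast_k * (below.std() + 1e-9):
            return []
    else:
        thr = float(threshold)
    binary = prof >= thr
    if not binary.any():
        return []

    # runs of consecutive True samples
    idx = np.flatnonzero(binary)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks], [idx[-1]]])
    runs = [
        [arc[s] - step / 2.0, arc[e] + step / 2.0, s, e]
        for s, e in zip(run_starts, run_ends)
    ]
    merged = [runs[0]]
    for run in runs[1:]:
        if run[0] - merged[-1][1] < gap_close_kb:
            merged[-1][1] = run[1]
            merged[-1][3] = run[3]
        else:
            merged.append(run)
    out: list[TractInterval] = []
    fiber_end = arc[-1] + step / 2.0
    for s_kb, e_kb, si, ei in merged:
        s_kb = max(0.0, s_kb)
        e_kb = min(fiber_end, e_kb)
        if e_kb - s_kb < min_tract_kb:
            continue
        out.append(
            TractInterval(
                fiber_id=fiber_id,
                start_kb=float(s_kb),
                end_kb=float(e_kb),
                mean_intensity=float(prof[si : ei + 1].mean()),
            )
        )
    return out
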