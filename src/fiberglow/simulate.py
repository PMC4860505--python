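"""Ground-truth generator for single-molecule DNA fiber experiments.

Fibers are uniformly CldU-prelabeled DNA molecules carrying psoralen
(Dig-TMP) adducts — mostly interstrand crosslinks, with a minority of
monoadducts — and IdU replication tracts laid down during a 1-h pulse after
photoactivation. Adducts follow a piecewise-constant-rate Poisson process
(a two-zone chromatin-accessibility model); replication events either abut
one side of an adduct (single-sided encounter), flank both sides
(double-sided), or sit far from any adduct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .config import AccessibilityConfig, ConfigError, ReplicationConfig, SimulationConfig

ICL = "ICL"
MONOADDUCT = "monoadduct"

# per-adduct replication-event labels recorded in ground truth
EVENT_NONE = "none"
EVENT_SINGLE = "single"
EVENT_DOUBLE = "double"


@dataclass(frozen=True)
class Adduct:
    """A covalent Dig-TMP adduct at ``position_kb`` from the fiber start."""

    position_kb: float
    kind: str  # ICL | monoadduct
    event: str = EVENT_NONE  # replication event attached to this adduct
    degraded: bool = False  # double-sided request degraded near a fiber end


@dataclass(frozen=True)
class Tract:
    """A labeled nucleoside tract occupying the half-open interval [start, end)."""

    start_kb: float
    end_kb: float
    label: str  # "CldU" | "IdU"
    adduct_index: int = -1  # index of the adduct this tract abuts, -1 if distant
    trimmed: bool = False  # free end shortened to resolve an overlap


@dataclass
class Fiber:
    """One simulated DNA molecule with its full ground truth."""

    id: int
    length_kb: float
    adducts: list[Adduct] = field(default_factory=list)
    tracts: list[Tract] = field(default_factory=list)
    origin_label: str = "lamp"
    in_roi: bool = True

    @property
    def idu_tracts(self) -> list[Tract]:
        return [t for t in self.tracts if t.label == "IdU"]


def place_adducts(
    length_kb: float,
    adduct_rate: float,
    accessibility: AccessibilityConfig,
    icl_fraction: float,
    rng: np.random.Generator,
) -> list[Adduct]:
    """Place adducts on one fiber by an inhomogeneous Poisson process.

    ``adduct_rate`` is the expected adduct count per 10^3 kb, length-weighted
    over the whole fiber. A contiguous accessible zone covering
    ``accessible_fraction`` of the fiber, at a uniformly random location,
    reacts ``rate_ratio`` times faster than the rest; the base rate is scaled
    so the fiber-wide mean rate equals ``adduct_rate`` exactly. Adduct kinds
    are i.i.d. Bernoulli: ICL with probability ``icl_fraction``.
    """
    if length_kb <= 0:
        raise ConfigError("length_kb must be positive")
    if adduct_rate < 0:
        raise ConfigError("adduct_rate must be non-negative")

    f = accessibility.accessible_fraction
    r = accessibility.rate_ratio
    if f in (0.0, 1.0) or r == 1.0:
        zones = [(0.0, length_kb, adduct_rate)]
    else:
        base = adduct_rate / (f * r + (1.0 - f))
        acc_len = f * length_kb
        start = rng.uniform(0.0, length_kb - acc_len)
        zones = [
            (0.0, start, base),
            (start, start + acc_len, base * r),
            (start + acc_len, length_kb, base),
        ]

    chunks = []
    for lo, hi, rate in zones:
        lam = rate * (hi - lo) / 1000.0
        k = rng.poisson(lam) if lam > 0 else 0
        if k:
            chunks.append(rng.uniform(lo, hi, k))
    if not chunks:
        return []
    positions = np.sort(np.concatenate(chunks))
    is_icl = rng.random(positions.size) < icl_fraction
    return [
        Adduct(position_kb=float(p), kind=ICL if icl else MONOADDUCT)
        for p, icl in zip(positions, is_icl)
    ]


@dataclass
class _PendingTract:
    start: float
    end: float
    start_fixed: bool
    end_fixed: bool
    adduct_index: int
    trimmed: bool = False


def _resolve_overlaps(pending: list[_PendingTract], eps: float = 1e-9) -> list[_PendingTract]:
    """Trim free tract ends so tracts of one label never overlap.

    Endpoints pinned to an adduct are never moved; where two free ends
    collide the boundary is placed at the midpoint of the overlap. A tract
    squeezed to zero length is dropped.
    """
    pending = sorted(pending, key=lambda t: (t.start, t.end))
    out: list[_PendingTract] = []
    for cur in pending:
        if not out:
            out.append(cur)
            continue
        prev = out[-1]
        if cur.start >= prev.end - eps:
            out.append(cur)
            continue
        if prev.end_fixed and cur.start_fixed:
            # both boundaries pinned at adducts: geometrically possible only
            # for pathological inputs; drop the later tract
            continue
        if prev.end_fixed:
            cur.start = prev.end
            cur.trimmed = True
        elif cur.start_fixed:
            prev.end = cur.start
            prev.trimmed = True
        else:
            b = 0.5 * (cur.start + prev.end)
            b = max(b, prev.start + eps)
            b = min(b, cur.end - eps)
            prev.end = b
            cur.start = b
            prev.trimmed = cur.trimmed = True
        if prev.end - prev.start <= eps:
            out.pop()
        if cur.end - cur.start > eps:
            out.append(cur)
    return out


def place_replication(
    fiber: Fiber,
    replication: ReplicationConfig,
    rng: np.random.Generator,
) -> list[Tract]:
    """Create IdU replication tracts for a fiber whose adducts are placed.

    Each adduct draws an encounter with probability ``encounter_fraction``;
    the encounter is single-sided with probability ``single_sided_prob``
    (side chosen at random), else double-sided with tracts abutting the
    adduct on both sides. Requests that cannot fit (adduct at a fiber end)
    degrade to the feasible side and are flagged in the ground truth. A
    distant tract unlinked to any adduct is added with
    ``distant_tract_prob``, clear of every adduct. The adducts on ``fiber``
    are replaced with copies annotated with their realized event labels.
    """
    L = fiber.length_kb
    eps = 1e-6
    pending: list[_PendingTract] = []
    new_adducts: list[Adduct] = []

    def draw_len() -> float:
        for _ in range(100):
            v = float(replication.tract_length_dist.sample(1, rng)[0])
            if v > 0:
                return v
        raise ConfigError("tract_length_dist keeps producing non-positive lengths")

    for i, ad in enumerate(fiber.adducts):
        p = ad.position_kb
        if rng.random() >= replication.encounter_fraction:
            new_adducts.append(Adduct(p, ad.kind, EVENT_NONE))
            continue
        left_ok = p > eps
        right_ok = p < L - eps
        want_single = rng.random() < replication.single_sided_prob
        degraded = False
        if want_single:
            side_left = rng.random() < 0.5
            if side_left and not left_ok:
                side_left = False
            elif not side_left and not right_ok:
                side_left = True
            sides = ["left" if side_left else "right"]
            event = EVENT_SINGLE
        else:
            sides = []
            if left_ok:
                sides.append("left")
            if right_ok:
                sides.append("right")
            if len(sides) < 2:
                degraded = True
                event = EVENT_SINGLE
            else:
                event = EVENT_DOUBLE
        for side in sides:
            ln = draw_len()
            if side == "left":
                pending.append(_PendingTract(max(0.0, p - ln), p, start_fixed=p - ln <= 0.0, end_fixed=True, adduct_index=i))
            else:
                pending.append(_PendingTract(p, min(L, p + ln), start_fixed=True, end_fixed=p + ln >= L, adduct_index=i))
        new_adducts.append(Adduct(p, ad.kind, event, degraded=degraded))

    # distant tract, kept clear of all adducts
    if rng.random() < replication.distant_tract_prob:
        clear = replication.distant_clearance_kb
        positions = [a.position_kb for a in fiber.adducts]
        for _ in range(50):
            ln = draw_len()
            if ln >= L:
                continue
            s = rng.uniform(0.0, L - ln)
            e = s + ln
            if any(s - clear < p < e + clear for p in positions):
                continue
            if any(not (e <= t.start or s >= t.end) for t in pending):
                continue
            pending.append(_PendingTract(s, e, start_fixed=False, end_fixed=False, adduct_index=-1))
            break

    resolved = _resolve_overlaps(pending)
    tracts = [
        Tract(t.start, t.end, "IdU", adduct_index=t.adduct_index, trimmed=t.trimmed)
        for t in resolved
        if t.end - t.start > 1e-9
    ]
    # relabel events from the realized geometry: when adducts sit close
    # enough that their replication events interact, overlap resolution can
    # drop a tract or a neighbour's tract can span an adduct, and the ground
    # truth must describe what is actually on the fiber
    tol = 1e-6
    relabeled: list[Adduct] = []
    for ad in new_adducts:
        p = ad.position_kb
        left = right = False
        for t in tracts:
            if t.start_kb < p - tol and t.end_kb > p + tol:
                left = right = True
            if abs(t.end_kb - p) <= tol and t.start_kb < p:
                left = True
            if abs(t.start_kb - p) <= tol and t.end_kb > p:
                right = True
        if left and right:
            event = EVENT_DOUBLE
        elif left or right:
            event = EVENT_SINGLE
        else:
            event = EVENT_NONE
        relabeled.append(Adduct(p, ad.kind, event, degraded=ad.degraded))
    fiber.adducts = relabeled
    return tracts


def simulate_fibers(config: SimulationConfig) -> tuple[list[Fiber], dict[str, pd.DataFrame]]:
    """Generate a fiber population and its ground-truth tables.

    Returns the fibers plus three DataFrames: ``fibers`` (id, length,
    origin, ROI membership), ``adducts`` (position, kind, replication event)
    and ``tracts`` (half-open kb intervals, label, linkage to adducts).
    Deterministic for a fixed config and seed. In laser mode only fibers
    drawn from exposed nuclei (probability ``roi_fiber_fraction``) carry
    adducts; the per-fiber adduct law is otherwise identical to lamp mode.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_fibers
    lengths = config.fiber_length_dist.sample(n, rng) if n else np.empty(0)
    if n and (lengths <= 0).any():
        raise ConfigError("fiber_length_dist produced non-positive lengths")
    if config.treatment_mode == "laser":
        in_roi = rng.random(n) < config.roi_fiber_fraction
    else:
        in_roi = np.ones(n, dtype=bool)

    fibers: list[Fiber] = []
    for i in range(n):
        fb = Fiber(
            id=i,
            length_kb=float(lengths[i]),
            origin_label=config.experiment_label,
            in_roi=bool(in_roi[i]),
        )
        # full-length CldU prelabel
        fb.tracts.append(Tract(0.0, fb.length_kb, "CldU"))
        if fb.in_roi:
            fb.adducts = place_adducts(
                fb.length_kb, config.adduct_rate, config.accessibility, config.icl_fraction, rng
            )
            fb.tracts.extend(place_replication(fb, config.replication, rng))
        fibers.append(fb)

    tables = ground_truth_tables(fibers)
    return fibers, tables


def ground_truth_tables(fibers: Iterable[Fiber]) -> dict[str, pd.DataFrame]:
    """Flatten fibers into the three canonical ground-truth tables."""
    fib_rows, add_rows, tract_rows = [], [], []
    for fb in fibers:
        fib_rows.append(
            {"fiber_id": fb.id, "length_kb": fb.length_kb, "origin_label": fb.origin_label, "in_roi": fb.in_roi}
        )
        for j, ad in enumerate(fb.adducts):
            add_rows.append(
                {
                    "fiber_id": fb.id,
                    "adduct_index": j,
                    "position_kb": ad.position_kb,
                    "kind": ad.kind,
                    "event": ad.event,
                    "degraded": ad.degraded,
                }
            )
        for t in fb.tracts:
            tract_rows.append(
                {
                    "fiber_id": fb.id,
                    "start_kb": t.start_kb,
                    "end_kb": t.end_kb,
                    "label": t.label,
                    "adduct_index": t.adduct_index,
                    "trimmed": t.trimmed,
                }
            )
    return {
        "fibers": pd.DataFrame(fib_rows, columns=["fiber_id", "length_kb", "origin_label", "in_roi"]),
        "adducts": pd.DataFrame(
            add_rows, columns=["fiber_id", "adduct_index", "position_kb", "kind", "event", "degraded"]
        ),
        "tracts": pd.DataFrame(
            tract_rows, columns=["fiber_id", "start_kb", "end_kb", "label", "adduct_index", "trimmed"]
        ),
    }
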