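"""Per-fiber and per-experiment single-molecule statistics.

Implements the quantities scored in the fiber assay: the fraction of
fibers carrying at least one Dig-TMP signal, the signal density per 10^3 kb
of fiber, pooled nearest-neighbour signal spacings, and the four-way
classification of replication-fork encounters with adducts:

- ``NO_SIGNAL``       — no adduct signal on the fiber
- ``SIGNAL_NO_TRACT`` — a signal but no replication tract anywhere
- ``TRACT_DISTANT``   — tracts present but none adjacent to a signal
- ``SINGLE_SIDED``    — a tract abuts exactly one side of a signal
- ``DOUBLE_SIDED``    — tracts abut (or replication spans) both sides

Adjacency is a configurable window ``adjacency_kb`` (default 2 kb, about
five pixels at the default calibration): a tract whose boundary lies within
the window of a signal counts as abutting that side, and a signal buried
deeper than the window inside a tract counts as replicated on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import Fiber

NO_SIGNAL = "NO_SIGNAL"
SIGNAL_NO_TRACT = "SIGNAL_NO_TRACT"
TRACT_DISTANT = "TRACT_DISTANT"
SINGLE_SIDED = "SINGLE_SIDED"
DOUBLE_SIDED = "DOUBLE_SIDED"

CATEGORIES = (NO_SIGNAL, SIGNAL_NO_TRACT, TRACT_DISTANT, SINGLE_SIDED, DOUBLE_SIDED)
# evidence ordering used to roll per-signal states up to one fiber category
_RANK = {TRACT_DISTANT: 0, SINGLE_SIDED: 1, DOUBLE_SIDED: 2}


class QuantError(ValueError):
    """Raised for empty or degenerate inputs to the quantification ops."""


@dataclass
class SignalClassification:
    arc_kb: float
    state: str  # TRACT_DISTANT | SINGLE_SIDED | DOUBLE_SIDED
    end_censored: bool


@dataclass
class FiberRecord:
    """One analyzed fiber, from imaging or directly from ground truth."""

    fiber_id: int
    experiment_label: str
    length_kb: float
    signals: list[float] = field(default_factory=list)  # sorted arc positions, kb
    idu_tracts: list[tuple[float, float]] = field(default_factory=list)  # half-open kb intervals
    category: str = NO_SIGNAL
    signal_states: list[SignalClassification] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signals = sorted(self.signals)
        self.idu_tracts = sorted(self.idu_tracts)


@dataclass
class ExperimentSummary:
    experiment_label: str
    n_fibers: int
    n_fibers_with_signal: int
    total_length_kb: float
    n_signals: int
    density_per_1000kb: float
    distances_kb: list[float]
    category_counts: dict[str, int]


def classify_signal(
    s: float,
    tracts: Sequence[tuple[float, float]],
    adjacency_kb: float,
    length_kb: float,
) -> SignalClassification:
    """Classify one signal against the fiber's tract intervals."""
    left = right = False
    for start, end in tracts:
        if start < s - adjacency_kb and end > s + adjacency_kb:
            # signal embedded in a continuous tract: replication passed it
            left = right = True
            continue
        if start <= s and abs(end - s) <= adjacency_kb:
            left = True
        if end >= s and abs(start - s) <= adjacency_kb:
            right = True
    if left and right:
        state = DOUBLE_SIDED
    elif left or right:
        state = SINGLE_SIDED
    else:
        state = TRACT_DISTANT
    censored = s < adjacency_kb or s > length_kb - adjacency_kb
    return SignalClassification(arc_kb=s, state=state, end_censored=censored)


def classify_fiber(record: FiberRecord, adjacency_kb: float = 2.0) -> str:
    """Assign the five-way category to a fiber (stored on the record).

    A fiber's category is the most advanced state over its signals
    (DOUBLE > SINGLE > DISTANT); per-signal states are kept on the record
    for auditing. Signals within ``adjacency_kb`` of a fiber end are flagged
    end-censored — a flanking tract could lie beyond the molecule's end —
    and excluded from encounter proportions downstream.
    """
    if not record.signals:
        record.category = NO_SIGNAL
        record.signal_states = []
        return record.category
    if not record.idu_tracts:
        record.category = SIGNAL_NO_TRACT
        record.signal_states = [
            SignalClassification(s, TRACT_DISTANT, s < adjacency_kb or s > record.length_kb - adjacency_kb)
            for s in record.signals
        ]
        return record.category
    states = [classify_signal(s, record.idu_tracts, adjacency_kb, record.length_kb) for s in record.signals]
    record.signal_states = states
    record.category = max((st.state for st in states), key=lambda c: _RANK[c])
    return record.category


def fraction_with_signal(records: Sequence[FiberRecord]) -> tuple[float, int, int]:
    """Fraction of fibers carrying >= 1 signal, with (hits, total) counts.

    A fiber with several signals counts once: this is a count of fibers,
    not of signals.
    """
    if not records:
        raise QuantError("fraction_with_signal requires at least one fiber record")
    hits = sum(1 for r in records if r.signals)
    return hits / len(records), hits, len(records)


def signals_per_1000kb(records: Sequence[FiberRecord]) -> float:
    """Signal density: total signals / total fiber length x 1000."""
    total_kb = sum(r.length_kb for r in records)
    if total_kb <= 0:
        raise QuantError("signals_per_1000kb requires positive total fiber length")
    n = sum(len(r.signals) for r in records)
    return n / total_kb * 1000.0


def interadduct_distances(records: Sequence[FiberRecord]) -> list[float]:
    """Consecutive distances between signals, pooled across fibers.

    Distances never span two fibers; fibers with fewer than two signals
    contribute nothing.
    """
    out: list[float] = []
    for r in records:
        if len(r.signals) >= 2:
            out.extend(float(d) for d in np.diff(sorted(r.signals)))
    return out


def encounter_proportions(
    records: Sequence[FiberRecord],
    include_end_censored: bool = False,
    level: str = "fiber",
) -> tuple[float, float, int]:
    """(single_fraction, double_fraction, n) over the SINGLE u DOUBLE subset.

    ``level='fiber'`` counts fibers by their rolled-up category;
    ``level='signal'`` counts individual adduct signals, the unit in which
    encounter frequencies are usually reported. By default end-censored
    signals (too close to a fiber end to ever show a flanking tract) are
    excluded. Fractions sum to 1 over the retained subset.
    """
    if level not in ("fiber", "signal"):
        raise QuantError("level must be 'fiber' or 'signal'")
    n_single = n_double = 0
    for r in records:
        states = r.signal_states
        if not include_end_censored:
            states = [st for st in states if not st.end_censored]
        if not states:
            continue
        if level == "signal":
            for st in states:
                if st.state == DOUBLE_SIDED:
                    n_double += 1
                elif st.state == SINGLE_SIDED:
                    n_single += 1
            continue
        best = max((st.state for st in states), key=lambda c: _RANK[c])
        if best == DOUBLE_SIDED:
            n_double += 1
        elif best == SINGLE_SIDED:
            n_single += 1
    n = n_single + n_double
    if n == 0:
        raise QuantError("no single- or double-sided fibers to form proportions")
    return n_single / n, n_double / n, n


def summarize(records: Sequence[FiberRecord], experiment_label: str = "") -> ExperimentSummary:
    """Roll records up into one per-experiment summary."""
    if not records:
        return ExperimentSummary(experiment_label, 0, 0, 0.0, 0, float("nan"), [], {c: 0 for c in CATEGORIES})
    frac, hits, total = fraction_with_signal(records)
    counts = {c: 0 for c in CATEGORIES}
    for r in records:
        counts[r.category] += 1
    return ExperimentSummary(
        experiment_label=experiment_label or records[0].experiment_label,
        n_fibers=total,
        n_fibers_with_signal=hits,
        total_length_kb=float(sum(r.length_kb for r in records)),
        n_signals=sum(len(r.signals) for r in records),
        density_per_1000kb=signals_per_1000kb(records),
        distances_kb=interadduct_distances(records),
        category_counts=counts,
    )


def records_from_ground_truth(
    fibers: Iterable[Fiber], adjacency_kb: float = 2.0
) -> list[FiberRecord]:
    """Build classified records straight from simulator ground truth.

    This bypasses rendering and image analysis entirely: signal positions
    are the true adduct positions (both adduct kinds — the immunotag cannot
    tell them apart) and tract intervals are the true IdU intervals.
    """
    records = []
    for fb in fibers:
        rec = FiberRecord(
            fiber_id=fb.id,
            experiment_label=fb.origin_label,
            length_kb=fb.length_kb,
            signals=[a.position_kb for a in fb.adducts],
            idu_tracts=[(t.start_kb, t.end_kb) for t in fb.idu_tracts],
        )
        classify_fiber(rec, adjacency_kb)
        records.append(rec)
    return records


def records_to_frame(records: Sequence[FiberRecord]) -> pd.DataFrame:
    rows = [
        {
            "fiber_id": r.fiber_id,
            "experiment_label": r.experiment_label,
            "length_kb": r.length_kb,
            "n_signals": len(r.signals),
            "n_idu_tracts": len(r.idu_tracts),
            "category": r.category,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["fiber_id", "experiment_label", "length_kb", "n_signals", "n_idu_tracts", "category"]
    )
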