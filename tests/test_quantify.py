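"""Tests of per-fiber quantification: signal fractions, densities, spacing,
and the replication-encounter classification (against a brute-force oracle)."""

import itertools

import numpy as np
import pytest

from fiberglow import (
    DOUBLE_SIDED,
    NO_SIGNAL,
    SIGNAL_NO_TRACT,
    SINGLE_SIDED,
    TRACT_DISTANT,
    FiberRecord,
    SimulationConfig,
    classify_fiber,
    encounter_proportions,
    fraction_with_signal,
    interadduct_distances,
    records_from_ground_truth,
    signals_per_1000kb,
    simulate_fibers,
    summarize,
)
from fiberglow.quantify import CATEGORIES, QuantError


def _rec(signals=(), tracts=(), length=200.0, label="x"):
    return FiberRecord(
        fiber_id=0, experiment_label=label, length_kb=length, signals=list(signals), idu_tracts=list(tracts)
    )


class TestFractionWithSignal:
    def test_pooled_5um_counts_give_11_25_pct(self):
        # three experiments: 33/297, 25/279, 32/224 -> 90/800
        records = []
        for hits, total in ((33, 297), (25, 279), (32, 224)):
            records += [_rec(signals=[10.0]) for _ in range(hits)]
            records += [_rec() for _ in range(total - hits)]
        frac, hits, total = fraction_with_signal(records)
        assert (hits, total) == (90, 800)
        assert frac == pytest.approx(0.1125)
        assert 0.10 <= frac <= 0.15

    def test_multiple_signals_count_once(self):
        frac, hits, _ = fraction_with_signal([_rec(signals=[1.0, 2.0, 3.0]), _rec()])
        assert (frac, hits) == (0.5, 1)

    def test_extremes_and_empty(self):
        assert fraction_with_signal([_rec()])[0] == 0.0
        assert fraction_with_signal([_rec(signals=[5.0])])[0] == 1.0
        with pytest.raises(QuantError):
            fraction_with_signal([])


class TestDensity:
    def test_one_signal_on_1000_kb(self):
        assert signals_per_1000kb([_rec(signals=[500.0], length=1000.0)]) == 1.0

    def test_five_signals_over_2000_kb(self):
        recs = [_rec(signals=[1, 2, 3], length=1200.0), _rec(signals=[4, 5], length=800.0)]
        assert signals_per_1000kb(recs) == pytest.approx(2.5)

    def test_zero_length_rejected(self):
        with pytest.raises(QuantError):
            signals_per_1000kb([])

    def test_ground_truth_bypass_density_is_unbiased(self):
        # mean over 50 seeded runs within 1% of the configured rate
        densities = []
        for seed in range(50):
            cfg = SimulationConfig(n_fibers=600, adduct_rate=2.69, seed=7000 + seed)
            fibers, _ = simulate_fibers(cfg)
            densities.append(signals_per_1000kb(records_from_ground_truth(fibers)))
        assert np.mean(densities) == pytest.approx(2.69, rel=0.01)


class TestDistances:
    def test_single_signal_contributes_nothing(self):
        assert interadduct_distances([_rec(signals=[50.0])]) == []

    def test_consecutive_differences(self):
        assert interadduct_distances([_rec(signals=[10.0, 60.0, 160.0])]) == [50.0, 100.0]

    def test_never_spans_fibers(self):
        recs = [_rec(signals=[10.0, 20.0]), _rec(signals=[190.0, 195.0])]
        assert interadduct_distances(recs) == [10.0, 5.0]

    def test_homogeneous_simulation_mean_gap_is_1000_over_rate(self):
        # fibers much longer than the mean gap, so window truncation of the
        # exponential gaps is negligible
        from fiberglow.config import AccessibilityConfig, DistributionSpec

        cfg = SimulationConfig(
            n_fibers=100,
            fiber_length_dist=DistributionSpec(kind="constant", value=5000.0),
            adduct_rate=20.0,
            seed=51,
            accessibility=AccessibilityConfig(accessible_fraction=0.0, rate_ratio=1.0),
        )
        fibers, _ = simulate_fibers(cfg)
        d = interadduct_distances(records_from_ground_truth(fibers))
        assert len(d) > 5000
        assert np.mean(d) == pytest.approx(1000.0 / 20.0, rel=0.03)


def _oracle_classify(signals, tracts, adjacency, length):
    """Independent brute-force classifier over explicit interval layouts."""
    if not signals:
        return NO_SIGNAL
    if not tracts:
        return SIGNAL_NO_TRACT
    best = TRACT_DISTANT
    rank = {TRACT_DISTANT: 0, SINGLE_SIDED: 1, DOUBLE_SIDED: 2}
    for s in signals:
        left = any(
            (st < s - adjacency and en > s + adjacency) or (st <= s and abs(en - s) <= adjacency)
            for st, en in tracts
        )
        right = any(
            (st < s - adjacency and en > s + adjacency) or (en >= s and abs(st - s) <= adjacency)
            for st, en in tracts
        )
        state = DOUBLE_SIDED if (left and right) else (SINGLE_SIDED if (left or right) else TRACT_DISTANT)
        if rank[state] > rank[best]:
            best = state
    return best


class TestClassifyFiber:
    def test_flanking_tracts_give_double_sided(self):
        rec = _rec(signals=[100.0], tracts=[(80.0, 98.0), (102.0, 130.0)])
        assert classify_fiber(rec, adjacency_kb=3.0) == DOUBLE_SIDED

    def test_signal_without_any_tract(self):
        rec = _rec(signals=[100.0])
        assert classify_fiber(rec, adjacency_kb=3.0) == SIGNAL_NO_TRACT

    def test_distant_tract(self):
        rec = _rec(signals=[100.0], tracts=[(40.0, 70.0)])
        assert classify_fiber(rec, adjacency_kb=3.0) == TRACT_DISTANT

    def test_embedded_signal_counts_as_double_sided(self):
        # replication passed over the adduct: one continuous tract spans it
        rec = _rec(signals=[100.0], tracts=[(60.0, 140.0)])
        assert classify_fiber(rec, adjacency_kb=2.0) == DOUBLE_SIDED

    def test_end_censoring_flags_signals_near_fiber_ends(self):
        rec = _rec(signals=[1.0], tracts=[(1.0, 40.0)], length=200.0)
        classify_fiber(rec, adjacency_kb=2.0)
        assert rec.signal_states[0].end_censored

    def test_matches_brute_force_oracle_on_exhaustive_grid(self):
        # all layouts of <= 2 signals x <= 2 tracts on a 10-kb grid, 100-kb fiber
        grid = [float(g) for g in range(0, 101, 10)]
        intervals = [(a, b) for a, b in itertools.combinations(grid, 2)]
        tract_sets = [()] + [(iv,) for iv in intervals] + [
            (a, b) for a, b in itertools.combinations(intervals, 2) if a[1] <= b[0]
        ]
        signal_sets = [()] + [(s,) for s in grid] + list(itertools.combinations(grid, 2))
        n_checked = 0
        for signals in signal_sets:
            for tracts in tract_sets:
                rec = _rec(signals=signals, tracts=tracts, length=100.0)
                got = classify_fiber(rec, adjacency_kb=2.0)
                want = _oracle_classify(list(signals), list(tracts), 2.0, 100.0)
                assert got == want, f"signals={signals} tracts={tracts}: {got} != {want}"
                n_checked += 1
        assert n_checked > 30_000

    def test_bypass_recovers_generator_event_labels(self):
        # exact recovery for adducts in unambiguous contexts: skip signals
        # whose window contains a foreign tract boundary, and censored ends
        cfg = SimulationConfig(n_fibers=2000, seed=3)
        fibers, _ = simulate_fibers(cfg)
        records = records_from_ground_truth(fibers, adjacency_kb=2.0)
        want_map = {"none": TRACT_DISTANT, "single": SINGLE_SIDED, "double": DOUBLE_SIDED}
        checked = 0
        for fb, rec in zip(fibers, records):
            bounds = [b for t in fb.idu_tracts for b in (t.start_kb, t.end_kb)]
            for ad, st in zip(fb.adducts, rec.signal_states):
                p = ad.position_kb
                ambiguous = any(0 < abs(b - p) <= 2.0 for b in bounds)
                if st.end_censored or ambiguous:
                    continue
                if ad.event == "none" and not fb.idu_tracts:
                    continue  # fiber-level SIGNAL_NO_TRACT, not per-signal
                assert st.state == want_map[ad.event]
                checked += 1
        assert checked > 800


class TestEncounterProportions:
    def test_pooled_counts_19_118(self):
        records = [_rec(signals=[100.0], tracts=[(80.0, 100.0)]) for _ in range(19)]
        records += [_rec(signals=[100.0], tracts=[(80.0, 100.0), (100.0, 120.0)]) for _ in range(118)]
        for r in records:
            classify_fiber(r, adjacency_kb=2.0)
        single, double, n = encounter_proportions(records)
        assert n == 137
        assert single == pytest.approx(19 / 137)
        assert double == pytest.approx(118 / 137)

    def test_all_single_and_simple_ratio(self):
        recs = [_rec(signals=[100.0], tracts=[(80.0, 100.0)]) for _ in range(4)]
        for r in recs:
            classify_fiber(r)
        assert encounter_proportions(recs)[:2] == (1.0, 0.0)
        recs2 = recs[:1] + [_rec(signals=[100.0], tracts=[(80.0, 100.0), (100.0, 120.0)]) for _ in range(3)]
        for r in recs2:
            classify_fiber(r)
        assert encounter_proportions(recs2)[:2] == (0.25, 0.75)

    def test_empty_subset_rejected(self):
        rec = _rec(signals=[100.0])
        classify_fiber(rec)
        with pytest.raises(QuantError):
            encounter_proportions([rec])

    def test_end_censored_signals_excluded_by_default(self):
        rec = _rec(signals=[1.0], tracts=[(1.0, 40.0)], length=200.0)
        classify_fiber(rec, adjacency_kb=2.0)
        with pytest.raises(QuantError):
            encounter_proportions([rec])
        assert encounter_proportions([rec], include_end_censored=True)[2] == 1


def test_category_counts_partition_the_fiber_set():
    cfg = SimulationConfig(n_fibers=500, seed=61)
    fibers, _ = simulate_fibers(cfg)
    records = records_from_ground_truth(fibers)
    summary = summarize(records, "lamp")
    assert sum(summary.category_counts.values()) == 500
    assert set(summary.category_counts) == set(CATEGORIES)
    assert summary.n_fibers_with_signal <= summary.n_fibers
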