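"""Tests of the ground-truth generator: Poisson adduct placement, adduct
typing, replication-tract geometry and population-level convergence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fiberglow import (
    AccessibilityConfig,
    Adduct,
    ConfigError,
    Fiber,
    ReplicationConfig,
    SimulationConfig,
    place_adducts,
    place_replication,
    simulate_fibers,
)
from fiberglow.config import DistributionSpec
from fiberglow.simulate import EVENT_DOUBLE, EVENT_SINGLE, ICL, MONOADDUCT

HOMOGENEOUS = AccessibilityConfig(accessible_fraction=0.0, rate_ratio=1.0)


class TestPlaceAdducts:
    def test_zero_rate_gives_no_adducts(self):
        rng = np.random.default_rng(0)
        assert place_adducts(1e4, 0.0, HOMOGENEOUS, 10 / 11, rng) == []

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigError):
            place_adducts(100.0, -1.0, HOMOGENEOUS, 0.5, np.random.default_rng(0))

    def test_positions_sorted_and_in_bounds(self):
        rng = np.random.default_rng(1)
        ads = place_adducts(500.0, 20.0, AccessibilityConfig(), 10 / 11, rng)
        pos = [a.position_kb for a in ads]
        assert pos == sorted(pos)
        assert all(0 <= p <= 500.0 for p in pos)

    def test_homogeneous_gaps_are_exponential_with_mean_1000_over_rate(self):
        # one long molecule at 5 adducts / 10^3 kb: gaps exponential, mean 200 kb
        rng = np.random.default_rng(2)
        ads = place_adducts(4e6, 5.0, HOMOGENEOUS, 10 / 11, rng)
        gaps = np.diff([a.position_kb for a in ads])
        assert gaps.mean() == pytest.approx(200.0, rel=0.03)

    def test_icl_monoadduct_ratio_ten_to_one(self):
        # >= 10^4 adducts: ICL:monoadduct count ratio 10:1 within 5%
        rng = np.random.default_rng(3)
        ads = place_adducts(4e6, 5.0, HOMOGENEOUS, 10 / 11, rng)
        assert len(ads) >= 10_000
        n_icl = sum(a.kind == ICL for a in ads)
        n_mono = sum(a.kind == MONOADDUCT for a in ads)
        assert n_icl / n_mono == pytest.approx(10.0, rel=0.05)

    def test_two_zone_model_preserves_mean_rate_but_clusters_gaps(self):
        # the length-weighted mean rate equals adduct_rate regardless of
        # zoning, while strong heterogeneity makes within-fiber gaps
        # detectably non-exponential (clustering without point hotspots)
        rng = np.random.default_rng(4)
        acc = AccessibilityConfig(accessible_fraction=0.2, rate_ratio=10.0)
        counts, gaps = [], []
        for _ in range(500):
            ads = place_adducts(1000.0, 10.0, acc, 1.0, rng)
            counts.append(len(ads))
            gaps.extend(np.diff([a.position_kb for a in ads]))
        assert np.mean(counts) == pytest.approx(10.0, rel=0.05)
        p = sps.kstest(np.asarray(gaps), "expon", args=(0, float(np.mean(gaps)))).pvalue
        assert p < 0.01

    def test_gap_distribution_passes_ks_against_exponential(self):
        # homogeneous rate: KS vs Exp(mean 200 kb) at alpha=0.01 in >= 95% of runs
        passes = 0
        n_runs = 40
        for seed in range(n_runs):
            rng = np.random.default_rng(1000 + seed)
            ads = place_adducts(2e5, 5.0, HOMOGENEOUS, 10 / 11, rng)
            gaps = np.diff([a.position_kb for a in ads])
            p = sps.kstest(gaps, "expon", args=(0, 200.0)).pvalue
            passes += p > 0.01
        assert passes >= int(0.95 * n_runs)


def _one_adduct_fiber(pos: float, length: float = 200.0) -> Fiber:
    return Fiber(id=0, length_kb=length, adducts=[Adduct(pos, ICL)])


class TestPlaceReplication:
    def test_zero_encounter_fraction_gives_no_tracts(self):
        rep = ReplicationConfig(encounter_fraction=0.0, distant_tract_prob=0.0)
        fb = _one_adduct_fiber(100.0)
        assert place_replication(fb, rep, np.random.default_rng(0)) == []

    def test_single_sided_fraction_matches_configuration(self):
        # 10^4 independent encounters: single-sided fraction 0.15 +/- 0.01
        rep = ReplicationConfig(encounter_fraction=1.0, single_sided_prob=0.15, distant_tract_prob=0.0)
        rng = np.random.default_rng(5)
        n_single = n_double = 0
        for _ in range(10_000):
            fb = _one_adduct_fiber(100.0)
            place_replication(fb, rep, rng)
            ev = fb.adducts[0].event
            n_single += ev == EVENT_SINGLE
            n_double += ev == EVENT_DOUBLE
        assert n_single + n_double == 10_000
        assert n_single / 10_000 == pytest.approx(0.15, abs=0.01)

    def test_double_sided_tracts_abut_the_adduct(self):
        rep = ReplicationConfig(encounter_fraction=1.0, single_sided_prob=0.0, distant_tract_prob=0.0)
        fb = _one_adduct_fiber(100.0)
        tracts = place_replication(fb, rep, np.random.default_rng(6))
        ends = sorted(t.end_kb for t in tracts)
        starts = sorted(t.start_kb for t in tracts)
        assert len(tracts) == 2
        assert 100.0 in ends and 100.0 in starts  # one ends, one starts, at the adduct
        assert fb.adducts[0].event == EVENT_DOUBLE

    def test_adduct_at_fiber_start_degrades_to_single_sided(self):
        rep = ReplicationConfig(encounter_fraction=1.0, single_sided_prob=0.0, distant_tract_prob=0.0)
        fb = _one_adduct_fiber(0.0)
        tracts = place_replication(fb, rep, np.random.default_rng(7))
        assert len(tracts) == 1 and tracts[0].start_kb == 0.0
        assert fb.adducts[0].event == EVENT_SINGLE
        assert fb.adducts[0].degraded

    def test_tracts_are_clipped_and_non_overlapping(self):
        rep = ReplicationConfig(
            encounter_fraction=1.0,
            single_sided_prob=0.0,
            distant_tract_prob=0.0,
            tract_length_dist=DistributionSpec(kind="constant", value=80.0),
        )
        rng = np.random.default_rng(8)
        fb = Fiber(id=0, length_kb=300.0, adducts=[Adduct(100.0, ICL), Adduct(150.0, ICL)])
        tracts = place_replication(fb, rep, rng)
        tracts = sorted(tracts, key=lambda t: t.start_kb)
        for t in tracts:
            assert 0.0 <= t.start_kb < t.end_kb <= 300.0
        for a, b in zip(tracts, tracts[1:]):
            assert a.end_kb <= b.start_kb + 1e-9

    def test_distant_tract_keeps_clearance_from_adducts(self):
        rep = ReplicationConfig(encounter_fraction=0.0, distant_tract_prob=1.0, distant_clearance_kb=10.0)
        rng = np.random.default_rng(9)
        for _ in range(50):
            fb = _one_adduct_fiber(100.0, length=400.0)
            tracts = place_replication(fb, rep, rng)
            for t in tracts:
                assert not (t.start_kb - 10.0 < 100.0 < t.end_kb + 10.0)


class TestSimulateFibers:
    def test_zero_fibers(self):
        fibers, truth = simulate_fibers(SimulationConfig(n_fibers=0))
        assert fibers == [] and truth["adducts"].empty

    def test_total_adduct_count_near_poisson_expectation(self):
        # lambda = 2.69 / 10^3 kb over 300 fibers: count within 3 Poisson SDs
        cfg = SimulationConfig(n_fibers=300, adduct_rate=2.69, seed=13)
        fibers, truth = simulate_fibers(cfg)
        total_kb = truth["fibers"]["length_kb"].sum()
        expected = 0.00269 * total_kb
        assert abs(len(truth["adducts"]) - expected) <= 3 * np.sqrt(expected)

    def test_same_seed_gives_identical_ground_truth(self):
        cfg = SimulationConfig(n_fibers=40, seed=17)
        _, t1 = simulate_fibers(cfg)
        _, t2 = simulate_fibers(cfg)
        for key in ("fibers", "adducts", "tracts"):
            pd.testing.assert_frame_equal(t1[key], t2[key])

    def test_cldu_prelabel_covers_every_fiber(self):
        fibers, _ = simulate_fibers(SimulationConfig(n_fibers=25, seed=19))
        for fb in fibers:
            cldu = [t for t in fb.tracts if t.label == "CldU"]
            assert len(cldu) == 1
            assert cldu[0].start_kb == 0.0 and cldu[0].end_kb == fb.length_kb

    def test_laser_mode_restricts_adducts_to_roi_fibers(self):
        cfg = SimulationConfig(n_fibers=400, seed=23, treatment_mode="laser", roi_fiber_fraction=0.5)
        fibers, truth = simulate_fibers(cfg)
        roi = {fb.id for fb in fibers if fb.in_roi}
        assert 0 < len(roi) < 400
        assert set(truth["adducts"]["fiber_id"]).issubset(roi)

    def test_population_density_converges_to_configured_rate(self):
        # total length ~4e6 kb at 5 / 10^3 kb: relative error < 2%
        cfg = SimulationConfig(
            n_fibers=19_000,
            adduct_rate=5.0,
            seed=29,
            replication=ReplicationConfig(encounter_fraction=0.0, distant_tract_prob=0.0),
        )
        fibers, truth = simulate_fibers(cfg)
        total_kb = truth["fibers"]["length_kb"].sum()
        assert total_kb >= 1e5
        density = len(truth["adducts"]) / total_kb * 1000.0
        assert density == pytest.approx(5.0, rel=0.02)
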