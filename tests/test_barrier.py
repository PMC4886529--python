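import numpy as np
import pytest

from ringmig import (
    BarrierSpec,
    RingGeometry,
    SegmentationConfig,
    SimulationParams,
    Track,
    clopper_pearson,
    detect_encounters,
    fit_invasion_survival,
    fit_transit_decay,
    segment_track,
    simulate_barrier_dataset,
    spontaneous_turning,
    state_occupancy_profile,
    to_polar,
    transit_curve,
    turning_probability,
    turning_probability_from_counts,
)
from ringmig.barrier import REVERSAL, TRANSIT, BarrierAnalysisError
from ringmig.simulate import BarrierModel, BernoulliMechanism, transit_probability

DT = 1 / 6
RING = RingGeometry((0.0, 0.0), 50.0)


def track_from_arc(arc, tid="t"):
    arc = np.asarray(arc, dtype=float)
    phi = arc / 50.0
    return Track(
        tid,
        t=np.arange(len(arc)) * DT,
        x=50 * np.cos(phi),
        y=50 * np.sin(phi),
    )


class TestDetectEncounters:
    spec = BarrierSpec(angular_position=0.0, d_gap=8.0)

    def test_far_track_has_no_encounters(self):
        arc = 150.0 + 5 * np.sin(np.linspace(0, 3, 40))  # stays ~150 um away
        pt = to_polar(track_from_arc(arc), RING)
        assert detect_encounters(pt, self.spec) == []

    def test_monotone_crossing_is_one_transit(self):
        arc = np.linspace(100, -100, 60)  # sweeps straight across the gap
        pt = to_polar(track_from_arc(arc), RING)
        enc = detect_encounters(pt, self.spec)
        assert len(enc) == 1
        assert enc[0].outcome == TRANSIT
        assert enc[0].entry_side == 1 and enc[0].exit_side == -1

    def test_scripted_three_approaches(self):
        """Reversal, reversal, transit - in that order."""
        inward = np.linspace(100, 10, 20)
        outward = inward[::-1]
        across = np.linspace(100, -100, 40)
        arc = np.r_[inward, outward, inward, outward, across]
        pt = to_polar(track_from_arc(arc), RING)
        enc = detect_encounters(pt, self.spec)
        assert [e.outcome for e in enc] == [REVERSAL, REVERSAL, TRANSIT]

    def test_track_ending_inside_zone_is_censored(self):
        arc = np.linspace(100, 20, 30)
        pt = to_polar(track_from_arc(arc), RING)
        enc = detect_encounters(pt, self.spec)
        assert [e.outcome for e in enc] == ["censored"]

    def test_zone_extends_from_gap_edge(self):
        # zone boundary at d_gap/2 + 50 = 54 um from the gap center
        arc = np.r_[np.linspace(80, 53, 20), np.linspace(53, 80, 20)]
        pt = to_polar(track_from_arc(arc), RING)
        assert len(detect_encounters(pt, self.spec)) == 1

    def test_invariants_on_spec(self):
        with pytest.raises(ValueError):
            BarrierSpec(0.0, d_gap=-1.0)
        with pytest.raises(ValueError):
            BarrierSpec(0.0, d_gap=20.0, zone_half_width=5.0)


class TestTurningProbability:
    def test_zero_reversals_clopper_pearson(self):
        est = turning_probability_from_counts(0, 10)
        assert est.p_turn == 0.0
        assert est.ci95[0] == 0.0
        assert est.ci95[1] == pytest.approx(0.3085, abs=1e-3)

    def test_five_of_ten(self):
        est = turning_probability_from_counts(5, 5)
        assert est.p_turn == 0.5
        assert est.ci95[0] == pytest.approx(0.187, abs=1e-3)
        assert est.ci95[1] == pytest.approx(0.813, abs=1e-3)

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 50))
            k = int(rng.integers(0, n + 1))
            est = turning_probability_from_counts(k, n - k)
            assert est.ci95[0] <= est.p_turn <= est.ci95[1]

    def test_no_encounters_raises(self):
        with pytest.raises(BarrierAnalysisError):
            turning_probability([])


class TestSpontaneousTurning:
    def test_ballistic_cells_never_turn(self):
        arcs = [np.linspace(0, 700, 280) + 40 * k for k in range(5)]
        pts = [to_polar(track_from_arc(a, tid=f"c{k}"), RING)
               for k, a in enumerate(arcs)]
        st = spontaneous_turning(pts)
        assert st.p_turn0 == 0.0

    def test_simulated_cells_have_finite_p_turn0(self, small_ensemble):
        _, ts, _ = small_ensemble
        pts = [to_polar(tr, RING) for tr in ts.tracks[:20]]
        st = spontaneous_turning(pts)
        assert 0.0 < st.p_turn0 < 1.0
        assert st.ci95[0] <= st.p_turn0 + 0.1  # pooled CI is informative
        assert len(st.per_zone) == 8


class TestTransitDecay:
    def test_noiseless_recovery(self):
        d = np.array([3.0, 8.0, 13.0, 19.0])
        n = np.full(4, 10_000.0)
        k = np.round(n * 0.8 * np.exp(-d / 8.0))
        fit = fit_transit_decay(d, n, k, p_turn0=0.2)
        assert fit.mu_trans == pytest.approx(8.0, abs=1e-3)

    def test_model_is_monotone_decreasing(self):
        mech = BernoulliMechanism(mu_trans=8.3, p_turn0=0.2)
        p = [transit_probability(mech, d) for d in np.linspace(0, 30, 40)]
        assert np.all(np.diff(p) < 0)

    def test_all_zero_transits_raise(self):
        with pytest.raises(BarrierAnalysisError):
            fit_transit_decay(
                np.array([3.0, 8.0]), np.array([10.0, 10.0]),
                np.array([0.0, 0.0]), 0.2,
            )

    def test_p_turn_plus_p_trans_is_one(self, rng):
        enc_by_gap = {}
        from ringmig.barrier import BarrierEncounter

        for d in (3.0, 8.0):
            outs = rng.random(60) < 0.5
            enc_by_gap[d] = [
                BarrierEncounter("t", 0, 1, 1, -1 if o else 1,
                                 TRANSIT if o else REVERSAL)
                for o in outs
            ]
        tc = transit_curve(enc_by_gap, p_turn0=0.2)
        np.testing.assert_allclose(
            tc.table["p_trans"] + tc.table["p_turn"], 1.0, atol=1e-12
        )


class TestOccupancyProfile:
    spec = BarrierSpec(angular_position=0.0, d_gap=8.0)

    def test_all_run_tracks_give_run_fraction_one(self, default_seg_config):
        arc = np.linspace(300, 900, 240)  # constant 30 um/h run, laps the ring
        pt = to_polar(track_from_arc(arc), RING)
        segs = segment_track(pt, default_seg_config)
        prof = state_occupancy_profile({"t": segs}, {"t": pt}, self.spec)
        assert np.all(prof["run_frac"] == 1.0)
        np.testing.assert_allclose(prof["run_frac"] + prof["rest_frac"], 1.0)

    def test_rest_accumulates_at_barrier(self, default_seg_config):
        params = SimulationParams(seed=9, barrier=BarrierModel(d_gap=13.0))
        data = simulate_barrier_dataset(params, [13.0], 25)
        ts, _ = data[13.0]
        segs_by, polar = {}, {}
        for tr in ts:
            pt = to_polar(tr, RING)
            polar[tr.track_id] = pt
            segs_by[tr.track_id] = segment_track(pt, default_seg_config)
        spec = BarrierSpec(0.0, 13.0)
        prof = state_occupancy_profile(segs_by, polar, spec, bin_width=25.0)
        near = prof[prof["bin_right"] <= 25.0]
        assert float(near["rest_frac"].iloc[0]) > float(near["run_frac"].iloc[0])


class TestInvasionSurvival:
    def test_noiseless_exponential_recovery(self):
        n = 2000
        m = np.arange(1, n)
        depths = np.r_[-11.8 * np.log(m / n), 120.0]
        fit = fit_invasion_survival(depths)
        assert fit.mu_inv == pytest.approx(11.8, rel=1e-6)
        assert fit.s0 == pytest.approx(1.0, rel=1e-6)

    def test_too_few_or_degenerate_depths_raise(self):
        with pytest.raises(BarrierAnalysisError):
            fit_invasion_survival(np.arange(5.0))
        with pytest.raises(BarrierAnalysisError):
            fit_invasion_survival(np.full(20, 7.0))


def test_clopper_pearson_exact_coverage(rng):
    """CP intervals cover the true p at >= 95% (exact-coverage property)."""
    n = 20
    cis = [clopper_pearson(k, n) for k in range(n + 1)]
    for p in (0.1, 0.5, 0.9):
        ks = rng.binomial(n, p, size=2000)
        cover = np.mean([cis[k][0] <= p <= cis[k][1] for k in ks])
        assert cover >= 0.95
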