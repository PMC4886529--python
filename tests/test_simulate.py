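import numpy as np
import pytest
from scipy import stats

from ringmig import (
    BarrierSpec,
    RingGeometry,
    SimulationParams,
    detect_encounters,
    fit_invasion_survival,
    simulate_barrier_dataset,
    simulate_barrier_track,
    simulate_encounter_outcomes,
    simulate_invasion_depths,
    simulate_track,
    simulate_tracks,
    to_polar,
    turning_probability,
)
from ringmig.barrier import CENSORED, clopper_pearson
from ringmig.segmentation import RUN, REST
from ringmig.simulate import (
    BarrierModel,
    BernoulliMechanism,
    InvasionMechanism,
    _draw_state_sequence,
    transit_probability,
)

RING = RingGeometry((0.0, 0.0), 50.0)


class TestSimulateTrack:
    def test_defaults_match_acquisition_protocol(self):
        p = SimulationParams()
        assert p.dt == pytest.approx(1 / 6)
        assert p.radius == 50.0
        tr, _ = simulate_track(SimulationParams(seed=0, duration=2.0))
        assert tr.frame_interval == pytest.approx(1 / 6)

    def test_stationary_limit(self):
        p = SimulationParams(
            seed=0, v_run=0.0, rest_diffusion=0.0, pos_noise_sigma=0.0,
            duration=4.0,
        )
        tr, _ = simulate_track(p)
        assert np.ptp(tr.x) == 0.0 and np.ptp(tr.y) == 0.0

    def test_same_seed_is_bit_identical(self):
        a, sa = simulate_track(SimulationParams(seed=7, duration=12.0))
        b, sb = simulate_track(SimulationParams(seed=7, duration=12.0))
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        assert [(s.start_idx, s.end_idx, s.label) for s in sa] == [
            (s.start_idx, s.end_idx, s.label) for s in sb
        ]

    def test_truth_segments_tile_track(self):
        tr, segs = simulate_track(SimulationParams(seed=3, duration=24.0))
        assert segs[0].start_idx == 0
        assert segs[-1].end_idx == tr.n_frames - 1
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end_idx == b.start_idx

    def test_run_time_fraction_matches_renewal_theory(self):
        """Long-run occupancy of the run state = tau_run/(tau_run+tau_rest)."""
        p = SimulationParams(seed=13)
        frac_expected = 13.6 / (13.6 + 6.5)
        _, truth = simulate_tracks(p, 500)
        run_t = rest_t = 0.0
        for segs in truth.values():
            for s in segs:
                if s.label == RUN:
                    run_t += s.duration
                else:
                    rest_t += s.duration
        frac = run_t / (run_t + rest_t)
        # 3 standard errors of the per-track occupancy fraction
        per_track = [
            sum(s.duration for s in segs if s.label == RUN)
            / sum(s.duration for s in segs)
            for segs in truth.values()
        ]
        se = np.std(per_track, ddof=1) / np.sqrt(len(per_track))
        assert abs(frac - frac_expected) < 3 * se

    def test_dwell_times_are_exponential(self):
        """Interior dwell times pass a KS test against Exp(tau) at alpha=0.01."""
        p = SimulationParams(seed=21, duration=2000.0)
        rng = np.random.default_rng(0)
        events = _draw_state_sequence(p, rng)
        for label, tau in ((RUN, 13.6), (REST, 6.5)):
            d = np.array([t1 - t0 for lab, t0, t1, _ in events[1:-1] if lab == label])
            d = d[:5000] if len(d) >= 5000 else d
            res = stats.kstest(d, "expon", args=(0, tau))
            assert res.pvalue > 0.01

    def test_spawned_streams_stable_under_track_count(self):
        p = SimulationParams(seed=4, duration=6.0)
        a, _ = simulate_tracks(p, 3)
        b, _ = simulate_tracks(p, 6)
        np.testing.assert_array_equal(a.tracks[0].x, b.tracks[0].x)
        np.testing.assert_array_equal(a.tracks[2].y, b.tracks[2].y)


class TestBarrierSimulation:
    def test_zero_gap_no_turning_always_transits(self):
        p = SimulationParams(
            seed=5,
            barrier=BarrierModel(
                d_gap=0.0, mechanism=BernoulliMechanism(p_turn0=0.0)
            ),
        )
        _, _, enc = simulate_barrier_track(p)
        outcomes = [e.outcome for e in enc if e.outcome != CENSORED]
        assert outcomes and all(o == "transit" for o in outcomes)

    def test_encounter_fraction_matches_formula(self):
        mech = BernoulliMechanism(mu_trans=8.3, p_turn0=0.2)
        rng = np.random.default_rng(11)
        out = simulate_encounter_outcomes(8.0, 300, mech, rng)
        p_target = transit_probability(mech, 8.0)
        lo, hi = clopper_pearson(int(out.sum()), len(out))
        assert lo <= p_target <= hi

    def test_track_level_transits_match_formula(self):
        p = SimulationParams(seed=17, barrier=BarrierModel(d_gap=8.0))
        data = simulate_barrier_dataset(p, [8.0], 50)
        ts, _ = data[8.0]
        spec = BarrierSpec(0.0, 8.0)
        enc = []
        for tr in ts:
            enc += detect_encounters(to_polar(tr, RING), spec)
        est = turning_probability(enc)
        p_target = transit_probability(BernoulliMechanism(), 8.0)
        assert est.ci95[0] <= 1 - p_target <= est.ci95[1]

    def test_detected_outcomes_match_generator_truth(self):
        p = SimulationParams(seed=23, barrier=BarrierModel(d_gap=8.0))
        tr, _, truth = simulate_barrier_track(p)
        det = detect_encounters(to_polar(tr, RING), BarrierSpec(0.0, 8.0))
        assert [e.outcome for e in det] == [e.outcome for e in truth]

    def test_cells_encounter_barrier_repeatedly(self):
        p = SimulationParams(seed=29, barrier=BarrierModel(d_gap=3.0))
        data = simulate_barrier_dataset(p, [3.0], 30)
        _, truth = data[3.0]
        assert max(len(v) for v in truth.values()) >= 2

    def test_invasion_mechanism_links_transit_to_depth_law(self):
        """Measured P_trans(d_gap) equals P(d_inv > d_gap) by construction."""
        mech = InvasionMechanism(mu_inv=11.8)
        rng = np.random.default_rng(31)
        for d_gap in (8.0, 19.0):
            out = simulate_encounter_outcomes(d_gap, 400, mech, rng)
            lo, hi = clopper_pearson(int(out.sum()), len(out))
            assert lo <= transit_probability(mech, d_gap) <= hi


class TestInvasionDepths:
    def test_support_and_reproducibility(self):
        d1 = simulate_invasion_depths(n=5, seed=3)
        d2 = simulate_invasion_depths(n=5, seed=3)
        np.testing.assert_array_equal(d1, d2)
        assert np.all(d1 >= 2.0) and np.all(d1 <= 30.0)

    def test_round_trip_with_invasion_fit(self):
        d = simulate_invasion_depths(mu_inv=11.8, n=5000, seed=1)
        fit = fit_invasion_survival(d)
        assert fit.mu_inv == pytest.approx(11.8, rel=0.05)

    def test_invalid_s0_rejected(self):
        with pytest.raises(ValueError):
            simulate_invasion_depths(s0=1.5, n=10, seed=0)
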