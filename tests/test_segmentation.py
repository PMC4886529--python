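import numpy as np
import pytest

from ringmig import (
    RingGeometry,
    SegmentationConfig,
    SimulationParams,
    classify_segment,
    detect_change_points,
    msd,
    segment_track,
    simulate_track,
    to_polar,
)
from ringmig.segmentation import RUN, REST, frame_labels

DT = 1 / 6


def split_oracle(v, n_changes):
    """Exhaustive least-squares split oracle, applied recursively.

    Greedily inserts the single split that most reduces the within-segment
    sum of squares until ``n_changes`` boundaries are placed.
    """
    def best_split(a, b):
        seg = v[a:b]
        n = len(seg)
        if n < 2:
            return None, 0.0
        c = np.cumsum(seg - seg.mean())
        k = np.arange(1, n)
        gain = c[:-1] ** 2 * n / (k * (n - k))
        i = int(np.argmax(gain))
        return a + i + 1, gain[i]

    bounds = [0, len(v)]
    for _ in range(n_changes):
        cand = [best_split(a, b) for a, b in zip(bounds[:-1], bounds[1:])]
        k, _ = max(cand, key=lambda t: t[1])
        if k is None:
            break
        bounds = sorted(set(bounds + [k]))
    return sorted(set(bounds) - {0, len(v)})


class TestDetectChangePoints:
    def test_constant_series_has_no_change_points(self, default_seg_config):
        r = detect_change_points(np.full(100, 5.0), default_seg_config)
        assert r.indices == []

    def test_single_step_found_near_oracle(self, default_seg_config, rng):
        v = np.r_[np.full(60, 30.0), np.zeros(60)] + rng.normal(0, 5, 120)
        r = detect_change_points(v, default_seg_config)
        oracle = split_oracle(v, 1)
        assert len(r.indices) >= 1
        assert min(abs(i - oracle[0]) for i in r.indices) <= 3
        assert min(abs(i - 60) for i in r.indices) <= 3

    def test_three_level_series_gives_two_changes(self, default_seg_config, rng):
        v = np.r_[np.full(60, 30.0), np.zeros(60), np.full(60, -30.0)]
        v = v + rng.normal(0, 5, 180)
        r = detect_change_points(v, default_seg_config)
        for true_cp in (60, 120):
            assert min(abs(i - true_cp) for i in r.indices) <= 3

    def test_sign_and_translation_symmetry(self, default_seg_config, rng):
        v = np.r_[np.full(50, 20.0), np.zeros(50)] + rng.normal(0, 4, 100)
        a = detect_change_points(v, default_seg_config).indices
        b = detect_change_points(-v, default_seg_config).indices
        c = detect_change_points(v + 17.3, default_seg_config).indices
        assert a == b == c

    def test_short_series_warns_and_returns_empty(self, default_seg_config):
        with pytest.warns(UserWarning):
            r = detect_change_points(np.ones(4), default_seg_config)
        assert len(r) == 0

    def test_min_spacing_respected(self, default_seg_config, rng):
        v = np.r_[np.full(40, 30.0), np.zeros(40)] + rng.normal(0, 5, 80)
        r = detect_change_points(v, default_seg_config)
        bounds = [0, *r.indices, 80]
        assert min(np.diff(bounds)) >= default_seg_config.min_segment_length


class TestMsd:
    def test_ballistic_closed_form(self):
        x = 30.0 * np.arange(200) * DT
        curve = msd(x, DT)
        assert curve.msd[0] == 0.0
        assert curve.loglog_slope == pytest.approx(2.0, abs=1e-6)
        np.testing.assert_allclose(
            curve.msd[1:], (30.0 * curve.lag[1:]) ** 2, rtol=1e-9
        )

    def test_random_walk_slope_near_one(self, rng):
        x = np.cumsum(rng.normal(0, 1.0, 500))
        assert 0.8 <= msd(x, DT).loglog_slope <= 1.2

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            msd(np.zeros(2), DT)


class TestClassifySegment:
    def test_constant_velocity_is_run(self, default_seg_config):
        x = 30.0 * np.arange(100) * DT
        assert classify_segment(x, DT, default_seg_config) == RUN

    def test_zero_mean_walk_is_rest(self, default_seg_config, rng):
        x = np.cumsum(rng.normal(0, 1.0, 100))
        assert classify_segment(x, DT, default_seg_config) == REST

    def test_state_velocities_separate_as_in_real_cells(self, small_ensemble,
                                                        default_seg_config,
                                                        nominal_ring):
        """Run-state mean speeds peak away from zero; rest states near zero."""
        _, ts, _ = small_ensemble
        run_v, rest_v = [], []
        for tr in ts.tracks[:12]:
            for seg in segment_track(to_polar(tr, nominal_ring), default_seg_config):
                (run_v if seg.label == RUN else rest_v).append(seg.mean_velocity)
        assert np.mean(np.abs(run_v)) > 20.0
        assert abs(np.mean(rest_v)) < 5.0
        assert np.mean(np.abs(rest_v)) < 10.0


class TestSegmentTrack:
    def test_pure_run_is_single_segment(self, nominal_ring, default_seg_config):
        params = SimulationParams(seed=0, tau_rest=1e-9, duration=12.0)
        # effectively always running: emulate directly with constant rotation
        omega = 30.0 / 50.0
        n = 73
        import ringmig

        tr = ringmig.Track(
            "t",
            t=np.arange(n) * DT,
            x=50 * np.cos(omega * np.arange(n) * DT),
            y=50 * np.sin(omega * np.arange(n) * DT),
        )
        segs = segment_track(to_polar(tr, nominal_ring), default_seg_config)
        assert len(segs) == 1 and segs[0].label == RUN

    def test_tiling_and_duration_sum(self, small_ensemble, nominal_ring,
                                     default_seg_config):
        _, ts, _ = small_ensemble
        for tr in ts.tracks[:8]:
            pt = to_polar(tr, nominal_ring)
            segs = segment_track(pt, default_seg_config)
            assert segs[0].start_idx == 0
            assert segs[-1].end_idx == pt.n_frames - 1
            for a, b in zip(segs[:-1], segs[1:]):
                assert a.end_idx == b.start_idx
            total = sum(s.duration for s in segs)
            assert total == pytest.approx(pt.duration, abs=1e-9)

    def test_labels_alternate_or_reverse_direction(self, small_ensemble,
                                                   nominal_ring,
                                                   default_seg_config):
        _, ts, _ = small_ensemble
        for tr in ts.tracks[:8]:
            segs = segment_track(to_polar(tr, nominal_ring), default_seg_config)
            for a, b in zip(segs[:-1], segs[1:]):
                if a.label == b.label:
                    assert a.label == RUN
                    assert np.sign(a.mean_velocity) != np.sign(b.mean_velocity)

    def test_boundaries_recovered_close_to_truth(self, small_ensemble,
                                                 nominal_ring,
                                                 default_seg_config):
        """Segment boundaries land within +-3 frames of the generator truth
        for the clear majority of true switches."""
        _, ts, truth = small_ensemble
        hits = misses = 0
        for tr in ts.tracks[:15]:
            segs = segment_track(to_polar(tr, nominal_ring), default_seg_config)
            det = {s.start_idx for s in segs} | {s.end_idx for s in segs}
            for s in truth[tr.track_id]:
                if s.n_samples < 3:
                    continue
                for b in (s.start_idx, s.end_idx):
                    if any(abs(b - d) <= 3 for d in det):
                        hits += 1
                    else:
                        misses += 1
        assert hits / (hits + misses) >= 0.85

    def test_frame_label_accuracy_against_truth(self, small_ensemble,
                                                nominal_ring,
                                                default_seg_config):
        """>= 90% of frames carry the true state label (dwells >> dt, SNR >= 3)."""
        _, ts, truth = small_ensemble
        correct = total = 0
        for tr in ts.tracks[:15]:
            pt = to_polar(tr, nominal_ring)
            segs = segment_track(pt, default_seg_config)
            got = frame_labels(segs, pt.n_frames)
            want = frame_labels(truth[tr.track_id], pt.n_frames)
            correct += int(np.sum(got == want))
            total += pt.n_frames
        assert correct / total >= 0.90

    def test_censoring_flag_follows_20h_rule(self, small_ensemble, nominal_ring,
                                             default_seg_config):
        _, ts, _ = small_ensemble
        pt = to_polar(ts.tracks[0], nominal_ring)
        for seg in segment_track(pt, default_seg_config):
            assert seg.censored == (seg.t_start > pt.t[-1] - 20.0)
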