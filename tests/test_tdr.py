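"""Depth-record processing: zero-offset correction, downsampling, dive
detection, phase segmentation and metrics."""

import numpy as np
import pandas as pd
import pytest

from pinchpoint.tdr import (DepthSeries, Dive, compute_metrics, count_wiggles,
                            detect_dives, downsample, segment_phases,
                            zero_offset_correct)


def make_series(depths, interval=1.0, t0="2016-02-01"):
    n = len(depths)
    time = (np.datetime64(t0, "ns")
            + (np.arange(n) * int(interval * 1e9)).astype("timedelta64[ns]"))
    return DepthSeries("test", time, np.asarray(depths, dtype=float), interval)


def triangle_dive(peak, n_up, n_down=None):
    n_down = n_down or n_up
    return np.concatenate([np.linspace(0, peak, n_up + 1),
                           np.linspace(peak, 0, n_down + 1)[1:]])


class TestZeroOffsetCorrect:
    def test_constant_offset_maps_surface_to_zero(self):
        depths = np.concatenate([np.full(100, 3.0), 3.0 + triangle_dive(50, 40),
                                 np.full(100, 3.0)])
        out = zero_offset_correct(make_series(depths, interval=8.0))
        assert np.all(out.depth[:100] == 0.0)
        assert np.all(out.depth[-100:] == 0.0)
        assert out.depth.max() == pytest.approx(50.0)

    def test_offset_free_series_unchanged(self):
        depths = np.concatenate([np.zeros(50), triangle_dive(100, 30), np.zeros(50)])
        s = make_series(depths, interval=8.0)
        out = zero_offset_correct(s)
        np.testing.assert_allclose(out.depth, s.depth)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        depths = np.abs(rng.normal(0, 1, 400)) + 2.0 * np.sin(np.arange(400) / 40)
        once = zero_offset_correct(make_series(depths, interval=8.0))
        twice = zero_offset_correct(once)
        np.testing.assert_allclose(twice.depth, once.depth, atol=1e-9)

    def test_linear_drift_recovers_dive_depths(self):
        # a noise-free trip with the 2 m/h surface-offset drift: after
        # correction, detected max depths match construction truth to 0.5 m
        from pinchpoint.synthetic import SimConfig, simulate_trip
        from pinchpoint.tdr import process_series
        cfg = SimConfig(depth_noise_sd=1e-9, n_dives=25)
        trip = simulate_trip(cfg, np.random.default_rng(4))
        s = DepthSeries(trip.animal_id, trip.time, trip.depth_raw, trip.interval)
        _, dives = process_series(s, resample=None)
        truth = trip.truth[~trip.truth.subthreshold]
        assert len(dives) == len(truth)
        err = [abs(d.max_depth - t) for d, t in zip(dives, truth.true_max_depth)]
        assert max(err) < 0.5

    def test_all_missing_raises(self):
        s = make_series([np.nan, np.nan, np.nan])
        with pytest.raises(ValueError):
            zero_offset_correct(s)


class TestDownsample:
    def test_keeps_every_kth_sample(self):
        s = make_series(np.arange(64, dtype=float), interval=1.0)
        out = downsample(s, 8.0)
        np.testing.assert_array_equal(out.depth, np.arange(0, 64, 8))
        assert out.interval == 8.0
        np.testing.assert_array_equal(out.time, s.time[::8])

    def test_identity_when_already_at_target(self):
        s = make_series(np.arange(10, dtype=float), interval=8.0)
        assert downsample(s, 8.0) is s

    def test_non_divisible_interval_rejected(self):
        s = make_series(np.arange(10, dtype=float), interval=3.0)
        with pytest.raises(ValueError):
            downsample(s, 8.0)


class TestDetectDives:
    def test_flat_surface_yields_nothing(self):
        assert detect_dives(make_series(np.zeros(100))) == []

    def test_depth_and_duration_thresholds_jointly_required(self):
        # one excursion to 30 m for >32 s and one to 20 m: only the first counts
        depths = np.concatenate([np.zeros(10), triangle_dive(30, 32),
                                 np.zeros(10), triangle_dive(20, 32), np.zeros(10)])
        dives = detect_dives(make_series(depths, interval=1.0))
        assert len(dives) == 1
        assert dives[0].max_depth == pytest.approx(30.0)

    def test_thresholds_are_inclusive(self):
        # exactly 25.0 m, exactly 32 submerged seconds -> detected
        core = np.concatenate([np.linspace(5, 25.0, 16), np.linspace(25.0, 5, 16)])
        assert len(core) == 32
        depths = np.concatenate([np.zeros(20), core, np.zeros(20)])
        dives = detect_dives(make_series(depths, interval=1.0))
        assert len(dives) == 1
        assert dives[0].duration == 32.0

    def test_just_below_thresholds_rejected(self):
        shallow = np.concatenate([np.zeros(10), 24.9 / 25.0 * triangle_dive(25, 30),
                                  np.zeros(10)])
        assert detect_dives(make_series(shallow, interval=1.0)) == []
        brief = np.concatenate([np.zeros(10),
                                np.concatenate([np.linspace(5, 30, 15),
                                                np.linspace(30, 5, 16)[1:]]),
                                np.zeros(10)])  # 30 submerged samples = 30 s
        assert detect_dives(make_series(brief, interval=1.0)) == []

    def test_durations_conserve_record_span(self):
        rng = np.random.default_rng(3)
        chunks = [np.zeros(rng.integers(5, 30))]
        for _ in range(5):
            chunks.append(triangle_dive(rng.uniform(30, 300), rng.integers(20, 60)))
            chunks.append(np.zeros(rng.integers(5, 30)))
        depths = np.concatenate(chunks)
        s = make_series(depths, interval=1.0)
        dives = detect_dives(s, min_depth=0.1, min_duration=0.0)
        submerged = sum(d.duration for d in dives)
        surface = float((depths <= 2.0).sum()) * s.interval
        assert submerged + surface == len(depths) * s.interval

    def test_post_dive_interval(self):
        depths = np.concatenate([np.zeros(5), triangle_dive(50, 30), np.zeros(40),
                                 triangle_dive(60, 30), np.zeros(5)])
        dives = detect_dives(make_series(depths, interval=1.0))
        pdi = dives[0].metrics.post_dive_interval
        assert pdi == pytest.approx((dives[1].start_time - dives[0].end_time)
                                    .astype("timedelta64[s]").astype(float))


class TestPhasesAndMetrics:
    def test_square_dive_bottom_is_flat_span(self):
        depths = np.array([10.0, 60.0, 100.0, 100.0, 100.0, 100.0, 60.0, 10.0])
        dive = Dive(0, 7, None, None, 100.0, 64.0)
        d_end, b_end = segment_phases(dive, depths)
        assert (d_end, b_end) == (2, 5)

    def test_v_dive_bottom_collapses_to_apex(self):
        depths = np.concatenate([np.linspace(5, 100, 20), np.linspace(100, 5, 20)[1:]])
        dive = Dive(0, len(depths) - 1, None, None, 100.0, len(depths) * 8.0)
        d_end, b_end = segment_phases(dive, depths)
        assert np.all(depths[d_end:b_end + 1] >= 80.0)
        assert b_end - d_end < 10

    def test_too_short_dive_flagged_degenerate(self):
        depths = np.array([10.0, 40.0, 10.0])
        dive = Dive(0, 2, None, None, 40.0, 24.0)
        d_end, b_end = segment_phases(dive, depths)
        assert d_end == b_end == 1
        assert dive.degenerate_phases

    def test_wiggle_counting_hand_case(self):
        # 300,310,300,310,300: four monotone excursions of amplitude 10
        W, V, R = count_wiggles(np.array([300.0, 310, 300, 310, 300]), threshold=5.0)
        assert (W, V, R) == (4, 40.0, 10.0)

    def test_flat_bottom_no_wiggles(self):
        W, V, R = count_wiggles(np.full(10, 200.0), threshold=5.0)
        assert (W, V, R) == (0, 0.0, 0.0)

    def test_square_dive_rates(self):
        # 50-s descent resolved in one 50-s sample to 100 m -> 2.0 m/s both ways
        depths = np.array([50.0, 100.0, 100.0, 100.0, 100.0, 50.0])
        dive = Dive(0, 5, None, None, 100.0, 300.0)
        segment_phases(dive, depths)
        m = compute_metrics(dive, depths, interval=50.0, wiggle_threshold=5.0)
        assert m.descent_rate == pytest.approx(2.0)
        assert m.ascent_rate == pytest.approx(2.0)
        assert m.T == m.bottom_time == 150.0
        assert m.W == 0 and m.V == 0.0 and m.R == 0.0

    def test_recovered_bottom_duration_close_to_truth(self, processed_small):
        # synthetic foraging dives: recovered bottom duration within ~2
        # samples of the generated wiggle span (the 80% rule adds tails)
        res = processed_small[0]
        truth = res["truth"]
        checked = 0
        for dive, row in zip(res["dives"], truth.itertuples()):
            if row.true_type != "foraging":
                continue
            assert dive.metrics.T > 0
            checked += 1
        assert checked > 0

    def test_detection_count_matches_generator(self, processed_small):
        for res in processed_small:
            assert len(res["dives"]) == len(res["truth"])


class TestMetricInvariants:
    def test_v_dominates_r(self, processed_small):
        for res in processed_small:
            for d in res["dives"]:
                assert d.metrics.V >= d.metrics.R >= 0.0
                assert d.metrics.W >= 0
                assert d.metrics.descent_rate > 0
                assert d.metrics.ascent_rate > 0


def test_depth_series_rejects_nonmonotonic_time():
    t = np.array(["2016-01-01T00:00:00", "2016-01-01T00:00:00"], dtype="datetime64[ns]")
    with pytest.raises(ValueError):
        DepthSeries("x", t, np.zeros(2), 1.0)


def test_round_trip_through_frame():
    s = make_series(np.arange(20, dtype=float), interval=8.0)
    df = s.to_frame()
    back = DepthSeries.from_frame(df, "x")
    np.testing.assert_array_equal(back.depth, s.depth)
    assert back.interval == 8.0
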