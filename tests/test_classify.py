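"""Dive-type classification: foraging index, vertical-speed KDE, drift and
benthic criteria, label assignment."""

import numpy as np
import pytest

from pinchpoint.classify import (ClassifierThresholds, ClassificationDetail,
                                 classify_dive, corner_offset, evaluate_kde,
                                 foraging_intensity_index, is_benthic, is_drift,
                                 vertical_speed_kde)
from pinchpoint.synthetic import SimConfig, simulate_dive
from pinchpoint.tdr import Dive, DiveMetrics, segment_phases, compute_metrics


def make_dive(depths, interval=8.0, bathymetry=None):
    dive = Dive(0, len(depths) - 1, None, None, float(np.max(depths)),
                len(depths) * interval)
    segment_phases(dive, depths)
    compute_metrics(dive, depths, interval)
    dive.bathymetry = bathymetry
    return dive


class TestForagingIntensityIndex:
    @pytest.mark.parametrize(
        "W,V,R,T,expected",
        [
            (0, 50.0, 10.0, 100.0, 0.0),
            (5, 100.0, 20.0, 500.0, 30.0),   # 25 + 25*0.2
            (10, 200.0, 20.0, 400.0, 150.0),  # 100 + 100*0.5
        ],
    )
    def test_hand_evaluated_cases(self, W, V, R, T, expected):
        m = DiveMetrics(W=W, V=V, R=R, T=T)
        assert foraging_intensity_index(m) == pytest.approx(expected, abs=1e-9)

    def test_threshold_is_strict(self):
        # W*V/R = 28, V/T = 0.25 -> index exactly 35: NOT foraging
        m = DiveMetrics(W=28, V=25.0, R=25.0, T=100.0)
        assert foraging_intensity_index(m) == 35.0
        depths = np.full(30, 100.0)
        dive = make_dive(np.concatenate([[20.0, 60.0], depths, [60.0, 20.0]]))
        dive.metrics = m
        label, _ = classify_dive(dive, np.concatenate([[20.0, 60.0], depths,
                                                       [60.0, 20.0]]), 8.0)
        assert label != "foraging"

    def test_zero_range_zero_wiggle_scores_zero(self):
        assert foraging_intensity_index(DiveMetrics(W=0, V=0, R=0, T=100)) == 0.0


class TestVerticalSpeedKDE:
    def test_identical_speeds_delta_peak(self):
        peak = vertical_speed_kde(np.full(20, -0.3))
        assert peak.location == pytest.approx(-0.3, abs=1e-4)  # grid resolution
        assert peak.height > 10.0

    def test_uniform_speeds_low_flat_density(self, rng):
        speeds = rng.uniform(-1, 1, 500)
        peak = vertical_speed_kde(speeds)
        assert peak.height <= 1.0
        assert peak.height == pytest.approx(0.5, abs=0.15)

    def test_concentrated_sample_peaks_at_mode(self, rng):
        speeds = np.concatenate([np.full(80, -0.35) + rng.normal(0, 0.02, 80),
                                 rng.uniform(-1.5, 1.5, 20)])
        peak = vertical_speed_kde(speeds)
        assert peak.location == pytest.approx(-0.35, abs=0.03)
        assert peak.height > 1.0

    def test_small_samples_rejected(self):
        assert vertical_speed_kde(np.arange(9.0)) is None

    def test_density_integrates_to_one(self, rng):
        speeds = rng.normal(0, 0.4, 200)
        grid = np.linspace(speeds.min() - 3, speeds.max() + 3, 20001)
        dens = evaluate_kde(speeds, grid)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)


class TestDriftCriterion:
    def test_synthetic_drift_dive_detected(self, rng):
        cfg = SimConfig()
        for _ in range(5):
            depths, _ = simulate_dive("drift", 600.0, rng, cfg)
            dive = make_dive(depths)
            drift, peak = is_drift(dive, depths, 8.0, ClassifierThresholds())
            assert drift
            assert 0.2 <= abs(peak.location) <= 0.5

    def test_transit_v_dive_not_drift(self, rng):
        cfg = SimConfig()
        for _ in range(5):
            depths, _ = simulate_dive("transit", 600.0, rng, cfg)
            dive = make_dive(depths)
            drift, _ = is_drift(dive, depths, 8.0, ClassifierThresholds())
            assert not drift


def square_bottom_dive(level=200.0, interval=8.0, n_bottom=20, descent_rate=1.5,
                       rng=None):
    """Sharp-cornered dive with a flat bottom at ``level``."""
    rng = rng or np.random.default_rng(0)
    n_down = int(level / (descent_rate * interval))
    down = np.linspace(descent_rate * interval, level, n_down)
    bottom = level + rng.normal(0, 0.3, n_bottom)
    up = np.linspace(level, descent_rate * interval, n_down)[1:]
    return np.concatenate([down, bottom, up])


class TestBenthicCriterion:
    def test_ideal_square_dive_at_seafloor(self):
        depths = square_bottom_dive(level=200.0)
        dive = make_dive(depths, bathymetry=205.0)
        ok, det = is_benthic(dive, depths, 8.0, 205.0, ClassifierThresholds())
        assert ok
        assert det.corner_offset_m < 15.0
        assert det.bottom_peak_height > 1.5

    def test_bathymetry_gate(self):
        depths = square_bottom_dive(level=130.0)
        dive = make_dive(depths, bathymetry=600.0)
        ok, det = is_benthic(dive, depths, 8.0, 600.0, ClassifierThresholds())
        assert not ok
        assert det.bathy_diff_m >= 100.0

    def test_missing_bathymetry_flagged(self):
        depths = square_bottom_dive()
        dive = make_dive(depths)
        ok, det = is_benthic(dive, depths, 8.0, None, ClassifierThresholds())
        assert not ok
        assert "no-bathy" in det.flags

    def test_rounded_corner_rejected(self):
        # descent at 1.5 m/s toward a line-intersection near 280 m, but the
        # observed trajectory rounds off early and flattens 25 m shallower
        interval = 8.0
        t_corner = 280.0 / 1.5
        t = np.arange(1, 60) * interval
        depth = np.where(
            t < t_corner - 60.0,
            1.5 * t,
            255.0 - 25.0 * np.exp(-(t - (t_corner - 60.0)) / 100.0),
        )
        depth = np.minimum(depth, 255.0)
        rng = np.random.default_rng(1)
        depth[t >= t_corner + 200] = 255.0 + rng.normal(0, 0.2,
                                                        int((t >= t_corner + 200).sum()))
        dive = make_dive(depth, bathymetry=260.0)
        off = corner_offset(dive, depth, interval)
        ok, det = is_benthic(dive, depth, interval, 260.0, ClassifierThresholds())
        if off is not None and off >= 15.0:
            assert not ok

    def test_corner_offset_small_for_sharp_corner(self):
        depths = square_bottom_dive(level=300.0)
        dive = make_dive(depths)
        off = corner_offset(dive, depths, 8.0)
        assert off is not None and off < 5.0


class TestClassifyDive:
    def test_unremarkable_dive_is_transit(self, rng):
        cfg = SimConfig()
        depths, _ = simulate_dive("transit", 600.0, rng, cfg)
        dive = make_dive(depths, bathymetry=600.0)
        label, _ = classify_dive(dive, depths, 8.0, bathymetry=600.0)
        assert label == "transit"

    def test_benthic_with_no_wiggles_never_foraging(self, rng):
        depths = square_bottom_dive(level=150.0, rng=rng)
        dive = make_dive(depths, bathymetry=152.0)
        label, det = classify_dive(dive, depths, 8.0, bathymetry=152.0)
        assert label == "benthic"
        assert det.fii <= 35.0

    def test_cohort_recovery(self, processed_small):
        """Labels recovered on the seeded synthetic cohort."""
        pred, true = [], []
        for res in processed_small:
            pred += [d.type for d in res["dives"]]
            true += list(res["truth"].true_type)
        agree = np.mean([p == t for p, t in zip(pred, true)])
        assert agree >= 0.90

    def test_every_dive_gets_exactly_one_label(self, processed_small):
        for res in processed_small:
            labels = [d.type for d in res["dives"]]
            assert all(l in ("transit", "foraging", "drift", "benthic")
                       for l in labels)

    def test_foraging_count_monotone_in_threshold(self, processed_small):
        res = processed_small[0]
        series = res["series"]
        counts = []
        for fii in (5.0, 35.0, 200.0):
            thr = ClassifierThresholds(fii_threshold=fii)
            n = 0
            for d in res["dives"]:
                label, _ = classify_dive(d, d.slice(series), series.interval,
                                         bathymetry=d.bathymetry, thresholds=thr)
                n += label == "foraging"
            counts.append(n)
        assert counts[0] >= counts[1] >= counts[2]

    def test_benthic_respects_bathy_gate_on_output(self, processed_small):
        for res in processed_small:
            for d in res["dives"]:
                if d.type == "benthic":
                    assert d.bathymetry is not None
                    assert abs(d.max_depth - d.bathymetry) < 100.0


def test_thresholds_must_be_positive():
    with pytest.raises(ValueError):
        ClassifierThresholds(fii_threshold=0.0)
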