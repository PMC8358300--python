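"""Stabilometric measure battery: oracles, closed forms, invariances."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import posturo as po
from oracles import (
    brute_ellipse_area,
    brute_mean_distance,
    brute_mean_frequency,
    brute_mean_velocity,
)


class TestBruteForceOracle:
    """Each measure matches an independent literal recomputation to 1e-9."""

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("n", [5, 17, 50])
    def test_all_measures_match(self, make_trajectory, n, seed):
        traj = make_trajectory(n=n, seed=seed)
        ap, ml, fs = list(traj.ap), list(traj.ml), traj.sampling_rate
        assert po.mean_distance(traj, "ap") == pytest.approx(
            brute_mean_distance(ap), rel=1e-9)
        assert po.mean_velocity(traj, "ml") == pytest.approx(
            brute_mean_velocity(ml, fs), rel=1e-9)
        assert po.ellipse_area_95(traj) == pytest.approx(
            brute_ellipse_area(ap, ml), rel=1e-9)
        assert po.mean_frequency(traj, "ap") == pytest.approx(
            brute_mean_frequency(ap, fs), rel=1e-9)


class TestMeanDistance:
    def test_hand_example(self):
        traj = po.COPTrajectory(ap=[-2, 0, 2], ml=[0, 0, 0], sampling_rate=10,
                                centered=True)
        assert po.mean_distance(traj, "ap") == pytest.approx(4 / 3)

    def test_sinusoid_closed_form(self, make_sinusoid):
        traj = po.center_trajectory(make_sinusoid(amplitude=10.0, freq=1.0))
        assert po.mean_distance(traj, "ap") == pytest.approx(
            20 / math.pi, rel=0.005)

    def test_requires_centered(self, make_sinusoid):
        with pytest.raises(po.MeasureError, match="centered"):
            po.mean_distance(make_sinusoid(), "ap")

    def test_constant_series_is_zero(self):
        traj = po.COPTrajectory(ap=np.zeros(10), ml=np.zeros(10),
                                sampling_rate=10, centered=True)
        assert po.mean_distance(traj, "ap") == 0.0


class TestMeanVelocity:
    def test_sinusoid_closed_form(self, make_sinusoid):
        # path length of A*sin(2*pi*f*t) per second is 4*A*f
        traj = po.center_trajectory(make_sinusoid(amplitude=10.0, freq=1.0))
        assert po.mean_velocity(traj, "ap") == pytest.approx(40.0, rel=1e-3)

    def test_linear_ramp(self):
        fs = 100.0
        n = round(10 * fs) + 1
        ramp = np.linspace(0, 10, n)
        traj = po.center_trajectory(
            po.COPTrajectory(ap=ramp, ml=np.zeros(n), sampling_rate=fs))
        assert po.mean_velocity(traj, "ap") == pytest.approx(1.0, rel=1e-9)

    def test_single_sample_rejected(self):
        traj = po.COPTrajectory(ap=[0.0], ml=[0.0], sampling_rate=10,
                                centered=True)
        with pytest.raises(po.MeasureError):
            po.mean_velocity(traj, "ap")


class TestEllipse:
    def test_gaussian_area_close_to_asymptotic(self):
        # independent unit-variance axes: area -> 2*pi*3.0*1 ~ 18.85 mm^2
        areas = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            traj = po.center_trajectory(po.COPTrajectory(
                ap=r.normal(0, 1, 4000), ml=r.normal(0, 1, 4000),
                sampling_rate=200))
            areas.append(po.ellipse_area_95(traj))
        assert np.mean(areas) == pytest.approx(18.85, rel=0.05)

    def test_collinear_path_degenerate(self):
        ap = np.array([-1.0, 0.0, 1.0, 2.0]) - 0.5
        traj = po.COPTrajectory(ap=ap, ml=np.zeros(4), sampling_rate=10,
                                centered=True)
        fit = po.ellipse_fit(traj)
        assert fit.degenerate and fit.area == 0.0

    def test_scaling_squares_area(self, make_trajectory):
        traj = make_trajectory(n=200)
        doubled = po.COPTrajectory(ap=2 * traj.ap, ml=2 * traj.ml,
                                   sampling_rate=traj.sampling_rate,
                                   centered=True)
        assert po.ellipse_area_95(doubled) == pytest.approx(
            4 * po.ellipse_area_95(traj), rel=1e-12)

    def test_coverage_near_quantile_single_seed(self):
        r = np.random.default_rng(99)
        traj = po.center_trajectory(po.COPTrajectory(
            ap=r.normal(0, 1, 4000), ml=r.normal(0, 1, 4000),
            sampling_rate=200))
        assert po.ellipse_coverage(traj) == pytest.approx(0.95, abs=0.03)


class TestMeanFrequency:
    def test_sinusoid_closed_form(self, make_sinusoid):
        # Mf = Vel/(4*sqrt(2)*Mean) = (4Af) / (4*sqrt(2)*2A/pi) = pi*f/(2*sqrt(2))
        for f in (0.5, 1.0, 2.0):
            traj = po.center_trajectory(make_sinusoid(freq=f))
            expected = math.pi * f / (2 * math.sqrt(2))
            assert po.mean_frequency(traj, "ap") == pytest.approx(
                expected, rel=0.005)

    def test_amplitude_invariant(self, make_sinusoid):
        t1 = po.center_trajectory(make_sinusoid(amplitude=5.0))
        t2 = po.center_trajectory(make_sinusoid(amplitude=10.0))
        assert po.mean_frequency(t1, "ap") == pytest.approx(
            po.mean_frequency(t2, "ap"), rel=1e-9)

    def test_constant_series_undefined(self):
        traj = po.COPTrajectory(ap=np.zeros(10), ml=np.zeros(10),
                                sampling_rate=10, centered=True)
        assert math.isnan(po.mean_frequency(traj, "ap"))


class TestBattery:
    def test_composition_matches_members(self, make_trajectory):
        traj = make_trajectory(n=300)
        bat = po.measure_battery(traj)
        assert bat.mean_ap == po.mean_distance(traj, "ap")
        assert bat.vel_ml == po.mean_velocity(traj, "ml")
        assert bat.area95 == po.ellipse_area_95(traj)
        assert bat.mf_ap == po.mean_frequency(traj, "ap")
        assert bat.undefined == frozenset()

    def test_pure_ap_sinusoid_flags_ml(self, make_sinusoid):
        bat = po.measure_battery(po.center_trajectory(make_sinusoid()))
        assert bat.mean_ml == 0.0 and bat.vel_ml == 0.0
        assert "mf_ml" in bat.undefined and math.isnan(bat.mf_ml)
        assert bat.area95 == 0.0  # collinear path

    def test_axis_swap_symmetry(self, make_trajectory):
        traj = make_trajectory(n=120)
        swapped = po.COPTrajectory(ap=traj.ml, ml=traj.ap,
                                   sampling_rate=traj.sampling_rate,
                                   centered=True)
        b1, b2 = po.measure_battery(traj), po.measure_battery(swapped)
        assert b1.mean_ap == b2.mean_ml and b1.vel_ap == b2.vel_ml
        assert b1.mf_ml == b2.mf_ap
        assert b1.area95 == pytest.approx(b2.area95, rel=1e-12)

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_homogeneity_scaling_laws(self, c):
        traj = _fixed_trajectory()
        scaled = po.COPTrajectory(ap=c * traj.ap, ml=c * traj.ml,
                                  sampling_rate=traj.sampling_rate,
                                  centered=True)
        b1, b2 = po.measure_battery(traj), po.measure_battery(scaled)
        assert b2.mean_ap == pytest.approx(c * b1.mean_ap, rel=1e-9)
        assert b2.vel_ml == pytest.approx(c * b1.vel_ml, rel=1e-9)
        assert b2.area95 == pytest.approx(c**2 * b1.area95, rel=1e-9)
        assert b2.mf_ap == pytest.approx(b1.mf_ap, rel=1e-9)

    def test_time_reversal_invariance(self, make_trajectory):
        traj = make_trajectory(n=80)
        rev = po.COPTrajectory(ap=traj.ap[::-1].copy(),
                               ml=traj.ml[::-1].copy(),
                               sampling_rate=traj.sampling_rate,
                               centered=True)
        b1, b2 = po.measure_battery(traj), po.measure_battery(rev)
        for name in po.MEASURE_NAMES:
            assert b1.value(name) == pytest.approx(b2.value(name), rel=1e-12)


def _fixed_trajectory():
    r = np.random.default_rng(7)
    return po.center_trajectory(po.COPTrajectory(
        ap=r.normal(0, 3, 64), ml=r.normal(0, 2, 64), sampling_rate=100))


class TestAggregate:
    def test_identical_trials(self, make_trajectory):
        bat = po.measure_battery(make_trajectory())
        agg = po.aggregate([bat, bat, bat])
        assert agg.mean_ap == bat.mean_ap and agg.area95 == bat.area95

    def test_mean_across_trials(self, make_trajectory):
        bats = [po.measure_battery(make_trajectory(seed=s)) for s in range(3)]
        agg = po.aggregate(bats)
        assert agg.mean_ap == pytest.approx(
            np.mean([b.mean_ap for b in bats]))

    def test_undefined_propagates(self, make_sinusoid, make_trajectory):
        good = po.measure_battery(make_trajectory())
        flagged = po.measure_battery(po.center_trajectory(make_sinusoid()))
        agg = po.aggregate([good, flagged, good])
        assert "mf_ml" in agg.undefined and math.isnan(agg.mf_ml)
        assert not math.isnan(agg.mean_ap)

    def test_empty_rejected(self):
        with pytest.raises(po.MeasureError):
            po.aggregate([])


class TestLongFormat:
    def test_roundtrip(self, tmp_path, make_trajectory):
        records = [(1, 1, "agg", po.measure_battery(make_trajectory(seed=1))),
                   (1, 4, "agg", po.measure_battery(make_trajectory(seed=2)))]
        df = po.batteries_to_long(records)
        assert len(df) == 2 * len(po.MEASURE_NAMES)
        path = tmp_path / "measures.csv"
        po.write_long_csv(df, path)
        back = po.read_long_csv(path)
        assert list(back.columns) == list(df.columns)
        np.testing.assert_allclose(back["value"], df["value"], rtol=1e-10)
        assert (back["flag"] == df["flag"]).all()
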