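"""Signal conditioning and COM reconstruction against analytic oracles."""

import numpy as np
import pytest

from swaysim import (
    AngularSeries,
    AnthropometricTable,
    GapSpec,
    angular_com,
    clip_and_demean,
    default_anthropometry,
    default_chain,
    integrate_velocity,
    interpolate_gaps,
    lowpass_filter,
    synthesize_markers,
    total_body_com,
)
from swaysim.types import MarkerSet, ComTrajectory


class TestIntegrateVelocity:
    def test_constant_velocity_ramp(self):
        v = AngularSeries(100.0, np.ones(201), "velocity")  # 2 s of 1 deg/s
        pos = integrate_velocity(v)
        assert pos.values[0] == 0.0
        assert pos.values[-1] == pytest.approx(2.0)
        assert len(pos.values) == len(v.values)

    def test_zero_velocity(self):
        v = AngularSeries(100.0, np.zeros(500), "velocity")
        assert np.all(integrate_velocity(v).values == 0.0)

    def test_cosine_antiderivative(self):
        """v = 2*pi*cos(2*pi*t) integrates to sin(2*pi*t)."""
        fs, dur = 100.0, 10.0
        t = np.arange(int(fs * dur) + 1) / fs
        v = AngularSeries(fs, 2 * np.pi * np.cos(2 * np.pi * t), "velocity")
        pos = integrate_velocity(v)
        # trapezoid error bound for this tone at 100 Hz (computed offline)
        assert np.max(np.abs(pos.values - np.sin(2 * np.pi * t))) < 5e-4

    def test_round_trip_differentiation(self):
        rng = np.random.default_rng(0)
        v = AngularSeries(50.0, rng.standard_normal(400), "velocity")
        pos = integrate_velocity(v)
        # d/dt of the cumulative trapezoid recovers interior midpoint values
        back = np.diff(pos.values) * 50.0
        np.testing.assert_allclose(back, (v.values[1:] + v.values[:-1]) / 2,
                                   atol=1e-9)

    def test_rejects_position_input(self):
        with pytest.raises(ValueError):
            integrate_velocity(AngularSeries(100.0, np.zeros(10), "position"))

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            integrate_velocity(AngularSeries(100.0, np.empty(0), "velocity"))


def _cubic_marker_set(gap_samples, start=100, fs=125.0, n=600):
    """One marker following a cubic polynomial with an injected gap."""
    t = np.arange(n) / fs
    poly = lambda t: 0.3 + 0.05 * t - 0.02 * t**2 + 0.004 * t**3
    markers, missing = {}, {}
    for name in ("ankle", "met", "knee", "hip", "c7"):
        xy = np.column_stack([poly(t), 1.0 + 0.1 * t])
        markers[name] = xy
        missing[name] = np.zeros(n, bool)
    markers["knee"][start:start + gap_samples] = np.nan
    missing["knee"][start:start + gap_samples] = True
    return MarkerSet(fs, markers, missing), poly, t


class TestInterpolateGaps:
    def test_cubic_gap_filled_exactly(self):
        ms, poly, t = _cubic_marker_set(gap_samples=3)  # 24 ms at 125 Hz
        out, reports = interpolate_gaps(ms)
        assert not out.missing["knee"].any()
        np.testing.assert_allclose(out.markers["knee"][100:103, 0],
                                   poly(t[100:103]), atol=1e-9)
        assert [r.filled for r in reports] == [True]

    def test_long_gap_left_missing(self):
        ms, _, _ = _cubic_marker_set(gap_samples=6)  # 48 ms >= 40 ms rule
        out, reports = interpolate_gaps(ms)
        assert out.missing["knee"].sum() == 6
        assert reports[0].filled is False
        assert "40" in reports[0].reason

    def test_boundary_gap_not_extrapolated(self):
        ms, _, _ = _cubic_marker_set(gap_samples=3, start=0)
        out, reports = interpolate_gaps(ms)
        assert out.missing["knee"].sum() == 3
        assert "boundary" in reports[0].reason

    def test_no_gaps_identity(self):
        ms, _, _ = _cubic_marker_set(gap_samples=0)
        out, reports = interpolate_gaps(ms)
        assert reports == []
        for name in ms.markers:
            np.testing.assert_array_equal(out.markers[name], ms.markers[name])

    def test_non_missing_samples_unaltered(self):
        ms, _, _ = _cubic_marker_set(gap_samples=3)
        before = {k: v.copy() for k, v in ms.markers.items()}
        out, _ = interpolate_gaps(ms)
        keep = ~ms.missing["knee"]
        np.testing.assert_array_equal(out.markers["knee"][keep],
                                      before["knee"][keep])


class TestLowpassFilter:
    def test_dc_gain_unity(self):
        x = np.full(2000, 3.7)
        y = lowpass_filter(x, 3.5, 100.0)
        np.testing.assert_allclose(y, x, rtol=1e-6)

    def test_tone_attenuation_matches_analytic_gain(self):
        """5 Hz tone through the 3.5 Hz order-4 dual-pass filter."""
        fs, dur = 100.0, 30.0
        t = np.arange(int(fs * dur)) / fs
        y = lowpass_filter(np.sin(2 * np.pi * 5.0 * t), 3.5, fs, order=4)
        mid = slice(int(5 * fs), int(25 * fs))
        amp = np.sqrt(2) * np.sqrt(np.mean(y[mid] ** 2))
        expected = 1.0 / (1.0 + (5.0 / 3.5) ** 8)
        assert amp == pytest.approx(expected, rel=0.05)

    def test_zero_phase_on_symmetric_pulse(self):
        fs = 100.0
        t = np.arange(int(20 * fs)) / fs
        x = np.exp(-0.5 * ((t - 10.0) / 0.8) ** 2)
        y = lowpass_filter(x, 3.5, fs)
        assert np.argmax(y) == np.argmax(x)

    def test_stopband_energy_reduction(self):
        """>= 99% energy removal two octaves above cutoff (order 4, dual pass)."""
        fs = 100.0
        t = np.arange(int(40 * fs)) / fs
        x = np.sin(2 * np.pi * 7.0 * t)  # 2x the 3.5 Hz cutoff
        y = lowpass_filter(x, 3.5, fs)
        mid = slice(int(5 * fs), int(35 * fs))
        assert np.sum(y[mid] ** 2) < 0.01 * np.sum(x[mid] ** 2)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            lowpass_filter(np.zeros(10), 3.5, 100.0)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros(1000), 60.0, 100.0)


class TestClipAndDemean:
    def test_clip_length(self):
        x = AngularSeries(100.0, np.random.default_rng(0).normal(size=12000),
                          "position")
        y = clip_and_demean(x, 80.0)
        assert len(y.values) == 8000

    def test_constant_becomes_zero(self):
        x = AngularSeries(100.0, np.full(9000, 4.2), "position")
        np.testing.assert_allclose(clip_and_demean(x).values, 0.0, atol=1e-12)

    def test_output_mean_zero(self):
        x = AngularSeries(100.0,
                          np.random.default_rng(1).normal(2.0, 1.0, 10000),
                          "position")
        assert abs(clip_and_demean(x).values.mean()) < 1e-12

    def test_short_series_rejected(self):
        x = AngularSeries(100.0, np.zeros(100), "position")
        with pytest.raises(ValueError, match="shorter"):
            clip_and_demean(x, 80.0)


class TestTotalBodyCom:
    def test_coincident_endpoints_give_that_point(self):
        p = np.array([0.12, 0.9])
        markers = {n: np.tile(p, (5, 1)) for n in
                   ("ankle", "met", "knee", "hip", "c7")}
        ms = MarkerSet(100.0, markers, {})
        com = total_body_com(ms, default_anthropometry())
        np.testing.assert_allclose(com.xy, np.tile(p, (5, 1)), atol=1e-12)

    def test_hand_computed_toy(self):
        """Two-sample toy checked against a spreadsheet-style calculation."""
        table = AnthropometricTable(
            mass_fraction={"foot": 0.1, "shank": 0.2, "thigh": 0.3,
                           "head_arms_trunk": 0.4},
            com_fraction={"foot": 0.5, "shank": 0.4, "thigh": 0.4,
                          "head_arms_trunk": 0.6},
        )
        markers = {
            "ankle": np.array([[0.0, 0.0], [0.1, 0.0]]),
            "met": np.array([[0.2, 0.0], [0.3, 0.0]]),
            "knee": np.array([[0.0, 0.5], [0.1, 0.5]]),
            "hip": np.array([[0.0, 1.0], [0.1, 1.0]]),
            "c7": np.array([[0.0, 1.5], [0.1, 1.5]]),
        }
        ms = MarkerSet(100.0, markers, {})
        com = total_body_com(ms, table)
        # sample 0, by hand:
        # foot: (0,0)+0.5*((0.2,0)-(0,0)) = (0.10, 0)      w 0.1
        # shank: (0,0)+0.4*((0,0.5)-(0,0)) = (0, 0.20)     w 0.2
        # thigh: (0,0.5)+0.4*((0,1.0)-(0,0.5)) = (0, 0.70) w 0.3
        # hat:  (0,1.0)+0.6*((0,1.5)-(0,1.0)) = (0, 1.30)  w 0.4
        # com = (0.010, 0.04+0.21+0.52) = (0.010, 0.770)
        np.testing.assert_allclose(com.xy[0], [0.010, 0.770], atol=1e-12)
        np.testing.assert_allclose(com.xy[1], [0.110, 0.770], atol=1e-12)

    def test_com_on_lean_line(self):
        theta = AngularSeries(125.0, np.full(50, 5.0), "position")
        ms = synthesize_markers(theta, default_chain(1.70), seed=0)
        com = total_body_com(ms, default_anthropometry())
        angles = np.degrees(np.arctan2(com.xy[:, 0], com.xy[:, 1]))
        np.testing.assert_allclose(angles, 5.0, atol=1e-9)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        markers = {n: rng.normal(0.0, 0.3, (20, 2)) + [0, 1.0]
                   for n in ("ankle", "met", "knee", "hip", "c7")}
        ms = MarkerSet(100.0, {k: v.copy() for k, v in markers.items()}, {})
        shift = np.array([0.25, -0.1])
        ms2 = MarkerSet(100.0, {k: v + shift for k, v in markers.items()}, {})
        table = default_anthropometry()
        np.testing.assert_allclose(total_body_com(ms2, table).xy,
                                   total_body_com(ms, table).xy + shift,
                                   atol=1e-12)

    def test_rotation_adds_to_angular_com(self):
        theta = AngularSeries(125.0, np.full(10, 2.0), "position")
        chain = default_chain(1.70)
        ms = synthesize_markers(theta, chain, seed=0)
        phi = np.deg2rad(4.0)
        rot = np.array([[np.cos(phi), np.sin(phi)],
                        [-np.sin(phi), np.cos(phi)]])
        ms2 = MarkerSet(125.0, {k: v @ rot.T for k, v in ms.markers.items()},
                        {})
        table = default_anthropometry()
        a1 = angular_com(total_body_com(ms, table)).values
        a2 = angular_com(total_body_com(ms2, table)).values
        np.testing.assert_allclose(a2, a1 + 4.0, atol=1e-9)

    def test_missing_segment_rejected(self):
        ms = MarkerSet(100.0, {"ankle": np.zeros((5, 2))}, {})
        with pytest.raises(ValueError, match="endpoints"):
            total_body_com(ms, default_anthropometry())


class TestAngularCom:
    @pytest.mark.parametrize("x,y,expected", [
        (0.0, 1.0, 0.0),
        (1.0, 1.0, 45.0),
        (0.05, 1.0, 2.8624),  # arctan(0.05) by hand
    ])
    def test_inverse_tangent(self, x, y, expected):
        c = ComTrajectory(100.0, np.array([[x, y]]))
        assert angular_com(c).values[0] == pytest.approx(expected, abs=5e-4)

    def test_nonpositive_vertical_offset_rejected(self):
        c = ComTrajectory(100.0, np.array([[0.1, -0.5]]))
        with pytest.raises(ValueError, match="non-physical"):
            angular_com(c)


class TestAnthropometricTable:
    def test_default_table_valid(self):
        table = default_anthropometry()
        assert sum(table.mass_fraction.values()) == pytest.approx(1.0, abs=1e-6)

    def test_bad_mass_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            AnthropometricTable(
                mass_fraction={"foot": 0.1, "shank": 0.2, "thigh": 0.3,
                               "head_arms_trunk": 0.5},
                com_fraction={"foot": 0.5, "shank": 0.5, "thigh": 0.5,
                              "head_arms_trunk": 0.5},
            )
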