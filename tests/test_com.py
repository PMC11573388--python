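"""Segmental CoM estimation and phase-space construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import stsmap as sm
from stsmap import com as cm
from stsmap.preprocess import CycleSet
from stsmap.synth import _linkage_markers, _markers_to_frame

from conftest import cohort_xy


def _frame(**markers):
    data = {}
    for name, arr in markers.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        for k, ax in enumerate(("x", "y", "z")):
            data[f"{name}_{ax}"] = arr[:, k]
    return pd.DataFrame(data)


class TestEstimateCom:
    def test_single_segment_midpoint(self):
        anthro = cm.AnthropometricTable(
            segments=(cm.SegmentDef("s", 1.0, 0.5, "p", "d"),)
        )
        markers = _frame(p=[[0, 0, 0]], d=[[0, 2, 0]])
        np.testing.assert_allclose(cm.estimate_com(markers, anthro), [[0, 1, 0]])

    def test_two_equal_segments_average(self):
        anthro = cm.AnthropometricTable(
            segments=(
                cm.SegmentDef("a", 0.5, 0.0, "p1", "d1"),
                cm.SegmentDef("b", 0.5, 0.0, "p2", "d2"),
            )
        )
        markers = _frame(
            p1=[[0, 0, 0]], d1=[[9, 9, 9]], p2=[[0, 2, 0]], d2=[[9, 9, 9]]
        )
        np.testing.assert_allclose(cm.estimate_com(markers, anthro), [[0, 1, 0]])

    def test_three_segment_weighted_sum_oracle(self, rng):
        # independent brute-force oracle: plain python loops over segments
        anthro = cm.AnthropometricTable(
            segments=(
                cm.SegmentDef("s1", 0.1, 0.3, "a", "b"),
                cm.SegmentDef("s2", 0.3, 0.7, "c", "d"),
                cm.SegmentDef("s3", 0.6, 0.45, "e", "f"),
            )
        )
        pos = {m: rng.normal(size=(20, 3)) for m in "abcdef"}
        markers = _frame(**pos)
        expected = np.zeros((20, 3))
        for frac, comf, p, d in [(0.1, 0.3, "a", "b"), (0.3, 0.7, "c", "d"),
                                 (0.6, 0.45, "e", "f")]:
            for t in range(20):
                for k in range(3):
                    seg = pos[p][t, k] + comf * (pos[d][t, k] - pos[p][t, k])
                    expected[t, k] += frac * seg
        np.testing.assert_allclose(cm.estimate_com(markers, anthro), expected, atol=1e-12)

    def test_translation_equivariance(self, rng):
        pos = {m: rng.normal(size=(5, 3)) for m in ("knee", "ankle", "hip", "shoulder")}
        markers = _frame(**pos)
        shift = np.array([1.0, -2.0, 0.5])
        shifted = _frame(**{m: v + shift for m, v in pos.items()})
        np.testing.assert_allclose(
            cm.estimate_com(shifted), cm.estimate_com(markers) + shift, atol=1e-12
        )

    def test_missing_marker_named_in_error(self):
        with pytest.raises(ValueError, match="knee"):
            cm.estimate_com(_frame(hip=[[0, 0, 0]], shoulder=[[0, 1, 0]],
                                   ankle=[[0, -1, 0]]))

    def test_mass_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            cm.AnthropometricTable(segments=(cm.SegmentDef("s", 0.9, 0.5, "p", "d"),))


class TestSagittalProjection:
    def test_com_at_midpoint_maps_to_origin(self):
        mall_l = np.tile([0.0, 0.1, -0.05], (4, 1))
        mall_r = np.tile([0.0, 0.1, 0.05], (4, 1))
        com3d = np.tile([0.0, 0.1, 0.0], (4, 1))
        x, y = cm.to_sagittal_relative(com3d, mall_l, mall_r)
        np.testing.assert_allclose(x, 0.0, atol=1e-12)
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_anterior_and_vertical_offsets(self):
        mall_l = np.tile([0.0, 0.0, -0.05], (2, 1))
        mall_r = np.tile([0.0, 0.0, 0.05], (2, 1))
        com3d = np.tile([0.1, 0.9, 0.3], (2, 1))
        x, y = cm.to_sagittal_relative(com3d, mall_l, mall_r)
        np.testing.assert_allclose(x, 0.1)
        np.testing.assert_allclose(y, 0.9)

    def test_standing_plateau_height_matches_linkage(self, small_cohort):
        subj = small_cohort.subjects[0]
        x, y = cohort_xy(small_cohort, subj.subject_id)
        standing = _markers_to_frame(_linkage_markers(np.ones(1), subj.body_height))
        expected = (
            cm.estimate_com(standing)[0, cm.VT_AXIS]
            - cm.marker_xyz(standing, "ankle")[0, cm.VT_AXIS]
        )
        timing = small_cohort.trial_truth[subj.subject_id]
        fs = small_cohort.config_echo.marker_fs
        idx = int(0.60 * timing["cycle_duration"] * fs)  # mid standing dwell
        assert y[idx] == pytest.approx(expected, abs=1e-6)


class TestPolarTransform:
    @pytest.mark.parametrize(
        "xy,expected",
        [
            ((0.0, 1.0), (1.0, 0.0)),
            ((1.0, 1.0), (np.sqrt(2.0), np.pi / 4)),
            ((0.3, 0.4), (0.5, np.arctan(0.75))),
        ],
    )
    def test_closed_form_points(self, xy, expected):
        mag, ang = cm.polar_transform(np.array([xy[0]]), np.array([xy[1]]))
        assert mag[0] == pytest.approx(expected[0], abs=1e-12)
        assert ang[0] == pytest.approx(expected[1], abs=1e-12)

    def test_origin_flagged_undefined(self):
        mag, ang = cm.polar_transform(np.array([0.0]), np.array([0.0]))
        assert mag[0] == 0.0 and np.isnan(ang[0])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.floats(min_value=-5, max_value=5, allow_nan=False),
        st.floats(min_value=1e-3, max_value=5, allow_nan=False),
    )
    def test_roundtrip_identity_above_ground(self, x, y):
        mag, ang = cm.polar_transform(np.array([x]), np.array([y]))
        xb, yb = cm.polar_inverse(mag, ang)
        assert xb[0] == pytest.approx(x, abs=1e-12)
        assert yb[0] == pytest.approx(y, abs=1e-12)


class TestDifferentiate:
    def test_constant_gives_zero(self):
        np.testing.assert_allclose(cm.differentiate(np.full(50, 3.3), 100.0), 0.0)

    def test_linear_ramp_exact(self):
        t = np.arange(200) / 100.0
        v = cm.differentiate(2.5 * t, 100.0)
        np.testing.assert_allclose(v, 2.5, atol=1e-9)

    def test_sine_derivative_closed_form(self):
        t = np.arange(0, 1, 1e-3)
        v = cm.differentiate(np.sin(2 * np.pi * t), 1000.0)
        assert np.max(np.abs(v - 2 * np.pi * np.cos(2 * np.pi * t))) < 1e-3


class TestPhaseTrajectory:
    def test_circle_velocities_match_analytic_forms(self):
        fs = 1000.0
        t = np.arange(0, 1.5, 1 / fs)
        x, y = np.cos(t), 2.0 + np.sin(t)
        cycles = CycleSet(intervals=[(0, len(t))], source_fs=fs)
        traj = cm.build_phase_trajectory(x, y, fs, cycles)[0]
        tn = np.linspace(0.0, (len(t) - 1) / fs, 100)
        vmag_true = 2 * np.cos(tn) / np.sqrt(5 + 4 * np.sin(tn))
        vang_true = (-2 * np.sin(tn) - 1) / (5 + 4 * np.sin(tn))
        assert np.max(np.abs(traj.vmag - vmag_true)) < 1e-2
        assert np.max(np.abs(traj.vang - vang_true)) < 1e-2

    def test_static_posture_zero_velocities(self):
        n = 50
        x, y = np.full(n, 0.1), np.full(n, 0.9)
        cycles = CycleSet(intervals=[(0, n)], source_fs=100.0)
        traj = cm.build_phase_trajectory(x, y, 100.0, cycles)[0]
        for v in (traj.vx, traj.vy, traj.vmag, traj.vang):
            np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_magnitude_identity_on_generator_data(self, small_cohort):
        subj = small_cohort.subjects[0]
        x, y = cohort_xy(small_cohort, subj.subject_id)
        from stsmap.preprocess import segment_upward_cycles

        cycles = segment_upward_cycles(y, small_cohort.config_echo.marker_fs)
        for traj in cm.build_phase_trajectory(
            x, y, small_cohort.config_echo.marker_fs, cycles
        ):
            np.testing.assert_allclose(
                traj.mag**2, traj.x**2 + traj.y**2, atol=1e-9
            )

    def test_short_cycle_fails(self):
        cycles = CycleSet(intervals=[(0, 2)], source_fs=100.0)
        with pytest.raises(ValueError):
            cm.build_phase_trajectory(np.arange(5.0), np.arange(5.0) + 1, 100.0, cycles)


class TestPhaseSpaceParameters:
    def _traj(self, vy_scale):
        n = 101  # odd count puts a sample exactly at the sine peak
        u = np.linspace(0, 1, n)
        x, y = 0.05 * u, 0.6 + 0.3 * u
        return cm.PhaseTrajectory(
            x=x, y=y, vx=np.gradient(x), vy=vy_scale * np.sin(np.pi * u),
            mag=np.hypot(x, y), ang=np.arctan2(x, y),
            vmag=np.gradient(np.hypot(x, y)), vang=np.gradient(np.arctan2(x, y)),
            fs_original=100.0,
        )

    def test_single_cycle_has_zero_spread(self):
        params = cm.phase_space_parameters([self._traj(1.0)])
        assert np.all(params.summary[["max_sd", "min_sd", "range_variability"]] == 0)

    def test_range_variability_hand_computed(self):
        params = cm.phase_space_parameters([self._traj(1.0), self._traj(1.2)])
        # vy ranges are 1.0 and 1.2 -> sample sd = 0.2 / sqrt(2)
        assert params.summary.loc["vy", "range_variability"] == pytest.approx(
            np.std([1.0, 1.2], ddof=1), abs=1e-9
        )
        assert params.summary.loc["vy", "range_variability"] == pytest.approx(0.1414, abs=1e-3)

    def test_identical_cycles_zero_variability(self):
        params = cm.phase_space_parameters([self._traj(1.0)] * 3)
        assert np.all(params.summary["range_variability"] == 0)
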