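"""Kinematic chain: filtering, segmentation, side assignment, minima
differences, total asymmetry and the change-from-baseline score."""

import numpy as np
import pytest

from equiasym import kinematics as kin
from equiasym.synth import GaitParams, simulate_gait


@pytest.fixture()
def noiseless_left():
    params = GaitParams(pelvis_asym_mm=-30.0, head_asym_mm=-12.0, noise_sd_mm=0.0)
    return simulate_gait(params)


class TestLowpassFilter:
    def test_preserves_inband_sinusoid(self):
        fs, f = 200.0, 1.3
        t = np.arange(0, 20, 1 / fs)
        x = np.sin(2 * np.pi * 2 * f * t)  # the 2/stride displacement component
        y = kin.lowpass_filter(x, fs, f)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        assert np.max(np.abs(y[mid])) == pytest.approx(1.0, rel=0.01)

    def test_contracts_white_noise_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=4000)
        y = kin.lowpass_filter(x, 200.0, 1.3)
        assert y.var() < x.var()

    def test_constant_signal_unchanged(self):
        x = np.full(1000, 3.7)
        assert kin.lowpass_filter(x, 200.0, 1.3) == pytest.approx(x)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(kin.ParameterError):
            kin.lowpass_filter(np.zeros(1000), 200.0, stride_frequency=20.0)


class TestStrideFrequency:
    def test_recovers_simulated_frequency(self):
        traj = simulate_gait(GaitParams(stride_frequency=1.3, noise_sd_mm=2.0, seed=3))
        f = kin.estimate_stride_frequency(traj.sacrale_z, traj.sampling_rate)
        assert f == pytest.approx(1.3, abs=0.05)

    def test_pure_two_per_stride_sinusoid(self):
        t = np.arange(0, 15, 1 / 200.0)
        x = np.sin(2 * np.pi * 2.6 * t)
        f = kin.estimate_stride_frequency(x, 200.0)
        assert f == pytest.approx(1.3, abs=0.02)

    def test_flat_signal_rejected(self):
        with pytest.raises(kin.DegenerateInputError):
            kin.estimate_stride_frequency(np.zeros(4000), 200.0)


class TestSegmentation:
    def test_detects_most_strides(self):
        traj = simulate_gait(GaitParams(n_strides=20, noise_sd_mm=0.0))
        filt = kin.lowpass_filter(traj.sacrale_z, traj.sampling_rate, 1.3)
        seg = kin.segment_strides(filt, traj.sampling_rate, 1.3)
        assert 18 <= seg.n_strides <= 20

    def test_signal_shorter_than_one_stride_rejected(self):
        t = np.arange(0, 0.5, 1 / 200.0)
        x = np.cos(2 * np.pi * 2.6 * t)
        with pytest.raises(kin.DegenerateInputError):
            kin.segment_strides(x, 200.0, 1.3)

    def test_stride_count_invariant_to_sampling_rate(self):
        counts = {}
        for fs in (200.0, 400.0):
            traj = simulate_gait(
                GaitParams(n_strides=20, noise_sd_mm=0.0, sampling_rate=fs)
            )
            filt = kin.lowpass_filter(traj.sacrale_z, fs, 1.3)
            counts[fs] = kin.segment_strides(filt, fs, 1.3).n_strides
        assert counts[200.0] == counts[400.0]


class TestSideAssignment:
    def _segmented(self, traj):
        filt = kin.lowpass_filter(traj.sacrale_z, traj.sampling_rate, 1.3)
        return filt, kin.segment_strides(filt, traj.sampling_rate, 1.3)

    def test_labels_follow_roll_convention(self, noiseless_left):
        _, seg = self._segmented(noiseless_left)
        seg = kin.assign_sides(seg, noiseless_left.roll)
        # labels alternate
        assert all(
            a != b for a, b in zip(seg.half_sides, seg.half_sides[1:])
        )
        # positive mean roll marks the right-stance half
        peaks = seg.peaks
        for k, side in enumerate(seg.half_sides):
            mean_roll = noiseless_left.roll[peaks[k] : peaks[k + 1] + 1].mean()
            assert (mean_roll > 0) == (side == "right")

    def test_inverted_roll_flips_all_labels(self, noiseless_left):
        _, seg1 = self._segmented(noiseless_left)
        _, seg2 = self._segmented(noiseless_left)
        kin.assign_sides(seg1, noiseless_left.roll)
        kin.assign_sides(seg2, -noiseless_left.roll)
        assert all(a != b for a, b in zip(seg1.half_sides, seg2.half_sides))

    def test_zero_roll_warns_and_falls_back(self, noiseless_left):
        _, seg = self._segmented(noiseless_left)
        with pytest.warns(UserWarning, match="ambiguity"):
            kin.assign_sides(seg, np.zeros_like(noiseless_left.roll))
        assert seg.side_warning is not None
        assert all(a != b for a, b in zip(seg.half_sides, seg.half_sides[1:]))


class TestMinDiff:
    @pytest.mark.parametrize("inject", [-60.0, -20.0, -5.0, 5.0, 20.0, 60.0])
    @pytest.mark.parametrize("f", [1.1, 1.3, 1.5])
    def test_noise_free_recovery_grid(self, inject, f):
        params = GaitParams(
            stride_frequency=f, pelvis_asym_mm=inject, head_asym_mm=inject,
            noise_sd_mm=0.0,
        )
        m = kin.measure_asymmetry(simulate_gait(params))
        assert m.pd_min_mm == pytest.approx(inject, abs=0.1)
        assert m.hd_min_mm == pytest.approx(inject, abs=0.1)

    def test_left_sided_asymmetry_is_negative(self, noiseless_left):
        m = kin.measure_asymmetry(noiseless_left)
        assert m.pd_min_mm == pytest.approx(-30.0, abs=0.1)
        assert m.hd_min_mm == pytest.approx(-12.0, abs=0.1)

    def test_requires_side_labels(self, noiseless_left):
        filt = kin.lowpass_filter(noiseless_left.sacrale_z, 200.0, 1.3)
        seg = kin.segment_strides(filt, 200.0, 1.3)
        with pytest.raises(kin.ParameterError):
            kin.compute_min_diff(filt, seg)

    def test_per_stride_scatter_tracks_noise(self):
        """Per-stride values under additive noise scatter far less than the
        raw noise sd (the filter removes most broadband power)."""
        params = GaitParams(pelvis_asym_mm=20.0, noise_sd_mm=2.0, seed=5)
        m = kin.measure_asymmetry(simulate_gait(params))
        assert 0.0 < np.std(m.stride_pd_mm) < 2.0


class TestTotalAsymmetry:
    @pytest.mark.parametrize(
        "hd,pd,expected", [(0, 0, 0.0), (-10, 20, 25.0), (8, -46, 50.0)]
    )
    def test_formula(self, hd, pd, expected):
        assert kin.total_asymmetry(hd, pd) == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(kin.ParameterError):
            kin.total_asymmetry(np.nan, 0.0)


class TestAsymmetryScore:
    def _measurement(self, total):
        return kin.AsymmetryMeasurement(
            hd_min_mm=0.0, pd_min_mm=total, total_asymmetry_mm=total, n_strides_used=20
        )

    def test_change_from_baseline(self):
        scores = kin.asymmetry_score(
            {"b0": self._measurement(5.0), "p1": self._measurement(66.0)},
            baseline_occasion="b0", horse="h1",
        )
        by_occ = {s.occasion: s.score_mm for s in scores}
        assert by_occ["b0"] == pytest.approx(0.0)
        assert by_occ["p1"] == pytest.approx(61.0)

    def test_negative_scores_allowed(self):
        scores = kin.asymmetry_score(
            {"b0": self._measurement(10.0), "p1": self._measurement(4.0)},
            baseline_occasion="b0",
        )
        assert {s.occasion: s.score_mm for s in scores}["p1"] == pytest.approx(-6.0)

    def test_missing_baseline_rejected(self):
        with pytest.raises(kin.ParameterError):
            kin.asymmetry_score({"p1": self._measurement(4.0)}, baseline_occasion="b0")


class TestEndToEndInvariants:
    def test_side_flip_negates_minima_diffs(self):
        p = GaitParams(pelvis_asym_mm=25.0, head_asym_mm=10.0, noise_sd_mm=0.0)
        m_right = kin.measure_asymmetry(simulate_gait(p))
        p_flip = GaitParams(pelvis_asym_mm=-25.0, head_asym_mm=-10.0, noise_sd_mm=0.0)
        m_left = kin.measure_asymmetry(simulate_gait(p_flip))
        assert m_left.pd_min_mm == pytest.approx(-m_right.pd_min_mm, abs=1e-3)
        assert m_left.hd_min_mm == pytest.approx(-m_right.hd_min_mm, abs=1e-3)
        assert m_left.total_asymmetry_mm == pytest.approx(
            m_right.total_asymmetry_mm, abs=1e-3
        )

    def test_time_reversal_leaves_total_asymmetry(self):
        traj = simulate_gait(GaitParams(pelvis_asym_mm=30.0, noise_sd_mm=0.0))
        m_fwd = kin.measure_asymmetry(traj)
        rev = kin.MarkerTrajectorySet(
            time=traj.time,
            poll_z=traj.poll_z[::-1].copy(),
            sacrale_z=traj.sacrale_z[::-1].copy(),
            roll=traj.roll[::-1].copy(),
            yaw=traj.yaw[::-1].copy(),
            sampling_rate=traj.sampling_rate,
        )
        m_rev = kin.measure_asymmetry(rev)
        assert m_rev.total_asymmetry_mm == pytest.approx(
            m_fwd.total_asymmetry_mm, abs=0.1
        )

    def test_filtering_idempotent_in_effect(self):
        traj = simulate_gait(GaitParams(pelvis_asym_mm=30.0, noise_sd_mm=2.0, seed=9))
        f = kin.estimate_stride_frequency(traj.sacrale_z, traj.sampling_rate)
        once = kin.lowpass_filter(traj.sacrale_z, traj.sampling_rate, f)
        twice = kin.lowpass_filter(once, traj.sampling_rate, f)

        def recovered(signal):
            seg = kin.segment_strides(signal, traj.sampling_rate, f)
            seg = kin.assign_sides(seg, traj.roll)
            return kin.compute_min_diff(signal, seg)[1]

        a, b = recovered(once), recovered(twice)
        assert abs(b - a) / abs(a) < 0.005

    def test_csv_round_trip(self, tmp_path):
        traj = simulate_gait(GaitParams(pelvis_asym_mm=12.0, noise_sd_mm=1.0, seed=2))
        path = tmp_path / "t.csv"
        traj.to_frame().to_csv(path, index=False)
        import pandas as pd

        back = kin.MarkerTrajectorySet.from_frame(pd.read_csv(path))
        assert back.sampling_rate == pytest.approx(traj.sampling_rate, rel=1e-6)
        m1 = kin.measure_asymmetry(traj)
        m2 = kin.measure_asymmetry(back)
        assert m2.pd_min_mm == pytest.approx(m1.pd_min_mm, abs=1e-6)
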