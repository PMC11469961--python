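import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyburst import (
    IntensityCalibration,
    SpotRecord,
    ThreeStateParams,
    UnitaryIntensity,
    calibrate_unitary,
    call_on_periods,
    correct_photobleaching,
    estimate_reinit,
    follow_site,
)
from polyburst.errors import AmbiguousStartError, StateError, ValidationError
from polyburst.synthetic import gen_trajectory

from conftest import make_trajectory


def _spot(frame, x, y=0.0, z=0.0, intensity=100.0, cell="c1"):
    return SpotRecord(
        cell_id=cell, frame=frame, time_min=frame * 4.0,
        x_um=x, y_um=y, z_um=z, intensity_au=intensity, volume_voxels=10,
    )


class TestFollowSite:
    def test_single_spot_per_frame_copied_through(self):
        spots = [_spot(f, x=1.0, intensity=10.0 * (f + 1)) for f in range(3)]
        traj = follow_site(spots, n_frames=4)
        assert np.allclose(traj.intensity_au, [10, 20, 30, 0])

    def test_nearest_spot_followed(self):
        spots = [
            _spot(0, x=1.0, intensity=50.0),
            _spot(1, x=1.1, intensity=60.0),        # true site, 0.1 um away
            _spot(1, x=4.0, intensity=999.0),       # distractor 3 um away
        ]
        traj = follow_site(spots, n_frames=2)
        assert traj.intensity_au[1] == 60.0

    def test_reference_retained_over_empty_frames(self):
        spots = [
            _spot(0, x=1.0, intensity=50.0),
            # frames 1-3 empty; distractor nearer to a drifted-away point
            _spot(4, x=1.2, intensity=70.0),
            _spot(4, x=9.0, intensity=10.0),
        ]
        traj = follow_site(spots, n_frames=5)
        assert np.allclose(traj.intensity_au[1:4], 0.0)
        assert traj.intensity_au[4] == 70.0

    def test_ambiguous_first_frame_needs_choice(self):
        spots = [_spot(0, x=1.0), _spot(0, x=5.0)]
        with pytest.raises(AmbiguousStartError):
            follow_site(spots, n_frames=1)
        traj = follow_site(spots, n_frames=1, initial_choice=1)
        assert traj.intensity_au[0] == 100.0

    def test_synthetic_distant_distractors_recovered_exactly(self, exact_unitary):
        params = ThreeStateParams(p_op=1.0, lambda_on=4.0)
        traj, _ = gen_trajectory(params, exact_unitary, noise_sd=0.0, seed=7)
        rng = np.random.default_rng(0)
        first_active = int(np.argmax(traj.intensity_au > 0))
        spots = []
        for frame, val in enumerate(traj.intensity_au):
            if frame < first_active:
                continue
            if val > 0:
                spots.append(_spot(frame, x=1.0 + 0.01 * frame, intensity=float(val)))
            # distractor always > 5 um away from the site
            spots.append(_spot(frame, x=8.0 + rng.random(), y=5.0,
                               intensity=float(rng.uniform(100, 400))))
        followed = follow_site(spots, n_frames=traj.n_frames, initial_choice=0)
        nonzero = traj.intensity_au > 0
        assert np.allclose(followed.intensity_au[nonzero], traj.intensity_au[nonzero])


class TestPhotobleaching:
    def test_frame_zero_unchanged_and_frame20_e(self):
        traj = make_trajectory(np.ones(21), corrected=False)
        out = correct_photobleaching(traj, rate=0.05)
        assert out.intensity_au[0] == 1.0
        assert out.intensity_au[20] == pytest.approx(np.e)

    def test_double_correction_is_error(self):
        traj = make_trajectory([1.0, 2.0], corrected=True)
        with pytest.raises(StateError):
            correct_photobleaching(traj)

    def test_correction_inverts_applied_bleach(self, exact_unitary):
        params = ThreeStateParams(p_op=1.0, lambda_on=4.0)
        clean, _ = gen_trajectory(params, exact_unitary, noise_sd=0.0, seed=11)
        bleached, _ = gen_trajectory(
            params, exact_unitary, noise_sd=0.0, seed=11, apply_bleach=True
        )
        restored = correct_photobleaching(bleached, rate=0.05)
        assert np.allclose(restored.intensity_au, clean.intensity_au)


class TestCalibration:
    def test_lens_and_excitation_factors(self):
        cal = IntensityCalibration()
        assert cal.lens_factor == pytest.approx(1.747, abs=5e-4)
        unit = calibrate_unitary([1000.0, 1000.0], cal)
        assert unit.mean_au == pytest.approx(1000 * 1.747 / 3, abs=0.3)

    def test_identity_calibration(self):
        cal = IntensityCalibration(lens_ratio=1.0, excitation_ratio=1.0)
        unit = calibrate_unitary([300.0, 360.0], cal)
        assert unit.mean_au == pytest.approx(330.0)
        assert unit.sd_au == pytest.approx(np.std([300, 360], ddof=1))

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            calibrate_unitary([100.0])


class TestOnPeriodCaller:
    def test_all_zero_trajectory_empty(self, exact_unitary):
        traj = make_trajectory(np.zeros(10))
        assert call_on_periods(traj, exact_unitary) == []

    def test_hand_constructed_single_period(self, exact_unitary):
        # transcripts 0,0,1,2,3,3,2,1,0 at 4-min frames
        traj = make_trajectory(np.array([0, 0, 1, 2, 3, 3, 2, 1, 0]) * 330.0)
        periods = call_on_periods(traj, exact_unitary)
        assert len(periods) == 1
        p = periods[0]
        assert p.min_frame == 1
        assert p.max_frame == 4
        assert p.amplitude_transcripts == pytest.approx(3.0)
        assert p.duration_min == pytest.approx(12.0)

    def test_low_amplitude_has_no_reinit_rate(self, exact_unitary):
        traj = make_trajectory(np.array([0, 1, 2, 2, 1, 0]) * 330.0)
        (p,) = call_on_periods(traj, exact_unitary)
        assert p.amplitude_transcripts == pytest.approx(2.0)
        assert p.reinit_rate is None

    def test_uncorrected_trajectory_rejected(self, exact_unitary):
        traj = make_trajectory([0, 330, 0], corrected=False)
        with pytest.raises(StateError):
            call_on_periods(traj, exact_unitary)

    def test_two_periods_with_baseline_between(self, exact_unitary):
        vals = np.array([0, 1, 3, 3, 0, 0, 0, 2, 4, 4, 0]) * 330.0
        periods = call_on_periods(make_trajectory(vals), exact_unitary)
        assert len(periods) == 2
        assert [p.min_frame for p in periods] == [0, 6]
        assert [p.max_frame for p in periods] == [2, 8]
        amps = [p.amplitude_transcripts for p in periods]
        assert amps == pytest.approx([3.0, 4.0])

    def test_calling_invariant_to_trailing_zeros(self, exact_unitary):
        vals = np.array([0, 1, 3, 3, 1, 0]) * 330.0
        base = call_on_periods(make_trajectory(vals), exact_unitary)
        padded = call_on_periods(
            make_trajectory(np.concatenate([vals, np.zeros(15)])), exact_unitary
        )
        assert [(p.min_frame, p.max_frame, p.amplitude_transcripts) for p in base] == [
            (p.min_frame, p.max_frame, p.amplitude_transcripts) for p in padded
        ]

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=25, deadline=None)
    def test_amplitude_invariant_to_common_rescaling(self, scale):
        vals = np.array([0, 1, 2, 4, 4, 2, 0]) * 330.0
        unit = UnitaryIntensity(330.0, 0.0)
        unit_s = UnitaryIntensity(330.0 * scale, 0.0)
        base = call_on_periods(make_trajectory(vals), unit)
        scaled = call_on_periods(make_trajectory(vals * scale), unit_s)
        assert len(base) == len(scaled) == 1
        assert scaled[0].amplitude_transcripts == pytest.approx(
            base[0].amplitude_transcripts
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_synthetic_truth_on_noise_free_data(self, seed, exact_unitary):
        params = ThreeStateParams(p_op=1.0, lambda_on=5.0)
        traj, truth = gen_trajectory(params, exact_unitary, noise_sd=0.0, seed=seed)
        periods = call_on_periods(traj, exact_unitary)
        assert len(periods) == len(truth.on_periods)
        for p, (start, end, amp) in zip(periods, truth.on_periods):
            assert p.min_frame * 4.0 == pytest.approx(start)
            assert p.max_frame * 4.0 == pytest.approx(end)
            assert p.amplitude_transcripts == pytest.approx(amp, abs=1e-9)
            assert p.duration_min == pytest.approx(end - start)

    def test_calling_is_idempotent(self, exact_unitary):
        params = ThreeStateParams(p_op=1.0, lambda_on=6.0)
        traj, _ = gen_trajectory(params, exact_unitary, noise_sd=0.0, seed=21)
        first = call_on_periods(traj, exact_unitary)
        second = call_on_periods(traj, exact_unitary)
        assert first == second


class TestReinit:
    def test_perfect_linear_rise(self, exact_unitary):
        est = estimate_reinit(np.array([0, 1, 2, 3]) * 330.0, exact_unitary, 4.0)
        assert est.rate_per_min == pytest.approx(0.25)
        assert est.interval_min == pytest.approx(4.0)

    def test_constant_segment_zero_slope(self, exact_unitary):
        est = estimate_reinit(np.array([2, 2, 2, 2]) * 330.0, exact_unitary, 4.0)
        assert est.rate_per_min == pytest.approx(0.0, abs=1e-12)
        assert est.interval_min is None

    def test_short_segment_undefined(self, exact_unitary):
        assert estimate_reinit(np.array([0, 330.0]), exact_unitary, 4.0) is None
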