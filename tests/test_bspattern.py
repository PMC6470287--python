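"""Binary pattern construction, suppression detection, HRF and regressor."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsfc import synth
from bsfc.bspattern import (
    BSPattern,
    DetectionError,
    DetectionParams,
    EEGRecording,
    HRFParams,
    build_bs_regressor,
    canonical_hrf,
    compute_bsr,
    detect_suppressions,
    make_binary_pattern,
    temporal_jaccard,
)


class TestBinaryPattern:
    def test_no_intervals_is_all_burst(self):
        p = make_binary_pattern([], 200.0, 10.0)
        assert p.values.all()
        assert compute_bsr(p) == 0.0

    def test_full_interval_is_all_suppression(self):
        p = make_binary_pattern([(0.0, 200.0)], 200.0, 10.0)
        assert not p.values.any()
        assert compute_bsr(p) == 100.0

    def test_bsr_is_sample_fraction(self):
        # 50 s suppressed out of 200 s at 10 Hz: 500 of 2000 samples
        p = make_binary_pattern([(10.0, 40.0), (100.0, 120.0)], 200.0, 10.0)
        assert compute_bsr(p) == 25.0

    def test_interval_round_trip(self):
        ivs = [(1.0, 3.5), (10.0, 12.25), (100.0, 180.5)]
        p = make_binary_pattern(ivs, 200.0, 20.0)
        assert p.intervals == ivs

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_binary_pattern([(0.0, 5.0), (4.0, 8.0)], 10.0, 10.0)

    def test_bsr_complement_identity(self):
        p = make_binary_pattern([(2.0, 9.0)], 50.0, 25.0)
        burst_fraction = float(np.mean(p.values == 1))
        assert compute_bsr(p) + 100.0 * burst_fraction == pytest.approx(100.0)

    @given(
        st.lists(
            st.tuples(
                st.floats(0.0, 90.0, allow_nan=False),
                st.floats(0.5, 8.0, allow_nan=False),
            ),
            max_size=6,
        )
    )
    @settings(deadline=None, max_examples=40)
    def test_intervals_values_round_trip(self, raw):
        # build disjoint intervals from (onset, length) pairs
        ivs, cursor = [], 0.0
        for onset, length in sorted(raw):
            start = max(onset, cursor)
            end = min(start + length, 100.0)
            if end - start >= 0.1:
                ivs.append((start, end))
                cursor = end + 0.1
        p = make_binary_pattern(ivs, 100.0, 10.0)
        p2 = make_binary_pattern(p.intervals, 100.0, 10.0)
        assert np.array_equal(p.values, p2.values)
        assert 0.0 <= compute_bsr(p) <= 100.0


class TestDetection:
    def test_all_burst_gives_no_intervals(self):
        pattern = make_binary_pattern([], 60.0, 500.0)
        eeg = synth.simulate_eeg(pattern, synth.EEGSimParams(n_channels=4), seed=0)
        assert detect_suppressions(eeg) == []

    def test_flat_recording_raises(self):
        eeg = EEGRecording(data=np.zeros((2, 5000)), sample_rate=500.0)
        with pytest.raises(DetectionError, match="amplitude contrast"):
            detect_suppressions(eeg)

    def test_single_inserted_suppression_boundaries(self):
        pattern = make_binary_pattern([(10.0, 12.0)], 60.0, 500.0)
        eeg = synth.simulate_eeg(pattern, synth.EEGSimParams(n_channels=8), seed=7)
        ivs = detect_suppressions(eeg)
        assert len(ivs) == 1
        onset, offset = ivs[0]
        assert abs(onset - 10.0) <= 0.05
        assert abs(offset - 12.0) <= 0.05

    def test_full_run_jaccard_against_ground_truth(self, bs_pattern):
        pattern, true_ivs = bs_pattern
        eeg = synth.simulate_eeg(pattern, synth.EEGSimParams(n_channels=8), seed=5)
        det = detect_suppressions(eeg)
        assert temporal_jaccard(det, true_ivs) >= 0.95

    def test_invariant_to_global_rescaling(self, bs_pattern):
        pattern, _ = bs_pattern
        eeg = synth.simulate_eeg(pattern, synth.EEGSimParams(n_channels=4), seed=9)
        ivs = detect_suppressions(eeg)
        scaled = EEGRecording(data=eeg.data * 37.5, sample_rate=eeg.sample_rate)
        assert detect_suppressions(scaled) == ivs

    def test_equal_amplitudes_yield_no_regime(self):
        pattern = make_binary_pattern([(5.0, 8.0), (20.0, 24.0)], 60.0, 500.0)
        eeg = synth.simulate_eeg(
            pattern,
            synth.EEGSimParams(
                n_channels=4, burst_amplitude=10.0, suppression_amplitude=9.99
            ),
            seed=3,
        )
        assert len(detect_suppressions(eeg)) <= 1


class TestHRF:
    def test_zero_at_origin(self):
        k = canonical_hrf(HRFParams(), dt=0.1)
        assert k[0] == pytest.approx(0.0, abs=1e-12)

    def test_peak_location_near_peak_delay(self):
        # dense numeric evaluation of the closed form
        k = canonical_hrf(HRFParams(), dt=0.001)
        t_peak = np.argmax(k) * 0.001
        assert 4.5 <= t_peak <= 5.5
        assert k.max() == pytest.approx(1.0)

    def test_single_sign_change(self):
        k = canonical_hrf(HRFParams(), dt=0.05)
        signs = np.sign(k[np.abs(k) > 1e-9])
        changes = np.sum(np.diff(signs) != 0)
        assert changes == 1

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HRFParams(peak_delay=-1.0)
        with pytest.raises(ValueError):
            HRFParams(kernel_length=5.0)  # shorter than undershoot delay

    def test_matches_reference_spm_kernel(self):
        # independent oracle: nilearn's SPM canonical HRF (same double-gamma
        # parameterization, different discretization convention)
        from nilearn.glm.first_level.hemodynamic_models import spm_hrf

        ours = canonical_hrf(HRFParams(), dt=0.1)
        ref = spm_hrf(1.0, oversampling=10, time_length=32.1)
        n = min(ours.size, ref.size)
        assert np.corrcoef(ours[:n], ref[:n])[0, 1] > 0.999
        assert abs(np.argmax(ours) - np.argmax(ref)) * 0.1 <= 0.2


class TestRegressor:
    def test_all_ones_pattern_flat_after_transient(self):
        p = make_binary_pattern([], 420.0, 50.0)
        reg = build_bs_regressor(p, tr=2.0, n_volumes=200, n_drop=10)
        # after the kernel-length transient, the mean-centered series is ~0
        tail = reg.values[int(32 / 2):]
        assert np.allclose(tail, tail[0], atol=1e-9)

    def test_impulse_reproduces_sampled_hrf(self):
        fs = 50.0
        values = np.ones(int(420 * fs), dtype=np.int8)
        values[0] = 0  # single-sample suppression dip at t=0
        p = BSPattern(values=values, sample_rate=fs)
        reg = build_bs_regressor(p, tr=2.0, n_volumes=200, n_drop=0)
        kernel = canonical_hrf(HRFParams(), dt=1 / fs)
        # response = conv(1 - delta) = step_response - kernel; relative to the
        # all-ones steady state the difference is the (negated) sampled kernel
        steady = build_bs_regressor(
            make_binary_pattern([], 420.0, fs), tr=2.0, n_volumes=200, n_drop=0
        )
        diff = (steady.values - steady.values.mean()) - (reg.values - reg.values.mean())
        idx = np.round(np.arange(200) * 2.0 * fs).astype(int)
        expected = kernel[idx[idx < kernel.size]]
        got = diff[: expected.size] - diff[: expected.size].mean() + expected.mean()
        assert np.allclose(got, expected, atol=1e-9)

    def test_matches_naive_convolution(self, bs_pattern):
        pattern, _ = bs_pattern
        # downsample the pattern for an O(N*K) brute-force check
        small = BSPattern(values=pattern.values[::25], sample_rate=20.0)
        reg = build_bs_regressor(small, tr=2.0, n_volumes=200, n_drop=10)
        kernel = canonical_hrf(HRFParams(), dt=1 / 20.0)
        x = small.values.astype(float)
        naive = np.zeros(x.size)
        for k, h in enumerate(kernel):
            naive[k:] += h * x[: x.size - k]
        idx = np.round(np.arange(10, 200) * 2.0 * 20.0).astype(int)
        expected = naive[idx]
        expected -= expected.mean()
        assert np.allclose(reg.values, expected, atol=1e-10)

    def test_linear_in_pattern(self):
        # regressor(p1) + regressor(p2) == regressor(p1 + p2) for binary sums
        fs = 20.0
        a = make_binary_pattern([(5.0, 10.0)], 420.0, fs)
        b = make_binary_pattern([(50.0, 60.0)], 420.0, fs)
        both = make_binary_pattern([(5.0, 10.0), (50.0, 60.0)], 420.0, fs)
        ra = build_bs_regressor(a, 2.0, 200, 0).values
        rb = build_bs_regressor(b, 2.0, 200, 0).values
        rboth = build_bs_regressor(both, 2.0, 200, 0).values
        ones = build_bs_regressor(make_binary_pattern([], 420.0, fs), 2.0, 200, 0).values
        assert np.allclose(ra + rb - ones, rboth, atol=1e-9)

    def test_insufficient_coverage_raises(self):
        p = make_binary_pattern([], 100.0, 20.0)
        with pytest.raises(ValueError, match="cover"):
            build_bs_regressor(p, tr=2.0, n_volumes=200, n_drop=10)
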