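"""Tests for the intensity -> OD -> motion -> filter -> MBLL -> block chain."""

import numpy as np
import pytest

from nirsleep.preprocess import (
    ConversionParams,
    MotionParams,
    QCParams,
    SubjectExcluded,
    assess_dataset_quality,
    block_average,
    correct_motion,
    detect_motion_by_channel,
    intensity_to_od,
    lowpass_filter,
    mean_response,
    od_to_concentration,
    peak_spectral_power,
    percent_clean_data,
    preprocess_subject,
    reject_trials,
    scalp_coupling_index,
)
from nirsleep.synthetic import (
    Event,
    ProbeLayout,
    forward_od,
    simulate_recording,
    social_paradigm,
)

FS = 10.0


def _recording_from_signals(per_wavelength: np.ndarray) -> "object":
    """Wrap a [channel, wavelength, time] array as intensity around 1."""
    from nirsleep.synthetic import RawRecording

    layout = ProbeLayout(n_channels=per_wavelength.shape[0])
    return RawRecording(intensity=1.0 + per_wavelength, events=[], layout=layout)


class TestChannelQuality:
    def _tone(self, n_ch=18, n_t=1200, f=2.5, amp=0.01, seed=0):
        t = np.arange(n_t) / FS
        sig = amp * np.sin(2 * np.pi * f * t)
        return np.tile(sig, (n_ch, 2, 1))

    def test_shared_sinusoid_sci_one(self):
        rec = _recording_from_signals(self._tone())
        assert np.allclose(scalp_coupling_index(rec), 1.0, atol=1e-6)

    def test_sign_flipped_sinusoid_sci_minus_one(self):
        x = self._tone()
        x[:, 1, :] *= -1
        rec = _recording_from_signals(x)
        assert np.allclose(scalp_coupling_index(rec), -1.0, atol=1e-6)

    def test_independent_noise_sci_near_zero(self):
        rng = np.random.default_rng(0)
        x = 0.01 * rng.normal(size=(18, 2, 6000))
        rec = _recording_from_signals(x)
        assert np.all(np.abs(scalp_coupling_index(rec)) < 0.35)

    def test_shared_tone_psp_above_threshold(self):
        rec = _recording_from_signals(self._tone())
        assert np.all(peak_spectral_power(rec) > 0.1)

    def test_broadband_noise_psp_below_threshold(self):
        rng = np.random.default_rng(1)
        x = 0.01 * rng.normal(size=(18, 2, 6000))
        rec = _recording_from_signals(x)
        assert np.all(peak_spectral_power(rec) < 0.1)

    def test_zero_signal_psp_zero(self):
        rec = _recording_from_signals(np.zeros((18, 2, 600)))
        assert np.all(peak_spectral_power(rec) == 0.0)
        assert np.all(scalp_coupling_index(rec) == 0.0)

    @pytest.mark.parametrize("n_bad, ok", [(0, True), (7, True), (8, False)])
    def test_dataset_rejection_fraction(self, n_bad, ok):
        sci = np.full(18, 0.95)
        psp = np.full(18, 0.5)
        sci[:n_bad] = 0.1
        bad, dataset_ok = assess_dataset_quality(sci, psp)
        assert len(bad) == n_bad
        assert dataset_ok is ok


class TestOpticalDensity:
    def test_constant_intensity_zero_od(self):
        rec = _recording_from_signals(np.zeros((2, 2, 100)))
        assert np.allclose(intensity_to_od(rec), 0.0)

    def test_halved_intensity_is_ln2(self):
        from nirsleep.synthetic import RawRecording

        n_t = 100000
        intensity = np.ones((1, 2, n_t))
        intensity[0, 0, 500] = 0.5
        rec = RawRecording(
            intensity=intensity, events=[], layout=ProbeLayout(n_channels=1)
        )
        od = intensity_to_od(rec)
        assert od[0, 0, 500] == pytest.approx(np.log(2), abs=1e-4)

    def test_scale_invariance(self):
        from nirsleep.synthetic import RawRecording

        rng = np.random.default_rng(3)
        base = 1.0 + 0.1 * rng.uniform(size=(2, 2, 200))
        r1 = RawRecording(intensity=base, events=[], layout=ProbeLayout(n_channels=2))
        r2 = RawRecording(
            intensity=7.3 * base, events=[], layout=ProbeLayout(n_channels=2)
        )
        assert np.allclose(intensity_to_od(r1), intensity_to_od(r2))

    def test_nonpositive_intensity_rejected(self):
        from nirsleep.synthetic import RawRecording

        with pytest.raises(ValueError):
            RawRecording(
                intensity=np.zeros((1, 2, 10)),
                events=[],
                layout=ProbeLayout(n_channels=1),
            )


class TestMotionDetection:
    def test_flat_signal_empty_mask(self):
        od = np.zeros((18, 2, 500))
        assert not detect_motion_by_channel(od).any()

    def test_step_flagged_with_mask_dilation(self):
        od = np.zeros((1, 2, 600))
        od[:, :, 300:] = 10 * MotionParams().amp_thresh
        mask = detect_motion_by_channel(od)
        assert mask[0, 300]
        # dilation: flags extend ~1 s (t_mask) on each side of the step
        assert mask[0, 290] and mask[0, 310]
        assert not mask[0, 100] and not mask[0, 500]

    def test_smooth_hemodynamic_drift_not_flagged(self):
        t = np.arange(1200) / FS
        slow = 0.02 * np.sin(2 * np.pi * 0.02 * t)  # HRF-scale, tiny slope
        od = np.tile(slow, (18, 2, 1))
        assert not detect_motion_by_channel(od).any()


class TestTrialRejection:
    def _events(self):
        return [Event(30.0, 8.0, "V"), Event(60.0, 8.0, "N")]

    def test_no_motion_all_valid(self):
        mask = np.zeros((18, 900), dtype=bool)
        assert reject_trials(mask, self._events()) == [True, True]

    def test_majority_channel_artifact_invalidates(self):
        mask = np.zeros((18, 900), dtype=bool)
        mask[:10, 320:330] = True  # 10/18 > 50% during trial 1
        assert reject_trials(mask, self._events()) == [False, True]

    def test_half_channels_is_retained(self):
        mask = np.zeros((18, 900), dtype=bool)
        mask[:9, 320:330] = True  # exactly 50%, not strictly more
        assert reject_trials(mask, self._events()) == [True, True]


class TestMotionCorrection:
    def test_clean_smooth_signal_passes_through(self):
        t = np.arange(1000) / FS
        od = np.tile(0.05 * np.sin(2 * np.pi * 0.05 * t), (2, 2, 1))
        mask = np.zeros((2, 1000), dtype=bool)
        out = correct_motion(od, mask)
        assert out.shape == od.shape
        # interior agrees tightly; wavelet symmetric extension leaves a
        # small boundary effect
        assert np.max(np.abs(out - od)[..., 50:-50]) < 1e-3
        assert np.max(np.abs(out - od)) < 0.01

    def test_step_artifact_excursion_reduced(self):
        rng = np.random.default_rng(0)
        od = 0.001 * rng.normal(size=(1, 2, 1200))
        od[:, :, 600:] += 1.0  # large baseline step
        mask = detect_motion_by_channel(od)
        assert mask[0, 600]
        out = correct_motion(od, mask)
        before = np.max(np.abs(np.diff(od[0, 0])))
        after = np.max(np.abs(np.diff(out[0, 0])))
        assert after <= 0.2 * before

    def test_duration_and_sampling_preserved(self):
        rng = np.random.default_rng(1)
        od = 0.01 * rng.normal(size=(3, 2, 777))
        mask = np.zeros((3, 777), dtype=bool)
        mask[0, 100:130] = True
        assert correct_motion(od, mask).shape == od.shape


class TestLowpass:
    def test_dc_preserved(self):
        od = np.full((1, 2, 800), 3.7)
        assert np.allclose(lowpass_filter(od), 3.7)

    def test_3hz_attenuated(self):
        t = np.arange(2000) / FS
        od = np.tile(np.sin(2 * np.pi * 3.0 * t), (1, 2, 1))
        out = lowpass_filter(od)
        # >= 90% amplitude attenuation away from the filtfilt edge transient
        assert np.abs(out[..., 200:-200]).max() < 0.1

    def test_slow_oscillation_preserved(self):
        t = np.arange(4000) / FS
        od = np.tile(np.sin(2 * np.pi * 0.05 * t), (1, 2, 1))
        out = lowpass_filter(od)
        mid = out[0, 0, 1000:3000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)


class TestBeerLambert:
    def test_zero_od_zero_concentration(self):
        assert np.allclose(od_to_concentration(np.zeros((4, 2, 50))), 0.0)

    def test_forward_inverse_identity(self):
        rng = np.random.default_rng(5)
        layout = ProbeLayout()
        hbo = rng.normal(0, 0.5, size=(18, 300))
        hbr = rng.normal(0, 0.2, size=(18, 300))
        od = forward_od(hbo, hbr, layout)
        conc = od_to_concentration(od)
        assert np.max(np.abs(conc[:, 0, :] - hbo)) < 1e-9
        assert np.max(np.abs(conc[:, 1, :] - hbr)) < 1e-9

    def test_doubling_dpf_halves_concentration(self):
        rng = np.random.default_rng(6)
        od = 0.01 * rng.normal(size=(2, 2, 100))
        c1 = od_to_concentration(od, ConversionParams(dpf=(5.22, 4.23)))
        c2 = od_to_concentration(od, ConversionParams(dpf=(10.44, 8.46)))
        assert np.allclose(c1, 2 * c2)


class TestBlockAverage:
    def _conc(self, n_t=3000, value=0.0):
        return np.full((18, 2, n_t), value)

    def _events(self, n=4):
        return [Event(40.0 + 60.0 * i, 8.0, "V") for i in range(n)]

    def test_constant_concentration_averages_to_zero(self, social):
        ba = block_average(
            self._conc(value=5.0), self._events(), [True] * 4, social, required=("V",)
        )
        assert np.allclose(ba.trace["V"], 0.0, atol=1e-12)

    def test_antisymmetric_trials_cancel(self, social):
        conc = self._conc()
        events = self._events(4)
        kernel = np.sin(np.linspace(0, np.pi, 80))
        for i, ev in enumerate(events):
            i0 = int(ev.onset_s * FS)
            conc[:, :, i0 : i0 + 80] += ((-1) ** i) * kernel
        ba = block_average(conc, events, [True] * 4, social,
                           detrend="none", required=("V",))
        assert np.allclose(ba.trace["V"], 0.0, atol=1e-9)

    def test_too_few_valid_trials_excludes_subject(self, social):
        with pytest.raises(SubjectExcluded):
            block_average(
                self._conc(),
                self._events(),
                [True, True, False, False],
                social,
                required=("V",),
            )

    def test_time_axis_matches_paradigm_range(self, social):
        ba = block_average(
            self._conc(), self._events(), [True] * 4, social, required=("V",)
        )
        assert ba.time_axis[0] == pytest.approx(-4.0)
        assert ba.time_axis[-1] == pytest.approx(20.0 - 1 / FS)

    def test_mean_response_of_constant_trace(self, social):
        ba = block_average(
            self._conc(), self._events(), [True] * 4, social, required=("V",)
        )
        ba.trace["V"][:] = 2.5
        resp = mean_response(ba, (8.0, 16.0))
        assert np.allclose(resp["V"], 2.5)

    def test_mean_response_window_straddling_peak(self, social, constant_qs_timeline,
                                                  sparse_schedule, noiseless_params):
        rec = simulate_recording(
            sparse_schedule, constant_qs_timeline, noiseless_params, paradigm=social
        )
        out = preprocess_subject(rec, social, required=("V",))
        val = out["responses"]["V"][:, 0]  # HbO
        assert np.all(val > 0.0)
        assert np.all(val < 0.8)  # mean over window < planted peak


class TestFullChain:
    def test_noiseless_round_trip_within_2pct(
        self, social, constant_qs_timeline, sparse_schedule, noiseless_params
    ):
        rec = simulate_recording(
            sparse_schedule, constant_qs_timeline, noiseless_params, paradigm=social
        )
        out = preprocess_subject(rec, social, required=("V",))
        ba = out["block_average"]
        hbo_peak = ba.trace["V"][:, 0, :].max(axis=-1)
        hbr_peak = ba.trace["V"][:, 1, :].min(axis=-1)
        assert np.all(np.abs(hbo_peak / 0.8 - 1.0) < 0.02)
        assert np.all(np.abs(hbr_peak / (-0.35 * 0.8) - 1.0) < 0.02)

    def test_percent_clean_bounds_and_monotonicity(self):
        rng = np.random.default_rng(2)
        base = np.zeros((18, 1000), dtype=bool)
        vals = []
        for n_art in (0, 3, 10):
            mask = base.copy()
            for k in range(n_art):
                t0 = 50 + 90 * k
                mask[:, t0 : t0 + 20] = True
            pct = percent_clean_data(mask)
            assert 0.0 <= pct <= 100.0
            vals.append(pct)
        assert vals[0] > vals[1] > vals[2]

    def test_channel_and_sample_counts_preserved(
        self, social, constant_qs_timeline, sparse_schedule, noiseless_params
    ):
        rec = simulate_recording(
            sparse_schedule, constant_qs_timeline, noiseless_params, paradigm=social
        )
        od = intensity_to_od(rec)
        mask = detect_motion_by_channel(od)
        corr = correct_motion(od, mask)
        filt = lowpass_filter(corr)
        conc = od_to_concentration(filt)
        assert od.shape == rec.intensity.shape
        assert corr.shape == od.shape and filt.shape == od.shape
        assert conc.shape == (18, 2, od.shape[2])
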