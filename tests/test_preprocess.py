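import numpy as np
import pytest

from gpdcpipe import preprocess as pp
from gpdcpipe import synth

FS = 220.0


def _sine(freq, duration_s=90.0, amp=10.0):
    t = np.arange(int(duration_s * FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t)[None, :].repeat(4, axis=0)


class TestNotch:
    def test_60hz_attenuated(self):
        out = pp.notch_filter(_sine(60.0))
        assert np.sqrt((out**2).mean()) < 0.35  # >30 dB on a 10 μV line tone

    def test_10hz_preserved(self):
        x = _sine(10.0)
        out = pp.notch_filter(x)
        assert np.sqrt((out**2).mean()) == pytest.approx(
            np.sqrt((x**2).mean()), rel=0.01)

    def test_zeros_in_zeros_out(self):
        assert np.allclose(pp.notch_filter(np.zeros((4, 2200))), 0.0)


class TestBandpass:
    def test_dc_rejected(self):
        out = pp.bandpass_filter(np.full((4, 13200), 50.0))
        assert np.abs(out.mean()) < 0.5

    def test_10hz_amplitude_and_zero_lag(self):
        x = _sine(10.0)
        out = pp.bandpass_filter(x)
        mid = slice(2000, -2000)
        assert np.abs(out[0, mid]).max() == pytest.approx(10.0, rel=0.02)
        xc = np.correlate(out[0, mid], x[0, mid], mode="full")
        lag = int(np.argmax(xc)) - (len(x[0, mid]) - 1)
        assert lag == 0

    def test_slow_drift_attenuated(self):
        x = _sine(0.1, duration_s=120.0)
        out = pp.bandpass_filter(x)
        assert np.sqrt((out**2).mean()) < 0.1 * np.sqrt((x**2).mean())

    def test_upper_edge_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            pp.bandpass_filter(np.zeros((4, 2200)), hi=120.0)


@pytest.fixture(scope="module")
def filtered_clean(clean_session):
    x = pp.notch_filter(clean_session.eeg)
    return pp.bandpass_filter(x)


class TestAsr:
    def test_noop_on_clean_var_data(self, filtered_clean):
        cleaned, mask = pp.asr_clean(filtered_clean)
        rms_in = np.sqrt((filtered_clean**2).mean())
        rms_delta = np.sqrt(((cleaned - filtered_clean) ** 2).mean())
        assert rms_delta < 0.05 * rms_in
        assert mask.sum() == 0

    def test_single_channel_burst_reduced_or_masked(self, filtered_clean):
        x = filtered_clean.copy()
        i0, i1 = int(40 * FS), int(41 * FS)
        rng = np.random.default_rng(2)
        x[2, i0:i1] += 500.0 * rng.normal(size=i1 - i0)
        cleaned, mask = pp.asr_clean(x)
        sub = pp.PreprocConfig().subwindow_samples
        burst_subs = slice(i0 // sub, int(np.ceil(i1 / sub)))
        masked = mask[2, burst_subs].all()
        rms_before = np.sqrt((x[2, i0:i1] ** 2).mean())
        rms_after = np.sqrt((cleaned[2, i0:i1] ** 2).mean())
        assert masked or rms_after < 0.2 * rms_before

    def test_deterministic(self, filtered_clean):
        c1, m1 = pp.asr_clean(filtered_clean)
        c2, m2 = pp.asr_clean(filtered_clean)
        assert np.array_equal(c1, c2) and np.array_equal(m1, m2)

    def test_short_calibration_rejected(self):
        with pytest.raises(ValueError, match="60"):
            pp.asr_clean(np.random.default_rng(0).normal(size=(4, 2200)))


class TestRejectionMask:
    def _streams(self, duration_s=66.0, seed=0):
        rng = np.random.default_rng(seed)
        n_e = int(duration_s * 220)
        eeg = rng.normal(0, 5, (4, n_e))
        accel = rng.normal(0, 0.05, (3, int(duration_s * 50)))
        contact = np.ones((4, int(duration_s * 10)), dtype=int)
        return eeg, accel, contact

    def test_clean_session_all_good(self):
        eeg, accel, contact = self._streams()
        mask = pp.rejection_mask(eeg, accel, contact)
        assert not mask.combined.any()
        assert mask.usable

    def test_voltage_step_masks_exact_subwindow(self):
        eeg, accel, contact = self._streams()
        step_at = int(30 * 220)
        eeg[1, step_at:] += 150.0
        mask = pp.rejection_mask(eeg, accel, contact)
        sub = pp.PreprocConfig().subwindow_samples
        expected = step_at // sub
        assert mask.reasons["jump"][expected]
        others = np.delete(mask.reasons["jump"], expected)
        assert not others.any()
        assert not mask.reasons["accel"].any()

    def test_accel_spike_masks_overlapping_subwindows(self):
        eeg, accel, contact = self._streams()
        accel[0, int(20 * 50):int(21 * 50)] = 1.5
        mask = pp.rejection_mask(eeg, accel, contact)
        sub = pp.PreprocConfig().subwindow_samples
        spike_subs = slice(int(20 * 220) // sub, int(21 * 220) // sub)
        assert mask.reasons["accel"][spike_subs].all()
        assert not mask.reasons["jump"].any()

    def test_contact_dropout_masks_and_gates_usability(self):
        eeg, accel, contact = self._streams()
        contact[3, 300:320] = 3  # 30-32 s: splits 66 s into runs < 60 s
        mask = pp.rejection_mask(eeg, accel, contact)
        assert mask.reasons["contact"].any()
        assert not mask.usable

    def test_unusable_reported_not_dropped(self):
        eeg, accel, contact = self._streams(duration_s=66.0)
        contact[:] = 2  # 'acceptable' is still not 'good'
        mask = pp.rejection_mask(eeg, accel, contact)
        assert mask.combined.all()
        assert not mask.usable


class TestCutEpochs:
    def _mask(self, n_sub, bad_subs=()):
        reasons = {r: np.zeros(n_sub, dtype=bool) for r in pp.REASONS}
        for b in bad_subs:
            reasons["jump"][b] = True
        return pp.RejectionMask(reasons=reasons, usable=True,
                                n_subwindows=n_sub)

    def test_66s_clean_yields_21_epochs(self):
        n = int(66 * 220)
        eeg = np.zeros((4, n))
        eps = pp.cut_epochs(eeg, self._mask(n // 55))
        assert len(eps) == 21  # floor((66-6)/3)+1
        assert all(e.shape == (4, 1320) for e in eps.epochs)
        assert eps.kept_fraction == 1.0

    def test_masked_interval_excludes_overlapping_epochs(self):
        n = int(66 * 220)
        eeg = np.zeros((4, n))
        bad = range(int(30 * 4), int(36 * 4))  # 30-36 s in 250 ms units
        eps = pp.cut_epochs(eeg, self._mask(n // 55, bad))
        starts_s = np.array(eps.epoch_start_samples) / 220
        overlaps = (starts_s < 36.0) & (starts_s + 6.0 > 30.0)
        assert not overlaps.any()
        # epochs starting 27,30,33 s overlap [30,36); the 24 s epoch ends at 30
        assert len(eps) == 21 - 3
        assert set(starts_s) == set(range(0, 25, 3)) | set(range(36, 61, 3))

    def test_zero_clean_epochs_warns_not_raises(self):
        n = int(66 * 220)
        eeg = np.zeros((4, n))
        with pytest.warns(UserWarning, match="no clean epochs"):
            eps = pp.cut_epochs(eeg, self._mask(n // 55,
                                                range(0, n // 55, 10)))
        assert len(eps) == 0


class TestPipelineProperties:
    def test_planted_artifact_recall_and_false_mask_rate(self, coupled_model):
        recalls, false_rates = [], []
        for seed in range(5):
            plan = synth.ArtifactPlan(
                burst_times=[(20.0, 2.0), (50.0, 1.0)], burst_amp_uv=500.0,
                burst_accel_ms2=3.0,
                dropout_times=[(2, 70.0, 3.0)],
            )
            rec = synth.generate_session(coupled_model, 90.0, plan,
                                         "Preparation", seed=100 + seed)
            eps = pp.preprocess_session(rec)
            mask = eps.rejection_mask
            sub = pp.PreprocConfig().subwindow_samples
            bad_samples = np.repeat(mask.combined, sub)
            planted = synth.artifact_sample_mask(plan, 90.0)
            planted[int(70 * 220):int(73 * 220)] = True  # dropout interval
            planted = planted[:bad_samples.size]
            recalls.append(bad_samples[planted].mean())

            clean = synth.generate_session(coupled_model, 90.0,
                                           synth.ArtifactPlan(),
                                           "Preparation", seed=200 + seed)
            ceps = pp.preprocess_session(clean)
            false_rates.append(ceps.rejection_mask.combined.mean())
        assert np.mean(recalls) >= 0.95
        assert np.mean(false_rates) <= 0.05

    def test_kept_fraction_monotone_in_artifact_density(self, coupled_model):
        kept = []
        for n_bursts in (0, 2, 5):
            plan = synth.ArtifactPlan(
                burst_times=[(10.0 + 12.0 * k, 2.0) for k in range(n_bursts)],
                burst_amp_uv=500.0, burst_accel_ms2=3.0,
            )
            rec = synth.generate_session(coupled_model, 90.0, plan,
                                         "Preparation", seed=7)
            eps = pp.preprocess_session(rec)
            kept.append(eps.kept_fraction)
        assert kept[0] >= kept[1] >= kept[2]

    def test_epoch_invariant_1320_samples(self, clean_epochs):
        assert all(e.shape[1] == 1320 for e in clean_epochs.epochs)
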