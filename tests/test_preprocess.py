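"""Preprocessing: filtering, blind source separation, re-referencing,
epoching."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import linalg, signal

import p300apt as pa
from p300apt.montage import EOG_LABELS
from p300apt.preprocess import _design_fir, _filtfilt_fir

from conftest import FAST_TIMING


def _recording(data, fs=500.0, n_eog=0, events=()):
    n_ch = data.shape[0]
    labels = [f"ch{i}" for i in range(n_ch - n_eog)] + list(EOG_LABELS[:n_eog])
    roles = ["eeg"] * (n_ch - n_eog) + ["eog"] * n_eog
    return pa.ContinuousRecording(
        data=data, sampling_rate=fs, channel_labels=labels,
        channel_roles=roles, events=list(events),
    )


class TestFirBandpass:
    def test_dc_blocked(self):
        rec = _recording(np.full((2, 4000), 7.3))
        out = pa.fir_bandpass(rec)
        assert abs(out.data.mean()) < 1e-6

    def test_passband_and_stopband_gain(self):
        """Designed response: near-unit gain at 10 Hz, strong attenuation at
        40 Hz (evaluated on the composed forward-backward response)."""
        fs = 500.0
        hp = _design_fir(fs, 0.5, "highpass")
        lp = _design_fir(fs, 20.0, "lowpass")
        for f, lo, hi in ((10.0, 0.95, 1.05), (40.0, 0.0, 0.1)):
            w, h_hp = signal.freqz(hp, worN=[f], fs=fs)
            _, h_lp = signal.freqz(lp, worN=[f], fs=fs)
            gain = (np.abs(h_hp) * np.abs(h_lp)) ** 2  # two-way application
            assert lo <= gain[0] <= hi

    def test_sinusoid_gains_end_to_end(self):
        fs = 500.0
        t = np.arange(int(20 * fs)) / fs
        x = np.stack([np.sin(2 * np.pi * 10 * t), np.sin(2 * np.pi * 40 * t)])
        out = pa.fir_bandpass(_recording(x, fs)).data
        mid = slice(int(5 * fs), int(15 * fs))
        assert 0.95 < out[0, mid].std() / x[0, mid].std() < 1.05
        assert out[1, mid].std() / x[1, mid].std() < 0.1

    def test_zero_phase_pulse_latency(self):
        x = np.zeros((1, 5000))
        x[0, 2500 - 25 : 2500 + 25] = signal.windows.hann(50)
        out = pa.fir_bandpass(_recording(x)).data
        assert abs(int(np.argmax(out[0])) - 2500) <= 1

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 3000))
        y = rng.standard_normal((2, 3000))
        fa = pa.fir_bandpass(_recording(2.0 * x + 3.0 * y)).data
        fb = 2.0 * pa.fir_bandpass(_recording(x)).data + 3.0 * pa.fir_bandpass(_recording(y)).data
        assert np.allclose(fa, fb, atol=1e-8)

    def test_cutoff_above_nyquist_rejected(self):
        rec = _recording(np.zeros((1, 1000)), fs=100.0)
        with pytest.raises(ValueError):
            pa.fir_bandpass(rec, 0.5, 60.0)


class TestAmuse:
    def test_ar_source_recovery(self):
        """Planted AR(1) sources with distinct lag-1 autocorrelations are
        recovered from a random 4x2 mixing with |r| > 0.95."""
        rng = np.random.default_rng(42)
        n = 20000
        s = np.zeros((2, n))
        for i, phi in enumerate((0.95, 0.2)):
            e = rng.standard_normal(n)
            for t in range(1, n):
                s[i, t] = phi * s[i, t - 1] + e[t]
        A = rng.standard_normal((4, 2))
        x = A @ s
        dec = pa.amuse(x)
        corr = np.abs(np.corrcoef(np.vstack([dec.sources[:2], s]))[:2, 2:])
        # best match per true source, up to permutation and sign
        assert corr.max(axis=0).min() > 0.95

    def test_identity_mixing_gives_signed_permutation(self):
        rng = np.random.default_rng(1)
        n = 50000
        s = np.zeros((2, n))
        for i, phi in enumerate((0.9, -0.5)):
            e = rng.standard_normal(n)
            for t in range(1, n):
                s[i, t] = phi * s[i, t - 1] + e[t]
        s /= s.std(axis=1, keepdims=True)
        dec = pa.amuse(s)
        P = np.abs(dec.unmixing)
        # each row has one dominant entry near 1 and the rest near 0
        assert np.allclose(np.sort(P, axis=1)[:, -1], 1.0, atol=0.1)
        assert np.all(np.sort(P, axis=1)[:, :-1] < 0.1)

    def test_eigenvalues_sorted_descending(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((5, 4000)).cumsum(axis=1)
        dec = pa.amuse(x)
        assert np.all(np.diff(dec.eigenvalues) <= 1e-12)

    def test_matches_generalized_eigenvalue_oracle(self):
        """AMUSE eigenvalues equal those of the generalized eigenproblem
        C1 v = lambda C0 v on a 3x3 problem."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal((3, 6000))
        x[1] += 0.5 * np.roll(x[0], 1)
        x[2] = np.convolve(x[2], np.ones(5) / 5, mode="same")
        xc = x - x.mean(axis=1, keepdims=True)
        n = xc.shape[1]
        C0 = xc @ xc.T / n
        C1 = xc[:, :-1] @ xc[:, 1:].T / (n - 1)
        # symmetrized lagged covariance in the C0 metric
        C1s = 0.5 * (C1 + C1.T)
        oracle = np.sort(linalg.eigvalsh(C1s, C0))[::-1]
        dec = pa.amuse(x, lag=1)
        assert np.allclose(dec.eigenvalues, oracle, atol=1e-8)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((4, 3000))
        dec = pa.amuse(x)
        xc = x - x.mean(axis=1, keepdims=True)
        assert np.allclose(dec.mixing @ dec.sources, xc, atol=1e-8)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pa.amuse(np.zeros((10, 5)))


class TestRemoveOcular:
    @staticmethod
    def _blinky_recording(seed=0):
        rng = np.random.default_rng(seed)
        n, fs = 30000, 500.0
        t = np.arange(n) / fs
        blink = np.zeros(n)
        for c in np.arange(2.0, 58.0, 4.0):
            blink += 100.0 * np.exp(-0.5 * ((t - c) / 0.05) ** 2)
        eeg = rng.standard_normal((6, n)) * 5.0
        frontal_gain = np.array([0.9, 0.7, 0.4, 0.2, 0.1, 0.05])
        eeg += frontal_gain[:, None] * blink[None, :]
        eog = np.vstack([
            blink + rng.standard_normal(n),
            -0.3 * blink + rng.standard_normal(n),
            rng.standard_normal(n),
            rng.standard_normal(n),
        ])
        return _recording(np.vstack([eeg, eog]), fs, n_eog=4)

    def test_planted_blink_removed(self):
        rec = self._blinky_recording()
        veog = rec.data[rec.eog_indices][0] - rec.data[rec.eog_indices][1]
        before = abs(np.corrcoef(rec.data[0], veog)[0, 1])
        out = pa.remove_ocular(rec, pa.amuse(rec))
        after = abs(np.corrcoef(out.data[0], veog)[0, 1])
        assert before > 0.9
        assert after < 0.2
        # EOG channels pass through unchanged
        assert np.array_equal(out.data[out.eog_indices], rec.data[rec.eog_indices])

    def test_threshold_one_keeps_everything(self):
        rec = self._blinky_recording(1)
        out = pa.remove_ocular(rec, pa.amuse(rec), eog_corr_threshold=1.0)
        assert np.allclose(out.data, rec.data, atol=1e-8)

    def test_clean_data_untouched(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((8, 20000))
        rec = _recording(data, n_eog=4)
        out = pa.remove_ocular(rec, pa.amuse(rec))
        assert np.allclose(out.data, rec.data, atol=1e-6)

    def test_missing_eog_rejected(self):
        rec = _recording(np.random.default_rng(0).standard_normal((4, 1000)))
        with pytest.raises(ValueError):
            pa.remove_ocular(rec, None)


class TestCommonAverageReference:
    def test_per_sample_sum_zero(self, oddball16):
        out = pa.common_average_reference(oddball16)
        sums = out.data[out.eeg_indices].sum(axis=0)
        assert np.max(np.abs(sums)) < 1e-9
        assert out.reference == "car"

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        rec = _recording(rng.standard_normal((5, 100)))
        once = pa.common_average_reference(rec)
        twice = pa.common_average_reference(once)
        assert np.allclose(once.data, twice.data)

    def test_single_active_channel_closed_form(self):
        """One nonzero channel among 63 keeps 62/63 of its value."""
        data = np.zeros((63, 10))
        data[17] = 1.0
        out = pa.common_average_reference(_recording(data))
        assert np.allclose(out.data[17], 62.0 / 63.0)
        assert np.allclose(out.data[0], -1.0 / 63.0)

    def test_eog_untouched(self):
        rng = np.random.default_rng(7)
        rec = _recording(rng.standard_normal((6, 50)), n_eog=2)
        out = pa.common_average_reference(rec)
        assert np.array_equal(out.data[out.eog_indices], rec.data[rec.eog_indices])


class TestEpochAndBaseline:
    def test_window_sample_count(self, oddball16):
        epochs = pa.epoch_and_baseline(oddball16)
        # [0, 800) ms at 250 Hz -> 200 samples (400 at the full 500 Hz rate)
        assert epochs.data.shape[2] == 200
        assert epochs.n_epochs == len(oddball16.events)

    def test_full_rate_gives_400_samples(self, quiet_profile):
        timing = pa.TimingConfig(oddball_runs=1, oddball_sequences_per_run=2)
        rec = pa.simulate_oddball_session(quiet_profile, timing, seed=0)
        epochs = pa.epoch_and_baseline(rec)
        assert epochs.data.shape[2] == 400

    def test_constant_epoch_zeroed_by_baseline(self):
        data = np.full((2, 2000), 4.2)
        ev = [pa.StimulusEvent(sample_index=500, kind="standard")]
        epochs = pa.epoch_and_baseline(_recording(data, events=ev))
        assert np.allclose(epochs.data, 0.0)

    def test_oddball_session_epoch_classes(self, oddball_epochs):
        # fast schedule: 1 run x 20 sequences... 10 sequences -> 10 deviants
        assert int(oddball_epochs.is_target.sum()) == 10
        assert oddball_epochs.n_epochs == 50

    def test_edge_events_dropped(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((2, 1000))
        events = [
            pa.StimulusEvent(sample_index=10, kind="standard"),   # no baseline room
            pa.StimulusEvent(sample_index=300, kind="standard"),  # fits
            pa.StimulusEvent(sample_index=900, kind="standard"),  # no post room
        ]
        epochs = pa.epoch_and_baseline(_recording(data, events=events))
        assert epochs.n_epochs == 1
        assert epochs.events[0].sample_index == 300

    def test_baseline_mean_zero(self, oddball_epochs):
        # re-derive the baseline from the continuous data is not possible
        # here; instead check a direct epoching round where baseline holds
        rng = np.random.default_rng(9)
        data = rng.standard_normal((3, 3000)).cumsum(axis=1)
        ev = [pa.StimulusEvent(sample_index=s, kind="standard") for s in (500, 1500)]
        epochs = pa.epoch_and_baseline(_recording(data, events=ev))
        fs = 500.0
        for e, ep in zip(ev, epochs.data):
            base = data[:, e.sample_index - 50 : e.sample_index]
            seg = data[:, e.sample_index : e.sample_index + 400]
            assert np.allclose(ep, seg - base.mean(axis=1, keepdims=True))


class TestPipeline:
    def test_pipeline_runs_and_preserves_counts(self, oddball16, oddball_epochs):
        assert oddball_epochs.n_epochs == len(oddball16.events)
        assert oddball_epochs.channel_labels == oddball16.eeg_labels

    def test_pipeline_deterministic(self, oddball16):
        a = pa.preprocess_recording(oddball16)
        b = pa.preprocess_recording(oddball16)
        assert np.array_equal(a.data, b.data)
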