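"""Synthetic-data generator: schedules, determinism, planted signal."""

from dataclasses import replace

import numpy as np
import pytest

import p300apt as pa
from p300apt.simulate import (
    N2_AMP_MEAN,
    N2_AMP_SD,
    N2_APTITUDE_RHO,
    make_participant,
)

from conftest import FAST_TIMING


class TestTimingConfig:
    def test_default_schedule_identities(self):
        """The published protocol durations follow from the stated timing."""
        t = pa.TimingConfig()
        assert t.oddball_soa_ms == 960.0
        assert t.oddball_run_duration_s == pytest.approx(96.0)
        assert t.soa_ms("visual") == 240.0
        assert t.soa_ms("auditory") == 1000.0
        assert t.letter_selection_s("visual") == pytest.approx(38.4)
        assert t.letter_stimulation_s("auditory") == pytest.approx(150.0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            pa.TimingConfig(oddball_isi_ms=-1.0)
        with pytest.raises(ValueError):
            pa.TimingConfig(stimuli_per_sequence=9)
        with pytest.raises(ValueError):
            pa.TimingConfig().soa_ms("tactile")

    def test_letter_positions_row_major(self):
        assert pa.letter_position("A") == (0, 0)
        assert pa.letter_position("Y") == (4, 4)
        assert pa.letter_position("B") == (0, 1)
        assert pa.letter_position("P") == (3, 0)
        assert "Z" not in pa.MATRIX_LETTERS


class TestMakeParticipant:
    def test_monotone_n2_link(self):
        """Under the same seed, higher aptitude gives a larger |N2|."""
        low = make_participant(1, aptitude=0.1)
        high = make_participant(1, aptitude=0.9)
        assert abs(high.components["N2"].amplitude_uV) > abs(low.components["N2"].amplitude_uV)
        assert high.components["late"].amplitude_uV > low.components["late"].amplitude_uV
        # P3 amplitude is aptitude-independent: identical under the same seed
        assert high.components["P3"].amplitude_uV == low.components["P3"].amplitude_uV

    def test_deterministic_in_seed(self):
        a, b = make_participant(7), make_participant(7)
        assert a.aptitude == b.aptitude
        assert a.noise_sigma == b.noise_sigma
        for name in a.components:
            ca, cb = a.components[name], b.components[name]
            assert (ca.amplitude_uV, ca.latency_ms, ca.width_ms) == (
                cb.amplitude_uV, cb.latency_ms, cb.width_ms)
            assert np.array_equal(ca.spatial, cb.spatial)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_participant(1, aptitude=1.5)
        with pytest.raises(ValueError):
            make_participant(-1)

    def test_population_amplitude_calibration(self):
        """A drawn cohort reproduces the published N2 population statistics."""
        profiles = pa.draw_cohort(40, seed=123, montage="midline8")
        amps = np.array([p.components["N2"].amplitude_uV for p in profiles])
        se = N2_AMP_SD / np.sqrt(len(amps))
        assert abs(amps.mean() - N2_AMP_MEAN) < 3 * se
        assert 1.4 < amps.std(ddof=1) < 3.2

    def test_population_rank_link_calibration(self):
        """Across many draws the planted |N2|-aptitude Spearman correlation
        sits near its configured value."""
        from scipy import stats

        profiles = pa.draw_cohort(400, seed=99, montage="midline8")
        apt = [p.aptitude for p in profiles]
        n2 = [abs(p.components["N2"].amplitude_uV) for p in profiles]
        rho, _ = stats.spearmanr(n2, apt)
        # 95% sampling band of Spearman's rho at n=400 is about +/-0.1
        assert abs(rho - N2_APTITUDE_RHO) < 0.12

    def test_profile_invariants(self):
        p = make_participant(5)
        assert p.components["N2"].amplitude_uV < 0
        assert p.components["P3"].amplitude_uV > 0
        assert p.components["late"].amplitude_uV > 0
        for c in p.components.values():
            assert np.max(np.abs(c.spatial)) == pytest.approx(1.0)


class TestErpTemplate:
    def test_nontarget_excludes_endogenous(self, profile16):
        t = pa.TimingConfig()
        tpl = pa.erp_template(profile16, "nontarget", "oddball", t)
        cz = list(profile16.eeg_labels).index("Cz")
        p3_sample = int(round(profile16.components["P3"].latency_ms * t.sampling_rate_hz / 1000))
        # at the P3 latency only the exogenous tail remains
        exo = sum(
            profile16.components[n].waveform(np.array([profile16.components["P3"].latency_ms]))[0]
            * profile16.components[n].spatial[cz]
            for n in ("N1", "P2")
        )
        assert tpl[cz, p3_sample] == pytest.approx(exo, abs=1e-9)

    def test_target_difference_peaks_at_p3(self):
        # a profile with a representative (non-floor) P3 amplitude
        prof = pa.make_participant(39, aptitude=0.7, montage="sparse16")
        t = pa.TimingConfig()
        diff = pa.erp_template(prof, "target", "oddball", t) - pa.erp_template(
            prof, "nontarget", "oddball", t
        )
        cz = list(prof.eeg_labels).index("Cz")
        peak_ms = np.argmax(diff[cz]) * 1000.0 / t.sampling_rate_hz
        assert abs(peak_ms - prof.components["P3"].latency_ms) < 30.0

    def test_gaussian_bump_integral_closed_form(self, profile16):
        """The planted bump integrates to amplitude * width * sqrt(2*pi)."""
        c = profile16.components["P3"]
        dt = 0.01  # ms; fine grid for the quadrature
        t = np.arange(0.0, 2000.0, dt)
        integral = c.waveform(t).sum() * dt
        expected = c.amplitude_uV * c.width_ms * np.sqrt(2 * np.pi)
        assert integral == pytest.approx(expected, rel=1e-6)

    def test_auditory_latencies_later_than_visual(self, profile16):
        t = pa.TimingConfig()
        cz = list(profile16.eeg_labels).index("Cz")
        ms = lambda tpl: np.argmax(tpl[cz]) * 1000.0 / t.sampling_rate_hz
        vis = pa.erp_template(profile16, "target", "visual", t)
        aud = pa.erp_template(profile16, "target", "auditory", t, duration_ms=1000.0)
        assert ms(aud) > ms(vis) + 100.0

    def test_unknown_modality_rejected(self, profile16):
        with pytest.raises(ValueError):
            pa.erp_template(profile16, "target", "tactile")


class TestOddballSession:
    def test_event_counts(self):
        """3 runs x 20 sequences x 5 tones: 60 deviants, 240 standards."""
        prof = make_participant(3, montage="midline8")
        quiet = replace(prof, noise_sigma=0.0, alpha_power=0.0, ocular_rate=0.0)
        rec = pa.simulate_oddball_session(quiet, pa.TimingConfig(), seed=1)
        kinds = [e.kind for e in rec.events]
        assert len(kinds) == 300
        assert kinds.count("deviant") == 60
        assert kinds.count("standard") == 240
        per_run = [sum(1 for e in rec.events if e.run_index == r) for r in range(3)]
        assert per_run == [100, 100, 100]
        # one deviant per 5-tone sequence
        for r in range(3):
            for s in range(20):
                seq = [e for e in rec.events if e.run_index == r and e.sequence_index == s]
                assert sum(e.kind == "deviant" for e in seq) == 1

    def test_sample_indices_strictly_increasing(self, oddball16):
        idx = [e.sample_index for e in oddball16.events]
        assert all(b > a for a, b in zip(idx, idx[1:]))

    def test_seed_determinism(self, profile16):
        a = pa.simulate_oddball_session(profile16, FAST_TIMING, seed=4)
        b = pa.simulate_oddball_session(profile16, FAST_TIMING, seed=4)
        assert np.array_equal(a.data, b.data)
        assert a.events == b.events

    def test_noiseless_deviant_average_recovers_template(self, quiet_profile):
        """With zero noise the epoch-averaged deviant ERP equals the planted
        target template exactly."""
        rec = pa.simulate_oddball_session(quiet_profile, FAST_TIMING, seed=2)
        epochs = pa.epoch_and_baseline(rec)
        avg = pa.average_erp(epochs, "target")
        tpl = pa.erp_template(quiet_profile, "target", "oddball", FAST_TIMING)
        assert np.allclose(avg, tpl, atol=1e-9)

    def test_eog_channels_present(self, oddball16):
        assert oddball16.eog_indices.size == 4
        assert oddball16.channel_roles.count("eeg") == 16


class TestSpellerSession:
    def test_event_counts_and_targets(self):
        prof = make_participant(3, montage="midline8")
        quiet = replace(prof, noise_sigma=0.0, alpha_power=0.0, ocular_rate=0.0)
        timing = pa.TimingConfig(letters_per_run=2, sequences_per_letter=3)
        rec = pa.simulate_bci_session(quiet, "visual", timing, seed=1)
        events = rec.events
        # 6 runs x 2 letters x 3 sequences x 10 stimuli
        assert len(events) == 6 * 2 * 3 * 10
        # per letter: one target row + one target column per sequence
        for r in range(6):
            for li in range(2):
                for s in range(3):
                    seq = [
                        e for e in events
                        if e.run_index == r and e.letter_index == li and e.sequence_index == s
                    ]
                    assert len(seq) == 10
                    targets = [e for e in seq if e.is_target]
                    assert len(targets) == 2
                    assert {e.kind[:3] for e in targets} == {"row", "col"}

    def test_full_default_schedule_counts(self):
        """The default session has 6 x 5 x 15 x 10 = 4500 stimulus events."""
        prof = make_participant(3, montage="midline8")
        quiet = replace(prof, noise_sigma=0.0, alpha_power=0.0, ocular_rate=0.0)
        rec = pa.simulate_bci_session(quiet, "visual", pa.TimingConfig(), seed=1)
        assert len(rec.events) == 4500
        targets = sum(e.is_target for e in rec.events)
        assert targets == 30 * 30  # 30 letters x (2 per sequence x 15)

    def test_auditory_rows_then_columns(self):
        prof = make_participant(4, montage="midline8")
        timing = pa.TimingConfig(letters_per_run=1, sequences_per_letter=2)
        rec = pa.simulate_bci_session(prof, "auditory", timing, seed=1)
        seq0 = [e for e in rec.events if e.run_index == 0 and e.sequence_index == 0]
        kinds = [e.kind for e in seq0]
        assert kinds == ["row_spoken"] * 5 + ["col_spoken"] * 5
        assert [e.stimulus_index for e in seq0] == [0, 1, 2, 3, 4, 0, 1, 2, 3, 4]

    def test_spelled_words_alternate(self):
        prof = make_participant(4, montage="midline8")
        timing = pa.TimingConfig(letters_per_run=5, sequences_per_letter=1)
        rec = pa.simulate_bci_session(prof, "visual", timing, seed=1)
        for run, word in zip(range(6), ["BRAIN", "POWER"] * 3):
            for li, letter in enumerate(word):
                seq = [e for e in rec.events if e.run_index == run and e.letter_index == li]
                rows = {e.stimulus_index for e in seq if e.is_target and e.kind == "row_flash"}
                cols = {e.stimulus_index for e in seq if e.is_target and e.kind == "col_flash"}
                assert (rows.pop(), cols.pop()) == pa.letter_position(letter)

    def test_unknown_modality_rejected(self, profile16):
        with pytest.raises(ValueError):
            pa.simulate_bci_session(profile16, "tactile", FAST_TIMING, seed=1)

    def test_seed_determinism(self, profile16):
        timing = pa.TimingConfig(letters_per_run=1, sequences_per_letter=2, sampling_rate_hz=250.0)
        a = pa.simulate_bci_session(profile16, "visual", timing, seed=9)
        b = pa.simulate_bci_session(profile16, "visual", timing, seed=9)
        assert np.array_equal(a.data, b.data)
        assert a.events == b.events
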