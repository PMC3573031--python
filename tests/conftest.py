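"""Shared fixtures: small, seeded synthetic sessions reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

import p300apt as pa


#: scaled-down schedule used by most pipeline tests: 250 Hz, sparse montage,
#: short oddball, one letter per run.  50 ms analysis bins are 12 samples.
FAST_TIMING = pa.TimingConfig(
    letters_per_run=1,
    sequences_per_letter=6,
    oddball_runs=1,
    oddball_sequences_per_run=10,
    sampling_rate_hz=250.0,
)
FAST_BIN = 12  # samples per 48 ms bin at 250 Hz


@pytest.fixture(scope="session")
def profile16() -> pa.ParticipantProfile:
    return pa.make_participant(21, aptitude=0.7, montage="sparse16")


@pytest.fixture(scope="session")
def quiet_profile(profile16) -> pa.ParticipantProfile:
    """Same participant without noise, alpha or ocular artifacts."""
    from dataclasses import replace

    return replace(profile16, noise_sigma=0.0, alpha_power=0.0, ocular_rate=0.0)


@pytest.fixture(scope="session")
def oddball16(profile16) -> pa.ContinuousRecording:
    return pa.simulate_oddball_session(profile16, FAST_TIMING, seed=3)


@pytest.fixture(scope="session")
def oddball_epochs(oddball16) -> pa.EpochSet:
    return pa.preprocess_recording(oddball16)


@pytest.fixture(scope="session")
def visual_runs(profile16) -> list[pa.EpochSet]:
    rec = pa.simulate_bci_session(profile16, "visual", FAST_TIMING, seed=5)
    epochs = pa.preprocess_recording(rec)
    run_ids = np.array([e.run_index for e in epochs.events])
    return [epochs.subset(run_ids == r) for r in range(6)]


@pytest.fixture(scope="session")
def visual_trials(visual_runs) -> list[pa.LetterTrial]:
    return pa.cross_validate(visual_runs, ma_width=FAST_BIN, decim=FAST_BIN)
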