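"""Seeded synthetic participants and continuous EEG sessions.

The generator plants Gaussian-windowed ERP components (N1, P2, N2, P3 and a
late anterior-negative/posterior-positive slow wave) into structured noise
(1/f background, amplitude-modulated 10 Hz alpha, blink and saccade
artifacts mirrored into the EOG channels).  Each participant carries a
latent *aptitude* in [0, 1]:

* oddball |N2| and late-component amplitudes increase with aptitude
  (linear link plus Gaussian residual, calibrated to the published
  population mean/SD and a planted rank correlation near 0.47/0.46);
* oddball P3 amplitude is drawn independently of aptitude (the planted
  null);
* speller-session signal-to-noise is driven by aptitude directly, so that
  classification performance covaries with the same latent the oddball N2
  and late components index, but not with the oddball P3.

Identical (seed, parameters) produce bit-identical sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .montage import EOG_LABELS, MONTAGES, late_slow_wave_map, spatial_map
from .recording import (
    ContinuousRecording,
    StimulusEvent,
    TimingConfig,
    NA,
    MATRIX_LETTERS,
    letter_position,
)

__all__ = [
    "Component",
    "ParticipantProfile",
    "make_participant",
    "draw_cohort",
    "erp_template",
    "simulate_oddball_session",
    "simulate_bci_session",
    "MATRIX_LETTERS",
    "letter_position",
    "SPELLER_WORDS",
]

SPELLER_WORDS = ("BRAIN", "POWER")

EXOGENOUS = ("N1", "P2")
ENDOGENOUS = ("N2", "P3", "late")

# Published component statistics used to seed the population (amplitude mean
# and SD in µV, latency mean and SD in ms) and the planted rank links.
N2_AMP_MEAN, N2_AMP_SD, N2_APTITUDE_RHO = -3.25, 2.25, 0.47
P3_AMP_MEAN, P3_AMP_SD = 4.99, 2.66
LATE_AMP_MEAN, LATE_AMP_SD, LATE_APTITUDE_RHO = 3.61, 2.10, 0.46
N2_LAT_MEAN, N2_LAT_SD = 229.05, 42.57
P3_LAT_MEAN, P3_LAT_SD = 378.00, 89.00
LATE_LAT_MEAN, LATE_LAT_SD = 548.65, 100.0  # SD truncated to fit the epoch

# Endogenous components in the speller sessions: amplitude scale and latency
# shift relative to the oddball (visual P3 near 309 ms, auditory near 508 ms,
# auditory amplitudes smaller), and the attenuation of the exogenous N1-P2
# complex (absent in the auditory speller).
MODALITY_ENDO_SCALE = {"oddball": 1.0, "visual": 0.95, "auditory": 0.67}
MODALITY_ENDO_SHIFT_MS = {"oddball": 0.0, "visual": -69.0, "auditory": 130.0}
MODALITY_EXO_SCALE = {"oddball": 1.0, "visual": 0.8, "auditory": 0.25}

# Speller signal gain as a function of aptitude; calibrated once so the
# default cohort lands near the study's group means (visual near ceiling,
# auditory intermediate).
SPELLER_SNR_BASE = 0.45
SPELLER_SNR_GAIN = 1.30

#: default per-participant noise level (µV RMS of the broadband background)
NOISE_SIGMA_UV = 9.0


def _link_coefficients(sd: float, rho: float) -> tuple[float, float]:
    """(gain, residual SD) of ``base + gain*aptitude + eps`` with aptitude
    uniform on [0, 1], matching a population SD ``sd`` and a Pearson link of
    ``rho`` between amplitude magnitude and aptitude."""
    gain = rho * sd * math.sqrt(12.0)
    resid = sd * math.sqrt(1.0 - rho**2)
    return gain, resid


@dataclass(frozen=True)
class Component:
    """One planted ERP component: a Gaussian bump in time times a fixed
    spatial map (unit maximum absolute weight over the EEG channels)."""

    amplitude_uV: float
    latency_ms: float
    width_ms: float  # Gaussian sigma
    spatial: np.ndarray

    def waveform(self, times_ms: np.ndarray) -> np.ndarray:
        """Time course at the spatial maximum (µV)."""
        return self.amplitude_uV * np.exp(
            -0.5 * ((times_ms - self.latency_ms) / self.width_ms) ** 2
        )


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    aptitude: float
    components: dict[str, Component]
    noise_sigma: float
    alpha_power: float
    ocular_rate: float  # blinks per minute
    seed: int
    montage: str = "full63"

    def __post_init__(self) -> None:
        if not 0.0 <= self.aptitude <= 1.0:
            raise ValueError("aptitude must lie in [0, 1]")
        if self.components["N2"].amplitude_uV >= 0:
            raise ValueError("N2 amplitude must be negative")
        if self.components["P3"].amplitude_uV <= 0 or self.components["late"].amplitude_uV <= 0:
            raise ValueError("P3 and late amplitudes must be positive")
        for name, c in self.components.items():
            if not math.isclose(np.max(np.abs(c.spatial)), 1.0, rel_tol=1e-9):
                raise ValueError(f"spatial map of {name} must have unit max abs weight")

    @property
    def eeg_labels(self) -> tuple[str, ...]:
        return MONTAGES[self.montage]


def make_participant(
    seed: int,
    aptitude: float | None = None,
    montage: str = "full63",
    participant_id: str | None = None,
) -> ParticipantProfile:
    """Draw a deterministic participant profile.

    If ``aptitude`` is None it is drawn uniformly on [0, 1].  |N2| and late
    amplitudes follow a monotone linear link in aptitude plus Gaussian
    residual; the P3 amplitude is drawn independently of aptitude.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    if aptitude is not None and not 0.0 <= aptitude <= 1.0:
        raise ValueError("aptitude must lie in [0, 1]")
    labels = MONTAGES[montage]
    rng = np.random.default_rng(seed)
    if aptitude is None:
        aptitude = float(rng.uniform())

    n2_gain, n2_resid = _link_coefficients(N2_AMP_SD, N2_APTITUDE_RHO)
    n2_base = -N2_AMP_MEAN - n2_gain / 2.0
    late_gain, late_resid = _link_coefficients(LATE_AMP_SD, LATE_APTITUDE_RHO)
    late_base = LATE_AMP_MEAN - late_gain / 2.0

    n2_amp = -max(n2_base + n2_gain * aptitude + rng.normal(0.0, n2_resid), 0.2)
    late_amp = max(late_base + late_gain * aptitude + rng.normal(0.0, late_resid), 0.2)
    p3_amp = max(rng.normal(P3_AMP_MEAN, P3_AMP_SD), 0.5)

    # exogenous complex kept smaller at Cz than the planted N2 range so the
    # sequential peak detector's pre-P300 minimum is the N2, as in the
    # grand averages the analysis is modelled on
    n1_amp = -max(rng.normal(2.0, 0.5), 0.8)
    p2_amp = max(rng.normal(2.5, 0.7), 0.8)

    n1_lat = float(np.clip(rng.normal(105.0, 8.0), 85.0, 130.0))
    p2_lat = float(np.clip(rng.normal(185.0, 10.0), 160.0, 215.0))
    n2_lat = float(np.clip(rng.normal(N2_LAT_MEAN, N2_LAT_SD), 150.0, 320.0))
    p3_lat = float(np.clip(rng.normal(P3_LAT_MEAN, P3_LAT_SD), n2_lat + 60.0, 680.0))
    late_lat = float(np.clip(rng.normal(LATE_LAT_MEAN, LATE_LAT_SD), p3_lat + 70.0, 770.0))

    components = {
        "N1": Component(n1_amp, n1_lat, 14.0, spatial_map(labels, "Fz", 0.7)),
        "P2": Component(p2_amp, p2_lat, 18.0, spatial_map(labels, "FCz", 0.8)),
        "N2": Component(n2_amp, n2_lat, 22.0, spatial_map(labels, "Cz", 0.6)),
        "P3": Component(p3_amp, p3_lat, 45.0, spatial_map(labels, "Cz", 0.7)),
        # the slow wave's sign flip sits at the vertex: its CAR-referenced
        # Cz projection is zero, keeping the Cz-based P3 measurement clean
        "late": Component(late_amp, late_lat, 65.0, late_slow_wave_map(labels, 0.8)),
    }
    return ParticipantProfile(
        participant_id=participant_id or f"P{seed:04d}",
        aptitude=aptitude,
        components=components,
        noise_sigma=float(max(rng.normal(NOISE_SIGMA_UV, 1.0), 3.0)),
        alpha_power=float(rng.uniform(1.0, 3.0)),
        ocular_rate=float(rng.uniform(4.0, 15.0)),
        seed=int(seed),
        montage=montage,
    )


def draw_cohort(n: int, seed: int, montage: str = "full63") -> list[ParticipantProfile]:
    """Draw ``n`` participants with independent seeds derived from ``seed``."""
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    return [
        make_participant(int(s), montage=montage, participant_id=f"P{i:03d}")
        for i, s in enumerate(child_seeds)
    ]


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def _speller_snr(aptitude: float) -> float:
    return SPELLER_SNR_BASE + SPELLER_SNR_GAIN * aptitude


def erp_template(
    profile: ParticipantProfile,
    stimulus_class: str,
    modality: str = "oddball",
    timing: TimingConfig | None = None,
    duration_ms: float = 800.0,
) -> np.ndarray:
    """Noise-free planted response, channels x samples over [0, duration_ms).

    Targets carry all five components; non-targets only the exogenous N1-P2
    complex.  In the speller modalities the endogenous amplitudes are the
    population means scaled by the participant's aptitude-dependent gain
    (the oddball, by contrast, uses the individually drawn amplitudes), the
    latencies are shifted per modality (auditory later than visual), and the
    exogenous complex is attenuated (essentially absent in the auditory
    speller).
    """
    if stimulus_class not in ("target", "nontarget"):
        raise ValueError(f"unknown stimulus class: {stimulus_class!r}")
    if modality not in MODALITY_ENDO_SCALE:
        raise ValueError(f"unknown modality: {modality!r}")
    timing = timing or TimingConfig()
    fs = timing.sampling_rate_hz
    n = int(round(duration_ms * fs / 1000.0))
    times = np.arange(n) * 1000.0 / fs
    n_ch = len(profile.eeg_labels)
    out = np.zeros((n_ch, n))

    canonical = {"N2": N2_AMP_MEAN, "P3": P3_AMP_MEAN, "late": LATE_AMP_MEAN}
    for name in EXOGENOUS:
        c = profile.components[name]
        amp = c.amplitude_uV * MODALITY_EXO_SCALE[modality]
        bump = amp * np.exp(-0.5 * ((times - c.latency_ms) / c.width_ms) ** 2)
        out += c.spatial[:, None] * bump[None, :]
    if stimulus_class == "target":
        for name in ENDOGENOUS:
            c = profile.components[name]
            if modality == "oddball":
                amp = c.amplitude_uV
            else:
                amp = (
                    canonical[name]
                    * _speller_snr(profile.aptitude)
                    * MODALITY_ENDO_SCALE[modality]
                )
            lat = c.latency_ms + MODALITY_ENDO_SHIFT_MS[modality]
            bump = amp * np.exp(-0.5 * ((times - lat) / c.width_ms) ** 2)
            out += c.spatial[:, None] * bump[None, :]
    return out


# ---------------------------------------------------------------------------
# noise and artifacts
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float) -> np.ndarray:
    """Unit-variance 1/f (power) noise, channels x samples."""
    n_ch, n = shape
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    gain[0] = 0.0  # no DC
    spec = rng.standard_normal((n_ch, freqs.size)) + 1j * rng.standard_normal((n_ch, freqs.size))
    x = np.fft.irfft(spec * gain[None, :], n=n, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def _alpha_oscillation(
    rng: np.random.Generator, n: int, fs: float, labels: tuple[str, ...], power: float
) -> np.ndarray:
    """Amplitude-modulated 10 Hz oscillation with a posterior topography."""
    t = np.arange(n) / fs
    # slow (~0.2 Hz) random envelope, strictly non-negative
    n_env = max(int(n * 0.4 / fs) + 2, 4)
    knots = rng.standard_normal(n_env)
    env = np.interp(np.linspace(0, n_env - 1, n), np.arange(n_env), knots)
    env = np.clip(1.0 + 0.7 * env, 0.0, None)
    carrier = np.sin(2.0 * np.pi * 10.0 * t + rng.uniform(0.0, 2.0 * np.pi))
    topo = spatial_map(labels, "Oz", 0.6)
    return power * topo[:, None] * (env * carrier)[None, :]


def _bump_train(
    rng: np.random.Generator,
    n: int,
    fs: float,
    rate_per_min: float,
    amp_range: tuple[float, float],
    width_range_ms: tuple[float, float],
    signed: bool = False,
) -> np.ndarray:
    """Poisson train of Gaussian transients (a blink/saccade source trace)."""
    out = np.zeros(n)
    n_events = rng.poisson(rate_per_min * n / fs / 60.0)
    t = np.arange(n) / fs
    for _ in range(n_events):
        center = rng.uniform(0.0, n / fs)
        width_s = rng.uniform(*width_range_ms) / 1000.0 / 6.0  # full width ~6 sigma
        amp = rng.uniform(*amp_range)
        if signed and rng.uniform() < 0.5:
            amp = -amp
        out += amp * np.exp(-0.5 * ((t - center) / width_s) ** 2)
    return out


def _background(
    rng: np.random.Generator,
    profile: ParticipantProfile,
    n: int,
    fs: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(eeg_noise, eog_data) for one run: 1/f + alpha + ocular artifacts."""
    labels = profile.eeg_labels
    n_eeg = len(labels)
    shared = _pink_noise(rng, (1, n), fs)
    own = _pink_noise(rng, (n_eeg, n), fs)
    eeg = profile.noise_sigma * (0.85 * own + 0.53 * shared)  # 0.85^2+0.53^2 ~ 1
    eeg += _alpha_oscillation(rng, n, fs, labels, profile.alpha_power)

    blink = _bump_train(rng, n, fs, profile.ocular_rate, (60.0, 140.0), (200.0, 400.0))
    saccade = _bump_train(rng, n, fs, 4.0, (30.0, 80.0), (200.0, 600.0), signed=True)
    frontal = spatial_map(labels, "Fpz", 0.5)
    lateral = spatial_map(labels, "F7", 0.5) - spatial_map(labels, "F8", 0.5)
    eeg += 0.6 * frontal[:, None] * blink[None, :]
    eeg += 0.15 * lateral[:, None] * saccade[None, :]

    eog = np.empty((4, n))
    eog_noise = 3.0 * rng.standard_normal((4, n))
    eog[0] = blink + eog_noise[0]          # above the eye
    eog[1] = -0.25 * blink + eog_noise[1]  # below the eye
    eog[2] = saccade + eog_noise[2]        # left canthus
    eog[3] = -saccade + eog_noise[3]       # right canthus
    return eeg, eog


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

_RUN_LEAD_S = 1.0
_RUN_TAIL_S = 1.0


def _empty_run(profile: ParticipantProfile, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    labels = profile.eeg_labels
    data = np.zeros((len(labels) + 4, n))
    if profile.noise_sigma > 0:
        eeg, eog = _background(rng, profile, n, fs)
        data[: len(labels)] = eeg
        data[len(labels):] = eog
    return data


def simulate_oddball_session(
    profile: ParticipantProfile,
    timing: TimingConfig | None = None,
    seed: int = 0,
) -> ContinuousRecording:
    """Three-run auditory oddball session.

    Each run has 20 sequences of five tones (four standards, one deviant at
    a uniformly random position), 960 ms onset asynchrony.  Deviants carry
    the full planted target response, standards only the exogenous N1-P2
    complex.
    """
    timing = timing or TimingConfig()
    fs = timing.sampling_rate_hz
    rng = np.random.default_rng(seed)
    soa = int(round(timing.oddball_soa_ms * fs / 1000.0))
    lead = int(round(_RUN_LEAD_S * fs))
    tail = int(round(_RUN_TAIL_S * fs))
    n_seq = timing.oddball_sequences_per_run
    run_samples = lead + n_seq * 5 * soa + tail

    target = erp_template(profile, "target", "oddball", timing)
    nontarget = erp_template(profile, "nontarget", "oddball", timing)
    n_eeg = target.shape[0]

    runs, events = [], []
    offset = 0
    for run in range(timing.oddball_runs):
        data = _empty_run(profile, run_samples, fs, rng)
        deviant_pos = rng.integers(0, 5, size=n_seq)
        for s in range(n_seq):
            for i in range(5):
                onset = lead + (s * 5 + i) * soa
                is_dev = i == deviant_pos[s]
                tpl = target if is_dev else nontarget
                data[:n_eeg, onset : onset + tpl.shape[1]] += tpl
                events.append(
                    StimulusEvent(
                        sample_index=offset + onset,
                        kind="deviant" if is_dev else "standard",
                        stimulus_index=NA,
                        is_target=is_dev,
                        sequence_index=s,
                        letter_index=NA,
                        run_index=run,
                    )
                )
        runs.append(data)
        offset += run_samples

    labels = list(profile.eeg_labels) + list(EOG_LABELS)
    roles = ["eeg"] * n_eeg + ["eog"] * 4
    return ContinuousRecording(
        data=np.concatenate(runs, axis=1),
        sampling_rate=fs,
        channel_labels=labels,
        channel_roles=roles,
        events=events,
        reference="nose",
    )


def _run_letters(run: int, letters_per_run: int) -> str:
    """Letters spelled in one run: BRAIN and POWER alternating."""
    word = SPELLER_WORDS[run % 2]
    return (word * math.ceil(letters_per_run / len(word)))[:letters_per_run]


def simulate_bci_session(
    profile: ParticipantProfile,
    modality: str,
    timing: TimingConfig | None = None,
    seed: int = 0,
) -> ContinuousRecording:
    """One speller session: runs x letters x sequences x 10 row/column stimuli.

    Visual: the 10 row/column stimuli are presented in random order within
    each sequence.  Auditory: rows 0-4 then columns 0-4, sequentially.
    Target stimuli (the attended letter's row and column) carry the
    modality-adjusted endogenous response.
    """
    if modality not in ("visual", "auditory"):
        raise ValueError(f"unknown modality: {modality!r}")
    timing = timing or TimingConfig()
    fs = timing.sampling_rate_hz
    rng = np.random.default_rng(seed)
    soa = int(round(timing.soa_ms(modality) * fs / 1000.0))
    pause = int(round(timing.inter_selection_pause_s * fs))
    lead = int(round(_RUN_LEAD_S * fs))
    n_seq = timing.sequences_per_letter
    n_stim = timing.stimuli_per_sequence
    letter_span = n_seq * n_stim * soa + pause
    run_samples = lead + timing.letters_per_run * letter_span

    tpl_ms = 1000.0 if modality == "auditory" else 800.0
    target = erp_template(profile, "target", modality, timing, duration_ms=tpl_ms)
    nontarget = erp_template(profile, "nontarget", modality, timing, duration_ms=tpl_ms)
    n_eeg = target.shape[0]
    kinds = ("row_spoken", "col_spoken") if modality == "auditory" else ("row_flash", "col_flash")

    runs, events = [], []
    offset = 0
    for run in range(timing.runs_per_session):
        data = _empty_run(profile, run_samples, fs, rng)
        for li, letter in enumerate(_run_letters(run, timing.letters_per_run)):
            t_row, t_col = letter_position(letter)
            letter_start = lead + li * letter_span
            for s in range(n_seq):
                stimuli = [("row", r) for r in range(timing.matrix_rows)] + [
                    ("col", c) for c in range(timing.matrix_cols)
                ]
                if modality == "visual":
                    order = rng.permutation(n_stim)
                    stimuli = [stimuli[i] for i in order]
                for k, (axis, idx) in enumerate(stimuli):
                    onset = letter_start + (s * n_stim + k) * soa
                    is_target = (axis == "row" and idx == t_row) or (
                        axis == "col" and idx == t_col
                    )
                    tpl = target if is_target else nontarget
                    stop = min(onset + tpl.shape[1], run_samples)
                    data[:n_eeg, onset:stop] += tpl[:, : stop - onset]
                    events.append(
                        StimulusEvent(
                            sample_index=offset + onset,
                            kind=kinds[0] if axis == "row" else kinds[1],
                            stimulus_index=idx,
                            is_target=is_target,
                            sequence_index=s,
                            letter_index=li,
                            run_index=run,
                        )
                    )
        runs.append(data)
        offset += run_samples

    labels = list(profile.eeg_labels) + list(EOG_LABELS)
    roles = ["eeg"] * n_eeg + ["eog"] * 4
    return ContinuousRecording(
        data=np.concatenate(runs, axis=1),
        sampling_rate=fs,
        channel_labels=labels,
        channel_roles=roles,
        events=events,
        reference="nose",
    )
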