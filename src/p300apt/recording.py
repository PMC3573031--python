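"""Core containers: stimulus timing, event markers and continuous EEG.

Conventions: sample indices are 0-based, time windows in milliseconds are
half-open ``[start, stop)``, and all signal amplitudes are in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

__all__ = ["TimingConfig", "StimulusEvent", "ContinuousRecording", "MATRIX_LETTERS", "letter_position"]

#: value used in integer event fields that do not apply to the event kind
NA = -1

#: 5x5 speller matrix, row-major, the latin alphabet without Z.
MATRIX_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXY"


def letter_position(letter: str) -> tuple[int, int]:
    """(row, column) of a letter in the row-major 5x5 matrix (A-Y, no Z)."""
    idx = MATRIX_LETTERS.index(letter.upper())
    return idx // 5, idx % 5

ODDBALL_KINDS = ("standard", "deviant")
SPELLER_KINDS = ("row_flash", "col_flash", "row_spoken", "col_spoken")


@dataclass(frozen=True)
class TimingConfig:
    """Stimulus schedule of the oddball and speller sessions.

    Defaults reproduce the study protocol: 160 ms complex tones with an
    800 ms inter-stimulus interval in the oddball (sequences of four
    standards and one deviant, 20 sequences per run, 3 runs); an 80 ms flash
    + 160 ms inter-flash interval in the visual speller; 450 ms spoken
    stimuli + 550 ms ISI in the auditory speller; 15 sequences of 10
    row/column stimuli per letter, 5 letters per run, 6 runs, with a 2.4 s
    classification pause between letter selections.
    """

    oddball_tone_ms: float = 160.0
    oddball_isi_ms: float = 800.0
    oddball_sequences_per_run: int = 20
    oddball_runs: int = 3
    vis_flash_ms: float = 80.0
    vis_interflash_ms: float = 160.0
    aud_stim_ms: float = 450.0
    aud_isi_ms: float = 550.0
    sequences_per_letter: int = 15
    stimuli_per_sequence: int = 10
    inter_selection_pause_s: float = 2.4
    letters_per_run: int = 5
    runs_per_session: int = 6
    matrix_rows: int = 5
    matrix_cols: int = 5
    sampling_rate_hz: float = 500.0

    def __post_init__(self) -> None:
        durations = (
            self.oddball_tone_ms, self.oddball_isi_ms, self.vis_flash_ms,
            self.vis_interflash_ms, self.aud_stim_ms, self.aud_isi_ms,
            self.inter_selection_pause_s, self.sampling_rate_hz,
        )
        if any(d <= 0 for d in durations):
            raise ValueError("all durations and rates must be positive")
        if self.stimuli_per_sequence != self.matrix_rows + self.matrix_cols:
            raise ValueError("stimuli_per_sequence must equal matrix_rows + matrix_cols")

    # ---- derived quantities -------------------------------------------------

    @property
    def oddball_soa_ms(self) -> float:
        """Stimulus-onset asynchrony of the oddball stream (tone + ISI)."""
        return self.oddball_tone_ms + self.oddball_isi_ms

    def soa_ms(self, modality: str) -> float:
        """Stimulus-onset asynchrony of a speller modality in ms."""
        if modality == "visual":
            return self.vis_flash_ms + self.vis_interflash_ms
        if modality == "auditory":
            return self.aud_stim_ms + self.aud_isi_ms
        raise ValueError(f"unknown modality: {modality!r}")

    @property
    def oddball_run_duration_s(self) -> float:
        """Stimulation time of one oddball run (100 tones at 960 ms SOA -> 96 s)."""
        return (
            self.oddball_sequences_per_run * 5 * self.oddball_soa_ms / 1000.0
        )

    def letter_stimulation_s(self, modality: str) -> float:
        """Stimulation time of one letter selection, excluding the pause."""
        return self.sequences_per_letter * self.stimuli_per_sequence * self.soa_ms(modality) / 1000.0

    def letter_selection_s(self, modality: str) -> float:
        """Full letter selection span: stimulation plus classification pause."""
        return self.letter_stimulation_s(modality) + self.inter_selection_pause_s

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TimingConfig":
        return cls(**d)


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus marker in a continuous recording.

    ``stimulus_index`` is the row/column index (0-4) for speller stimuli and
    ``NA`` (-1) for oddball tones; ``letter_index`` counts letter selections
    within a run and is ``NA`` for the oddball.
    """

    sample_index: int
    kind: str
    stimulus_index: int = NA
    is_target: bool = False
    sequence_index: int = NA
    letter_index: int = NA
    run_index: int = 0

    def __post_init__(self) -> None:
        # normalize numpy scalars so events compare and serialize cleanly
        object.__setattr__(self, "sample_index", int(self.sample_index))
        object.__setattr__(self, "stimulus_index", int(self.stimulus_index))
        object.__setattr__(self, "is_target", bool(self.is_target))
        object.__setattr__(self, "sequence_index", int(self.sequence_index))
        object.__setattr__(self, "letter_index", int(self.letter_index))
        object.__setattr__(self, "run_index", int(self.run_index))
        if self.kind not in ODDBALL_KINDS + SPELLER_KINDS:
            raise ValueError(f"unknown event kind: {self.kind!r}")
        if self.kind in SPELLER_KINDS and not 0 <= self.stimulus_index <= 4:
            raise ValueError("speller events need a row/column index in 0..4")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusEvent":
        return cls(**d)


@dataclass
class ContinuousRecording:
    """Multichannel continuous time series with stimulus events.

    ``data`` is channels x samples in microvolts.  ``channel_roles`` marks
    each row as ``"eeg"`` or ``"eog"``; ``reference`` records whether the
    EEG rows are nose-referenced (as recorded) or common-average referenced.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    channel_roles: list[str]
    events: list[StimulusEvent] = field(default_factory=list)
    reference: str = "nose"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data row count must equal channel label count")
        if len(self.channel_roles) != len(self.channel_labels):
            raise ValueError("one role per channel required")
        if any(r not in ("eeg", "eog") for r in self.channel_roles):
            raise ValueError("channel roles must be 'eeg' or 'eog'")
        if self.reference not in ("nose", "car"):
            raise ValueError("reference must be 'nose' or 'car'")
        n = self.data.shape[1]
        if any(not 0 <= e.sample_index < n for e in self.events):
            raise ValueError("event sample_index out of range")

    # ---- channel helpers ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.flatnonzero([r == "eeg" for r in self.channel_roles])

    @property
    def eog_indices(self) -> np.ndarray:
        return np.flatnonzero([r == "eog" for r in self.channel_roles])

    @property
    def eeg_labels(self) -> list[str]:
        return [self.channel_labels[i] for i in self.eeg_indices]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]

    def copy(self) -> "ContinuousRecording":
        return replace(
            self,
            data=self.data.copy(),
            channel_labels=list(self.channel_labels),
            channel_roles=list(self.channel_roles),
            events=list(self.events),
        )
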