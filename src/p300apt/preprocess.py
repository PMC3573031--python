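"""Offline preprocessing: zero-phase FIR band-pass, AMUSE-based ocular
artifact removal, common-average re-referencing, epoching and baseline
correction.

The canonical stage order (enforced by :func:`preprocess_recording`) is
band-pass -> BSS artifact removal -> CAR -> epoching -> baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import signal

from .recording import ContinuousRecording, StimulusEvent

__all__ = [
    "fir_bandpass",
    "BssDecomposition",
    "amuse",
    "remove_ocular",
    "common_average_reference",
    "EpochSet",
    "epoch_and_baseline",
    "preprocess_recording",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# zero-phase FIR filtering
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _design_fir(fs: float, cutoff_hz: float, kind: str) -> np.ndarray:
    """Least-squares FIR filter with the classic EEG order heuristic
    (3 * fs / cutoff taps, forced odd).  The high-pass is tweaked to an
    exact DC null so constant offsets are fully removed."""
    numtaps = 3 * int(fs / cutoff_hz)
    numtaps += 1 - numtaps % 2  # type-I (odd) for a valid high-pass
    trans = 0.5 * cutoff_hz
    nyq = fs / 2.0
    if kind == "highpass":
        bands = [0.0, max(cutoff_hz - trans, 0.0), cutoff_hz, nyq]
        desired = [0.0, 0.0, 1.0, 1.0]
    elif kind == "lowpass":
        bands = [0.0, cutoff_hz, min(cutoff_hz + trans, nyq), nyq]
        desired = [1.0, 1.0, 0.0, 0.0]
    else:  # pragma: no cover
        raise ValueError(kind)
    taps = signal.firls(numtaps, bands, desired, fs=fs)
    if kind == "highpass":
        taps = taps - taps.mean()  # exact zero at DC
    return taps


def _filtfilt_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward application of an FIR filter along the last axis,
    with odd-reflection edge padding of one filter length."""
    pad = min(len(taps), data.shape[-1] - 1)
    left = 2.0 * data[..., :1] - data[..., 1 : pad + 1][..., ::-1]
    right = 2.0 * data[..., -1:] - data[..., -pad - 1 : -1][..., ::-1]
    x = np.concatenate([left, data, right], axis=-1)
    h = taps[None, :] if data.ndim == 2 else taps
    y = signal.fftconvolve(x, h, mode="same", axes=-1)
    y = signal.fftconvolve(y[..., ::-1], h, mode="same", axes=-1)[..., ::-1]
    return y[..., pad : pad + data.shape[-1]]


def fir_bandpass(
    recording: ContinuousRecording,
    low_hz: float = 0.5,
    high_hz: float = 20.0,
) -> ContinuousRecording:
    """Zero-phase band-pass: a high-pass pass followed by a low-pass pass,
    each applied forward and backward (no phase distortion; the effective
    magnitude response is the squared single-pass response)."""
    fs = recording.sampling_rate
    if high_hz >= fs / 2.0 or low_hz >= fs / 2.0:
        raise ValueError("cutoff frequencies must be below the Nyquist rate")
    if low_hz <= 0 or high_hz <= low_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    out = recording.copy()
    out.data = _filtfilt_fir(out.data, _design_fir(fs, low_hz, "highpass"))
    out.data = _filtfilt_fir(out.data, _design_fir(fs, high_hz, "lowpass"))
    return out


# ---------------------------------------------------------------------------
# AMUSE blind source separation
# ---------------------------------------------------------------------------

@dataclass
class BssDecomposition:
    """Linear decomposition of the EEG channels into temporally structured
    sources, ordered by descending eigenvalue of the symmetrized lagged
    covariance of the whitened data."""

    unmixing: np.ndarray   # components x channels
    mixing: np.ndarray     # channels x components
    sources: np.ndarray    # components x samples
    eigenvalues: np.ndarray
    lag: int
    channel_mean: np.ndarray  # per-channel mean removed before decomposition


def amuse(recording: ContinuousRecording | np.ndarray, lag: int = 1) -> BssDecomposition:
    """Second-order blind source separation (AMUSE).

    Whiten via the eigendecomposition of the zero-lag covariance, then
    eigendecompose the symmetrized lag-``lag`` covariance of the whitened
    data; the composed transform separates sources with distinct lagged
    autocorrelations.  Operates on the EEG channels of a recording (or on a
    raw channels x samples array).
    """
    X = recording.data[recording.eeg_indices] if isinstance(recording, ContinuousRecording) else np.asarray(recording, dtype=float)
    n_ch, n = X.shape
    if n <= n_ch:
        raise ValueError("need more samples than channels")
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    C0 = (Xc @ Xc.T) / n
    evals, evecs = np.linalg.eigh(C0)
    tol = max(evals.max(), 0.0) * 1e-12
    if evals.min() <= tol:
        warnings.warn("rank-deficient covariance; regularizing whitening", RuntimeWarning)
        evals = evals + max(evals.max() * 1e-10, 1e-12)
    whitener = (evecs / np.sqrt(evals)).T  # rows scale the principal axes
    Z = whitener @ Xc
    C1 = (Z[:, :-lag] @ Z[:, lag:].T) / (n - lag)
    C1 = 0.5 * (C1 + C1.T)
    lam, V = np.linalg.eigh(C1)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    unmixing = V.T @ whitener
    mixing = np.linalg.pinv(unmixing)
    return BssDecomposition(
        unmixing=unmixing,
        mixing=mixing,
        sources=unmixing @ Xc,
        eigenvalues=lam,
        lag=lag,
        channel_mean=mean,
    )


def _bipolar_eog(recording: ContinuousRecording) -> tuple[np.ndarray, np.ndarray]:
    """(vertical, horizontal) bipolar EOG derivations."""
    eog = recording.data[recording.eog_indices]
    if eog.shape[0] < 4:
        raise ValueError("recording has no (complete) EOG channel set")
    return eog[0] - eog[1], eog[2] - eog[3]


def remove_ocular(
    recording: ContinuousRecording,
    decomposition: BssDecomposition | None = None,
    eog_corr_threshold: float = 0.7,
) -> ContinuousRecording:
    """Zero BSS components correlated with the bipolar EOG derivations.

    Components whose absolute Pearson correlation with either the vertical
    (above minus below the eye) or horizontal (left minus right canthus)
    EOG trace exceeds the threshold are removed; the EEG is reconstructed
    from the remaining components.  EOG channels pass through unchanged.
    """
    if decomposition is None:
        decomposition = amuse(recording)
    veog, heog = _bipolar_eog(recording)
    S = decomposition.sources
    keep = np.ones(S.shape[0], dtype=bool)
    for ref in (veog, heog):
        rc = ref - ref.mean()
        denom = np.linalg.norm(rc) * np.linalg.norm(S - S.mean(axis=1, keepdims=True), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (S - S.mean(axis=1, keepdims=True)) @ rc / np.where(denom > 0, denom, np.inf)
        keep &= np.abs(r) <= eog_corr_threshold
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("removing %d ocular component(s)", n_removed)
    out = recording.copy()
    cleaned = decomposition.mixing[:, keep] @ S[keep] + decomposition.channel_mean
    out.data[out.eeg_indices] = cleaned
    return out


# ---------------------------------------------------------------------------
# re-referencing and epoching
# ---------------------------------------------------------------------------

def common_average_reference(recording: ContinuousRecording) -> ContinuousRecording:
    """Subtract the instantaneous mean over EEG channels from every EEG
    channel (EOG untouched).  Idempotent."""
    idx = recording.eeg_indices
    if idx.size < 2:
        raise ValueError("common average reference needs at least 2 EEG channels")
    out = recording.copy()
    out.data[idx] -= out.data[idx].mean(axis=0, keepdims=True)
    out.reference = "car"
    return out


@dataclass
class EpochSet:
    """Stimulus-locked EEG epochs (epochs x channels x samples, µV) with the
    originating event metadata.  Windows are half-open in ms."""

    data: np.ndarray
    events: list[StimulusEvent]
    sampling_rate: float
    channel_labels: list[str]
    window_ms: tuple[float, float] = (0.0, 800.0)
    baseline_ms: tuple[float, float] = (-100.0, 0.0)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if self.data.shape[0] != len(self.events):
            raise ValueError("one event per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.window_ms[0] + np.arange(n) * 1000.0 / self.sampling_rate

    @property
    def is_target(self) -> np.ndarray:
        return np.array([e.is_target for e in self.events], dtype=bool)

    def subset(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return replace(
            self, data=self.data[idx], events=[self.events[i] for i in idx],
            channel_labels=list(self.channel_labels),
        )

    @classmethod
    def concatenate(cls, parts: list["EpochSet"]) -> "EpochSet":
        first = parts[0]
        return replace(
            first,
            data=np.concatenate([p.data for p in parts], axis=0),
            events=[e for p in parts for e in p.events],
            channel_labels=list(first.channel_labels),
        )


def epoch_and_baseline(
    recording: ContinuousRecording,
    window_ms: tuple[float, float] = (0.0, 800.0),
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
) -> EpochSet:
    """Cut one epoch per stimulus event and subtract the per-channel mean of
    the pre-stimulus baseline window.

    Sample windows are half-open: at 500 Hz, [0, 800) ms gives 400 samples.
    Events too close to a recording edge are dropped (logged count).
    """
    fs = recording.sampling_rate
    start = int(round(window_ms[0] * fs / 1000.0))
    stop = int(round(window_ms[1] * fs / 1000.0))
    b0 = int(round(baseline_ms[0] * fs / 1000.0))
    b1 = int(round(baseline_ms[1] * fs / 1000.0))
    if stop <= start or b1 <= b0:
        raise ValueError("empty epoch or baseline window")
    idx = recording.eeg_indices
    eeg = recording.data[idx]
    n = eeg.shape[1]

    kept_events, slabs = [], []
    n_dropped = 0
    for e in recording.events:
        lo = e.sample_index + min(start, b0)
        hi = e.sample_index + max(stop, b1)
        if lo < 0 or hi > n:
            n_dropped += 1
            continue
        seg = eeg[:, e.sample_index + start : e.sample_index + stop]
        base = eeg[:, e.sample_index + b0 : e.sample_index + b1].mean(axis=1, keepdims=True)
        slabs.append(seg - base)
        kept_events.append(e)
    if n_dropped:
        logger.info("dropped %d event(s) too close to a recording edge", n_dropped)
    if not kept_events:
        raise ValueError("no events with enough surrounding data to epoch")
    return EpochSet(
        data=np.stack(slabs),
        events=kept_events,
        sampling_rate=fs,
        channel_labels=list(recording.eeg_labels),
        window_ms=tuple(window_ms),
        baseline_ms=tuple(baseline_ms),
    )


def preprocess_recording(
    recording: ContinuousRecording,
    low_hz: float = 0.5,
    high_hz: float = 20.0,
    eog_corr_threshold: float = 0.7,
    bss_lag: int = 1,
    window_ms: tuple[float, float] = (0.0, 800.0),
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
) -> EpochSet:
    """Full offline pipeline in the canonical order:
    band-pass -> AMUSE ocular removal -> CAR -> epoch -> baseline."""
    stages: list[str] = []
    rec = fir_bandpass(recording, low_hz, high_hz)
    stages.append("bandpass")
    rec = remove_ocular(rec, amuse(rec, lag=bss_lag), eog_corr_threshold)
    stages.append("bss_removal")
    rec = common_average_reference(rec)
    stages.append("car")
    epochs = epoch_and_baseline(rec, window_ms, baseline_ms)
    stages.append("epoch_baseline")
    assert stages == ["bandpass", "bss_removal", "car", "epoch_baseline"]
    return epochs
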