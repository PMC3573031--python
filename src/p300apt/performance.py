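"""Offline performance evaluation.

Leave-one-run-out cross-validation of the SWLDA speller, letter-accuracy as
a function of the number of stimulus repetitions, the interpolated
repetitions-to-70%-accuracy aptitude metric, selection-time conversion, and
two information transfer rate definitions (Pierce's symmetric-channel
formula and mutual information over the empirical selection-offset
distribution).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import EpochSet
from .recording import TimingConfig, MATRIX_LETTERS
from .swlda import (
    ClassifierModel,
    FeatureMatrix,
    ModelGenerationError,
    featurize,
    score,
    select_letter,
    swlda_fit,
)

__all__ = [
    "LetterTrial",
    "cross_validate",
    "AccuracyCurve",
    "accuracy_vs_repetitions",
    "reps_to_criterion",
    "NOT_REACHED",
    "selection_time",
    "timewindow_accuracy",
    "pierce_itr",
    "mutual_information_itr",
    "error_offset_matrix",
    "PerformanceRecord",
]

logger = logging.getLogger(__name__)

#: sentinel recorded when 70% accuracy is never reached within 15 repetitions
#: (one beyond the maximum; preserves rank order without discarding anyone)
NOT_REACHED = 16.0


@dataclass
class LetterTrial:
    """Scores for one held-out letter selection."""

    run_index: int
    letter_index: int
    target: tuple[int, int]  # (row, col) ground truth
    scores: np.ndarray       # one score per stimulus event of this letter
    events: list             # matching StimulusEvent metadata

    @property
    def target_letter(self) -> str:
        return MATRIX_LETTERS[self.target[0] * 5 + self.target[1]]


def _target_of(events) -> tuple[int, int]:
    rows = {e.stimulus_index for e in events if e.is_target and e.kind.startswith("row")}
    cols = {e.stimulus_index for e in events if e.is_target and e.kind.startswith("col")}
    if len(rows) != 1 or len(cols) != 1:
        raise ValueError("letter events must mark exactly one target row and column")
    return rows.pop(), cols.pop()


def cross_validate(
    runs: list[EpochSet],
    p_enter: float = 0.10,
    p_remove: float = 0.15,
    max_iter: int = 60,
    ma_width: int = 25,
    decim: int = 25,
) -> list[LetterTrial]:
    """Leave-one-run-out cross-validation over a 6-run speller session.

    For each fold the classifier is trained on the other five runs and
    applied to every letter of the held-out run, so every letter is scored
    exactly once.  A fold whose model generation fails (no significant
    feature) falls back to all-zero scores for its letters (logged).
    """
    if len(runs) != 6:
        raise ValueError("leave-one-run-out evaluation expects exactly 6 runs")
    trials: list[LetterTrial] = []
    for held_out in range(len(runs)):
        train = EpochSet.concatenate([r for i, r in enumerate(runs) if i != held_out])
        assert all(e.run_index != runs[held_out].events[0].run_index for e in train.events)
        train_fm = featurize(train, ma_width=ma_width, decim=decim)
        test_fm = featurize(runs[held_out], ma_width=ma_width, decim=decim)
        try:
            model = swlda_fit(train_fm, p_enter=p_enter, p_remove=p_remove, max_iter=max_iter)
            fold_scores = score(model, test_fm)
        except ModelGenerationError:
            logger.info("fold %d: model generation failed; scoring zeros", held_out)
            fold_scores = np.zeros(test_fm.n_trials)
        letters = sorted({e.letter_index for e in test_fm.events})
        for li in letters:
            mask = np.array([e.letter_index == li for e in test_fm.events])
            ev = [e for e in test_fm.events if e.letter_index == li]
            trials.append(
                LetterTrial(
                    run_index=ev[0].run_index,
                    letter_index=li,
                    target=_target_of(ev),
                    scores=fold_scores[mask],
                    events=ev,
                )
            )
    return trials


@dataclass
class AccuracyCurve:
    """Letter accuracy (percent) per number of repetitions 1..len(values)."""

    accuracy_percent: np.ndarray
    n_letters: int

    def __post_init__(self) -> None:
        a = np.asarray(self.accuracy_percent, dtype=float)
        if ((a < 0) | (a > 100)).any():
            raise ValueError("accuracies must lie in [0, 100]")
        self.accuracy_percent = a


def accuracy_vs_repetitions(
    trials: list[LetterTrial],
    max_reps: int = 15,
) -> AccuracyCurve:
    """Accuracy curve: select every letter using only the first k sequences,
    for k = 1..max_reps."""
    acc = np.empty(max_reps)
    for k in range(1, max_reps + 1):
        correct = 0
        for t in trials:
            row, col, _ = select_letter(t.scores, t.events, n_reps=k)
            correct += (row, col) == t.target
        acc[k - 1] = 100.0 * correct / len(trials)
    return AccuracyCurve(accuracy_percent=acc, n_letters=len(trials))


def selections_from_trials(
    trials: list[LetterTrial], n_reps: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(selections, targets) as (row, col) pairs at a given repetition count."""
    sels, targs = [], []
    for t in trials:
        row, col, _ = select_letter(t.scores, t.events, n_reps=n_reps)
        sels.append((row, col))
        targs.append(t.target)
    return sels, targs


def reps_to_criterion(curve: AccuracyCurve, criterion: float = 70.0) -> float:
    """Interpolated number of repetitions to reach the criterion accuracy.

    The smallest k with accuracy >= criterion, linearly interpolated between
    (k-1, acc(k-1)) and (k, acc(k)); if the first repetition already meets
    the criterion, interpolation anchors at (0, 0).  Returns
    :data:`NOT_REACHED` (16) if the criterion is never met.
    """
    acc = curve.accuracy_percent
    reached = np.flatnonzero(acc >= criterion)
    if reached.size == 0:
        return NOT_REACHED
    k = int(reached[0]) + 1  # 1-based repetition count
    prev_acc = 0.0 if k == 1 else float(acc[k - 2])
    this_acc = float(acc[k - 1])
    return (k - 1) + (criterion - prev_acc) / (this_acc - prev_acc)


def selection_time(
    reps: float,
    modality: str,
    timing: TimingConfig | None = None,
) -> tuple[float, float]:
    """(seconds per selection, selections per minute) at a repetition count.

    Time = reps x 10 stimuli x SOA + inter-selection pause; the SOA is
    240 ms (visual) or 1000 ms (auditory) under the default timing.
    """
    if reps <= 0:
        raise ValueError("repetition count must be positive")
    timing = timing or TimingConfig()
    seconds = (
        reps * timing.stimuli_per_sequence * timing.soa_ms(modality) / 1000.0
        + timing.inter_selection_pause_s
    )
    return seconds, 60.0 / seconds


def timewindow_accuracy(
    runs: list[EpochSet],
    bin_ms: float = 50.0,
    range_ms: tuple[float, float] | None = None,
    n_reps: int | None = None,
    **swlda_params,
) -> tuple[np.ndarray, np.ndarray]:
    """Letter accuracy per non-overlapping time bin.

    Each bin's samples are featurized alone (one feature per channel for
    50 ms bins at 500 Hz), trained and tested with the same leave-one-run-out
    loop.  Returns (bin_center_ms, accuracy_percent).
    """
    first = runs[0]
    lo, hi = range_ms if range_ms is not None else first.window_ms
    if (hi - lo) % bin_ms:
        raise ValueError("bin width must divide the analysis range")
    n_bins = int(round((hi - lo) / bin_ms))
    if n_bins < 1:
        raise ValueError("empty analysis range")
    fs = first.sampling_rate
    if n_reps is None:
        n_reps = max(e.sequence_index for e in first.events) + 1
    centers = lo + (np.arange(n_bins) + 0.5) * bin_ms
    acc = np.empty(n_bins)
    t0 = first.window_ms[0]
    for b in range(n_bins):
        s0 = int(round((lo + b * bin_ms - t0) * fs / 1000.0))
        s1 = int(round((lo + (b + 1) * bin_ms - t0) * fs / 1000.0))
        if s1 <= s0:
            raise ValueError("empty time bin")
        width = s1 - s0
        sliced = []
        for r in runs:
            sub = r.subset(np.arange(r.n_epochs))
            sub.data = r.data[:, :, s0:s1]
            sub.window_ms = (lo + b * bin_ms, lo + (b + 1) * bin_ms)
            sliced.append(sub)
        trials = cross_validate(sliced, ma_width=width, decim=width, **swlda_params)
        curve = accuracy_vs_repetitions(trials, max_reps=n_reps)
        acc[b] = curve.accuracy_percent[n_reps - 1]
    return centers, acc


# ---------------------------------------------------------------------------
# information transfer rate
# ---------------------------------------------------------------------------

def pierce_itr(accuracy: float, n_classes: int = 25, selections_per_min: float = 1.0) -> float:
    """Symmetric-channel bits/min: B = log2 N + P log2 P + (1-P) log2((1-P)/(N-1)),
    times the selection rate.  Below-chance accuracy yields 0 with a warning."""
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must be a fraction in [0, 1]")
    if accuracy < 1.0 / n_classes:
        warnings.warn("accuracy below chance; reporting 0 bits/min", RuntimeWarning)
        return 0.0
    if accuracy == 1.0:
        bits = np.log2(n_classes)
    else:
        p = accuracy
        bits = (
            np.log2(n_classes)
            + p * np.log2(p)
            + (1.0 - p) * np.log2((1.0 - p) / (n_classes - 1))
        )
    return float(bits * selections_per_min)


def error_offset_matrix(
    selections: list[tuple[int, int]],
    targets: list[tuple[int, int]],
    n_rows: int = 5,
    n_cols: int = 5,
) -> np.ndarray:
    """Probability grid of (selected - target) offsets.

    Rows index the row offset -(n_rows-1)..+(n_rows-1), columns the column
    offset; the centre cell is the correct-selection probability.
    """
    if not selections:
        raise ValueError("no selections given")
    if len(selections) != len(targets):
        raise ValueError("selections and targets must align")
    grid = np.zeros((2 * n_rows - 1, 2 * n_cols - 1))
    for (sr, sc), (tr, tc) in zip(selections, targets):
        grid[sr - tr + n_rows - 1, sc - tc + n_cols - 1] += 1.0
    return grid / grid.sum()


def mutual_information_itr(
    matrix: np.ndarray,
    selections_per_min: float = 1.0,
    n_rows: int = 5,
    n_cols: int = 5,
) -> float:
    """Mutual-information bits/min from a selection-offset probability grid.

    The offset distribution is treated as the channel's conditional error
    structure: targets are uniform over the 5x5 matrix, and for each target
    the offsets are clipped to the reachable cells and renormalized.  Bits
    per selection is I(target; selection) = sum p(x,y) log2 p(x,y)/(p(x)p(y)).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (2 * n_rows - 1, 2 * n_cols - 1):
        raise ValueError("offset matrix has the wrong shape")
    if (matrix < 0).any() or abs(matrix.sum() - 1.0) > 1e-9:
        raise ValueError("offset probabilities must be non-negative and sum to 1")
    n_cells = n_rows * n_cols
    joint = np.zeros((n_cells, n_cells))
    p_target = 1.0 / n_cells
    for tr in range(n_rows):
        for tc in range(n_cols):
            block = matrix[n_rows - 1 - tr : 2 * n_rows - 1 - tr,
                           n_cols - 1 - tc : 2 * n_cols - 1 - tc]
            total = block.sum()
            if total <= 0:
                raise ValueError("a target position has zero reachable probability")
            cond = block / total
            joint[tr * n_cols + tc] = p_target * cond.ravel()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    bits = float(np.nansum(terms))
    return bits * selections_per_min


@dataclass
class PerformanceRecord:
    """Summary of one participant x modality evaluation."""

    participant_id: str
    modality: str
    accuracy_percent: float        # at the full repetition count
    reps_to_criterion: float       # NOT_REACHED sentinel if never met
    criterion: float
    selection_time_s: float
    selections_per_min: float
    itr_pierce_bits_per_min: float
    curve: AccuracyCurve | None = None

    @property
    def reached_criterion(self) -> bool:
        return self.reps_to_criterion < NOT_REACHED
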