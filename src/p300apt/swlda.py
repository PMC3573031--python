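"""Featurization and stepwise linear discriminant analysis (SWLDA).

Epochs are smoothed with a 25-sample moving average and decimated by 25,
giving channel x time-bin features (63 x 16 = 1008 for 400-sample epochs).
SWLDA regresses the ±1 class label on the features with forward inclusion /
backward removal by partial-F significance, yielding a sparse bias-free
linear scorer.  Letter selection sums scores per row and per column over
sequences and takes the arg-max of each (ties toward the lower index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess import EpochSet
from .recording import StimulusEvent, MATRIX_LETTERS

__all__ = [
    "FeatureMatrix",
    "featurize",
    "ClassifierModel",
    "swlda_fit",
    "score",
    "select_letter",
    "ModelGenerationError",
]


class ModelGenerationError(RuntimeError):
    """No feature reached the inclusion threshold on the first step."""


@dataclass
class FeatureMatrix:
    """Trials x features design matrix with per-feature provenance."""

    values: np.ndarray
    feature_index: list[tuple[str, int, float]]  # (channel label, bin index, bin center ms)
    labels: np.ndarray  # +1 target / -1 nontarget
    events: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.feature_index):
            raise ValueError("feature_index length must equal feature count")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def featurize(epochs: EpochSet, ma_width: int = 25, decim: int = 25) -> FeatureMatrix:
    """Moving-average smoothing followed by decimation, per channel.

    The trailing ``ma_width`` window is aligned so that with
    ``ma_width == decim`` bin *b* is exactly the mean of samples
    ``[b*decim, (b+1)*decim)``.  Trials are stacked in event order; labels
    are +1 for target epochs and -1 otherwise.
    """
    n_epochs, n_ch, n_samp = epochs.data.shape
    if ma_width > n_samp:
        raise ValueError("ma_width exceeds the epoch sample count")
    if ma_width < 1 or decim < 1:
        raise ValueError("ma_width and decim must be positive")
    n_bins = n_samp // decim
    if n_bins < 1:
        raise ValueError("decimation factor exceeds the epoch sample count")
    # trailing moving average via cumulative sums
    cs = np.cumsum(epochs.data, axis=2, dtype=float)
    cs = np.concatenate([np.zeros((n_epochs, n_ch, 1)), cs], axis=2)
    pick = np.arange(n_bins) * decim + ma_width - 1
    pick = np.minimum(pick, n_samp - 1)
    smoothed = (cs[:, :, pick + 1] - cs[:, :, pick + 1 - ma_width]) / ma_width

    values = smoothed.reshape(n_epochs, n_ch * n_bins)
    ms_per_sample = 1000.0 / epochs.sampling_rate
    t0 = epochs.window_ms[0]
    index = [
        (epochs.channel_labels[c], b, t0 + (b * decim + (ma_width - 1) / 2.0 + 0.5) * ms_per_sample)
        for c in range(n_ch)
        for b in range(n_bins)
    ]
    labels = np.where(epochs.is_target, 1.0, -1.0)
    return FeatureMatrix(values=values, feature_index=index, labels=labels, events=list(epochs.events))


@dataclass
class ClassifierModel:
    """Sparse bias-free linear scorer over selected features."""

    selected: list[int]
    weights: np.ndarray
    p_enter: float
    p_remove: float
    n_iterations: int
    feature_index: list[tuple[str, int, float]]

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected features must be unique")
        if len(self.weights) != len(self.selected):
            raise ValueError("one weight per selected feature required")

    def to_json(self) -> str:
        """Serialize as JSON: one entry per selected feature with its
        channel label, bin center (ms) and weight, plus the fit settings."""
        import json

        return json.dumps(
            {
                "p_enter": self.p_enter,
                "p_remove": self.p_remove,
                "n_iterations": self.n_iterations,
                "n_features": len(self.feature_index),
                "feature_index": [list(f) for f in self.feature_index],
                "selected": [
                    {
                        "index": int(i),
                        "channel": self.feature_index[i][0],
                        "bin": int(self.feature_index[i][1]),
                        "bin_center_ms": float(self.feature_index[i][2]),
                        "weight": float(w),
                    }
                    for i, w in zip(self.selected, self.weights)
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        import json

        d = json.loads(text)
        return cls(
            selected=[e["index"] for e in d["selected"]],
            weights=np.array([e["weight"] for e in d["selected"]]),
            p_enter=d["p_enter"],
            p_remove=d["p_remove"],
            n_iterations=d["n_iterations"],
            feature_index=[tuple(f) for f in d["feature_index"]],
        )


def _refit_stats(X: np.ndarray, y: np.ndarray, selected: list[int]) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS fit on the selected columns (no intercept): weights, per-feature
    two-sided removal p-values, and residual sum of squares."""
    n = X.shape[0]
    k = len(selected)
    Xs = X[:, selected]
    G = Xs.T @ Xs
    Ginv = np.linalg.pinv(G)
    w = Ginv @ (Xs.T @ y)
    rss = float(y @ y - w @ (Xs.T @ y))
    dof = n - k
    if dof <= 0:
        return w, np.zeros(k), rss
    s2 = max(rss / dof, 0.0)
    var_w = np.clip(np.diag(Ginv), 0.0, None) * s2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(var_w > 0, w**2 / var_w, np.inf)
    p = stats.f.sf(f, 1, dof)
    return w, p, rss


def swlda_fit(
    features: FeatureMatrix,
    p_enter: float = 0.10,
    p_remove: float = 0.15,
    max_iter: int = 60,
) -> ClassifierModel:
    """Forward/backward stepwise regression of the ±1 label on the features.

    Each iteration adds the candidate with the smallest partial-F p-value if
    it is below ``p_enter``, then removes included features whose p-value
    exceeds ``p_remove``, until ``max_iter`` iterations or no candidate
    qualifies.  Raises :class:`ModelGenerationError` if no feature qualifies
    on the first step.
    """
    X = np.asarray(features.values, dtype=float)
    y = np.asarray(features.labels, dtype=float)
    n, m = X.shape
    if np.sum(y > 0) < 2 or np.sum(y < 0) < 2:
        raise ValueError("need at least two trials per class")

    selected: list[int] = []
    in_model = np.zeros(m, dtype=bool)
    # R holds every column residualized against the selected set (modified
    # Gram-Schmidt, updated incrementally); y_res likewise.
    R = X.copy()
    y_res = y.copy()
    scale2 = np.einsum("ij,ij->j", X, X)  # collinearity reference

    def _rebuild() -> None:
        nonlocal R, y_res
        R = X.copy()
        y_res = y.copy()
        for j in selected:
            q = R[:, j]
            nq = np.linalg.norm(q)
            if nq > 0:
                q = q / nq
                R -= np.outer(q, q @ R)
                y_res -= q * (q @ y_res)

    for iteration in range(max_iter):
        # ---- forward step: partial F of every excluded candidate ----------
        rn2 = np.einsum("ij,ij->j", R, R)
        proj = R.T @ y_res
        rss_old = float(y_res @ y_res)
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(rn2 > scale2 * 1e-10, proj**2 / rn2, 0.0)
        gain[in_model] = 0.0
        dof = n - len(selected) - 1
        if dof <= 0:
            break
        rss_new = np.maximum(rss_old - gain, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fstat = np.where(rss_new > 0, gain / (rss_new / dof), np.inf)
        pvals = stats.f.sf(fstat, 1, dof)
        pvals[in_model] = 1.0
        best = int(np.argmin(pvals))
        if pvals[best] >= p_enter:
            if iteration == 0:
                raise ModelGenerationError(
                    "no feature reached the inclusion threshold on the first step"
                )
            break
        selected.append(best)
        in_model[best] = True
        q = R[:, best] / np.linalg.norm(R[:, best])
        R -= np.outer(q, q @ R)
        y_res -= q * (q @ y_res)

        # ---- backward step: drop features above the removal threshold -----
        removed = False
        while len(selected) > 1:
            _, p_in, _ = _refit_stats(X, y, selected)
            worst = int(np.argmax(p_in))
            if p_in[worst] <= p_remove:
                break
            in_model[selected[worst]] = False
            del selected[worst]
            removed = True
        if removed:
            _rebuild()
    else:
        iteration = max_iter - 1

    w, _, _ = _refit_stats(X, y, selected)
    return ClassifierModel(
        selected=selected,
        weights=w,
        p_enter=p_enter,
        p_remove=p_remove,
        n_iterations=iteration + 1,
        feature_index=list(features.feature_index),
    )


def score(model: ClassifierModel, features: FeatureMatrix) -> np.ndarray:
    """Per-trial linear score (weighted sum over selected features, no bias,
    no threshold)."""
    if features.n_features != len(model.feature_index):
        raise ValueError("feature space does not match the trained model")
    for i in model.selected:
        if features.feature_index[i] != model.feature_index[i]:
            raise ValueError("feature space does not match the trained model")
    return features.values[:, model.selected] @ model.weights


def select_letter(
    scores: np.ndarray,
    events: list[StimulusEvent],
    n_reps: int,
    n_rows: int = 5,
    n_cols: int = 5,
) -> tuple[int, int, str]:
    """Row/column selection from per-stimulus scores.

    Sums scores over the first ``n_reps`` sequences separately per row and
    per column; the arg-max row and column (ties toward the lower index)
    define the letter in the 5x5 matrix.
    """
    if len(scores) != len(events):
        raise ValueError("one score per event required")
    row_scores = np.zeros(n_rows)
    col_scores = np.zeros(n_cols)
    row_seen = np.zeros(n_rows, dtype=int)
    col_seen = np.zeros(n_cols, dtype=int)
    for s, e in zip(scores, events):
        if e.sequence_index >= n_reps:
            continue
        if e.kind.startswith("row"):
            row_scores[e.stimulus_index] += s
            row_seen[e.stimulus_index] += 1
        elif e.kind.startswith("col"):
            col_scores[e.stimulus_index] += s
            col_seen[e.stimulus_index] += 1
    if (row_seen < n_reps).any() or (col_seen < n_reps).any():
        raise ValueError("events do not cover every row and column for n_reps sequences")
    row = int(np.argmax(row_scores))
    col = int(np.argmax(col_scores))
    return row, col, MATRIX_LETTERS[row * n_cols + col]
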