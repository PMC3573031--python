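"""Grand averages, target/non-target difference maps, sequential
N200/P300/late-component peak detection, and group statistics.

Peak detection follows the sequential rule of the analysis: the P300 is
located first (maximum at Cz between 250 and 700 ms), the N200 is the
minimum at Cz before the P300 latency, and the late component the maximum
at POz after it.  Latencies sit on the sample grid (2 ms at 500 Hz), no
sub-sample fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import EpochSet

__all__ = [
    "average_erp",
    "difference_map",
    "ErpFeatures",
    "detect_components",
    "TTestResult",
    "paired_ttest",
    "independent_ttest",
]


def average_erp(epochs: EpochSet, which: str = "target") -> np.ndarray:
    """Arithmetic mean over the epochs of one class (channels x samples)."""
    if which not in ("target", "nontarget"):
        raise ValueError(f"unknown class: {which!r}")
    mask = epochs.is_target if which == "target" else ~epochs.is_target
    if not mask.any():
        raise ValueError(f"no {which} epochs to average")
    return epochs.data[mask].mean(axis=0)


def difference_map(target_avg: np.ndarray, nontarget_avg: np.ndarray) -> np.ndarray:
    """Elementwise target minus non-target (channels x samples, µV)."""
    if target_avg.shape != nontarget_avg.shape:
        raise ValueError("averages must have matching shapes")
    return target_avg - nontarget_avg


@dataclass
class ErpFeatures:
    """Component peaks of one participant's target ERP."""

    n200_amp_uV: float
    n200_lat_ms: float
    p300_amp_uV: float
    p300_lat_ms: float
    late_amp_uV: float
    late_lat_ms: float
    degenerate: bool = False


def detect_components(
    target_avg: np.ndarray,
    channel_labels: list[str],
    sampling_rate: float,
    window_start_ms: float = 0.0,
    p300_window_ms: tuple[float, float] = (250.0, 700.0),
    n200_floor_ms: float = 0.0,
    p300_channel: str = "Cz",
    late_channel: str = "POz",
) -> ErpFeatures:
    """Sequential peak detection on an averaged target waveform.

    P300 = maximum of the Cz trace within [250, 700] ms; N200 = minimum of
    Cz in [floor, P300 latency); late = maximum of POz in (P300 latency,
    epoch end].  A P300 at the very start of its window leaves no N200
    search range; the entry is then flagged degenerate (N200 falls back to
    the P300 sample).
    """
    times = window_start_ms + np.arange(target_avg.shape[1]) * 1000.0 / sampling_rate
    cz = target_avg[channel_labels.index(p300_channel)]
    poz = target_avg[channel_labels.index(late_channel)]

    p3_mask = (times >= p300_window_ms[0]) & (times <= p300_window_ms[1])
    if not p3_mask.any():
        raise ValueError("waveform does not cover the P300 search window")
    p3_idx = np.flatnonzero(p3_mask)[np.argmax(cz[p3_mask])]
    p3_amp, p3_lat = float(cz[p3_idx]), float(times[p3_idx])

    degenerate = False
    n2_mask = (times >= n200_floor_ms) & (times < p3_lat)
    if n2_mask.any():
        n2_idx = np.flatnonzero(n2_mask)[np.argmin(cz[n2_mask])]
    else:
        degenerate = True
        n2_idx = p3_idx
    n2_amp, n2_lat = float(cz[n2_idx]), float(times[n2_idx])

    late_mask = times > p3_lat
    if late_mask.any():
        late_idx = np.flatnonzero(late_mask)[np.argmax(poz[late_mask])]
    else:
        degenerate = True
        late_idx = p3_idx
    late_amp, late_lat = float(poz[late_idx]), float(times[late_idx])

    if p3_amp == 0.0 and n2_amp == 0.0 and late_amp == 0.0:
        degenerate = True
    return ErpFeatures(
        n200_amp_uV=n2_amp, n200_lat_ms=n2_lat,
        p300_amp_uV=p3_amp, p300_lat_ms=p3_lat,
        late_amp_uV=late_amp, late_lat_ms=late_lat,
        degenerate=degenerate,
    )


@dataclass
class TTestResult:
    t: float
    dof: float
    p: float


def paired_ttest(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Two-sided t-test for dependent samples, aligned by participant.

    A zero-variance difference vector (identical inputs) is reported as
    t = 0, p = 1 rather than NaN.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired test needs two aligned vectors of length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        t = 0.0 if np.allclose(d.mean(), 0.0) else np.inf
        return TTestResult(t=t, dof=a.size - 1, p=1.0 if t == 0.0 else 0.0)
    res = stats.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), dof=a.size - 1, p=float(res.pvalue))


def independent_ttest(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Two-sided pooled-variance t-test for independent groups."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(res.statistic), dof=a.size + b.size - 2, p=float(res.pvalue))
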