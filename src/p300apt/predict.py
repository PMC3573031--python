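"""Aptitude prediction from oddball ERPs.

Median split into high/low aptitude groups, channel x time Spearman
correlation maps between oddball deviant amplitudes and BCI performance
(reported as signed r^2 = sign(rho) * rho^2), and component-level rank
correlations with performance.

Sign convention: the performance metric is the number of sequences needed
to reach 70% accuracy, so *lower is better* and a positive correlation
means higher amplitude goes with worse performance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .erp import ErpFeatures, average_erp, detect_components
from .preprocess import EpochSet
from .swlda import featurize

__all__ = [
    "median_split",
    "CorrelationMap",
    "spearman_map",
    "component_correlations",
    "extract_oddball_amplitude_features",
]

logger = logging.getLogger(__name__)


def median_split(performance: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    """Label participants 'high' / 'low' aptitude at the median.

    Values at or below the median (fewer repetitions = better) are the high
    aptitude group.  ``basis`` may supply a different splitting variable
    (e.g. the mean of the visual and auditory metrics) while ``performance``
    carries the participants; if omitted, performance itself is used.
    """
    values = np.asarray(performance if basis is None else basis, dtype=float)
    if values.size < 2:
        raise ValueError("median split needs at least 2 participants")
    if np.allclose(values, values[0]):
        raise ValueError("all performance values identical; split undefined")
    med = np.median(values)
    return np.where(values <= med, "high", "low")


@dataclass
class CorrelationMap:
    """Per channel x time-bin rank correlation with performance."""

    rho: np.ndarray
    signed_r2: np.ndarray
    p: np.ndarray
    channel_labels: list[str]
    bin_centers_ms: np.ndarray
    performance_definition: str = "sequences to 70%"

    def extrema(self) -> dict:
        """Locations and values of the strongest positive and negative rho."""
        out = {}
        for name, arg in (("max", np.nanargmax), ("min", np.nanargmin)):
            c, b = np.unravel_index(arg(self.rho), self.rho.shape)
            out[name] = {
                "rho": float(self.rho[c, b]),
                "signed_r2": float(self.signed_r2[c, b]),
                "p": float(self.p[c, b]),
                "channel": self.channel_labels[c],
                "time_ms": float(self.bin_centers_ms[b]),
            }
        return out

    def adjusted_p(self) -> np.ndarray:
        """Benjamini-Hochberg adjusted p-values over the whole grid.

        An optional extension: the canonical analysis reports raw p-values
        per cell, so this layer is never applied implicitly.
        """
        flat = self.p.ravel()
        ok = np.isfinite(flat)
        out = np.full_like(flat, np.nan)
        out[ok] = stats.false_discovery_control(flat[ok], method="bh")
        return out.reshape(self.p.shape)

    def to_frame(self) -> pd.DataFrame:
        ch = np.repeat(self.channel_labels, len(self.bin_centers_ms))
        t = np.tile(self.bin_centers_ms, len(self.channel_labels))
        return pd.DataFrame(
            {
                "channel": ch,
                "bin_center_ms": t,
                "rho": self.rho.ravel(),
                "signed_r2": self.signed_r2.ravel(),
                "p": self.p.ravel(),
            }
        )


def _rank(x: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, axis, x)


def spearman_map(
    amplitudes: np.ndarray,
    performance: np.ndarray,
    channel_labels: list[str],
    bin_centers_ms: np.ndarray,
) -> CorrelationMap:
    """Spearman rho / signed r^2 / p per channel x time cell.

    ``amplitudes`` is participants x channels x bins (deviant-average
    amplitudes); ``performance`` the per-participant repetitions-to-criterion
    (not-reached sentinels enter at their sentinel rank).  Mid-ranks handle
    ties; p-values use the t approximation (as scipy's spearmanr does).
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    performance = np.asarray(performance, dtype=float)
    n = amplitudes.shape[0]
    if n < 4:
        raise ValueError("need at least 4 participants")
    if performance.shape != (n,):
        raise ValueError("one performance value per participant required")
    if np.allclose(performance, performance[0]):
        raise ValueError("performance vector is constant; correlation undefined")

    ra = _rank(amplitudes.reshape(n, -1), axis=0)
    rp = stats.rankdata(performance)[:, None]
    ra_c = ra - ra.mean(axis=0)
    rp_c = rp - rp.mean()
    denom = np.sqrt((ra_c**2).sum(axis=0) * (rp_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra_c * rp_c).sum(axis=0) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.isinf(t)] = 0.0
    shape = amplitudes.shape[1:]
    return CorrelationMap(
        rho=rho.reshape(shape),
        signed_r2=(np.sign(rho) * rho**2).reshape(shape),
        p=p.reshape(shape),
        channel_labels=list(channel_labels),
        bin_centers_ms=np.asarray(bin_centers_ms, dtype=float),
    )


_COMPONENT_COLUMNS = {
    ("N200", "amplitude"): "n200_amp_uV",
    ("N200", "latency"): "n200_lat_ms",
    ("P300", "amplitude"): "p300_amp_uV",
    ("P300", "latency"): "p300_lat_ms",
    ("late", "amplitude"): "late_amp_uV",
    ("late", "latency"): "late_lat_ms",
}


def component_correlations(
    features: pd.DataFrame,
    performance: pd.DataFrame,
) -> pd.DataFrame:
    """Rank correlations of each component measure with performance.

    ``features`` holds one row per participant with the ErpFeatures columns;
    ``performance`` has columns (participant_id, modality, reps_to_criterion).
    Returns tidy rows (component, measure, modality, rho, p, n) mirroring the
    published table layout.  Participants missing from either side are
    dropped with a log message.
    """
    rows = []
    for modality, perf in performance.groupby("modality"):
        merged = features.merge(perf, on="participant_id", how="inner")
        dropped = len(features) - len(merged)
        if dropped:
            logger.info("%s: dropped %d participant(s) without both measures", modality, dropped)
        for (component, measure), col in _COMPONENT_COLUMNS.items():
            rho, p = stats.spearmanr(merged[col], merged["reps_to_criterion"])
            rows.append(
                {
                    "component": component,
                    "measure": measure,
                    "modality": modality,
                    "rho": float(rho),
                    "p": float(p),
                    "n": len(merged),
                }
            )
    return pd.DataFrame(rows)


def extract_oddball_amplitude_features(
    epochs: EpochSet,
    reduce: str = "raw_grid",
    decim: int = 25,
):
    """Features of one participant's preprocessed oddball epochs.

    ``raw_grid``: the deviant-epoch average binned like the classifier's
    features (channels x bins).  ``component_peaks``: the sequential
    N200/P300/late detection (an :class:`~p300apt.erp.ErpFeatures`).
    """
    deviants = epochs.subset(epochs.is_target)
    if deviants.n_epochs == 0:
        raise ValueError("no deviant epochs present")
    if reduce == "raw_grid":
        fm = featurize(deviants, ma_width=decim, decim=decim)
        n_bins = len({i[1] for i in fm.feature_index})
        grid = fm.values.mean(axis=0).reshape(len(epochs.channel_labels), n_bins)
        centers = np.array(
            [ms for (_, b, ms) in fm.feature_index[:n_bins]]
        )
        return grid, centers
    if reduce == "component_peaks":
        avg = average_erp(epochs, "target")
        return detect_components(
            avg, epochs.channel_labels, epochs.sampling_rate,
            window_start_ms=epochs.window_ms[0],
        )
    raise ValueError(f"unknown reduction: {reduce!r}")
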