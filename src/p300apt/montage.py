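"""Electrode montages and approximate 2-D scalp geometry.

The full montage is the 63-channel EEG layout of the study setup (modified
10-20 system) plus four periocular EOG electrodes (vertical pair above/below
the right eye, horizontal pair at the outer canthi).  2-D positions are an
azimuthal-equidistant projection of the standard 10-05 electrode positions
shipped with mne; they are only used to build smooth spatial component maps
for the simulator, not for source analysis.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: 63 EEG labels in recording order.
EEG_LABELS_63: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FT9", "FT7",
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10", "T7",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8", "TP9", "TP7",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10", "P9",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO5", "PO1", "POz", "PO6", "PO2", "PO8", "O1", "Oz", "O2",
    "O9", "Iz", "O10",
)

#: A sparse 16-channel subset covering the midline and the lateral sites the
#: analysis refers to; used for fast, scaled-down simulations.
EEG_LABELS_16: tuple[str, ...] = (
    "Fpz", "Fz", "FC5", "FCz", "FC6", "C3", "Cz", "C2",
    "CPz", "P3", "Pz", "P4", "PO7", "POz", "PO2", "Oz",
)

#: An 8-channel midline-heavy subset for the cheapest replicate studies.
EEG_LABELS_8: tuple[str, ...] = ("Fz", "FCz", "Cz", "C3", "CPz", "Pz", "POz", "Oz")

#: Periocular channels: vertical pair (upper/lower right eye), horizontal
#: pair (left/right outer canthus).
EOG_LABELS: tuple[str, ...] = ("EOGvu", "EOGvl", "EOGhl", "EOGhr")

MONTAGES: dict[str, tuple[str, ...]] = {
    "full63": EEG_LABELS_63,
    "sparse16": EEG_LABELS_16,
    "midline8": EEG_LABELS_8,
}

# 10-05 names for labels the recording setup spells differently.
_ALIASES = {"O9": "I1", "O10": "I2"}


@lru_cache(maxsize=1)
def _standard_positions() -> dict[str, np.ndarray]:
    import mne  # deferred: mne import is slow

    montage = mne.channels.make_standard_montage("colin27_1005")
    return {k: np.asarray(v, dtype=float) for k, v in montage.get_positions()["ch_pos"].items()}


@lru_cache(maxsize=8)
def positions_2d(labels: tuple[str, ...]) -> np.ndarray:
    """Project electrode positions onto the plane.

    Azimuthal-equidistant projection: each unit position vector maps to
    ``theta * (cos phi, sin phi)`` where ``theta`` is the polar angle from the
    vertex and ``phi`` the azimuth.  Distances from the vertex are therefore
    in radians (the ear line sits near 1.57).

    Parameters
    ----------
    labels
        EEG channel labels (must exist in the 10-05 nomenclature, up to the
        O9/O10 aliases).

    Returns
    -------
    (n_channels, 2) array of projected coordinates.
    """
    pos = _standard_positions()
    out = np.empty((len(labels), 2))
    for i, label in enumerate(labels):
        p = pos[_ALIASES.get(label, label)]
        r = np.linalg.norm(p)
        theta = np.arccos(np.clip(p[2] / r, -1.0, 1.0))
        phi = np.arctan2(p[1], p[0])
        out[i] = theta * np.cos(phi), theta * np.sin(phi)
    return out


def late_slow_wave_map(labels: tuple[str, ...], sigma: float = 0.8) -> np.ndarray:
    """Anterior-negative / posterior-positive slow-wave topography.

    A posterior (POz) Gaussian minus a frontal (Fz) Gaussian, with the
    frontal gain chosen per montage so that the *common-average-referenced*
    projection at Cz vanishes: the slow wave's sign flip sits at the vertex,
    which is why the analysis measures it at POz while the P300 is measured
    at Cz.  Normalised to unit maximum absolute weight.
    """
    xy = positions_2d(tuple(labels))
    post = positions_2d(("POz",))[0]
    front = positions_2d(("Fz",))[0]
    cz = list(labels).index("Cz")
    g_p = np.exp(-np.sum((xy - post) ** 2, axis=1) / (2.0 * sigma**2))
    g_f = np.exp(-np.sum((xy - front) ** 2, axis=1) / (2.0 * sigma**2))
    denom = g_f[cz] - g_f.mean()
    gain = (g_p[cz] - g_p.mean()) / denom if abs(denom) > 1e-12 else 1.0
    w = g_p - gain * g_f
    return w / np.max(np.abs(w))


def spatial_map(
    labels: tuple[str, ...],
    center: str,
    sigma: float = 0.8,
    anti_center: str | None = None,
    anti_gain: float = 0.0,
) -> np.ndarray:
    """Smooth spatial weighting for a component topography.

    A Gaussian bump (scale ``sigma`` radians) around ``center``, optionally
    minus ``anti_gain`` times a bump around ``anti_center`` (used for the
    anterior-negative/posterior-positive late slow wave).  The result is
    normalised to unit maximum absolute weight.
    """
    xy = positions_2d(tuple(labels))
    c = positions_2d((center,))[0]  # center need not be part of the montage
    w = np.exp(-np.sum((xy - c) ** 2, axis=1) / (2.0 * sigma**2))
    if anti_center is not None and anti_gain != 0.0:
        a = positions_2d((anti_center,))[0]
        w = w - anti_gain * np.exp(-np.sum((xy - a) ** 2, axis=1) / (2.0 * sigma**2))
    return w / np.max(np.abs(w))

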