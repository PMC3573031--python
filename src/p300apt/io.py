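"""Recording and epoch I/O.

Continuous recordings are written as EDF (16-bit, physical units µV) with a
JSON event sidecar.  The EDF writer is a minimal, self-contained
implementation of the fixed-layout EDF header + int16 data records; reading
goes through mne's EDF reader, which doubles as an independent check of the
writer.  Epoch sets round-trip through a compact ``.npz`` archive with a
JSON manifest embedded.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np

from .preprocess import EpochSet
from .recording import ContinuousRecording, StimulusEvent

__all__ = ["write_recording", "read_recording", "save_epochs", "load_epochs"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r}")
    return s.ljust(width).encode("ascii")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".events.json")


def write_recording(recording: ContinuousRecording, path: str | os.PathLike) -> None:
    """Write an EDF file plus the ``<name>.edf.events.json`` sidecar.

    Samples are quantized to 16 bits over a per-channel symmetric physical
    range; the sidecar stores the events, channel roles, reference and the
    exact sample count (the final EDF record is zero-padded).
    """
    path = Path(path)
    fs = recording.sampling_rate
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    data = recording.data
    n_ch, n_samples = data.shape
    n_records = int(np.ceil(n_samples / spr))

    pmax = np.maximum(np.abs(data).max(axis=1) * 1.001, 0.01)
    pmax = np.array([float(f"{v:.4g}") for v in pmax])
    scale = (2.0 * pmax) / (_DIG_MAX - _DIG_MIN)
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_samples] = data
    # EDF affine map: physical = pmin + (digital - dmin) * step
    digital = np.clip(
        np.round((padded + pmax[:, None]) / scale[:, None]) + _DIG_MIN,
        _DIG_MIN,
        _DIG_MAX,
    ).astype("<i2")

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X", 80),
            _ascii("synthetic EEG session", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (n_ch + 1), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),
            _ascii(n_ch, 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_ascii(lbl, 16) for lbl in recording.channel_labels),
            b"".join(_ascii("AgAgCl electrode", 80) for _ in range(n_ch)),
            b"".join(_ascii("uV", 8) for _ in range(n_ch)),
            b"".join(_ascii(f"{-v:.4g}", 8) for v in pmax),
            b"".join(_ascii(f"{v:.4g}", 8) for v in pmax),
            b"".join(_ascii(_DIG_MIN, 8) for _ in range(n_ch)),
            b"".join(_ascii(_DIG_MAX, 8) for _ in range(n_ch)),
            b"".join(_ascii("", 80) for _ in range(n_ch)),
            b"".join(_ascii(spr, 8) for _ in range(n_ch)),
            b"".join(_ascii("", 32) for _ in range(n_ch)),
        ]
    )
    records = digital.reshape(n_ch, n_records, spr).transpose(1, 0, 2)

    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        fh.write(records.tobytes())
    os.replace(tmp, path)

    sidecar = {
        "sampling_rate": fs,
        "n_samples": int(n_samples),
        "reference": recording.reference,
        "channel_labels": list(recording.channel_labels),
        "channel_roles": list(recording.channel_roles),
        "events": [e.to_dict() for e in recording.events],
    }
    tmp = Path(str(_sidecar_path(path)) + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(sidecar, fh, indent=1)
    os.replace(tmp, _sidecar_path(path))


def read_recording(path: str | os.PathLike) -> ContinuousRecording:
    """Read an EDF file with its JSON event sidecar back into a recording."""
    import mne  # deferred: slow import

    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing event sidecar: {sidecar_file}")
    with open(sidecar_file) as fh:
        meta = json.load(fh)

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"could not parse EDF file {path}: {exc}") from exc
    if list(raw.ch_names) != list(meta["channel_labels"]):
        raise ValueError("EDF channel labels do not match the event sidecar")
    data = raw.get_data() * 1e6  # mne loads EEG in volts
    data = data[:, : meta["n_samples"]]
    return ContinuousRecording(
        data=data,
        sampling_rate=float(meta["sampling_rate"]),
        channel_labels=list(meta["channel_labels"]),
        channel_roles=list(meta["channel_roles"]),
        events=[StimulusEvent.from_dict(d) for d in meta["events"]],
        reference=meta["reference"],
    )


def save_epochs(epochs: EpochSet, path: str | os.PathLike) -> None:
    """Compact binary archive (.npz) with an embedded JSON manifest."""
    manifest = {
        "sampling_rate": epochs.sampling_rate,
        "channel_labels": list(epochs.channel_labels),
        "window_ms": list(epochs.window_ms),
        "baseline_ms": list(epochs.baseline_ms),
        "events": [e.to_dict() for e in epochs.events],
    }
    np.savez_compressed(path, data=epochs.data, manifest=json.dumps(manifest))


def load_epochs(path: str | os.PathLike) -> EpochSet:
    with np.load(path, allow_pickle=False) as archive:
        data = archive["data"]
        manifest = json.loads(str(archive["manifest"]))
    return EpochSet(
        data=data,
        events=[StimulusEvent.from_dict(d) for d in manifest["events"]],
        sampling_rate=float(manifest["sampling_rate"]),
        channel_labels=list(manifest["channel_labels"]),
        window_ms=tuple(manifest["window_ms"]),
        baseline_ms=tuple(manifest["baseline_ms"]),
    )
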