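"""Reading and writing recordings: EDF and a plain array fixture format.

EDF files are read through :mod:`mne`.  Writing uses a small built-in EDF
writer (16-bit samples, one-second data records, per-channel physical
scaling) so that synthetic recordings can round-trip through the standard
reader.  The fixture format is a NumPy ``.npz`` bundle with a JSON metadata
entry — lossless and convenient for intermediate results.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np

from .recording import MultichannelRecording, _duplicates

__all__ = ["read_recording", "write_edf", "write_fixture", "read_fixture"]

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: MultichannelRecording, path: str | Path) -> Path:
    """Write a recording as EDF (µV physical units, 1-second data records).

    The sampling rate must be a positive integer and the recording an integer
    number of seconds long, so that data records tile the signal exactly.
    Amplitudes are quantized to 16 bits over each channel's physical range.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per 1 s record
    if rec.n_samples % spr != 0:
        raise ValueError(
            "EDF writer requires a whole number of seconds "
            f"({rec.n_samples} samples at {spr} Hz)"
        )
    n_records = rec.n_samples // spr
    n_sig = rec.n_channels

    pmins = rec.data.min(axis=1)
    pmaxs = rec.data.max(axis=1)
    flat = pmaxs - pmins < 1e-12
    pmins[flat] -= 1.0
    pmaxs[flat] += 1.0

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad(f"Startdate X X X X state:{rec.state_label or 'X'}", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (1 + n_sig)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_sig), 4),
        ]
    )
    fields = [
        ("".join(_pad(lab, 16).decode() for lab in rec.channel_labels), 16),
        ("".join(_pad("", 80).decode() for _ in range(n_sig)), 80),
        ("".join(_pad("uV", 8).decode() for _ in range(n_sig)), 8),
        ("".join(_pad(f"{pmins[i]:.6g}"[:8], 8).decode() for i in range(n_sig)), 8),
        ("".join(_pad(f"{pmaxs[i]:.6g}"[:8], 8).decode() for i in range(n_sig)), 8),
        ("".join(_pad(str(_EDF_DIG_MIN), 8).decode() for _ in range(n_sig)), 8),
        ("".join(_pad(str(_EDF_DIG_MAX), 8).decode() for _ in range(n_sig)), 8),
        ("".join(_pad("", 80).decode() for _ in range(n_sig)), 80),
        ("".join(_pad(str(spr), 8).decode() for _ in range(n_sig)), 8),
        ("".join(_pad("", 32).decode() for _ in range(n_sig)), 32),
    ]
    sig_header = b"".join(f[0].encode("ascii") for f in fields)

    # The stated physical min/max (8 ASCII chars) must match the scaling used
    # for quantization, otherwise read-back values shift; re-parse them.
    pmins_w = np.array([float(f"{pmins[i]:.6g}"[:8]) for i in range(n_sig)])
    pmaxs_w = np.array([float(f"{pmaxs[i]:.6g}"[:8]) for i in range(n_sig)])
    pmaxs_w = np.maximum(pmaxs_w, pmins_w + 1e-9)

    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmaxs_w - pmins_w)
    digital = np.rint(
        (np.clip(rec.data.T, pmins_w, pmaxs_w) - pmins_w) * scale + _EDF_DIG_MIN
    ).astype("<i2")  # (n_samples, n_sig)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            block = digital[r * spr : (r + 1) * spr]  # (spr, n_sig)
            fh.write(block.T.tobytes())
    return path


def _edf_header_fields(path: Path) -> tuple[list[str], str]:
    """Channel labels and recording-id string straight from the EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        try:
            n_sig = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise ValueError(f"{path}: unreadable EDF header") from exc
        recording_id = head[88:168].decode("ascii", "replace").strip()
        raw = fh.read(16 * n_sig)
    labels = [raw[i * 16 : (i + 1) * 16].decode("ascii", "replace").strip() for i in range(n_sig)]
    return labels, recording_id


def _read_edf(path: Path) -> MultichannelRecording:
    import mne

    labels, recording_id = _edf_header_fields(path)
    dupes = _duplicates(labels)
    if dupes:
        raise ValueError(f"{path}: duplicate channel labels: {sorted(dupes)}")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne holds EEG in volts; recordings are in µV
    state = None
    if "state:" in recording_id:
        state = recording_id.split("state:", 1)[1].split()[0]
        state = None if state == "X" else state
    return MultichannelRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        state_label=state,
    )


def write_fixture(rec: MultichannelRecording, path: str | Path) -> Path:
    """Write the lossless ``.npz`` fixture bundle (data + JSON metadata)."""
    path = Path(path)
    meta = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "state_label": rec.state_label,
    }
    np.savez_compressed(path, data=rec.data, meta=np.array(json.dumps(meta)))
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_fixture(path: str | Path) -> MultichannelRecording:
    path = Path(path)
    with np.load(path, allow_pickle=False) as bundle:
        if "data" not in bundle or "meta" not in bundle:
            raise ValueError(f"{path}: not a recording fixture (missing data/meta)")
        data = bundle["data"]
        meta = json.loads(str(bundle["meta"]))
    labels = meta["channel_labels"]
    dupes = _duplicates(labels)
    if dupes:
        raise ValueError(f"{path}: duplicate channel labels: {sorted(dupes)}")
    return MultichannelRecording(
        data=data,
        fs=float(meta["fs"]),
        channel_labels=labels,
        state_label=meta.get("state_label"),
    )


def read_recording(path: str | Path, format: str | None = None) -> MultichannelRecording:
    """Read a recording from EDF or the fixture format.

    ``format`` may be ``"edf"`` or ``"fixture"``; when omitted it is inferred
    from the file extension.  Channel order is preserved from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix == ".edf":
            format = "edf"
        elif suffix == ".npz":
            format = "fixture"
        else:
            raise ValueError(f"cannot infer format from extension {suffix!r}")
    if format == "edf":
        return _read_edf(path)
    if format == "fixture":
        return read_fixture(path)
    raise ValueError(f"unknown format {format!r} (expected 'edf' or 'fixture')")
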