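"""EDF reading and writing for EEG recordings.

Reading goes through MNE's EDF/EDF+ reader with optional channel-label
normalization (clinical systems often export labels like "EEG Fp1-Ref").
Writing uses a small self-contained EDF writer: fixed-format ASCII header,
16-bit little-endian samples, one-second data records, amplitudes in
microvolts. Sub-second trailing data is dropped on write (EDF stores an
integer number of records); quantization to the 16-bit range bounds the
round-trip error by (physical range)/65535 per sample.
"""

from __future__ import annotations

import math
import re
from pathlib import Path

import numpy as np

from .recording import EEGRecording, ELECTRODES_1020

_1020_BY_LOWER = {e.lower(): e for e in ELECTRODES_1020}


def _fixed(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def _num(value: float, width: int) -> bytes:
    for p in range(width - 2, -1, -1):
        s = f"{value:.{p}f}" if p else f"{value:.0f}"
        if len(s) <= width:
            return _fixed(s, width)
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(recording: EEGRecording, path: str | Path) -> Path:
    """Write a recording to EDF (one-second records, int16 samples)."""
    path = Path(path)
    fs = recording.fs
    if not math.isclose(fs, round(fs)):
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per (1-s) record per channel
    n_records = recording.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    nch = recording.n_channels
    data = recording.data[:, : n_records * spr]

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-6
    pmin = np.where(flat, pmin - 1.0, pmin)
    pmax = np.where(flat, pmax + 1.0, pmax)
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin[:, None]) * gain[:, None] + dmin).astype("<i2")

    with open(path, "wb") as f:
        f.write(_fixed("0", 8))
        f.write(_fixed(f"subject {recording.subject_id}", 80))
        f.write(_fixed("eegsync synthetic recording", 80))
        f.write(_fixed("01.01.00", 8))
        f.write(_fixed("00.00.00", 8))
        f.write(_fixed(str(256 * (nch + 1)), 8))
        f.write(_fixed("", 44))
        f.write(_fixed(str(n_records), 8))
        f.write(_fixed("1", 8))
        f.write(_fixed(str(nch), 4))
        for lab in recording.channel_labels:
            f.write(_fixed(f"EEG {lab}"[:16], 16))
        for _ in range(nch):
            f.write(_fixed("", 80))  # transducer
        for _ in range(nch):
            f.write(_fixed("uV", 8))
        for v in pmin:
            f.write(_num(float(v), 8))
        for v in pmax:
            f.write(_num(float(v), 8))
        for _ in range(nch):
            f.write(_fixed(str(dmin), 8))
        for _ in range(nch):
            f.write(_fixed(str(dmax), 8))
        for _ in range(nch):
            f.write(_fixed("", 80))  # prefiltering
        for _ in range(nch):
            f.write(_fixed(str(spr), 8))
        for _ in range(nch):
            f.write(_fixed("", 32))
        for r in range(n_records):
            f.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    return path


def normalize_label(raw: str, label_map: dict[str, str] | None = None) -> str | None:
    """Map an exported channel label to its bare 10-20 electrode name.

    An explicit ``label_map`` wins; otherwise common decorations
    ("EEG Fp1-Ref", "FP1-A1", case differences) are stripped. Returns
    None when no 10-20 electrode can be recognized.
    """
    if label_map and raw in label_map:
        return label_map[raw]
    s = re.sub(r"^EEG[ _]*", "", raw.strip(), flags=re.IGNORECASE)
    s = re.split(r"[-_ ]", s)[0]
    return _1020_BY_LOWER.get(s.lower())


def read_edf(
    path: str | Path,
    label_map: dict[str, str] | None = None,
    require_1020: bool = True,
) -> EEGRecording:
    """Read an EDF/EDF+ file into an :class:`EEGRecording` (microvolts).

    Channels whose labels normalize to 10-20 electrode names are kept
    under the bare names; others are retained as-is unless
    ``require_1020`` and none match, which is an error. Mismatched
    per-channel rates are resampled by MNE to the highest rate.
    """
    import mne

    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FileNotFoundError(f"EDF file missing or empty: {path}")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels, keep = [], []
    for i, ch in enumerate(raw.ch_names):
        norm = normalize_label(ch, label_map)
        if norm is not None:
            labels.append(norm)
            keep.append(i)
    if not labels:
        if require_1020:
            raise ValueError(f"no recognizable 10-20 channel labels in {path}")
        labels = list(raw.ch_names)
        keep = list(range(len(labels)))
    data = raw.get_data(picks=keep, units="uV")
    return EEGRecording(
        subject_id=path.stem,
        channel_labels=labels,
        fs=float(raw.info["sfreq"]),
        data=data,
    )
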