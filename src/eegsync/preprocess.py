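"""Preprocessing: resampling, bipolar montage, 2-s epoching, artifact
screening and zero-phase band-pass filtering.

The chain mirrors routine clinical EEG practice: signals are brought to a
common sampling rate (500 Hz by default), re-referenced to a longitudinal
bipolar montage, cut into short contiguous epochs so the stationarity
assumption behind phase estimation is plausible, screened for gross
artifacts, and band-pass filtered with a zero-phase filter. Zero-phase
filtering is non-negotiable here: any phase distortion introduced by the
filter would contaminate the phase-synchronization metrics downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

from .recording import (
    BandDefinition,
    EEGRecording,
    EpochSet,
    LONGITUDINAL_PAIRS,
    montage_channel_names,
    validate_band,
)

DEFAULT_EPOCH_LENGTH_S = 2.0
DEFAULT_AMPLITUDE_THRESHOLD_UV = 200.0
DEFAULT_FLATLINE_EPS_UV = 0.1


class InsufficientCleanDataError(RuntimeError):
    """Raised when artifact screening leaves no usable epochs."""


@dataclass
class PreprocessConfig:
    """Knobs of the preprocessing chain, with clinical-practice defaults."""

    target_fs: float = 500.0
    epoch_length_s: float = DEFAULT_EPOCH_LENGTH_S
    amplitude_threshold_uv: float = DEFAULT_AMPLITUDE_THRESHOLD_UV
    flatline_eps_uv: float = DEFAULT_FLATLINE_EPS_UV
    filter_order: int = 4
    #: "epoch" filters each 2-s epoch with reflective padding; "whole"
    #: filters the continuous record before epoching.
    filter_mode: str = "epoch"


def resample(recording: EEGRecording, target_fs: float, max_band_high: float | None = None) -> EEGRecording:
    """Polyphase-resample a recording to ``target_fs``.

    ``max_band_high`` (Hz), when given, guards against resampling below the
    Nyquist rate of the highest band to be analyzed.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if max_band_high is not None and target_fs <= 2 * max_band_high:
        raise ValueError(
            f"target_fs {target_fs} Hz is not above twice the highest band edge {max_band_high} Hz"
        )
    if math.isclose(target_fs, recording.fs):
        return recording
    ratio = Fraction(target_fs / recording.fs).limit_denominator(1000)
    data = signal.resample_poly(recording.data, ratio.numerator, ratio.denominator, axis=1)
    return EEGRecording(
        subject_id=recording.subject_id,
        channel_labels=list(recording.channel_labels),
        fs=target_fs,
        data=data,
    )


def to_bipolar(
    recording: EEGRecording,
    montage_pairs: Sequence[tuple[str, str]] = LONGITUDINAL_PAIRS,
) -> EEGRecording:
    """Derive bipolar channels ``A-B = A - B`` in montage order."""
    rows = []
    for a, b in montage_pairs:
        for label in (a, b):
            if label not in recording.channel_labels:
                raise KeyError(f"montage electrode {label!r} not present in recording")
        rows.append(recording.channel(a) - recording.channel(b))
    out = EEGRecording(
        subject_id=recording.subject_id,
        channel_labels=montage_channel_names(montage_pairs),
        fs=recording.fs,
        data=np.vstack(rows),
    )
    return out


def segment_epochs(recording: EEGRecording, epoch_length_s: float = DEFAULT_EPOCH_LENGTH_S) -> EpochSet:
    """Cut contiguous non-overlapping epochs; a trailing partial epoch is
    discarded. Epoch k covers samples [k*L, (k+1)*L)."""
    L = int(round(epoch_length_s * recording.fs))
    if L <= 0:
        raise ValueError("epoch_length_s too short for this sampling rate")
    n_epochs = recording.n_samples // L
    if n_epochs < 1:
        raise ValueError(
            f"recording duration {recording.duration_s:.2f} s shorter than one "
            f"{epoch_length_s} s epoch"
        )
    trimmed = recording.data[:, : n_epochs * L]
    epochs = trimmed.reshape(recording.n_channels, n_epochs, L).transpose(1, 0, 2)
    return EpochSet(
        epochs=epochs.copy(),
        fs=recording.fs,
        epoch_length_s=epoch_length_s,
        channel_labels=list(recording.channel_labels),
    )


def reject_artifacts(
    epoch_set: EpochSet,
    amplitude_threshold_uv: float = DEFAULT_AMPLITUDE_THRESHOLD_UV,
    flatline_eps_uv: float = DEFAULT_FLATLINE_EPS_UV,
) -> EpochSet:
    """Drop epochs with extreme amplitudes or flat channels.

    A programmatic stand-in for visual artifact review: an epoch is
    rejected when any channel's peak absolute amplitude exceeds
    ``amplitude_threshold_uv`` (gross movement/electrode artifact) or any
    channel's range falls below ``flatline_eps_uv`` (disconnected lead).
    Kept epochs are passed through unmodified.
    """
    if amplitude_threshold_uv <= 0 or flatline_eps_uv <= 0:
        raise ValueError("thresholds must be positive")
    peak = np.abs(epoch_set.epochs).max(axis=2)  # (n_epochs, n_channels)
    rng_ = epoch_set.epochs.max(axis=2) - epoch_set.epochs.min(axis=2)
    too_big = peak > amplitude_threshold_uv
    too_flat = rng_ < flatline_eps_uv
    bad = (too_big | too_flat).any(axis=1)
    log = [
        {
            "epoch": int(i),
            "reason": "amplitude" if too_big[i].any() else "flatline",
            "channels": [epoch_set.channel_labels[c] for c in np.nonzero(too_big[i] | too_flat[i])[0]],
        }
        for i in np.nonzero(bad)[0]
    ]
    kept = epoch_set.epochs[~bad]
    if kept.shape[0] == 0:
        raise InsufficientCleanDataError(
            "every epoch was rejected by artifact screening; not enough clean data"
        )
    out = epoch_set.replace_epochs(kept)
    out.rejection_log = list(epoch_set.rejection_log) + log
    return out


def _sos(band: BandDefinition, fs: float, order: int) -> np.ndarray:
    return signal.butter(order, [band.low, band.high], btype="bandpass", fs=fs, output="sos")


def _filtfilt(data: np.ndarray, band: BandDefinition, fs: float, order: int) -> np.ndarray:
    sos = _sos(band, fs, order)
    # Reflective padding of at least three time constants of the slowest
    # edge, capped by the segment length.
    padlen = min(data.shape[-1] - 1, int(3 * fs / band.low))
    return signal.sosfiltfilt(sos, data, axis=-1, padlen=padlen)


def bandpass(epoch_set: EpochSet, band: BandDefinition, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass applied per epoch."""
    validate_band(band, epoch_set.fs)
    filtered = _filtfilt(epoch_set.epochs, band, epoch_set.fs, order)
    return epoch_set.replace_epochs(filtered, band=band)


def bandpass_recording(recording: EEGRecording, band: BandDefinition, order: int = 4) -> EEGRecording:
    """Zero-phase band-pass over the continuous record (filter-then-epoch mode)."""
    validate_band(band, recording.fs)
    return EEGRecording(
        subject_id=recording.subject_id,
        channel_labels=list(recording.channel_labels),
        fs=recording.fs,
        data=_filtfilt(recording.data, band, recording.fs, order),
    )


def preprocess(
    recording: EEGRecording,
    montage_pairs: Sequence[tuple[str, str]] | None = LONGITUDINAL_PAIRS,
    config: PreprocessConfig | None = None,
) -> EpochSet:
    """Full broadband chain: resample -> bipolar -> epoch -> artifact screen.

    Band-pass filtering is applied downstream per band (see
    :mod:`eegsync.connectivity`). ``montage_pairs=None`` skips the bipolar
    derivation and analyzes the referential channels directly.
    """
    cfg = config or PreprocessConfig()
    rec = resample(recording, cfg.target_fs)
    if montage_pairs is not None:
        rec = to_bipolar(rec, montage_pairs)
    epochs = segment_epochs(rec, cfg.epoch_length_s)
    if montage_pairs is not None:
        epochs.montage_pairs = tuple(montage_pairs)
    return reject_artifacts(epochs, cfg.amplitude_threshold_uv, cfg.flatline_eps_uv)
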