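"""Phase-synchronization metrics: PLV, PLI and wPLI.

All three metrics summarize the distribution of the instantaneous phase
difference between two narrowband signals, obtained from the analytic
signal (Hilbert transform):

* PLV (phase-locking value): modulus of the time-averaged unit phasor of
  the phase difference. 1 for a constant phase difference, 0 when the
  difference is uniform on (0, 2*pi). Sensitive to volume conduction,
  because a zero-lag common source produces a constant (zero) phase
  difference.
* PLI (phase lag index): absolute mean sign of the wrapped phase
  difference. It measures the *asymmetry* of the phase-difference
  distribution around zero, so zero-lag (and pi-lag) coupling — the
  signature of volume conduction — contributes nothing. 1 for a constant
  phase difference that is neither 0 nor pi.
* wPLI (weighted PLI): |E[Im S]| / E[|Im S|] with S the cross-spectrum
  a * conj(b). Weighting by the magnitude of the imaginary cross-spectrum
  de-emphasizes samples near the 0/pi discontinuity of the PLI sign
  function.

Conventions fixed here: phase differences are wrapped to (-pi, pi];
sign(0) = 0, so the PLI of a signal against itself is exactly 0; a wPLI
with an identically zero imaginary cross-spectrum (e.g. strict zero lag)
is degenerate and reported as 0 with a logged flag.

Metrics are estimated per 2-s epoch and averaged across epochs, then
across channel pairs (unweighted), yielding one "mean global" value per
metric per band — 18 features per subject over the six clinical bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .preprocess import (
    PreprocessConfig,
    bandpass,
    bandpass_recording,
    preprocess,
    resample,
    to_bipolar,
)
from .recording import (
    BANDS,
    BandDefinition,
    EEGRecording,
    EpochSet,
    FEATURE_BANDS,
    LONGITUDINAL_PAIRS,
    METRICS,
    sync_feature_names,
)

logger = logging.getLogger(__name__)

#: Fraction of samples trimmed from each end of an epoch's phase series
#: before metric computation, to suppress Hilbert edge artifacts.
DEFAULT_EDGE_TRIM = 0.10


@dataclass
class AnalyticEpoch:
    """Analytic signal of one (channels x samples) epoch."""

    analytic: np.ndarray
    degenerate_channels: list[int] = field(default_factory=list)

    @property
    def phase(self) -> np.ndarray:
        """Instantaneous phase in radians, wrapped to (-pi, pi]."""
        return np.angle(self.analytic)


@dataclass
class PairwiseConnectivity:
    """Symmetric pair-value matrix for one metric in one band."""

    metric: str
    band: str
    channel_labels: list[str]
    matrix: np.ndarray
    n_epochs_used: int

    def mean_global(self) -> float:
        """Unweighted mean over unordered off-diagonal pairs."""
        n = self.matrix.shape[0]
        iu = np.triu_indices(n, k=1)
        return float(np.mean(self.matrix[iu]))


@dataclass
class SyncFeatureVector:
    """The 18 global synchronization features of one subject."""

    subject_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        expected = sync_feature_names()
        if list(self.values.keys()) != expected:
            raise ValueError("sync feature names/order must be the canonical 18")
        for k, v in self.values.items():
            if not (-1e-9 <= v <= 1 + 1e-9):
                raise ValueError(f"feature {k} = {v} outside [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


def analytic_signal(epoch: np.ndarray) -> AnalyticEpoch:
    """Hilbert-transform analytic signal of a (channels x samples) epoch.

    The real part equals the input; the argument is the instantaneous
    phase. Channels that are identically zero have no defined phase and
    are flagged as degenerate.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[-1] == 0:
        raise ValueError("cannot take the analytic signal of a zero-length epoch")
    degenerate = [int(i) for i in np.nonzero(np.abs(epoch).max(axis=-1) == 0)[0]]
    if degenerate:
        logger.warning("analytic_signal: channels %s are identically zero (phase undefined)", degenerate)
    return AnalyticEpoch(analytic=hilbert(epoch, axis=-1), degenerate_channels=degenerate)


def _check_equal_length(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape[-1] != b.shape[-1]:
        raise ValueError(f"length mismatch: {a.shape[-1]} vs {b.shape[-1]}")


def plv(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Phase-locking value of two phase series: |mean exp(i * dphi)|."""
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    _check_equal_length(phase_a, phase_b)
    return float(np.abs(np.mean(np.exp(1j * (phase_a - phase_b)))))


def wrap_phase(dphi: np.ndarray) -> np.ndarray:
    """Wrap phase differences to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(dphi, dtype=float)))


def pli(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Phase lag index: |mean sign(wrapped dphi)| with sign(0) = 0."""
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    _check_equal_length(phase_a, phase_b)
    return float(np.abs(np.mean(np.sign(wrap_phase(phase_a - phase_b)))))


def wpli(analytic_a: np.ndarray, analytic_b: np.ndarray) -> float:
    """Weighted phase lag index from two analytic signals.

    ``|mean Im S| / mean |Im S|`` with ``S = a * conj(b)``. When the
    imaginary cross-spectrum vanishes identically (strict zero-lag
    coupling) the estimator is degenerate; 0 is returned and a flag
    logged so fixtures with exact zero lag flow through the pipeline.
    """
    analytic_a = np.asarray(analytic_a)
    analytic_b = np.asarray(analytic_b)
    _check_equal_length(analytic_a, analytic_b)
    S = analytic_a * np.conj(analytic_b)
    imag = np.imag(S)
    denom = np.mean(np.abs(imag))
    # Relative threshold: rounding leaves |Im| ~ 1e-17 * |S| even for
    # strictly zero-lag pairs (e.g. a signal against itself).
    if denom <= 1e-12 * np.mean(np.abs(S)):
        logger.warning("wpli: imaginary cross-spectrum vanishes; degenerate, returning 0")
        return 0.0
    return float(np.abs(np.mean(imag)) / denom)


def _trim_slice(n_samples: int, trim_fraction: float) -> slice:
    t = int(n_samples * trim_fraction)
    return slice(t, n_samples - t) if t > 0 else slice(None)


def _pair_epoch_means(
    analytic: np.ndarray, trim_fraction: float
) -> dict[str, np.ndarray]:
    """Epoch-averaged pair matrices for all three metrics.

    ``analytic`` has shape (n_epochs, n_channels, L); epochs were
    Hilbert-transformed before edge trimming. Returns, per metric, the
    symmetric (n_channels x n_channels) matrix of pair values averaged
    over epochs (diagonal left at 0).
    """
    n_ep, n_ch, L = analytic.shape
    sl = _trim_slice(L, trim_fraction)
    A = analytic[:, :, sl]
    mag = np.abs(A)
    safe = np.where(mag == 0, 1.0, mag)
    E = A / safe  # unit phasors; zero where the signal is degenerate
    out = {m: np.zeros((n_ch, n_ch)) for m in METRICS}
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            S = A[:, i, :] * np.conj(A[:, j, :])  # cross-spectrum per epoch
            U = E[:, i, :] * np.conj(E[:, j, :])  # unit phasor of dphi
            plv_ep = np.abs(U.mean(axis=1))
            pli_ep = np.abs(np.sign(np.angle(U)).mean(axis=1))
            imag = np.imag(S)
            denom = np.abs(imag).mean(axis=1)
            num = np.abs(imag.mean(axis=1))
            degen = denom <= 1e-12 * np.abs(S).mean(axis=1)
            wpli_ep = np.where(degen, 0.0, num / np.where(degen, 1.0, denom))
            if np.any(degen):
                logger.warning(
                    "wpli degenerate (zero imaginary cross-spectrum) for pair (%d, %d) "
                    "in %d epoch(s); contributing 0",
                    i, j, int(np.sum(degen)),
                )
            for name, vals in (("plv", plv_ep), ("pli", pli_ep), ("wpli", wpli_ep)):
                v = float(vals.mean())
                out[name][i, j] = out[name][j, i] = v
    return out


def global_metric(
    epoch_set: EpochSet,
    metric: str,
    trim_fraction: float = DEFAULT_EDGE_TRIM,
) -> tuple[float, PairwiseConnectivity]:
    """Mean global value of one metric over a band-filtered epoch set.

    The metric is computed per unordered channel pair per epoch, averaged
    over epochs, then averaged (unweighted) over pairs.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if epoch_set.n_channels < 2:
        raise ValueError("need at least 2 channels for pairwise synchronization")
    if epoch_set.n_epochs < 1:
        raise ValueError("need at least one epoch")
    analytic = hilbert(epoch_set.epochs, axis=-1)
    mats = _pair_epoch_means(analytic, trim_fraction)
    conn = PairwiseConnectivity(
        metric=metric,
        band=epoch_set.band.name if epoch_set.band else "broadband",
        channel_labels=list(epoch_set.channel_labels),
        matrix=mats[metric],
        n_epochs_used=epoch_set.n_epochs,
    )
    return conn.mean_global(), conn


def extract_sync_features(
    recording: EEGRecording,
    bands: Sequence[str] = FEATURE_BANDS,
    montage_pairs: Sequence[tuple[str, str]] | None = LONGITUDINAL_PAIRS,
    config: PreprocessConfig | None = None,
    trim_fraction: float = DEFAULT_EDGE_TRIM,
    hilbert_mode: str = "epoch",
    metrics: Sequence[str] = METRICS,
) -> SyncFeatureVector:
    """Run the full chain and return the 18 global synchronization features.

    ``hilbert_mode="epoch"`` (default) epochs first and phase-transforms
    each 2-s epoch; ``"whole"`` band-filters and phase-transforms the
    continuous bipolar record and treats it as a single long epoch (no
    artifact screening in that mode).
    """
    cfg = config or PreprocessConfig()
    values: dict[str, float] = {name: 0.0 for name in sync_feature_names()}
    if hilbert_mode == "epoch":
        broadband = preprocess(recording, montage_pairs, cfg)
        for band_name in bands:
            banded = bandpass(broadband, BANDS[band_name], cfg.filter_order)
            analytic = hilbert(banded.epochs, axis=-1)
            mats = _pair_epoch_means(analytic, trim_fraction)
            iu = np.triu_indices(banded.n_channels, k=1)
            for m in metrics:
                values[f"{m}_{band_name}"] = float(np.mean(mats[m][iu]))
    elif hilbert_mode == "whole":
        rec = resample(recording, cfg.target_fs)
        if montage_pairs is not None:
            rec = to_bipolar(rec, montage_pairs)
        for band_name in bands:
            banded = bandpass_recording(rec, BANDS[band_name], cfg.filter_order)
            analytic = hilbert(banded.data, axis=-1)[np.newaxis, :, :]
            mats = _pair_epoch_means(analytic, trim_fraction)
            iu = np.triu_indices(banded.n_channels, k=1)
            for m in metrics:
                values[f"{m}_{band_name}"] = float(np.mean(mats[m][iu]))
    else:
        raise ValueError("hilbert_mode must be 'epoch' or 'whole'")
    if tuple(bands) == FEATURE_BANDS and tuple(metrics) == METRICS:
        return SyncFeatureVector(subject_id=recording.subject_id, values=values)
    # Subsetted extraction (e.g. a Monte-Carlo run over one metric) skips
    # the full-vector validation; unrequested entries stay at 0.0.
    partial = SyncFeatureVector.__new__(SyncFeatureVector)
    partial.subject_id = recording.subject_id
    partial.values = values
    return partial
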