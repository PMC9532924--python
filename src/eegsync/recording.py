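"""Core containers: labeled multichannel EEG, frequency bands, epoch sets.

Amplitudes are in microvolts throughout; sampling rates in Hz. Channel
labels follow the international 10-20 placement scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

#: The 19 scalp electrodes of the 10-20 system used throughout the package.
ELECTRODES_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz", "F7", "F8",
)

#: Default longitudinal ("double banana") bipolar chains over the 19
#: electrodes: 18 derived channels.
LONGITUDINAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "F7"), ("F7", "T3"), ("T3", "T5"), ("T5", "O1"),
    ("Fp1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("Fp2", "F8"), ("F8", "T4"), ("T4", "T6"), ("T6", "O2"),
    ("Fp2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ("Fz", "Cz"), ("Cz", "Pz"),
)


class BandDefinition(NamedTuple):
    """A named frequency band with edges in Hz (0 < low < high)."""

    name: str
    low: float
    high: float


#: Standard clinical EEG bands. ``beta`` spans both beta sub-bands and is
#: extracted as a feature but excluded from per-band hypothesis testing.
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "low_beta": BandDefinition("low_beta", 13.0, 20.0),
    "high_beta": BandDefinition("high_beta", 20.0, 29.0),
    "beta": BandDefinition("beta", 13.0, 29.0),
}

#: Bands entering the per-metric FDR family (combined beta excluded).
TESTED_BANDS: tuple[str, ...] = ("delta", "theta", "alpha", "low_beta", "high_beta")

#: All bands, in feature-vector order.
FEATURE_BANDS: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "low_beta", "high_beta")

#: Synchronization metric names, in feature-vector order.
METRICS: tuple[str, ...] = ("plv", "pli", "wpli")


def sync_feature_names() -> list[str]:
    """The 18 synchronization feature names: 3 metrics x 6 bands."""
    return [f"{m}_{b}" for m in METRICS for b in FEATURE_BANDS]


@dataclass
class EEGRecording:
    """A labeled multichannel time series.

    Parameters
    ----------
    subject_id
        Identifier carried through the pipeline.
    channel_labels
        Unique channel names, one per data row.
    fs
        Sampling rate in Hz.
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    """

    subject_id: str
    channel_labels: list[str]
    fs: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = list(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.data[idx]


@dataclass
class EpochSet:
    """Fixed-length contiguous epochs cut from a recording.

    ``epochs`` has shape ``(n_epochs, n_channels, L)`` with
    ``L = epoch_length_s * fs`` exactly.
    """

    epochs: np.ndarray
    fs: float
    epoch_length_s: float
    channel_labels: list[str]
    montage_pairs: tuple[tuple[str, str], ...] | None = None
    band: BandDefinition | None = None
    rejection_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n_epochs, n_channels, L)")
        L = int(round(self.epoch_length_s * self.fs))
        if self.epochs.shape[2] != L:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} != epoch_length_s*fs = {L}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    def replace_epochs(self, epochs: np.ndarray, band: BandDefinition | None = None) -> "EpochSet":
        return EpochSet(
            epochs=epochs,
            fs=self.fs,
            epoch_length_s=self.epoch_length_s,
            channel_labels=list(self.channel_labels),
            montage_pairs=self.montage_pairs,
            band=band if band is not None else self.band,
            rejection_log=list(self.rejection_log),
        )


def validate_band(band: BandDefinition, fs: float) -> None:
    """Raise if a band's edges are not strictly inside (0, fs/2)."""
    if not (0 < band.low < band.high):
        raise ValueError(f"band {band.name}: need 0 < low < high, got {band.low}, {band.high}")
    if band.high >= fs / 2:
        raise ValueError(
            f"band {band.name}: high edge {band.high} Hz not below Nyquist {fs / 2} Hz"
        )


def montage_channel_names(pairs: Sequence[tuple[str, str]]) -> list[str]:
    return [f"{a}-{b}" for a, b in pairs]


def default_montage_for(labels: Sequence[str]) -> tuple[tuple[str, str], ...]:
    """Best bipolar montage for the electrodes actually present.

    The standard longitudinal chains when every required electrode
    exists; otherwise a simple chain over consecutive available labels
    (reduced-montage recordings, e.g. scaled-down simulations).
    """
    present = set(labels)
    if all(a in present and b in present for a, b in LONGITUDINAL_PAIRS):
        return LONGITUDINAL_PAIRS
    if len(labels) < 3:
        raise ValueError("need at least 3 channels to form a bipolar chain")
    return tuple((labels[i], labels[i + 1]) for i in range(len(labels) - 1))
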