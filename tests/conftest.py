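"""Shared fixtures: deterministic synthetic recordings and feature cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from eegsync import (
    ClinicalRecord,
    CouplingSpec,
    EEGRecording,
    generate_coupled_recording,
    sync_feature_names,
)


def make_sinusoid_recording(
    freq_hz: float = 10.0,
    fs: float = 500.0,
    duration_s: float = 10.0,
    phase_offsets=(0.0, np.pi / 4),
    labels=("Fp1", "Fp2"),
    amplitude: float = 50.0,
    subject_id: str = "sine",
) -> EEGRecording:
    """Pure sinusoids with fixed per-channel phase offsets."""
    t = np.arange(int(round(duration_s * fs))) / fs
    data = np.vstack([amplitude * np.cos(2 * np.pi * freq_hz * t + p) for p in phase_offsets])
    return EEGRecording(subject_id=subject_id, channel_labels=list(labels), fs=fs, data=data)


@pytest.fixture
def sine_pair() -> EEGRecording:
    """Two 10-Hz sinusoids with a rigid pi/4 lag, 10 s at 500 Hz."""
    return make_sinusoid_recording()


@pytest.fixture
def rigid_recording() -> EEGRecording:
    """Two-channel rigid-locked alpha oscillators (coupling 1, lag pi/4)."""
    spec = CouplingSpec(band_name="alpha", coupling_strength=1.0,
                        phase_lag=np.pi / 4, mixing_coefficient=0.0, noise_sd=0.0)
    return generate_coupled_recording(2, 10, 500, spec, seed=7)


def random_clinical(rng: np.random.Generator) -> ClinicalRecord:
    etio = ("structural", "genetic", "autoimmune", "unknown")
    syn = ("infantile_spasms", "LGS", "EOEE", "unclassified")
    mri = ("local", "multifocal", "negative")
    types = [t for t in ("generalized", "focal", "spasms", "multiple") if rng.random() < 0.5]
    onset = float(rng.uniform(0, 8))
    dur = float(rng.uniform(0.5, 8))
    return ClinicalRecord(
        bmi=float(rng.normal(16.7, 3.0)), diastolic_pressure=float(rng.normal(60, 6)),
        pulse_pressure=float(rng.normal(41, 7)), age_implantation=onset + dur,
        epilepsy_duration=dur, age_onset=onset, prior_surgery=bool(rng.random() < 0.15),
        seizure_frequency=float(rng.lognormal(5, 1)),
        etiology=etio[rng.integers(4)],
        seizure_types=frozenset(types or ["focal"]),
        syndrome=syn[rng.integers(4)], mri=mri[rng.integers(3)],
        n_asm_historical=int(rng.integers(2, 10)), n_asm_baseline=int(rng.integers(0, 6)),
        gender="male" if rng.random() < 0.6 else "female",
        benzodiazepine_use=bool(rng.random() < 0.5),
    )


def feature_cohort(n: int = 40, effect: float = 0.0, seed: int = 0):
    """Feature-level cohort: clinical records + sync features + labels.

    ``effect`` shifts the responder group's high-beta PLI/wPLI features,
    planting a detectable synchronization signal without touching the
    clinical covariates.
    """
    rng = np.random.default_rng(seed)
    n_resp = n // 2
    labels = np.array([True] * n_resp + [False] * (n - n_resp))
    labels = labels[rng.permutation(n)]
    ids = [f"S{i:03d}" for i in range(n)]
    clinical = {i: random_clinical(rng) for i in ids}
    names = sync_feature_names()
    sync = {}
    for sid, lab in zip(ids, labels):
        base = np.clip(rng.normal(0.3, 0.05, len(names)), 0, 1)
        vals = dict(zip(names, base))
        if lab and effect:
            for k in ("pli_high_beta", "wpli_high_beta"):
                vals[k] = float(np.clip(vals[k] + effect, 0, 1))
        sync[sid] = vals
    label_map = {i: bool(l) for i, l in zip(ids, labels)}
    return clinical, sync, label_map


@pytest.fixture(scope="session")
def planted_feature_cohort():
    return feature_cohort(n=40, effect=0.12, seed=42)
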