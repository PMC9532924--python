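"""Phase metrics: analytic signal, PLV/PLI/wPLI, global averaging."""

import numpy as np
import pytest
from scipy.signal import hilbert

from eegsync import (
    BANDS,
    CouplingSpec,
    bandpass,
    extract_sync_features,
    generate_coupled_recording,
    global_metric,
    pli,
    plv,
    preprocess,
    segment_epochs,
    wpli,
)
from eegsync.connectivity import PairwiseConnectivity, analytic_signal, wrap_phase

from conftest import make_sinusoid_recording


# ---------------------------------------------------------------- oracles

def plv_naive(pa, pb):
    acc = 0.0 + 0.0j
    for a, b in zip(pa, pb):
        acc += complex(np.cos(a - b), np.sin(a - b))
    return abs(acc / len(pa))


def pli_naive(pa, pb):
    acc = 0.0
    for a, b in zip(pa, pb):
        d = np.angle(np.exp(1j * (a - b)))
        acc += float(d > 0) - float(d < 0)
    return abs(acc / len(pa))


def wpli_naive(aa, ab):
    num = 0.0
    den = 0.0
    for a, b in zip(aa, ab):
        im = (a * np.conj(b)).imag
        num += im
        den += abs(im)
    return 0.0 if den == 0 else abs(num) / den


# ---------------------------------------------------------- analytic signal

class TestAnalyticSignal:
    def test_cosine_phase_matches_closed_form(self):
        fs, f = 500.0, 10.0
        t = np.arange(1000) / fs
        ae = analytic_signal(np.cos(2 * np.pi * f * t))
        expected = wrap_phase(2 * np.pi * f * t)
        mid = slice(100, 900)
        err = np.abs(wrap_phase(ae.phase[0, mid] - expected[mid]))
        assert err.max() < 0.01

    def test_quadrature_shift(self):
        t = np.arange(1000) / 500.0
        a = analytic_signal(np.cos(2 * np.pi * 10 * t))
        b = analytic_signal(np.sin(2 * np.pi * 10 * t))
        d = wrap_phase(a.phase[0, 100:900] - b.phase[0, 100:900])
        assert np.allclose(d, np.pi / 2, atol=0.01)

    def test_real_part_preserved(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(256)
        ae = analytic_signal(x)
        assert np.allclose(ae.analytic.real, x)

    def test_zero_signal_flagged_degenerate(self):
        ae = analytic_signal(np.zeros(100))
        assert ae.degenerate_channels == [0]

    def test_zero_length_raises(self):
        with pytest.raises(ValueError):
            analytic_signal(np.empty(0))


# ----------------------------------------------------------------- metrics

class TestMetricIdentities:
    def test_plv_constant_difference_is_one(self):
        rng = np.random.default_rng(1)
        pa = rng.uniform(-np.pi, np.pi, 5000)
        assert plv(pa, pa - np.pi / 4) == pytest.approx(1.0, abs=1e-12)

    def test_plv_uniform_difference_vanishes(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(0, 2 * np.pi, 10**6)
        assert plv(d, np.zeros_like(d)) < 5e-3

    def test_plv_antipodal_phasors_cancel(self):
        d = np.array([0.0, np.pi] * 500)
        assert plv(d, np.zeros_like(d)) == pytest.approx(0.0, abs=1e-12)

    def test_pli_constant_nonzero_lag_is_one(self):
        pa = np.linspace(0, 20, 4000)
        assert pli(pa, pa - np.pi / 4) == pytest.approx(1.0)

    def test_pli_self_is_exactly_zero(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(-np.pi, np.pi, 1000)
        assert pli(p, p) == 0.0

    def test_pli_symmetric_differences_cancel(self):
        d = np.array([np.pi / 6, -np.pi / 6] * 500)
        assert pli(d, np.zeros_like(d)) == pytest.approx(0.0, abs=1e-12)

    def test_wpli_quarter_cycle_lag_is_one(self):
        t = np.arange(2000) / 500.0
        a = hilbert(np.cos(2 * np.pi * 10 * t))
        b = hilbert(np.sin(2 * np.pi * 10 * t))  # quarter cycle behind
        assert wpli(a[100:-100], b[100:-100]) == pytest.approx(1.0, abs=1e-6)

    def test_wpli_zero_lag_degenerate_returns_zero(self):
        t = np.arange(2000) / 500.0
        a = hilbert(np.cos(2 * np.pi * 10 * t))
        assert wpli(a, a) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            plv(np.zeros(5), np.zeros(6))
        with pytest.raises(ValueError):
            pli(np.zeros(5), np.zeros(6))
        with pytest.raises(ValueError):
            wpli(np.zeros(5, complex), np.zeros(6, complex))


class TestMetricProperties:
    def test_bounds_and_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            pa = rng.uniform(-np.pi, np.pi, 64)
            pb = rng.uniform(-np.pi, np.pi, 64)
            aa, ab = hilbert(rng.standard_normal(64)), hilbert(rng.standard_normal(64))
            for v in (plv(pa, pb), pli(pa, pb), wpli(aa, ab)):
                assert 0.0 <= v <= 1.0
            assert plv(pa, pb) == plv(pb, pa)
            assert pli(pa, pb) == pli(pb, pa)
            # division rounding can differ by 1 ulp between orders
            assert wpli(aa, ab) == pytest.approx(wpli(ab, aa), abs=1e-14)

    def test_plv_invariant_under_constant_offset(self):
        rng = np.random.default_rng(8)
        pa, pb = rng.uniform(-np.pi, np.pi, 256), rng.uniform(-np.pi, np.pi, 256)
        assert plv(pa + 1.234, pb) == pytest.approx(plv(pa, pb), abs=1e-12)

    def test_pli_invariant_for_sign_preserving_offset(self):
        rng = np.random.default_rng(9)
        pa = rng.uniform(0.3, 0.6, 256)  # differences stay in (0, pi)
        pb = np.zeros(256)
        assert pli(pa + 0.2, pb) == pytest.approx(pli(pa, pb), abs=1e-12)

    def test_oracle_equivalence_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(32, 128))
            pa = rng.uniform(-np.pi, np.pi, n)
            pb = rng.uniform(-np.pi, np.pi, n)
            aa = hilbert(rng.standard_normal(n))
            ab = hilbert(rng.standard_normal(n))
            assert plv(pa, pb) == pytest.approx(plv_naive(pa, pb), abs=1e-12)
            assert pli(pa, pb) == pytest.approx(pli_naive(pa, pb), abs=1e-12)
            assert wpli(aa, ab) == pytest.approx(wpli_naive(aa, ab), abs=1e-12)


# ----------------------------------------------------------- global metric

class TestGlobalMetric:
    def test_rigid_lock_gives_unit_plv_and_pli(self, rigid_recording):
        es = bandpass(preprocess(rigid_recording, montage_pairs=None), BANDS["alpha"])
        v_plv, _ = global_metric(es, "plv")
        v_pli, _ = global_metric(es, "pli")
        assert v_plv == pytest.approx(1.0, abs=1e-3)
        assert v_pli == pytest.approx(1.0, abs=1e-6)

    def test_mean_global_is_unweighted_pair_mean(self):
        mat = np.zeros((3, 3))
        mat[0, 1] = mat[1, 0] = 0.2
        mat[0, 2] = mat[2, 0] = 0.4
        mat[1, 2] = mat[2, 1] = 0.6
        conn = PairwiseConnectivity("plv", "alpha", ["a", "b", "c"], mat, 1)
        assert conn.mean_global() == pytest.approx(0.4)

    def test_channel_permutation_invariance(self):
        spec = CouplingSpec(band_name="alpha", coupling_strength=0.6, noise_sd=0.5)
        rec = generate_coupled_recording(3, 10, 500, spec, seed=5)
        es = bandpass(preprocess(rec, montage_pairs=None), BANDS["alpha"])
        v1, _ = global_metric(es, "pli")
        perm = es.replace_epochs(es.epochs[:, ::-1, :])
        v2, _ = global_metric(perm, "pli")
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_fewer_than_two_channels_rejected(self, sine_pair):
        es = segment_epochs(sine_pair, 2.0)
        single = es.replace_epochs(es.epochs[:, :1, :])
        single.channel_labels = ["Fp1"]
        with pytest.raises(ValueError):
            global_metric(single, "plv")

    def test_epoch_averaging_matches_whole_series_when_stationary(self):
        """Rigid lock: per-epoch averaging equals the whole-series value.

        Exact analytic signals isolate the estimator arithmetic from
        Hilbert edge ripple (which the edge trim only attenuates).
        """
        t = np.arange(10_000) / 500.0
        a = np.exp(1j * 2 * np.pi * 10 * t)
        b = np.exp(1j * (2 * np.pi * 10 * t - np.pi / 4))
        pa, pb = np.angle(a), np.angle(b)
        L = 1000
        for fn, xs in (
            (plv, (pa, pb)), (pli, (pa, pb)), (wpli, (a, b)),
        ):
            whole = fn(*xs)
            per_epoch = np.mean([
                fn(*(x[k * L:(k + 1) * L] for x in xs)) for k in range(10)
            ])
            assert per_epoch == pytest.approx(whole, abs=1e-6)

    def test_epoch_and_whole_pipeline_agree_on_rigid_sinusoids(self, sine_pair):
        """Through the full pipeline the two Hilbert modes agree to the
        level Hilbert edge ripple allows (trimmed, ~1e-3)."""
        per_epoch = extract_sync_features(sine_pair, bands=["alpha"],
                                          montage_pairs=None, hilbert_mode="epoch")
        whole = extract_sync_features(sine_pair, bands=["alpha"],
                                      montage_pairs=None, hilbert_mode="whole")
        assert per_epoch.values["plv_alpha"] == pytest.approx(
            whole.values["plv_alpha"], abs=2e-3)
        assert per_epoch.values["pli_alpha"] == pytest.approx(
            whole.values["pli_alpha"], abs=1e-6)


class TestExtractSyncFeatures:
    def test_vector_has_18_bounded_entries(self):
        spec = CouplingSpec(band_name="alpha", coupling_strength=0.5, noise_sd=1.0)
        rec = generate_coupled_recording(4, 8, 500, spec, seed=2)
        vec = extract_sync_features(rec, montage_pairs=None)
        assert len(vec.values) == 18
        assert all(0.0 <= v <= 1.0 for v in vec.values.values())

    def test_rigid_lock_in_band_plv_is_one(self, rigid_recording):
        vec = extract_sync_features(rigid_recording, montage_pairs=None)
        assert vec.values["plv_alpha"] == pytest.approx(1.0, abs=1e-3)

    def test_deterministic(self):
        spec = CouplingSpec(band_name="theta", coupling_strength=0.5)
        rec = generate_coupled_recording(3, 8, 500, spec, seed=4)
        v1 = extract_sync_features(rec, montage_pairs=None)
        v2 = extract_sync_features(rec, montage_pairs=None)
        assert v1.values == v2.values
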