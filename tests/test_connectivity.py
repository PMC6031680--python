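"""Instantaneous phase and PLV adjacency: conventions and invariants."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plvnet.connectivity import (BandDefinition, ConnectivityMatrix,
                                 DEFAULT_BANDS, PhaseEpochs, band_plv,
                                 cohort_connectivity, connectivity_index,
                                 instantaneous_phase, load_matrix,
                                 plv_matrix, save_matrix)
from plvnet.preprocess import EpochSet
from plvnet.synthetic_data import SimConfig, generate_subject_epochs

LOW_BETA = BandDefinition("low_beta", 12.0, 18.0)


def _epochs(data, fs=1000.0, tmin=-100.0, conds=None):
    n = data.shape[0]
    return EpochSet(
        data=data, sample_rate=fs, tmin_ms=tmin,
        conditions=(np.full(n, "nogo", dtype=object) if conds is None
                    else np.asarray(conds, dtype=object)),
        correct=np.ones(n, dtype=bool),
    )


def _phase_epochs(phases, fs=1000.0):
    return PhaseEpochs(phases=phases, sample_rate=fs,
                       window_ms=(200.0, 700.0))


class TestInstantaneousPhase:
    def test_cosine_phase_slope(self):
        fs, f = 1000.0, 15.0
        t = np.arange(1000) / fs - 0.1
        data = np.cos(2 * np.pi * f * t)[None, None, :]
        ph = instantaneous_phase(_epochs(data))
        slope = np.diff(np.unwrap(ph.phases[0, 0])).mean() * fs
        assert slope == pytest.approx(2 * np.pi * f, rel=0.01)

    def test_sin_vs_cos_quarter_cycle_offset(self):
        fs, f = 1000.0, 15.0
        t = np.arange(1000) / fs - 0.1
        data = np.stack([np.cos(2 * np.pi * f * t),
                         np.sin(2 * np.pi * f * t)])[None, :, :]
        ph = instantaneous_phase(_epochs(data))
        diff = np.angle(np.exp(1j * (ph.phases[0, 0] - ph.phases[0, 1])))
        assert np.allclose(diff, np.pi / 2, atol=0.02)

    def test_zero_signal_raises(self):
        with pytest.raises(ValueError):
            instantaneous_phase(_epochs(np.zeros((1, 2, 1000))))

    def test_window_outside_epoch_raises(self):
        data = np.random.default_rng(0).standard_normal((1, 1, 100))
        with pytest.raises(ValueError):
            instantaneous_phase(_epochs(data, fs=1000.0, tmin=0.0),
                                window_ms=(200.0, 700.0))

    def test_window_cropping(self):
        rng = np.random.default_rng(0)
        ph = instantaneous_phase(
            _epochs(rng.standard_normal((2, 3, 1000))))
        assert ph.phases.shape == (2, 3, 500)  # [200, 700) ms at 1 kHz


class TestPlvMatrix:
    def test_identical_phases_lock_perfectly(self, rng):
        p = rng.uniform(-np.pi, np.pi, (20, 1, 50))
        phases = _phase_epochs(np.repeat(p, 3, axis=1))
        W = plv_matrix(phases).weights
        assert np.allclose(W[np.triu_indices(3, 1)], 1.0)

    def test_constant_per_trial_offset_still_locks(self, rng):
        base = rng.uniform(-np.pi, np.pi, (30, 1, 40))
        shifted = base + 1.1  # fixed lag
        phases = _phase_epochs(np.concatenate([base, shifted], axis=1))
        assert plv_matrix(phases).weights[0, 1] == pytest.approx(1.0)

    def test_independent_phases_hit_noise_floor(self, rng):
        n_trials = 100
        phases = _phase_epochs(
            rng.uniform(-np.pi, np.pi, (n_trials, 10, 30)))
        W = plv_matrix(phases).weights
        mean_off = W[np.triu_indices(10, 1)].mean()
        # E[resultant of N uniform unit vectors] ~ sqrt(pi)/(2 sqrt(N))
        assert mean_off == pytest.approx(np.sqrt(np.pi) / 2
                                         / np.sqrt(n_trials), abs=0.03)

    def test_trial_permutation_invariance(self, rng):
        p = rng.uniform(-np.pi, np.pi, (12, 4, 25))
        W1 = plv_matrix(_phase_epochs(p)).weights
        W2 = plv_matrix(_phase_epochs(p[rng.permutation(12)])).weights
        assert np.allclose(W1, W2, atol=1e-12)

    def test_global_per_trial_phase_shift_invariance(self, rng):
        p = rng.uniform(-np.pi, np.pi, (12, 4, 25))
        shift = rng.uniform(-np.pi, np.pi, (12, 1, 1))
        W1 = plv_matrix(_phase_epochs(p)).weights
        W2 = plv_matrix(_phase_epochs(p + shift)).weights
        assert np.allclose(W1, W2, atol=1e-12)

    def test_single_trial_rejected_with_guidance(self, rng):
        p = rng.uniform(-np.pi, np.pi, (1, 4, 25))
        with pytest.raises(ValueError, match="within_trial"):
            plv_matrix(_phase_epochs(p))
        # the within-trial convention is defined for a single trial
        W = plv_matrix(_phase_epochs(p), convention="within_trial").weights
        assert W.shape == (4, 4)

    def test_unknown_convention_rejected(self, rng):
        p = rng.uniform(-np.pi, np.pi, (3, 2, 10))
        with pytest.raises(ValueError):
            plv_matrix(_phase_epochs(p), convention="sideways")

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matrix_invariants_for_arbitrary_phases(self, seed):
        r = np.random.default_rng(seed)
        p = r.uniform(-np.pi, np.pi, (5, 6, 12))
        W = plv_matrix(_phase_epochs(p)).weights
        assert np.allclose(W, W.T)
        assert np.all(np.diag(W) == 0)
        assert W.min() >= 0.0 and W.max() <= 1.0


class TestBandPlvEquivalence:
    def test_band_plv_matches_explicit_pipeline(self):
        cfg = SimConfig(n_nodes=4, n_trials=20, sample_rate=250.0,
                        nogo_only=True)
        ep = generate_subject_epochs(cfg, 0.6, seed=4)
        from plvnet.preprocess import bandpass_filter
        explicit = plv_matrix(
            instantaneous_phase(bandpass_filter(ep, 12.0, 18.0)),
            band="low_beta").weights
        fused = band_plv(ep, LOW_BETA).weights
        assert np.allclose(explicit, fused, atol=1e-10)


class TestCohortConnectivity:
    def _cohort(self, n_subjects=3, n_trials=20):
        cfg = SimConfig(n_nodes=5, n_trials=n_trials, sample_rate=250.0,
                        nogo_only=True)
        return {
            f"sub-{i}": generate_subject_epochs(cfg, 0.6, seed=i)
            for i in range(n_subjects)
        }

    def test_subject_band_matrix_counts(self):
        conn = cohort_connectivity(self._cohort(3), bands=DEFAULT_BANDS,
                                   condition=None)
        mats = [m for per in conn.values() for m in per.values()]
        assert len(mats) == 12
        index = connectivity_index(conn)
        assert len(index) == 12 and index["n_trials"].eq(20).all()

    def test_zero_jitter_subject_locks_in_carrier_band(self):
        cfg = SimConfig(n_nodes=5, n_trials=20, sample_rate=250.0,
                        nogo_only=True, amplitude_noise_sd=0.0)
        conn = cohort_connectivity(
            {"s": generate_subject_epochs(cfg, 0.0, seed=0)},
            bands=(LOW_BETA,), condition=None)
        W = conn["s"]["low_beta"].weights
        assert np.all(W[np.triu_indices(5, 1)] > 0.95)

    def test_subject_with_too_few_epochs_dropped(self, caplog):
        cohort = self._cohort(2)
        cfg1 = SimConfig(n_nodes=5, n_trials=1, sample_rate=250.0,
                         nogo_only=True)
        cohort["sub-tiny"] = generate_subject_epochs(cfg1, 0.6, seed=9)
        with caplog.at_level(logging.WARNING):
            conn = cohort_connectivity(cohort, bands=(LOW_BETA,),
                                       condition=None)
        assert "sub-tiny" not in conn and len(conn) == 2
        assert "dropped" in caplog.text

    def test_mean_plv_decreases_with_subject_jitter(self):
        cfg = SimConfig(n_nodes=8, n_trials=48, sample_rate=250.0,
                        nogo_only=True)
        sigmas = [0.3, 0.6, 0.9, 1.2]
        means = []
        for i, s in enumerate(sigmas):
            ep = generate_subject_epochs(cfg, s, seed=100 + i)
            W = band_plv(ep, LOW_BETA).weights
            means.append(W[np.triu_indices(8, 1)].mean())
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_node_count_mismatch_rejected(self):
        cohort = self._cohort(1)
        cfg = SimConfig(n_nodes=6, n_trials=20, sample_rate=250.0,
                        nogo_only=True)
        cohort["odd"] = generate_subject_epochs(cfg, 0.5, seed=1)
        with pytest.raises(ValueError):
            cohort_connectivity(cohort, condition=None)


def test_matrix_io_roundtrip_bit_exact(tmp_path, rng):
    p = rng.uniform(-np.pi, np.pi, (8, 6, 20))
    mat = plv_matrix(_phase_epochs(p), band="alpha", subject_id="s1")
    path = tmp_path / "m.csv"
    save_matrix(mat, path)
    back = load_matrix(path, band="alpha", subject_id="s1")
    assert np.array_equal(back.weights, mat.weights)


def test_connectivity_matrix_validation(rng):
    with pytest.raises(ValueError):
        ConnectivityMatrix(np.array([[0.0, 1.2], [1.2, 0.0]]))
    with pytest.raises(ValueError):
        ConnectivityMatrix(np.array([[0.0, 0.5], [0.4, 0.0]]))
    with pytest.raises(ValueError):
        ConnectivityMatrix(np.array([[0.5, 0.5], [0.5, 0.5]]))
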