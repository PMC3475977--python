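"""Cluster-phase statistics: identities, invariances, and a naive oracle."""

import cmath
import math

import numpy as np
import pytest

from clusterphase import (
    ClusterPhaseAnalyzer,
    DegeneracyError,
    ValidationError,
    analyze_trial,
    cluster_phase,
    group_sync,
    individual_sync,
    relative_phase,
    wrap_angle,
)
from tests.conftest import make_phase_series


def naive_cluster_statistics(theta):
    """Direct-from-equations reimplementation with explicit complex loops.

    Independent oracle: scalar cmath arithmetic only, no shared code with the
    package implementation.
    """
    n, N = len(theta), len(theta[0])
    q = []
    for i in range(N):
        s = 0j
        for k in range(n):
            s += cmath.exp(1j * theta[k][i])
        s /= n
        q.append(math.atan2(s.imag, s.real))
    phi = [[math.atan2(math.sin(theta[k][i] - q[i]), math.cos(theta[k][i] - q[i]))
            for i in range(N)] for k in range(n)]
    phi_bar, rho_k = [], []
    for k in range(n):
        s = 0j
        for i in range(N):
            s += cmath.exp(1j * phi[k][i])
        s /= N
        phi_bar.append(math.atan2(s.imag, s.real))
        rho_k.append(abs(s))
    rho_group_t = []
    for i in range(N):
        s = 0j
        for k in range(n):
            s += cmath.exp(1j * (phi[k][i] - phi_bar[k]))
        rho_group_t.append(abs(s / n))
    rho_group = sum(rho_group_t) / N
    return q, phi, phi_bar, rho_k, rho_group_t, rho_group


class TestClusterPhase:
    def test_identical_rows_reproduce_theta(self, rng):
        row = rng.uniform(-np.pi, np.pi, size=50)
        theta = make_phase_series(np.tile(row, (4, 1)))
        q, mask = cluster_phase(theta)
        np.testing.assert_allclose(q, row, atol=1e-12)
        assert not mask.any()

    def test_two_oscillator_hand_sum(self):
        theta = make_phase_series([[0.0, 0.0], [np.pi / 2, np.pi / 2]])
        q, mask = cluster_phase(theta)
        np.testing.assert_allclose(q, np.pi / 4, atol=1e-12)
        phi = relative_phase(theta, q)
        np.testing.assert_allclose(phi[0], -np.pi / 4, atol=1e-12)
        np.testing.assert_allclose(phi[1], np.pi / 4, atol=1e-12)

    def test_antipodal_step_flagged_degenerate(self):
        theta = make_phase_series([[0.0, 0.0], [0.0, np.pi]])
        _, mask = cluster_phase(theta)
        assert mask.tolist() == [False, True]

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError):
            cluster_phase(np.zeros((1, 10)))

    def test_common_offset_leaves_phi_unchanged(self, rng):
        base = rng.uniform(-np.pi, np.pi, size=(3, 40))
        q0, _ = cluster_phase(base)
        phi0 = relative_phase(base, q0)
        shifted = wrap_angle(base + 1.2)
        q1, _ = cluster_phase(shifted)
        phi1 = relative_phase(shifted, q1)
        np.testing.assert_allclose(phi1, phi0, atol=1e-9)
        np.testing.assert_allclose(np.abs(wrap_angle(q1 - q0 - 1.2)), 0.0, atol=1e-9)


class TestIndividualSync:
    def test_constant_relative_phase_is_full_sync(self):
        phi_bar, rho = individual_sync(np.full(100, 0.7))
        assert rho == pytest.approx(1.0, abs=1e-12)
        assert phi_bar == pytest.approx(0.7, abs=1e-12)

    def test_uniform_sweep_cancels(self):
        # m full cycles sampled evenly: roots-of-unity cancellation
        for m in (1, 3):
            phi = wrap_angle(2 * np.pi * m * np.arange(120) / 120)
            _, rho = individual_sync(phi)
            assert rho < 1e-9

    def test_hand_complex_sum(self):
        phi_bar, rho = individual_sync([0.0, np.pi / 2])
        assert (phi_bar, rho) == (pytest.approx(np.pi / 4), pytest.approx(0.70711, abs=1e-5))


class TestGroupSync:
    def test_identical_rows_full_sync(self):
        phi = np.zeros((4, 30))
        rho_t, rho = group_sync(phi, np.zeros(4))
        np.testing.assert_allclose(rho_t, 1.0, atol=1e-12)
        assert rho == pytest.approx(1.0)

    def test_constant_offsets_absorbed(self, rng):
        # phi_k(t) = c_k: offsets absorbed by phi_bar, rho_group = 1
        c = rng.uniform(-np.pi, np.pi, size=5)
        phi = np.tile(c[:, None], (1, 50))
        phi_bar = c.copy()
        _, rho = group_sync(phi, phi_bar)
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_undefined_phi_bar_fallback_and_error(self, caplog):
        phi = np.zeros((3, 20))
        phi_bar = np.array([0.0, np.nan, 0.0])
        with caplog.at_level("WARNING", logger="clusterphase.cluster"):
            _, rho = group_sync(phi, phi_bar)
        assert rho == pytest.approx(1.0)
        assert any("substituting 0" in rec.message for rec in caplog.records)
        with pytest.raises(DegeneracyError):
            group_sync(phi, phi_bar, undefined_phi_bar="error")

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            group_sync(np.zeros((3, 10)), np.zeros(4))


class TestAnalyzeTrial:
    def test_six_identical_sinusoids_full_sync(self, six_identical):
        result = analyze_trial(six_identical)
        np.testing.assert_allclose(result.rho_k, 1.0, atol=1e-6)
        assert result.rho_group == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(result.phi_bar, 0.0, atol=1e-6)

    def test_incommensurate_member_detected(self, five_plus_odd):
        result = analyze_trial(five_plus_odd)
        # the odd member's rho_k falls near the n-member contamination floor
        # ~1/(2(n-1)) = 0.1 while the locked members stay near 1
        assert result.rho_k[5] < 0.15
        assert result.rho_k[:5].min() > 0.9

    def test_deterministic_bit_identical(self, six_identical):
        a = analyze_trial(six_identical)
        b = analyze_trial(six_identical)
        np.testing.assert_array_equal(a.rho_group_t, b.rho_group_t)
        assert a.rho_group == b.rho_group

    def test_mean_frequency_estimated(self, six_identical):
        result = analyze_trial(six_identical)
        assert result.mean_frequency_hz == pytest.approx(0.6, rel=0.01)


class TestOracleEquivalence:
    def test_matches_naive_reimplementation(self, rng):
        for _ in range(12):
            n = int(rng.integers(2, 5))
            N = int(rng.integers(4, 17))
            theta = rng.uniform(-np.pi, np.pi, size=(n, N))
            q_o, phi_o, phi_bar_o, rho_k_o, rho_t_o, rho_o = naive_cluster_statistics(theta.tolist())
            analyzer = ClusterPhaseAnalyzer().fit(theta.T)
            np.testing.assert_allclose(wrap_angle(analyzer.cluster_phase_ - np.array(q_o)), 0.0, atol=1e-12)
            np.testing.assert_allclose(analyzer.relative_phase_, phi_o, atol=1e-12)
            np.testing.assert_allclose(analyzer.mean_relative_phase_, phi_bar_o, atol=1e-12)
            np.testing.assert_allclose(analyzer.rho_k_, rho_k_o, atol=1e-12)
            np.testing.assert_allclose(analyzer.rho_group_t_, rho_t_o, atol=1e-12)
            assert analyzer.rho_group_ == pytest.approx(rho_o, abs=1e-12)


class TestInvariances:
    def test_permutation_relabels_consistently(self, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(5, 60))
        perm = rng.permutation(5)
        a = ClusterPhaseAnalyzer().fit(theta.T)
        b = ClusterPhaseAnalyzer().fit(theta[perm].T)
        np.testing.assert_allclose(b.rho_k_, a.rho_k_[perm], atol=1e-12)
        np.testing.assert_allclose(b.mean_relative_phase_, a.mean_relative_phase_[perm], atol=1e-12)
        np.testing.assert_allclose(b.rho_group_t_, a.rho_group_t_, atol=1e-12)

    def test_global_rotation_invariance(self, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(4, 50))
        a = ClusterPhaseAnalyzer().fit(theta.T)
        b = ClusterPhaseAnalyzer().fit(wrap_angle(theta + 0.9).T)
        np.testing.assert_allclose(b.rho_k_, a.rho_k_, atol=1e-12)
        np.testing.assert_allclose(b.rho_group_t_, a.rho_group_t_, atol=1e-12)
        np.testing.assert_allclose(np.abs(wrap_angle(b.cluster_phase_ - a.cluster_phase_ - 0.9)), 0.0, atol=1e-9)

    def test_time_reversal_leaves_rho_group(self, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(4, 50))
        a = ClusterPhaseAnalyzer().fit(theta.T)
        b = ClusterPhaseAnalyzer().fit(theta[:, ::-1].T)
        assert b.rho_group_ == pytest.approx(a.rho_group_, abs=1e-12)

    def test_bounds_and_full_sync_characterisation(self, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(6, 80))
        a = ClusterPhaseAnalyzer().fit(theta.T)
        assert np.all((0 <= a.rho_k_) & (a.rho_k_ <= 1))
        assert np.all((0 <= a.rho_group_t_) & (a.rho_group_t_ <= 1))
        assert a.rho_group_ < 1
        # rho_group = 1 iff offset-corrected relative phases coincide at every step
        locked = wrap_angle(np.linspace(0, 20, 80)[None, :] + rng.uniform(-np.pi, np.pi, size=(6, 1)))
        b = ClusterPhaseAnalyzer().fit(locked.T)
        assert b.rho_group_ == pytest.approx(1.0, abs=1e-9)

    def test_coupled_group_mean_offset_near_inphase(self):
        # strongly coupled groups lock with mean relative phases clustered at 0
        from clusterphase import circular_mean_and_resultant, make_group_trial

        offsets = []
        for seed in range(5):
            x = make_group_trial("coupled", seed=seed, duration_s=60.0, sample_rate=60.0)
            result = analyze_trial(x)
            offsets.extend(result.phi_bar.tolist())
        mean_dir, _ = circular_mean_and_resultant(offsets)
        assert abs(np.degrees(mean_dir)) < 5.0

    def test_degenerate_policy_error_raises(self):
        theta = make_phase_series([[0.0, 0.0], [0.0, np.pi]])
        with pytest.raises(DegeneracyError):
            ClusterPhaseAnalyzer(degenerate_policy="error").fit(theta)
        # exclude policy drops the degenerate step from the averages
        a = ClusterPhaseAnalyzer(degenerate_policy="exclude").fit(theta)
        assert a.degenerate_mask_.sum() == 1
        assert a.rho_group_ == pytest.approx(1.0)
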