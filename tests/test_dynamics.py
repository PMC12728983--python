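import numpy as np
import pytest

from polymelt.core import Topology, Trajectory
from polymelt.dynamics import (
    CorrelationCurve,
    autocorrelate_vectors,
    dipole_decomposition,
    fit_relaxation,
    map_to_rouse_beads,
    msd_and_diffusion,
    rouse_mode_series,
    rouse_scaling_report,
    rouse_transform_matrix,
    vector_cross_correlation,
)


def brute_force_cross(a, b):
    """Double-loop ⟨a(t0+t)·b(t0)⟩ over all origins — the reference."""
    T, E, _ = a.shape
    out = np.zeros(T)
    for t in range(T):
        acc = 0.0
        for t0 in range(T - t):
            acc += np.sum(a[t0 + t] * b[t0])
        out[t] = acc / ((T - t) * E)
    return out


class TestCorrelators:
    def test_static_vectors_give_unit_acf(self):
        series = np.tile(np.array([1.0, 2.0, 2.0]), (30, 4, 1))
        c = autocorrelate_vectors(series, dt=1.0)
        assert np.allclose(c.value, 1.0)

    def test_sign_flipping_vectors_alternate(self):
        series = np.tile(np.array([0.0, 0.0, 1.0]), (20, 1, 1))
        series[1::2] *= -1
        c = autocorrelate_vectors(series, dt=1.0)
        assert np.allclose(c.value[::2], 1.0)
        assert np.allclose(c.value[1::2], -1.0)

    def test_c0_is_exactly_one_in_per_entity_mode(self, rng):
        series = rng.normal(size=(50, 7, 3))
        c = autocorrelate_vectors(series, dt=0.5, normalization="per_entity_t0")
        assert c.value[0] == pytest.approx(1.0, abs=1e-12)
        assert c.lag[0] == 0.0

    @pytest.mark.parametrize("normalization", ["per_entity_t0", "ensemble"])
    def test_fft_matches_brute_force(self, rng, normalization):
        series = rng.normal(size=(60, 3, 3))
        c = autocorrelate_vectors(series, dt=1.0, normalization=normalization,
                                  origin_stride=1)
        if normalization == "per_entity_t0":
            ref = brute_force_cross(series, series / np.sum(series**2, axis=-1, keepdims=True))
        else:
            raw = brute_force_cross(series, series)
            ref = raw / raw[0]
        assert np.allclose(c.value, ref, atol=1e-9)

    def test_strided_origins_match_direct_subsampling(self, rng):
        a = rng.normal(size=(40, 2, 3))
        c = vector_cross_correlation(a, a, dt=1.0, origin_stride=7)
        # reference: only origins 0, 7, 14, ...
        T = 40
        for lag in (0, 5, 20):
            origins = [t0 for t0 in range(0, T, 7) if t0 + lag < T]
            ref = np.mean([np.sum(a[t0 + lag] * a[t0]) / 2 for t0 in origins])
            assert c.value[lag] == pytest.approx(ref, abs=1e-12)

    def test_ou_relaxation_time_recovered(self):
        rng = np.random.default_rng(42)
        tau, dt, T, E = 8.0, 0.5, 4000, 40
        rho = np.exp(-dt / tau)
        x = np.zeros((T, E, 3))
        x[0] = rng.normal(size=(E, 3))
        noise = rng.normal(size=(T, E, 3)) * np.sqrt(1 - rho**2)
        for t in range(1, T):
            x[t] = rho * x[t - 1] + noise[t]
        c = autocorrelate_vectors(x, dt=dt, origin_stride=1, max_lag_frames=200)
        fit = fit_relaxation(c, model="exponential")
        assert fit.tau == pytest.approx(tau, rel=0.10)

    def test_n_origins_non_increasing_enforced(self):
        with pytest.raises(ValueError):
            CorrelationCurve(np.array([0.0, 1.0]), np.ones(2), np.array([3, 5]))


class TestFitRelaxation:
    def test_exact_exponential_self_consistency(self):
        t = np.arange(0, 60.0)
        curve = CorrelationCurve(t, np.exp(-t / 5.0), np.full(t.size, 100))
        fit = fit_relaxation(curve, model="exponential")
        assert fit.tau == pytest.approx(5.0, abs=1e-6)
        assert fit.beta == 1.0
        assert fit.tau_mean == pytest.approx(5.0, abs=1e-6)

    def test_exact_plateau_kww_self_consistency(self):
        t = np.arange(0, 200.0)
        y = 0.1 + 0.9 * np.exp(-((t / 10.0) ** 0.5))
        curve = CorrelationCurve(t, y, np.full(t.size, 100))
        fit = fit_relaxation(curve, model="kww_plateau")
        assert fit.plateau == pytest.approx(0.1, abs=1e-4)
        assert fit.tau == pytest.approx(10.0, abs=1e-3)
        assert fit.beta == pytest.approx(0.5, abs=1e-4)

    def test_kww_mean_relaxation_time(self):
        t = np.arange(0, 300.0)
        y = np.exp(-((t / 20.0) ** 0.5))
        curve = CorrelationCurve(t, y, np.full(t.size, 100))
        fit = fit_relaxation(curve, model="kww")
        # ⟨τ⟩ = (τ/β)Γ(1/β) = 20/0.5·Γ(2) = 40
        assert fit.tau_mean == pytest.approx(40.0, rel=1e-3)

    def test_noisy_kww_recovery_within_three_se(self):
        rng = np.random.default_rng(11)
        t = np.arange(0, 150.0)
        y = np.exp(-((t / 12.0) ** 0.7)) + rng.normal(scale=0.01, size=t.size)
        curve = CorrelationCurve(t, y, np.full(t.size, 100))
        fit = fit_relaxation(curve, model="kww")
        se_tau = max(fit.stderr.get("tau", 0.5), 0.3)
        se_beta = max(fit.stderr.get("beta", 0.02), 0.01)
        assert abs(fit.tau - 12.0) < 3 * se_tau
        assert abs(fit.beta - 0.7) < 3 * se_beta

    def test_short_or_flat_curves_rejected(self):
        t = np.arange(0, 3.0)
        with pytest.raises(ValueError, match="5 usable"):
            fit_relaxation(CorrelationCurve(t, np.exp(-t), np.full(3, 50)))
        t = np.arange(0, 30.0)
        with pytest.raises(ValueError, match="all equal"):
            fit_relaxation(CorrelationCurve(t, np.ones(30), np.full(30, 50)))


def _two_group_system(T, rng, q_alpha=0.3, rotate_independently=True):
    """Two rigid dipolar groups per chain on one chain, freely rotating."""
    n_atoms = 4  # two backbone, two terminal
    charges = np.array([q_alpha, -q_alpha, 0.5, -0.5])  # terminal pair, backbone pair
    topo = Topology(
        n_atoms, np.ones(n_atoms), charges,
        chains=[np.arange(4)],
        named_selections={"alpha_end": np.array([0, 1])},
    )
    pos = np.zeros((T, 4, 3))
    u1 = rng.normal(size=(T, 3))
    u1 /= np.linalg.norm(u1, axis=1, keepdims=True)
    u2 = rng.normal(size=(T, 3))
    u2 /= np.linalg.norm(u2, axis=1, keepdims=True)
    pos[:, 0] = 0.1 * u1
    pos[:, 1] = -0.1 * u1
    pos[:, 2] = np.array([5.0, 0, 0]) + 0.1 * u2
    pos[:, 3] = np.array([5.0, 0, 0]) - 0.1 * u2
    traj = Trajectory(pos, np.arange(float(T)), None, wrapped=False)
    return traj, topo


class TestDipoleDecomposition:
    def test_zero_terminal_charges_kill_three_parts(self, rng):
        traj, topo = _two_group_system(40, rng, q_alpha=0.0)
        dec = dipole_decomposition(traj, topo)
        assert np.allclose(dec.phi_aa.value, 0.0, atol=1e-12)
        assert np.allclose(dec.phi_pa.value, 0.0, atol=1e-12)
        assert np.allclose(dec.phi_ap.value, 0.0, atol=1e-12)
        assert np.allclose(dec.phi_total.value,
                           dec.phi_pp.value, atol=1e-12)

    def test_additivity_for_random_charges(self, rng):
        # random net-neutral charges on both groups
        T, A = 30, 6
        q_term = rng.normal(size=2)
        q_term -= q_term.mean()
        q_back = rng.normal(size=4)
        q_back -= q_back.mean()
        charges = np.concatenate([q_term, q_back])
        topo = Topology(A, np.ones(A), charges, chains=[np.arange(A)],
                        named_selections={"alpha_end": np.array([0, 1])})
        pos = rng.normal(size=(T, A, 3))
        traj = Trajectory(pos, np.arange(float(T)), None, wrapped=False)
        dec = dipole_decomposition(traj, topo, normalize=False)
        total = dec.phi_pp.value + dec.phi_aa.value + dec.phi_pa.value + dec.phi_ap.value
        assert np.allclose(dec.phi_total.value, total, atol=1e-9)

    def test_independent_groups_have_vanishing_cross_terms(self, rng):
        traj, topo = _two_group_system(4000, rng)
        dec = dipole_decomposition(traj, topo, normalize=False, origin_stride=1)
        # independent isotropic rotors: cross correlations are 0 in expectation
        scale = dec.phi_pp.value[0]
        assert abs(dec.phi_pa.value[1:50].mean()) < 0.05 * scale
        assert abs(dec.phi_ap.value[1:50].mean()) < 0.05 * scale

    def test_net_charged_group_rejected(self, rng):
        topo = Topology(4, np.ones(4), np.array([0.5, 0.0, 0.2, -0.2]),
                        chains=[np.arange(4)],
                        named_selections={"alpha_end": np.array([0, 1])})
        traj = Trajectory(rng.normal(size=(5, 4, 3)), np.arange(5.0), None, wrapped=False)
        with pytest.raises(ValueError, match="net charge"):
            dipole_decomposition(traj, topo)


class TestRouseMachinery:
    def test_24_monomers_give_12_blocks_of_2(self):
        T, A = 3, 24
        topo = Topology(A, np.ones(A), np.zeros(A), chains=[np.arange(A)])
        pos = np.arange(A, dtype=float)[None, :, None] * np.ones(3)
        traj = Trajectory(np.tile(pos, (T, 1, 1)), np.arange(float(T)), None, wrapped=False)
        beads = map_to_rouse_beads(traj, topo, 12)
        assert beads.shape == (T, 1, 12, 3)
        assert np.allclose(beads[0, 0, :, 0], np.arange(12) * 2 + 0.5)

    def test_identity_mapping(self, rng):
        A = 7
        topo = Topology(A, rng.uniform(1, 3, A), np.zeros(A), chains=[np.arange(A)])
        pos = rng.normal(size=(2, A, 3))
        traj = Trajectory(pos, np.arange(2.0), None, wrapped=False)
        beads = map_to_rouse_beads(traj, topo, A)
        assert np.allclose(beads[:, 0], pos)

    def test_block_centers_match_brute_force(self, rng):
        A, n_beads = 10, 4
        masses = rng.uniform(1, 5, A)
        topo = Topology(A, masses, np.zeros(A), chains=[np.arange(A)])
        pos = rng.normal(size=(1, A, 3))
        traj = Trajectory(pos, np.array([0.0]), None, wrapped=False)
        beads = map_to_rouse_beads(traj, topo, n_beads)
        blocks = np.array_split(np.arange(A), n_beads)
        for bi, blk in enumerate(blocks):
            ref = (pos[0, blk] * masses[blk, None]).sum(axis=0) / masses[blk].sum()
            assert np.allclose(beads[0, 0, bi], ref)

    def test_free_transform_is_orthonormal(self):
        phi = rouse_transform_matrix(12, "free")
        assert np.allclose(phi @ phi.T, np.eye(12), atol=1e-12)

    def test_reconstruction_from_all_modes(self, rng):
        N = 9
        phi = rouse_transform_matrix(N, "free")
        R = rng.normal(size=(N, 3))
        X = phi @ R
        assert np.allclose(phi.T @ X, R, atol=1e-9)

    def test_collapsed_chain_has_zero_modes(self):
        beads = np.ones((5, 2, 8, 3)) * 3.3
        for p in (1, 2, 3):
            phi = rouse_transform_matrix(8, "free")
            X = np.einsum("tcnj,n->tcj", beads, phi[p])
            assert np.allclose(X, 0.0, atol=1e-12)

    def test_scaling_report_identifies_exact_spectra(self):
        class Stub:
            def __init__(self, p, tau):
                self.mode_index, self.tau_p = p, tau

        free = [Stub(p, 100.0 / p**2) for p in range(1, 7)]
        rep = rouse_scaling_report(free)
        assert rep.dev_free.sum() == pytest.approx(0.0, abs=1e-12)
        assert rep.attrs["preferred_end_condition"] == "free"

        fixed = [Stub(p, 100.0 / (p - 0.5) ** 2) for p in range(1, 7)]
        rep = rouse_scaling_report(fixed)
        assert rep.dev_fixed.sum() == pytest.approx(0.0, abs=1e-12)
        assert rep.attrs["preferred_end_condition"] == "fixed"

    def test_bd_spectrum_matches_discrete_rouse(self):
        from polymelt.synth import RouseBDSpec, rouse_mode_time, simulate_rouse_bd

        spec = RouseBDSpec(n_beads=12, n_steps=1_000_000, stride=50, seed=21)
        traj = simulate_rouse_bd(spec)
        beads = traj.positions[:, None, :, :]
        taus = {}
        for p in range(1, 5):
            res = rouse_mode_series(beads, p, traj.dt_frame, max_lag_frames=400)
            taus[p] = res.tau_p
        for p in range(2, 5):
            expected = rouse_mode_time(spec, p) / rouse_mode_time(spec, 1)
            assert taus[p] / taus[1] == pytest.approx(expected, rel=0.15)

    def test_invalid_mode_index(self):
        beads = np.zeros((4, 1, 6, 3))
        with pytest.raises(ValueError, match="mode index"):
            rouse_mode_series(beads, 0, 1.0)


class TestMsdDiffusion:
    def _traj(self, pos, dt=1.0):
        n = pos.shape[1]
        topo = Topology(n, np.ones(n), np.zeros(n), chains=[np.arange(n)])
        times = np.arange(pos.shape[0], dtype=float) * dt
        return Trajectory(pos, times, None, wrapped=False), topo

    def test_static_system_has_zero_diffusion(self):
        pos = np.tile(np.array([[1.0, 2.0, 3.0]]), (50, 1, 1))
        traj, topo = self._traj(pos)
        res = msd_and_diffusion(traj, topo)
        assert res.D == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.msd, 0.0, atol=1e-12)  # FFT roundoff only

    def test_ballistic_motion_flagged_nonlinear(self):
        t = np.arange(100.0)
        pos = np.zeros((100, 1, 3))
        pos[:, 0, 0] = 0.05 * t
        traj, topo = self._traj(pos)
        res = msd_and_diffusion(traj, topo)
        assert np.allclose(res.msd, (0.05 * t) ** 2, atol=1e-10)
        assert not res.linear

    def test_brownian_diffusion_recovered(self):
        rng = np.random.default_rng(8)
        D_nm2_ps = 0.01
        dt = 1.0
        steps = rng.normal(scale=np.sqrt(2 * D_nm2_ps * dt), size=(3000, 20, 3))
        pos = np.cumsum(steps, axis=0)
        topo = Topology(20, np.ones(20), np.zeros(20),
                        chains=[np.array([i]) for i in range(20)])
        traj = Trajectory(pos, np.arange(3000.0), None, wrapped=False)
        res = msd_and_diffusion(traj, topo, fit_window=(0.02, 0.2))
        assert res.D == pytest.approx(D_nm2_ps * 1e4, rel=0.10)

    def test_msd_matches_brute_force(self, rng):
        from polymelt.dynamics import msd_curve

        x = np.cumsum(rng.normal(size=(80, 2, 3)), axis=0)
        msd = msd_curve(x)
        for lag in (0, 1, 7, 40):
            ref = np.mean([
                np.mean(np.sum((x[lag:, e] - x[:-lag or None, e]) ** 2, axis=-1))
                for e in range(2)
            ])
            assert msd[lag] == pytest.approx(ref, abs=1e-9)

    def test_wrapped_input_rejected(self):
        pos = np.zeros((20, 1, 3))
        topo = Topology(1, np.ones(1), np.zeros(1), chains=[np.array([0])])
        traj = Trajectory(pos, np.arange(20.0), np.full((20, 3), 5.0), wrapped=True)
        with pytest.raises(ValueError, match="unwrap"):
            msd_and_diffusion(traj, topo)

    def test_too_narrow_window_rejected(self):
        pos = np.zeros((30, 1, 3))
        traj, topo = self._traj(pos)
        with pytest.raises(ValueError, match="window"):
            msd_and_diffusion(traj, topo, fit_window=(0.5, 0.55))
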