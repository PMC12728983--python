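import numpy as np
import pytest

from polymelt.core import KB_KJ_PER_MOL_K, minimum_image_displacement
from polymelt.structure import (
    Extremum,
    PmfProfile,
    locate_extrema,
    pmf,
    rcn,
    rcn_profile,
    rdf,
    stability_gate,
)


def brute_force_counts(pa, pb, boxes, edges, same_species):
    """Naive per-pair histogram — the independent counting oracle."""
    counts = np.zeros(edges.size - 1)
    T, Na = pa.shape[:2]
    for t in range(T):
        for i in range(Na):
            for j in range(pb.shape[1]):
                if same_species and i == j:
                    continue
                d = minimum_image_displacement(pa[t, i], pb[t, j], boxes[t])
                r = np.linalg.norm(d)
                if r < edges[-1]:
                    counts[np.searchsorted(edges, r, side="right") - 1] += 1
    return counts / (T * Na)


class TestRdf:
    def test_ideal_gas_is_flat(self, rng):
        L = 6.0
        pos = rng.uniform(0, L, size=(40, 120, 3))
        boxes = np.full((40, 3), L)
        profile = rdf(pos, pos, boxes, bin_width=0.2, same_species=True)
        raw = profile.counts * profile.n_frames * 120  # total pair samples/bin
        keep = raw > 50
        sigma = 1.0 / np.sqrt(raw[keep])
        assert np.all(np.abs(profile.g[keep] - 1.0) < 5 * sigma)

    def test_single_pair_lands_in_one_bin(self):
        L = 100.0
        d = 1.23
        pa = np.array([[[10.0, 10, 10]]])
        pb = np.array([[[10.0 + d, 10, 10]]])
        profile = rdf(pa, pb, np.full((1, 3), L), bin_width=0.1, same_species=False)
        nz = np.flatnonzero(profile.counts)
        assert nz.size == 1
        assert profile.bin_centers[nz[0]] == pytest.approx(1.25)

    def test_counts_match_brute_force_oracle(self, rng):
        L = 4.0
        pa = rng.uniform(0, L, size=(3, 15, 3))
        pb = rng.uniform(0, L, size=(3, 20, 3))
        boxes = np.full((3, 3), L)
        profile = rdf(pa, pb, boxes, bin_width=0.25, same_species=False)
        edges = np.arange(profile.counts.size + 1) * 0.25
        ref = brute_force_counts(pa, pb, boxes, edges, same_species=False)
        assert np.allclose(profile.counts, ref, atol=1e-12)

    def test_same_species_excludes_self_pair(self, rng):
        L = 5.0
        pos = rng.uniform(0, L, size=(2, 10, 3))
        boxes = np.full((2, 3), L)
        profile = rdf(pos, pos, boxes, bin_width=0.25)
        assert profile.same_species
        edges = np.arange(profile.counts.size + 1) * 0.25
        ref = brute_force_counts(pos, pos, boxes, edges, same_species=True)
        assert np.allclose(profile.counts, ref, atol=1e-12)

    def test_ball_average_of_g_is_one_by_construction(self, rng):
        # the finite-cutoff normalization invariant, on any data
        L = 3.0
        pa = rng.uniform(0, L, size=(4, 8, 3))
        pb = rng.uniform(0, L, size=(4, 12, 3))
        boxes = np.full((4, 3), L)
        profile = rdf(pa, pb, boxes, bin_width=0.05, same_species=False)
        edges = np.arange(profile.counts.size + 1) * 0.05
        shell_vol = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        ball_vol = 4 / 3 * np.pi * profile.r_cut**3
        weighted = np.sum(profile.g * shell_vol) / ball_vol
        assert weighted == pytest.approx(1.0, abs=1e-9)

    def test_r_cut_above_half_box_rejected(self, rng):
        pos = rng.uniform(0, 4, size=(1, 5, 3))
        with pytest.raises(ValueError, match="half"):
            rdf(pos, pos, np.full((1, 3), 4.0), r_cut=2.5)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rdf(np.empty((1, 0, 3)), np.ones((1, 2, 3)), np.full((1, 3), 4.0))


class TestRcn:
    def _flat_profile(self, rho=0.5, r_cut=2.0, bin_width=0.01):
        n = int(r_cut / bin_width)
        centers = (np.arange(n) + 0.5) * bin_width
        from polymelt.structure import RdfProfile

        return RdfProfile(bin_centers=centers, g=np.ones(n), r_cut=r_cut,
                          counts=np.zeros(n))

    def test_uniform_gas_gives_ball_volume(self):
        rho = 0.7
        profile = self._flat_profile()
        n = rcn(profile, rho, 0.0, 1.5)
        assert n == pytest.approx(4 / 3 * np.pi * rho * 1.5**3, rel=1e-3)

    def test_zero_g_shell_contributes_nothing(self):
        profile = self._flat_profile()
        profile.g[:] = 0.0
        assert rcn(profile, 1.0, 0.0, 1.0) == 0.0

    def test_planted_first_shell_count(self, rng):
        # k=6 neighbors at 0.5 nm on the octahedron vertices around each site
        L = 10.0
        center = np.array([5.0, 5, 5])
        offsets = 0.5 * np.vstack([np.eye(3), -np.eye(3)])
        pb = (center + offsets)[None]
        pa = center[None, None]
        boxes = np.full((1, 3), L)
        profile = rdf(pa, pb, boxes, bin_width=0.05, same_species=False)
        rho = 6 / L**3
        n = rcn(profile, rho, 0.0, 1.0)
        # mean density in the r_c ball is what normalizes g: integrating
        # rho*g over the first shell returns the planted neighbor count
        rho_ball = profile.mean_partner_density
        n_ball = rcn(profile, rho_ball, 0.0, 1.0)
        assert n_ball == pytest.approx(6.0, rel=0.02)

    def test_full_ball_integral_matches_raw_counts(self, rng):
        L = 4.0
        pa = rng.uniform(0, L, size=(5, 10, 3))
        pb = rng.uniform(0, L, size=(5, 14, 3))
        boxes = np.full((5, 3), L)
        profile = rdf(pa, pb, boxes, bin_width=0.02, same_species=False)
        n = rcn(profile, profile.mean_partner_density, 0.0, profile.r_cut)
        assert n == pytest.approx(profile.counts.sum(), rel=5e-3)

    def test_invalid_bounds_rejected(self):
        profile = self._flat_profile()
        with pytest.raises(ValueError, match="bounds"):
            rcn(profile, 1.0, 1.5, 1.0)

    def test_cumulative_profile_monotone(self, rng):
        profile = self._flat_profile()
        prof = rcn_profile(profile, 0.3)
        assert prof.n_cum[0] == 0.0
        assert np.all(np.diff(prof.n_cum) >= 0)


class TestPmf:
    def _profile_from_g(self, g, bin_width=0.01):
        from polymelt.structure import RdfProfile

        n = g.size
        centers = (np.arange(n) + 0.5) * bin_width
        return RdfProfile(bin_centers=centers, g=g, r_cut=n * bin_width,
                          counts=np.zeros(n))

    def test_flat_g_gives_zero_pmf(self):
        p = pmf(self._profile_from_g(np.ones(50)), 360.0)
        assert np.allclose(p.W, 0.0, atol=1e-12)

    def test_one_over_e_bin_equals_thermal_energy(self):
        g = np.ones(50)
        g[10] = np.exp(-1.0)
        p = pmf(self._profile_from_g(g), 360.0)
        # −kB·360·ln(e⁻¹) = kB·360 = 2.993 kJ/mol
        assert p.W[10] == pytest.approx(2.993, abs=1e-3)

    def test_zero_g_masked_not_infinite(self):
        g = np.ones(30)
        g[3] = 0.0
        p = pmf(self._profile_from_g(g), 300.0)
        assert np.isnan(p.W[3])
        assert np.isfinite(p.W[[0, 1, 2, 4]]).all()

    def test_sticky_pair_boltzmann_inversion_recovers_potential(self):
        from polymelt.synth import StickyPairSpec, simulate_sticky_pair

        depth = -3.0
        r_grid = np.linspace(0.005, 3.0, 3000)
        u = np.where((r_grid > 0.4) & (r_grid < 0.9), depth, 0.0)
        spec = StickyPairSpec(r_grid=r_grid, u_grid=u, temperature=360,
                              box_length=5.0, n_sweeps=10_000_000, seed=4,
                              step_size=0.3)
        traj = simulate_sticky_pair(spec)
        profile = rdf(traj.positions[:, :1], traj.positions[:, 1:], traj.boxes,
                      bin_width=0.1, same_species=False)
        p = pmf(profile, 360.0)
        # compare well-bottom to outside plateau: ΔW should equal Δu
        in_well = (p.r > 0.5) & (p.r < 0.8)
        outside = (p.r > 1.2) & (p.r < 2.0)
        delta = np.nanmean(p.W[in_well]) - np.nanmean(p.W[outside])
        assert abs(delta - depth) < 0.3


class TestExtremaAndGate:
    def _pmf_from_curve(self, r, W):
        p = PmfProfile(r=r, W=W, temperature=360.0, g=np.exp(-W / (KB_KJ_PER_MOL_K * 360)))
        return p

    def test_single_well_barrier(self):
        r = np.linspace(0.1, 2.0, 200)
        W = 3.0 * np.exp(-((r - 1.2) ** 2) / 0.01) - 4.0 * np.exp(-((r - 0.5) ** 2) / 0.02)
        p = locate_extrema(self._pmf_from_curve(r, W), smoothing_window=1)
        kinds = [e.kind for e in p.extrema]
        assert kinds.count("CM") == 1
        cm = next(e for e in p.extrema if e.kind == "CM")
        rim = next(e for e in p.extrema if e.kind == "MAX")
        assert p.barriers["CM"] == pytest.approx(rim.W - cm.W)
        assert cm.r == pytest.approx(0.5, abs=0.02)

    def test_double_well_labels_and_barrier_arithmetic(self):
        r = np.linspace(0.1, 3.0, 600)
        W = (-4.0 * np.exp(-((r - 0.5) ** 2) / 0.01)
             + 1.0 * np.exp(-((r - 1.0) ** 2) / 0.01)
             - 1.0 * np.exp(-((r - 1.5) ** 2) / 0.01))
        p = locate_extrema(self._pmf_from_curve(r, W), smoothing_window=1)
        labels = [e.kind for e in p.extrema if e.kind != "MAX"]
        assert labels == ["CM", "SAM"]
        # CM at −4, first maximum at +1 → dissociation barrier 5 kJ/mol
        assert p.barriers["CM"] == pytest.approx(5.0, abs=0.05)

    def test_printed_barrier_conversion_to_thermal_units(self):
        kT = KB_KJ_PER_MOL_K * 360.0
        assert round(12.94 / kT, 1) == 4.3
        assert round(7.6 / kT, 1) == 2.5

    @pytest.mark.parametrize(
        "w_cm,expected",
        [(-1.0, False), (-7.0, True), (-2 * KB_KJ_PER_MOL_K * 360.0, False)],
    )
    def test_stability_gate(self, w_cm, expected):
        p = PmfProfile(r=np.linspace(0.1, 1, 10), W=np.zeros(10), temperature=360.0,
                       g=np.ones(10))
        p.extrema = [Extremum("CM", 0.5, w_cm)]
        assert stability_gate(p, threshold_kT=2.0) is expected

    def test_gate_requires_located_cm(self):
        p = PmfProfile(r=np.linspace(0.1, 1, 10), W=np.zeros(10), temperature=360.0,
                       g=np.ones(10))
        with pytest.raises(ValueError, match="contact minimum"):
            stability_gate(p)

    def test_no_minimum_raises(self):
        r = np.linspace(0.1, 2.0, 100)
        with pytest.raises(ValueError, match="no PMF minimum"):
            locate_extrema(self._pmf_from_curve(r, -r), smoothing_window=1,
                           min_prominence=0.1)
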