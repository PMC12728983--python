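"""Synthetic trajectories with known ground truth.

These miniature generators stand in for microsecond all-atom melt
simulations: a freely-jointed-chain melt for conformational statistics,
an overdamped bead-spring (Rouse) integrator for relaxation spectra,
planted cluster configurations for single-linkage analysis, a two-particle
Metropolis sampler for PMF recovery, and a stochastic exchange process for
survival/hydrogen-bond kinetics. Every generator is exactly reproducible
from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from numba import njit

from .core import Topology, Trajectory, wrap_positions

__all__ = [
    "GaussianMeltSpec",
    "RouseBDSpec",
    "PlantedClusterSpec",
    "StickyPairSpec",
    "ExchangeSpec",
    "generate_gaussian_melt",
    "simulate_rouse_bd",
    "generate_planted_clusters",
    "simulate_sticky_pair",
    "generate_exchange_trajectory",
    "rouse_mode_time",
]

from .core import KB_KJ_PER_MOL_K as _KB


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianMeltSpec:
    """Freely-jointed-chain melt: independent frames of ideal chains."""

    n_chains: int = 512
    n_bonds: int = 200
    bond_length: float = 0.15
    box_length: float = 12.0
    n_frames: int = 50
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_bonds < 1:
            raise ValueError("n_bonds must be >= 1")
        if self.box_length <= 0:
            raise ValueError("box_length must be positive")
        if self.n_chains < 1 or self.n_frames < 1:
            raise ValueError("n_chains and n_frames must be >= 1")


@dataclass(frozen=True)
class RouseBDSpec:
    """Overdamped Langevin bead-spring chain (harmonic springs, no EV)."""

    n_beads: int = 12
    spring_k: float = 100.0      # kJ mol^-1 nm^-2
    friction: float = 100.0      # amu ps^-1
    temperature: float = 360.0   # K
    dt: float = 0.01             # ps
    n_steps: int = 2_000_000
    stride: int = 100
    seed: int = 7
    end_constraint: str = "free"

    def __post_init__(self) -> None:
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        if self.spring_k > 0 and self.dt * self.spring_k / self.friction >= 0.1:
            raise ValueError(
                "unstable integration: require dt*spring_k/friction < 0.1, got "
                f"{self.dt * self.spring_k / self.friction:.3f}"
            )
        if self.end_constraint not in ("free", "fixed"):
            raise ValueError("end_constraint must be 'free' or 'fixed'")


@dataclass(frozen=True)
class PlantedClusterSpec:
    """Point configuration whose single-linkage partition is known exactly."""

    size_counts: Mapping[int, int] = field(default_factory=lambda: {2: 3, 1: 4})
    intra_spacing: float = 0.3   # nm, consecutive members of one cluster
    inter_spacing: float = 1.5   # nm, minimum gap between clusters
    box_length: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intra_spacing >= self.inter_spacing:
            raise ValueError("intra_spacing must be smaller than inter_spacing")
        for s, c in self.size_counts.items():
            if s < 1 or c < 0:
                raise ValueError("size_counts keys must be >= 1 and values >= 0")


@dataclass(frozen=True)
class StickyPairSpec:
    """Two-particle Metropolis MC in a periodic box with tabulated u(r)."""

    r_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.01, 2.5, 250))
    u_grid: np.ndarray = field(default_factory=lambda: np.zeros(250))
    temperature: float = 360.0
    box_length: float = 5.0
    n_sweeps: int = 100_000
    step_size: float = 0.2       # nm, max trial displacement per component
    record_stride: int = 10      # sweeps between recorded frames
    seed: int = 1

    def __post_init__(self) -> None:
        r = np.asarray(self.r_grid, dtype=float)
        u = np.asarray(self.u_grid, dtype=float)
        if r.shape != u.shape or r.ndim != 1:
            raise ValueError("r_grid and u_grid must be 1-D and matching")
        if not np.all(np.isfinite(u)):
            raise ValueError("u_grid must be finite")
        if r.max() < self.box_length / 2:
            raise ValueError("r_grid must cover (0, box_length/2]")
        object.__setattr__(self, "r_grid", r)
        object.__setattr__(self, "u_grid", u)


@dataclass(frozen=True)
class ExchangeSpec:
    """Particles with exponential residence/absence around a static site."""

    n_particles: int = 50
    sphere_radius: float = 0.5   # nm
    mean_residence: float = 50.0  # ps
    dt: float = 1.0              # ps
    n_frames: int = 2000
    seed: int = 11

    def __post_init__(self) -> None:
        if self.mean_residence <= self.dt:
            raise ValueError("mean_residence must exceed dt")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _random_unit_vectors(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Uniform points on the unit sphere, shape (..., 3)."""
    v = rng.normal(size=shape + (3,))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def generate_gaussian_melt(spec: GaussianMeltSpec) -> tuple[Trajectory, Topology]:
    """Independent frames of freely-jointed chains placed randomly in a box.

    Each chain is a random walk of ``n_bonds`` fixed-length bonds with
    uniformly random orientations, so ⟨Ree²⟩ = n·b² and
    ⟨Rg²⟩ = b²·n(n+2)/(6(n+1)) exactly. Coordinates are left unwrapped
    (chains whole); first/last beads of each chain are tagged as
    ``alpha_end`` / ``omega_end``.
    """
    rng = np.random.default_rng(spec.seed)
    n_atoms_per_chain = spec.n_bonds + 1
    T, C, A = spec.n_frames, spec.n_chains, n_atoms_per_chain
    starts = rng.uniform(0, spec.box_length, size=(T, C, 3))
    bonds = _random_unit_vectors(rng, (T, C, spec.n_bonds)) * spec.bond_length
    pos = np.empty((T, C, A, 3))
    pos[:, :, 0] = starts
    pos[:, :, 1:] = starts[:, :, None, :] + np.cumsum(bonds, axis=2)
    positions = pos.reshape(T, C * A, 3)
    times = np.arange(T, dtype=float)
    boxes = np.full((T, 3), spec.box_length)
    traj = Trajectory(positions, times, boxes, wrapped=False)
    chains = [np.arange(i * A, (i + 1) * A, dtype=np.intp) for i in range(C)]
    topo = Topology(
        n_atoms=C * A,
        masses=np.ones(C * A),
        charges=np.zeros(C * A),
        chains=chains,
        named_selections={
            "alpha_end": np.array([c[0] for c in chains], dtype=np.intp),
            "omega_end": np.array([c[-1] for c in chains], dtype=np.intp),
        },
    )
    return traj, topo


@njit(cache=True)
def _rouse_kernel(
    x0: np.ndarray,
    n_steps: int,
    stride: int,
    kz_dt: float,
    noise_amp: float,
    fixed_ends: bool,
    noise: np.ndarray,
) -> np.ndarray:
    """Euler–Maruyama loop; noise is pre-drawn (n_steps, N, 3)."""
    N = x0.shape[0]
    n_out = n_steps // stride
    out = np.empty((n_out, N, 3))
    x = x0.copy()
    f = np.empty((N, 3))
    for step in range(n_steps):
        for d in range(3):
            for j in range(N):
                acc = 0.0
                if j > 0:
                    acc += x[j - 1, d] - x[j, d]
                if j < N - 1:
                    acc += x[j + 1, d] - x[j, d]
                f[j, d] = acc
        for j in range(N):
            for d in range(3):
                x[j, d] += kz_dt * f[j, d] + noise_amp * noise[step, j, d]
        if fixed_ends:
            for d in range(3):
                x[0, d] = x0[0, d]
                x[N - 1, d] = x0[N - 1, d]
        if (step + 1) % stride == 0:
            out[(step + 1) // stride - 1] = x
    return out


def simulate_rouse_bd(spec: RouseBDSpec) -> Trajectory:
    """Brownian-dynamics trajectory of one harmonic bead-spring chain.

    Integrates dR_j = (k/ζ)(R_{j+1} − 2R_j + R_{j−1})dt + √(2kBT dt/ζ)·η
    with free or fixed ends, returning positions every ``stride`` steps in
    a large non-periodic box. The free-end discrete mode spectrum is
    τ_p = ζ / (4k sin²(pπ/2N)); see :func:`rouse_mode_time`.
    """
    rng = np.random.default_rng(spec.seed)
    N = spec.n_beads
    # start from a compact random coil
    x0 = np.cumsum(rng.normal(scale=0.1, size=(N, 3)), axis=0)
    kz_dt = spec.spring_k / spec.friction * spec.dt
    noise_amp = np.sqrt(2.0 * _KB * spec.temperature * spec.dt / spec.friction)
    # pre-draw noise in blocks to bound memory
    block = 200_000
    chunks = []
    x = x0.copy()
    remaining = spec.n_steps
    done = 0
    while remaining > 0:
        n = min(block, remaining)
        # keep the block a multiple of stride so output slicing stays aligned
        n = max(spec.stride, (n // spec.stride) * spec.stride)
        n = min(n, remaining)
        noise = rng.normal(size=(n, N, 3))
        out = _rouse_kernel(x, n, spec.stride, kz_dt, noise_amp,
                            spec.end_constraint == "fixed", noise)
        if out.shape[0]:
            x = out[-1].copy()
            chunks.append(out)
        done += n
        remaining -= n
    pos = np.concatenate(chunks, axis=0)
    if np.any(np.abs(pos) > 1e6):
        raise RuntimeError(
            "Rouse BD diverged (|coordinate| > 1e6 nm); "
            "check the stability condition dt*spring_k/friction < 0.1"
        )
    times = (np.arange(pos.shape[0], dtype=float) + 1) * spec.stride * spec.dt
    times -= times[0]
    return Trajectory(pos, times, boxes=None, wrapped=False)


def rouse_mode_time(spec: RouseBDSpec, p: int) -> float:
    """Ground-truth relaxation time of mode p for the free-end discrete chain."""
    N = spec.n_beads
    return spec.friction / (4.0 * spec.spring_k * np.sin(p * np.pi / (2 * N)) ** 2)


def generate_planted_clusters(spec: PlantedClusterSpec) -> tuple[np.ndarray, np.ndarray]:
    """Points whose single-linkage partition is known for any threshold
    in (intra_spacing, inter_spacing).

    Returns (positions (S, 3), labels (S,)). Cluster members sit on a line
    with consecutive spacing exactly ``intra_spacing``; cluster anchors sit
    on a cubic grid with pitch ≥ inter_spacing + max cluster extent, so the
    nearest inter-cluster distance exceeds ``inter_spacing``.
    """
    rng = np.random.default_rng(spec.seed)
    sizes: list[int] = []
    for s in sorted(spec.size_counts):
        sizes.extend([s] * spec.size_counts[s])
    if not sizes:
        raise ValueError("size_counts is empty")
    rng.shuffle(sizes)
    max_extent = (max(sizes) - 1) * spec.intra_spacing
    pitch = spec.inter_spacing + max_extent + 1e-6
    per_side = max(1, int(np.floor(spec.box_length / pitch)))
    if per_side**3 < len(sizes):
        raise ValueError(
            f"cannot place {len(sizes)} clusters at pitch {pitch:.3f} nm "
            f"in a {spec.box_length} nm box"
        )
    grid = np.array(
        [(i, j, k) for i in range(per_side) for j in range(per_side) for k in range(per_side)],
        dtype=float,
    ) * pitch + pitch / 2.0
    anchor_ids = rng.choice(len(grid), size=len(sizes), replace=False)
    positions, labels = [], []
    for label, (size, aid) in enumerate(zip(sizes, anchor_ids)):
        direction = _random_unit_vectors(rng, ())
        for m in range(size):
            positions.append(grid[aid] + direction * (m * spec.intra_spacing))
            labels.append(label)
    pos = np.asarray(positions)
    return pos, np.asarray(labels, dtype=np.intp)


@njit(cache=True)
def _sticky_pair_kernel(
    pos0: np.ndarray,
    n_sweeps: int,
    record_stride: int,
    step: float,
    L: float,
    beta: float,
    r_grid: np.ndarray,
    u_grid: np.ndarray,
    seed: int,
) -> np.ndarray:
    np.random.seed(seed)
    pos = pos0.copy()

    def energy(p):
        r2 = 0.0
        for d in range(3):
            dd = p[1, d] - p[0, d]
            dd -= np.round(dd / L) * L
            r2 += dd * dd
        return np.interp(np.sqrt(r2), r_grid, u_grid)

    e = energy(pos)
    n_out = n_sweeps // record_stride
    out = np.empty((n_out, 2, 3))
    for sweep in range(n_sweeps):
        i = sweep % 2
        old = pos[i].copy()
        for d in range(3):
            pos[i, d] = (pos[i, d] + (np.random.random() * 2.0 - 1.0) * step) % L
        e_new = energy(pos)
        if e_new > e and np.random.random() >= np.exp(-beta * (e_new - e)):
            pos[i] = old
        else:
            e = e_new
        if (sweep + 1) % record_stride == 0:
            out[(sweep + 1) // record_stride - 1] = pos
    return out


def simulate_sticky_pair(spec: StickyPairSpec) -> Trajectory:
    """Metropolis Monte Carlo of two particles interacting via tabulated u(r).

    One sweep = one single-particle trial move (uniform displacement,
    acceptance min(1, exp(−Δu/kBT))); wrapped positions are recorded
    every ``record_stride`` sweeps, with the sweep index as the frame
    "time" in ps so the trajectory container can carry it.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.box_length
    beta = 1.0 / (_KB * spec.temperature)
    pos0 = rng.uniform(0, L, size=(2, 3))
    out = _sticky_pair_kernel(
        pos0, spec.n_sweeps, spec.record_stride, spec.step_size, L, beta,
        np.ascontiguousarray(spec.r_grid), np.ascontiguousarray(spec.u_grid),
        spec.seed % 2**31,
    )
    times = np.arange(out.shape[0], dtype=float) * spec.record_stride
    boxes = np.full((out.shape[0], 3), L)
    return Trajectory(out, times, boxes, wrapped=True)


def generate_exchange_trajectory(
    spec: ExchangeSpec,
) -> tuple[Trajectory, Topology, np.ndarray]:
    """Particles that dwell in a sphere, leave, and re-enter stochastically.

    Atom 0 is the static reference site at the box center; atoms 1..n are
    exchange particles. Residence and absence intervals are exponential
    with mean ``mean_residence`` each, so the strict survival probability
    of in-sphere particles decays as exp(−τ/mean_residence). Returns
    (trajectory, topology, indicator) where indicator[t, i] is the
    ground-truth inside/outside state of particle i at frame t.
    """
    rng = np.random.default_rng(spec.seed)
    T, P = spec.n_frames, spec.n_particles
    L = max(8.0 * spec.sphere_radius, 4.0)
    center = np.full(3, L / 2.0)
    inside_state = np.empty((T, P), dtype=bool)
    # simulate the two-state renewal process per particle in continuous time
    for i in range(P):
        state = bool(rng.random() < 0.5)
        t_next = rng.exponential(spec.mean_residence)
        for t in range(T):
            now = t * spec.dt
            while now >= t_next:
                state = not state
                t_next += rng.exponential(spec.mean_residence)
            inside_state[t, i] = state
    # positions: uniform within the sphere while inside, far corner while out
    u = rng.random((T, P))
    radii = spec.sphere_radius * 0.98 * u ** (1.0 / 3.0)
    dirs = _random_unit_vectors(rng, (T, P))
    inside_pos = center + radii[..., None] * dirs
    outside_pos = center + np.array([3.0 * spec.sphere_radius, 0.0, 0.0])
    particle_pos = np.where(inside_state[..., None], inside_pos, outside_pos)
    positions = np.empty((T, P + 1, 3))
    positions[:, 0] = center
    positions[:, 1:] = particle_pos
    times = np.arange(T, dtype=float) * spec.dt
    boxes = np.full((T, 3), L)
    traj = Trajectory(positions, times, boxes, wrapped=True)
    topo = Topology(
        n_atoms=P + 1,
        masses=np.ones(P + 1),
        charges=np.zeros(P + 1),
        chains=[],
        named_selections={
            "reference_site": np.array([0], dtype=np.intp),
            "exchange_particles": np.arange(1, P + 1, dtype=np.intp),
        },
    )
    return traj, topo, inside_state
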