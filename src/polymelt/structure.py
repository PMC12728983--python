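"""Finite-cutoff RDFs, running coordination numbers, and PMFs.

The radial distribution function here is normalized not by the global
number density but by the mean density of the partner species within a
ball of radius r_c (half the box edge by default) around each reference
particle. For small systems the two normalizations differ measurably;
the finite-cutoff form guarantees that the density-weighted average of
g(r) over the r ≤ r_c ball is exactly 1. The potential of mean force is
the Boltzmann inversion W(r) = −kB·T·ln g(r), with minima labelled in
radial order (contact, solvent-assisted, solvent-shared,
solvent-separated) and per-minimum dissociation barriers measured to the
next maximum at larger r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import KB_KJ_PER_MOL_K, minimum_image_displacement

__all__ = [
    "RdfProfile",
    "RcnProfile",
    "PmfProfile",
    "Extremum",
    "rdf",
    "rcn",
    "pmf",
    "locate_extrema",
    "stability_gate",
    "MINIMUM_LABELS",
]

#: PMF minimum labels in radial order.
MINIMUM_LABELS = ("CM", "SAM", "SShM", "SSM")


@dataclass
class RdfProfile:
    bin_centers: np.ndarray     # nm
    g: np.ndarray
    r_cut: float                # nm, normalization radius r_c
    counts: np.ndarray          # mean pair count per bin per reference particle
    species: tuple[str, str] = ("alpha", "beta")
    same_species: bool = False
    n_frames: int = 0
    mean_partner_density: float = 0.0  # ⟨ρ_β(r_c)⟩, nm⁻³

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


@dataclass
class RcnProfile:
    r: np.ndarray
    n_cum: np.ndarray
    rho_beta: float


@dataclass(frozen=True)
class Extremum:
    kind: str                   # CM | SAM | SShM | SSM | MAX
    r: float                    # nm
    W: float                    # kJ/mol


@dataclass
class PmfProfile:
    r: np.ndarray
    W: np.ndarray               # kJ/mol, NaN where g = 0
    temperature: float
    g: np.ndarray
    extrema: list[Extremum] = field(default_factory=list)
    barriers: dict[str, float] = field(default_factory=dict)


def rdf(
    positions_alpha: np.ndarray,
    positions_beta: np.ndarray,
    boxes: np.ndarray,
    bin_width: float = 0.002,
    r_cut: float | None = None,
    same_species: bool | None = None,
    species: tuple[str, str] = ("alpha", "beta"),
    global_density_norm: bool = False,
) -> RdfProfile:
    """Finite-cutoff-normalized g_αβ(r) from wrapped center positions.

    ``positions_alpha`` / ``positions_beta`` are (T, Nα, 3) / (T, Nβ, 3)
    per-frame centers; pass the same array for a same-species RDF (the
    self pair is then excluded). ``boxes`` is (T, 3). The default r_c is
    half the shortest box edge. With ``global_density_norm`` the
    denominator is instead the global partner density Nβ/V (sensitivity
    alternative).
    """
    pa = np.asarray(positions_alpha, dtype=float)
    pb = np.asarray(positions_beta, dtype=float)
    boxes = np.asarray(boxes, dtype=float)
    if pa.ndim != 3 or pb.ndim != 3:
        raise ValueError("positions must be (T, N, 3)")
    if pa.shape[1] == 0 or pb.shape[1] == 0:
        raise ValueError("empty selection for RDF")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    half_min = float(np.min(boxes)) / 2.0
    if r_cut is None:
        r_cut = half_min
    elif r_cut > half_min + 1e-12:
        raise ValueError(f"r_cut {r_cut} exceeds half the shortest box edge {half_min}")
    if same_species is None:
        same_species = positions_alpha is positions_beta or (
            pa.shape == pb.shape and np.array_equal(pa, pb)
        )

    n_bins = int(np.ceil(r_cut / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    T = pa.shape[0]
    Na = pa.shape[1]
    for t in range(T):
        d = minimum_image_displacement(pa[t][:, None, :], pb[t][None, :, :], boxes[t])
        r = np.linalg.norm(d, axis=-1)
        if same_species:
            np.fill_diagonal(r, np.inf)
        r = r[r < r_cut]
        counts += np.histogram(r, bins=edges)[0]
    counts /= T * Na  # mean pair count per reference particle per frame

    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ball_vol = 4.0 / 3.0 * np.pi * r_cut**3
    local_density = counts / shell_vol
    if global_density_norm:
        vol = float(np.mean(np.prod(boxes, axis=1)))
        n_partners = pb.shape[1] - (1 if same_species else 0)
        ref_density = n_partners / vol
    else:
        ref_density = counts.sum() / ball_vol  # ⟨ρ_β(r_c)⟩ from the same frames
    if ref_density <= 0:
        raise ValueError("no pairs found within r_cut; cannot normalize RDF")
    g = local_density / ref_density
    centers = (edges[:-1] + edges[1:]) / 2.0
    return RdfProfile(
        bin_centers=centers,
        g=g,
        r_cut=float(r_cut),
        counts=counts,
        species=species,
        same_species=bool(same_species),
        n_frames=T,
        mean_partner_density=float(ref_density),
    )


def rcn(
    profile: RdfProfile,
    rho_beta: float,
    r1: float = 0.0,
    r2: float | None = None,
) -> float:
    """Running coordination number n = 4πρ_β ∫_{r1}^{r2} r²g(r) dr.

    Trapezoidal quadrature on the bin grid. With ``r2`` omitted the upper
    bound is the first minimum of g after its first peak (first-shell
    coordination number).
    """
    r = profile.bin_centers
    g = profile.g
    if r2 is None:
        peaks, _ = find_peaks(g)
        if peaks.size == 0:
            raise ValueError("no RDF peak found; supply r2 explicitly")
        after = g[peaks[0]:]
        minima, _ = find_peaks(-after)
        if minima.size == 0:
            raise ValueError("no first minimum found after the first peak")
        r2 = float(r[peaks[0] + minima[0]])
    if not (0 <= r1 < r2 <= profile.r_cut + 1e-12):
        raise ValueError(f"invalid shell bounds ({r1}, {r2}) for r_cut {profile.r_cut}")
    # bin-wise integration, exact for the histogram estimate of g:
    # ∫ r²g dr over each bin = g_i (hi³ − lo³)/3 with edges clipped to [r1, r2]
    dw = profile.bin_width
    lo = np.clip(r - dw / 2, r1, r2)
    hi = np.clip(r + dw / 2, r1, r2)
    integral = np.sum(g * (hi**3 - lo**3) / 3.0)
    return float(4.0 * np.pi * rho_beta * integral)


def rcn_profile(profile: RdfProfile, rho_beta: float) -> RcnProfile:
    """Cumulative coordination number n(r) on the full bin grid."""
    r = profile.bin_centers
    dw = profile.bin_width
    per_bin = profile.g * ((r + dw / 2) ** 3 - (r - dw / 2) ** 3) / 3.0
    cum = np.concatenate(([0.0], np.cumsum(per_bin)))
    edges = np.concatenate(([r[0] - dw / 2], r + dw / 2))
    return RcnProfile(r=edges, n_cum=4.0 * np.pi * rho_beta * cum, rho_beta=rho_beta)


def pmf(profile: RdfProfile, temperature: float) -> PmfProfile:
    """Potential of mean force W(r) = −kB·T·ln g(r) (natural log).

    Bins with g = 0 are masked (NaN), not −∞.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    g = profile.g
    W = np.full_like(g, np.nan)
    pos = g > 0
    W[pos] = -KB_KJ_PER_MOL_K * temperature * np.log(g[pos])
    return PmfProfile(
        r=profile.bin_centers.copy(), W=W, temperature=temperature, g=g.copy()
    )


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average that tolerates NaN gaps."""
    if window <= 1:
        return y
    kernel = np.ones(window)
    mask = np.isfinite(y)
    filled = np.where(mask, y, 0.0)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(mask.astype(float), kernel, mode="same")
    out = np.full_like(y, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    out[~mask] = np.nan
    return out


def locate_extrema(
    profile: PmfProfile,
    smoothing_window: int = 5,
    min_prominence: float = 0.2,
) -> PmfProfile:
    """Annotate the PMF with labelled minima, maxima and barriers.

    Minima and maxima of the (smoothed) W are found with a prominence
    floor that suppresses bin noise; minima are labelled CM, SAM, SShM,
    SSM purely by radial order, maxima as MAX. Each minimum's
    dissociation barrier is W(next maximum at larger r) − W(minimum).
    """
    finite = np.isfinite(profile.W)
    if finite.sum() < 10:
        raise ValueError("PMF has fewer than 10 unmasked bins")
    Ws = _smooth(profile.W, smoothing_window)
    # operate on the contiguous finite tail (small r is usually masked)
    idx = np.flatnonzero(np.isfinite(Ws))
    sub = Ws[idx]
    minima, _ = find_peaks(-sub, prominence=min_prominence)
    maxima, _ = find_peaks(sub, prominence=min_prominence)
    if minima.size == 0:
        raise ValueError("no PMF minimum found")
    extrema: list[Extremum] = []
    for rank, m in enumerate(minima):
        label = MINIMUM_LABELS[rank] if rank < len(MINIMUM_LABELS) else f"MIN{rank + 1}"
        extrema.append(Extremum(label, float(profile.r[idx[m]]), float(Ws[idx[m]])))
    for m in maxima:
        extrema.append(Extremum("MAX", float(profile.r[idx[m]]), float(Ws[idx[m]])))
    extrema.sort(key=lambda e: e.r)
    barriers: dict[str, float] = {}
    for i, e in enumerate(extrema):
        if e.kind == "MAX":
            continue
        for nxt in extrema[i + 1:]:
            if nxt.kind == "MAX":
                barriers[e.kind] = nxt.W - e.W
                break
    profile.extrema = extrema
    profile.barriers = barriers
    return profile


def stability_gate(
    profile: PmfProfile,
    threshold_kT: float = 2.0,
    temperature: float | None = None,
) -> bool:
    """Cluster-stability criterion |W(r_CM)| > threshold·kB·T (strict).

    The contact minimum must have been located (see
    :func:`locate_extrema`).
    """
    cm = next((e for e in profile.extrema if e.kind == "CM"), None)
    if cm is None:
        raise ValueError("no contact minimum located; run locate_extrema first")
    T = temperature if temperature is not None else profile.temperature
    return bool(abs(cm.W) > threshold_kT * KB_KJ_PER_MOL_K * T)
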