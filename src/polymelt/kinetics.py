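"""Residence/exchange kinetics of terminal groups and hydrogen bonds.

Survival probability P(τ) of target sites remaining in a spherical
region, geometric hydrogen-bond detection, and the continuous /
intermittent hydrogen-bond time correlation functions with their
stretched-exponential fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import minimum_image_displacement
from .dynamics import CorrelationCurve, FitResult, fit_relaxation

__all__ = [
    "SurvivalCurve",
    "HbondSeries",
    "HbondCorrelation",
    "survival_probability",
    "detect_hbonds",
    "hbond_correlations",
]

_MAX_ORIGINS = 10_000


@dataclass
class SurvivalCurve:
    tau: np.ndarray             # ps
    P: np.ndarray
    sphere_radius: float        # nm
    n_origins: int              # M_tot (origin × reference-site pairs used)
    fit: FitResult | None = None

    def __post_init__(self) -> None:
        if abs(self.P[0] - 1.0) > 1e-9:
            raise ValueError("P(0) must equal 1")
        if np.any(np.diff(self.P) > 1e-12):
            raise ValueError("P must be non-increasing in tau")


@dataclass
class HbondSeries:
    """Per-frame 0/1 indicators for each donor–acceptor pair, (T, n_pairs)."""

    h: np.ndarray
    dist_cutoff: float          # H···A cutoff, nm
    angle_cutoff: float         # D–H···A cutoff, degrees

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h)
        if not np.isin(self.h, (0, 1)).all():
            raise ValueError("indicators must be 0/1")
        self.h = self.h.astype(bool)


@dataclass
class HbondCorrelation:
    continuous: CorrelationCurve
    intermittent: CorrelationCurve
    fit_continuous: FitResult | None = None
    fit_intermittent: FitResult | None = None


# ---------------------------------------------------------------------------
# Survival probability
# ---------------------------------------------------------------------------

def _run_lengths(flags: np.ndarray) -> np.ndarray:
    """run[t] = consecutive True frames starting at t (along axis 0)."""
    run = np.zeros(flags.shape, dtype=np.int64)
    run[-1] = flags[-1]
    for t in range(flags.shape[0] - 2, -1, -1):
        run[t] = np.where(flags[t], run[t + 1] + 1, 0)
    return run


def _continuous_counts(inside: np.ndarray, max_lag: int) -> tuple[np.ndarray, int]:
    """Strict survival sums from a boolean (T, R, G) array.

    Origins are restricted to t ≤ T−1−max_lag so every origin covers the
    full lag range; P(τ) is then a mean of per-origin non-increasing
    sequences and is itself non-increasing. Returns (P, origin count).
    """
    T = inside.shape[0]
    T0 = T - max_lag
    run = _run_lengths(inside)  # (T, R, G)
    N_t = inside[:T0].sum(axis=2)  # (T0, R)
    origin_mask = N_t > 0
    n_origins = int(origin_mask.sum())
    if n_origins == 0:
        raise ValueError("no origin with any target inside the sphere")
    stride = 1
    if n_origins > _MAX_ORIGINS:
        stride = int(np.ceil(T0 / (_MAX_ORIGINS / max(1, inside.shape[1]))))
        origin_mask = origin_mask.copy()
        keep = np.zeros(T0, dtype=bool)
        keep[::stride] = True
        origin_mask &= keep[:, None]
        n_origins = int(origin_mask.sum())
    run0 = run[:T0]
    P = np.empty(max_lag + 1)
    safe_N = np.where(origin_mask, N_t, 1)
    for tau in range(max_lag + 1):
        surv = (run0 >= tau + 1).sum(axis=2)  # (T0, R)
        frac = np.where(origin_mask, surv / safe_N, 0.0)
        P[tau] = frac.sum() / n_origins
    return P, n_origins


def survival_probability(
    reference_positions: np.ndarray,
    target_positions: np.ndarray,
    boxes: np.ndarray,
    sphere_radius: float,
    dt: float,
    max_lag_frames: int | None = None,
    mode: str = "strict",
    fit: bool = True,
) -> SurvivalCurve:
    """P(τ): probability that targets found in a sphere remain there.

    ``reference_positions`` is (T, R, 3) — one sphere per reference site
    per frame; ``target_positions`` is (T, G, 3). ``mode`` is ``strict``
    (inside at every sampled frame of [t, t+τ]; default) or ``lenient``
    (inside at t and t+τ only). A KWW fit with mean survival time
    ⟨τ_sp⟩ = (τ/β)Γ(1/β) is attached.
    """
    ref = np.asarray(reference_positions, dtype=float)
    tgt = np.asarray(target_positions, dtype=float)
    if ref.ndim == 2:
        ref = ref[:, None, :]
    if sphere_radius <= 0:
        raise ValueError("sphere_radius must be positive")
    T = ref.shape[0]
    d = minimum_image_displacement(
        ref[:, :, None, :], tgt[:, None, :, :], np.asarray(boxes)[:, None, None, :]
    )
    inside = np.linalg.norm(d, axis=-1) <= sphere_radius  # (T, R, G)
    if max_lag_frames is None:
        max_lag_frames = T // 2
    max_lag_frames = min(max_lag_frames, T - 1)
    if mode == "strict":
        P, n_origins = _continuous_counts(inside, max_lag_frames)
    elif mode == "lenient":
        sums = np.zeros(max_lag_frames + 1)
        N_t = inside.sum(axis=2)
        n_origins = 0
        for t in range(T - max_lag_frames):
            for r in range(inside.shape[1]):
                if N_t[t, r] == 0:
                    continue
                n_origins += 1
                both = (inside[t, r] & inside[t : t + max_lag_frames + 1, r, :]).sum(axis=1)
                sums += both / N_t[t, r]
        if n_origins == 0:
            raise ValueError("no origin with any target inside the sphere")
        P = sums / n_origins
        # lenient re-entries can produce non-monotone P; keep raw values
    else:
        raise ValueError(f"unknown survival mode {mode!r}")
    tau = np.arange(P.size) * dt
    if mode == "lenient":
        curve = SurvivalCurve.__new__(SurvivalCurve)
        curve.tau, curve.P = tau, P
        curve.sphere_radius, curve.n_origins, curve.fit = sphere_radius, n_origins, None
    else:
        curve = SurvivalCurve(tau=tau, P=P, sphere_radius=sphere_radius, n_origins=n_origins)
    if fit and P.size >= 5 and np.ptp(P) > 0:
        cc = CorrelationCurve(lag=tau, value=P, n_origins=np.full(P.size, n_origins))
        try:
            curve.fit = fit_relaxation(cc, model="kww", min_origins=1)
        except (RuntimeError, ValueError):
            curve.fit = None
    return curve


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def detect_hbonds(
    donor_positions: np.ndarray,
    hydrogen_positions: np.ndarray,
    acceptor_positions: np.ndarray,
    box: np.ndarray,
    dist_cutoff: float = 0.25,
    angle_cutoff: float = 130.0,
) -> np.ndarray:
    """Geometric hydrogen-bond indicators for one frame.

    ``donor_positions``/``hydrogen_positions`` are (n_dh, 3) covalently
    paired D–H sites; ``acceptor_positions`` is (n_acc, 3). A bond exists
    iff the minimum-image H···A distance is ≤ ``dist_cutoff`` (nm) and
    the D–H···A angle is ≥ ``angle_cutoff`` (degrees). Returns a boolean
    (n_dh, n_acc) matrix.
    """
    D = np.atleast_2d(np.asarray(donor_positions, dtype=float))
    H = np.atleast_2d(np.asarray(hydrogen_positions, dtype=float))
    A = np.atleast_2d(np.asarray(acceptor_positions, dtype=float))
    if D.shape != H.shape:
        raise ValueError("each hydrogen needs exactly one bonded donor")
    ha = minimum_image_displacement(H[:, None, :], A[None, :, :], box)  # H→A
    r_ha = np.linalg.norm(ha, axis=-1)
    hd = minimum_image_displacement(H, D, box)  # H→D
    r_hd = np.linalg.norm(hd, axis=-1)
    if np.any(r_hd == 0):
        raise ValueError("coincident donor and hydrogen positions")
    cos = np.einsum("daj,dj->da", ha, hd) / (r_ha * r_hd[:, None])
    angle = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    # D-H···A angle: vectors H→D and H→A; linear arrangement gives 180°
    return (r_ha <= dist_cutoff) & (angle >= angle_cutoff)


def hbond_series(
    trajectory_positions: np.ndarray,
    boxes: np.ndarray,
    donor_idx: np.ndarray,
    hydrogen_idx: np.ndarray,
    acceptor_idx: np.ndarray,
    dist_cutoff: float = 0.25,
    angle_cutoff: float = 130.0,
) -> HbondSeries:
    """Indicator time series over all frames, flattened to (T, n_pairs)."""
    T = trajectory_positions.shape[0]
    out = []
    for t in range(T):
        p = trajectory_positions[t]
        h = detect_hbonds(
            p[donor_idx], p[hydrogen_idx], p[acceptor_idx],
            boxes[t], dist_cutoff, angle_cutoff,
        )
        out.append(h.ravel())
    return HbondSeries(np.asarray(out), dist_cutoff, angle_cutoff)


def hbond_correlations(
    series: HbondSeries | np.ndarray,
    dt: float,
    max_lag_frames: int | None = None,
    fit: bool = True,
) -> HbondCorrelation:
    """Continuous and intermittent hydrogen-bond correlation functions.

    Intermittent: C_I(t) = ⟨Σ_ij h_ij(t0)·h_ij(t0+t)⟩ / ⟨Σ_ij h_ij(t0)²⟩
    over all origins t0. Continuous: the same numerator but a pair counts
    at t0+t only if it stayed bonded at every intermediate frame. The
    continuous curve gets a KWW fit, the intermittent one a
    plateau-KWW fit C(t) = P + C(0)exp[−(t/τ)^β].
    """
    h = series.h if isinstance(series, HbondSeries) else np.asarray(series, dtype=bool)
    if h.ndim != 2:
        raise ValueError("indicator series must be (T, n_pairs)")
    T = h.shape[0]
    if T < 2:
        raise ValueError("need at least 2 frames")
    if not h.any():
        raise ValueError("no hydrogen bonds ever formed")
    if max_lag_frames is None:
        max_lag_frames = T - 1
    max_lag_frames = min(max_lag_frames, T - 1)
    L = max_lag_frames + 1
    hf = h.astype(float)

    # intermittent numerator via FFT autocorrelation summed over pairs
    n = 1 << (2 * T - 1).bit_length()
    f = np.fft.rfft(hf, n=n, axis=0)
    ac = np.fft.irfft(f * np.conj(f), n=n, axis=0)[:T].sum(axis=1)
    counts = np.arange(T, 0, -1, dtype=float)
    denom_per_lag = np.concatenate(([0.0], np.cumsum(hf.sum(axis=1))))
    # ⟨Σ h(t0)²⟩ over the origins valid at each lag: Σ_{t0<=T-1-t} h(t0)
    denom = denom_per_lag[T - np.arange(T)]
    inter = (ac / counts) / (denom / counts)
    inter = inter[:L]

    # continuous: run lengths of 1s starting at each t0
    run = np.zeros(h.shape, dtype=np.int64)
    run[-1] = h[-1]
    for t in range(T - 2, -1, -1):
        run[t] = np.where(h[t], run[t + 1] + 1, 0)
    cont_num = np.empty(L)
    cont_den = np.empty(L)
    for tau in range(L):
        valid = T - tau
        cont_num[tau] = np.sum(run[:valid] >= tau + 1)
        cont_den[tau] = hf[:valid].sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        cont = np.where(cont_den > 0, cont_num / cont_den, 0.0)

    lag = np.arange(L) * dt
    n_origins = np.arange(T, T - L, -1)
    continuous = CorrelationCurve(lag=lag, value=cont, n_origins=n_origins)
    intermittent = CorrelationCurve(lag=lag, value=inter, n_origins=n_origins.copy())
    result = HbondCorrelation(continuous=continuous, intermittent=intermittent)
    if fit and L >= 5:
        try:
            result.fit_continuous = fit_relaxation(continuous, model="kww", min_origins=1)
        except (RuntimeError, ValueError):
            pass
        try:
            result.fit_intermittent = fit_relaxation(
                intermittent, model="kww_plateau", min_origins=1
            )
        except (RuntimeError, ValueError):
            pass
    return result
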