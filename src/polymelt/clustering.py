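"""Single-linkage encounter analysis and PMF-gated cluster fractions.

Two end-group sites (or an end-group and a peptide site) closer than a
threshold r_th are in an encountering state; the relation is closed
transitively, so the encounter clusters are exactly the connected
components of the thresholded contact graph (single linkage). The
encountering-event fraction f_enc(s) is the mean fraction of end-group
sites living in clusters of size s. The cluster-formation fraction
f_cluster(s) applies the same machinery but admits contact edges only
between species pairs whose PMF contact minimum passes the stability
criterion |W(r_CM)| > 2 kB T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import minimum_image_displacement

__all__ = [
    "SiteSet",
    "ClusterSizeDistribution",
    "single_linkage",
    "encounter_fraction",
    "cluster_fraction",
    "size_distribution_report",
]


@dataclass
class SiteSet:
    """Per-frame positions of cluster-eligible sites.

    ``positions`` is (T, S, 3) wrapped nm coordinates; ``types`` is a
    length-S sequence of site-type labels (e.g. ``"alpha_end"``,
    ``"peptide"``); ``owners`` identifies the owning chain/molecule;
    ``end_types`` names which site types count as chain end-groups for
    the normalization M.
    """

    positions: np.ndarray
    boxes: np.ndarray
    types: Sequence[str]
    owners: Sequence[int] | None = None
    end_types: frozenset[str] = frozenset({"alpha_end"})

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.positions.ndim != 3:
            raise ValueError("positions must be (T, S, 3)")
        if len(self.types) != self.positions.shape[1]:
            raise ValueError("types must have one label per site")
        self.types = list(self.types)
        self.end_types = frozenset(self.end_types)

    @property
    def n_sites(self) -> int:
        return self.positions.shape[1]

    @property
    def end_mask(self) -> np.ndarray:
        return np.array([t in self.end_types for t in self.types])


@dataclass
class ClusterSizeDistribution:
    """f(s) per cluster size with its normalization metadata."""

    sizes: np.ndarray
    f: np.ndarray
    r_th: float
    gated: bool
    n_frames: int               # K
    n_end_sites: int            # M

    def __post_init__(self) -> None:
        total = float(np.sum(self.f))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"size fractions must sum to 1, got {total}")
        if np.any(self.f < 0):
            raise ValueError("size fractions must be non-negative")

    def fraction(self, s: int) -> float:
        hit = np.flatnonzero(self.sizes == s)
        return float(self.f[hit[0]]) if hit.size else 0.0


def _pair_type_key(a: str, b: str) -> frozenset[str]:
    return frozenset((a, b))


def single_linkage(
    positions: np.ndarray,
    box: np.ndarray,
    r_th: float,
    types: Sequence[str] | None = None,
    allowed_pairs: Iterable[frozenset[str]] | None = None,
) -> np.ndarray:
    """Connected components of the contact graph at threshold r_th.

    Edges join sites at minimum-image distance strictly below ``r_th``;
    when ``allowed_pairs`` is given, only edges between those type pairs
    are admitted (a pair is a frozenset of one or two type labels).
    Returns integer labels, one per site.
    """
    pos = np.asarray(positions, dtype=float)
    S = pos.shape[0]
    if S == 0:
        return np.empty(0, dtype=np.intp)
    if r_th <= 0:
        raise ValueError("r_th must be positive")
    d = minimum_image_displacement(pos[:, None, :], pos[None, :, :], box)
    dist = np.linalg.norm(d, axis=-1)
    adj = dist < r_th
    np.fill_diagonal(adj, False)
    if allowed_pairs is not None:
        if types is None:
            raise ValueError("allowed_pairs requires site types")
        allowed = {frozenset(p) for p in allowed_pairs}
        type_arr = list(types)
        permit = np.zeros((S, S), dtype=bool)
        for i in range(S):
            for j in range(S):
                permit[i, j] = _pair_type_key(type_arr[i], type_arr[j]) in allowed
        adj &= permit
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels.astype(np.intp)


def _fractions_from_frames(
    sites: SiteSet,
    r_th: float,
    allowed_pairs: Iterable[frozenset[str]] | None,
    gated: bool,
) -> ClusterSizeDistribution:
    end_mask = sites.end_mask
    M = int(end_mask.sum())
    if M == 0:
        raise ValueError("no end-group sites; nothing to normalize by")
    K = sites.positions.shape[0]
    accum: dict[int, float] = {}
    for t in range(K):
        labels = single_linkage(
            sites.positions[t], sites.boxes[t], r_th, sites.types, allowed_pairs
        )
        # cluster size counts every member (peptides included); n_s counts
        # only end-group members, so Σ_s n_s = M and Σ_s f(s) = 1
        cluster_sizes = np.bincount(labels)
        per_site_size = cluster_sizes[labels]
        for s in np.unique(per_site_size[end_mask]):
            n_s = int(np.sum(per_site_size[end_mask] == s))
            accum[int(s)] = accum.get(int(s), 0.0) + n_s
    sizes = np.array(sorted(accum), dtype=int)
    f = np.array([accum[s] for s in sizes]) / (M * K)
    return ClusterSizeDistribution(
        sizes=sizes, f=f, r_th=r_th, gated=gated, n_frames=K, n_end_sites=M
    )


def encounter_fraction(sites: SiteSet, r_th: float = 0.6) -> ClusterSizeDistribution:
    """Encountering-event fraction f_enc(s) = (1/M)(1/K) Σ_k n_s(k).

    All site-type pairs may form contacts. Singletons (s = 1) are
    included so the fractions sum to 1 exactly.
    """
    return _fractions_from_frames(sites, r_th, allowed_pairs=None, gated=False)


def cluster_fraction(
    sites: SiteSet,
    r_th: float,
    gates: Mapping[frozenset[str], bool],
) -> ClusterSizeDistribution:
    """Stability-gated cluster-formation fraction f_cluster(s).

    ``gates`` maps each occurring site-type pair to the verdict of the
    PMF criterion |W(r_CM)| > 2 kB T; contact edges are admitted only for
    pairs gated True. Sites whose every potential partner is gated off
    fall into s = 1, keeping Σ f = 1.
    """
    present = sorted(set(sites.types))
    needed = [
        _pair_type_key(a, b)
        for i, a in enumerate(present)
        for b in present[i:]
    ]
    gates = {frozenset(k): v for k, v in gates.items()}
    missing = [p for p in needed if p not in gates]
    if missing:
        raise ValueError(f"missing stability gate for type pairs: {sorted(map(sorted, missing))}")
    allowed = [p for p, ok in gates.items() if ok]
    return _fractions_from_frames(sites, r_th, allowed_pairs=allowed, gated=True)


def size_distribution_report(
    distributions: Mapping[str, ClusterSizeDistribution] | Sequence[ClusterSizeDistribution],
) -> pd.DataFrame:
    """Long-format (system, s, f, gated) table for plotting/regression."""
    if not isinstance(distributions, Mapping):
        distributions = {str(i): d for i, d in enumerate(distributions)}
    if not distributions:
        raise ValueError("need at least one distribution")
    rows = []
    for name, dist in distributions.items():
        for s, f in zip(dist.sizes, dist.f):
            rows.append(dict(system=name, s=int(s), f=float(f), gated=dist.gated,
                             r_th=dist.r_th, K=dist.n_frames, M=dist.n_end_sites))
    return pd.DataFrame(rows)
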