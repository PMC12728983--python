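"""Domain types and periodic-boundary geometry shared by all analyses.

Units are GROMACS-native throughout the package: lengths in nm, times in ps,
masses in amu, energies in kJ/mol, temperatures in K, charges in elementary
charge units. Only orthorhombic boxes are supported; triclinic input is
rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Box",
    "Frame",
    "Trajectory",
    "Topology",
    "PhysicalConstants",
    "KB_KJ_PER_MOL_K",
    "DEBYE_PER_E_NM",
    "minimum_image_displacement",
    "wrap_positions",
    "unwrap",
    "make_whole",
    "group_center",
]

#: Boltzmann constant, kJ mol^-1 K^-1.
KB_KJ_PER_MOL_K = 0.0083144621

#: Conversion factor: 1 e·nm in Debye.
DEBYE_PER_E_NM = 48.0321


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic box with edge lengths in nm."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        if lengths.shape != (3,):
            raise ValueError(f"box lengths must be a 3-vector, got shape {lengths.shape}")
        if not np.all(lengths > 0):
            raise ValueError(f"box lengths must be positive, got {lengths}")
        object.__setattr__(self, "lengths", lengths)

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    @property
    def half_min(self) -> float:
        """Half the shortest edge: the largest valid minimum-image distance."""
        return float(np.min(self.lengths)) / 2.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Boltzmann constant and system temperature for free-energy conversions."""

    kB: float = KB_KJ_PER_MOL_K
    temperature: float = 360.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kT(self) -> float:
        """Thermal energy kB·T in kJ/mol."""
        return self.kB * self.temperature


@dataclass
class Frame:
    """One trajectory frame: time (ps), positions (N, 3) in nm, box."""

    time: float
    positions: np.ndarray
    box: Box | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        self.positions = pos


class Trajectory:
    """Ordered frames with uniform sampling interval.

    Stored internally as stacked arrays for vectorized analysis:
    ``positions`` is (T, N, 3) nm, ``times`` is (T,) ps, ``boxes`` is
    (T, 3) nm edge lengths (or None when the source format carries no box).
    """

    def __init__(
        self,
        positions: np.ndarray,
        times: np.ndarray,
        boxes: np.ndarray | None,
        wrapped: bool = True,
    ) -> None:
        positions = np.asarray(positions, dtype=float)
        times = np.asarray(times, dtype=float)
        if positions.ndim != 3 or positions.shape[2] != 3:
            raise ValueError("positions must be (T, N, 3)")
        if times.shape != (positions.shape[0],):
            raise ValueError("times must match the number of frames")
        if positions.shape[0] >= 2:
            dts = np.diff(times)
            if np.any(dts <= 0):
                raise ValueError("frame times must be strictly increasing")
            if np.ptp(dts) > 1e-9:
                raise ValueError("frame sampling interval must be uniform (tol 1e-9 ps)")
        if not np.all(np.isfinite(positions)):
            raise ValueError("positions must be finite")
        if boxes is not None:
            boxes = np.asarray(boxes, dtype=float)
            if boxes.shape != (positions.shape[0], 3):
                raise ValueError("boxes must be (T, 3)")
            if not np.all(boxes > 0):
                raise ValueError("box lengths must be positive")
        self.positions = positions
        self.times = times
        self.boxes = boxes
        self.wrapped = bool(wrapped)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def dt_frame(self) -> float:
        """Sampling interval in ps (0 for a single-frame trajectory)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def box(self, i: int = 0) -> Box:
        if self.boxes is None:
            raise ValueError("trajectory carries no box; periodic analysis impossible")
        return Box(self.boxes[i])

    def frame(self, i: int) -> Frame:
        box = Box(self.boxes[i]) if self.boxes is not None else None
        return Frame(time=float(self.times[i]), positions=self.positions[i], box=box)

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def window(self, start: int, stop: int | None = None) -> "Trajectory":
        """Sub-trajectory over a frame slice (shares underlying arrays)."""
        sl = slice(start, stop)
        boxes = self.boxes[sl] if self.boxes is not None else None
        return Trajectory(self.positions[sl], self.times[sl], boxes, self.wrapped)


@dataclass
class Topology:
    """Chains, per-atom masses/charges and named atom selections.

    ``chains`` is a list of integer index arrays, one per chain;
    ``named_selections`` maps labels like ``"alpha_end"`` or
    ``"peptide_site"`` to index arrays.
    """

    n_atoms: int
    masses: np.ndarray
    charges: np.ndarray
    chains: list[np.ndarray] = field(default_factory=list)
    named_selections: dict[str, np.ndarray] = field(default_factory=dict)
    source: str | None = None

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.masses.shape != (self.n_atoms,) or self.charges.shape != (self.n_atoms,):
            raise ValueError("masses and charges must have length n_atoms")
        self.chains = [np.asarray(c, dtype=np.intp) for c in self.chains]
        seen: set[int] = set()
        for c in self.chains:
            if c.size and (c.min() < 0 or c.max() >= self.n_atoms):
                raise ValueError("chain indices out of range")
            idx = set(int(i) for i in c)
            if seen & idx:
                raise ValueError("chains must not overlap")
            seen |= idx
        cleaned = {}
        for label, sel in self.named_selections.items():
            sel = np.asarray(sel, dtype=np.intp)
            if sel.size and (sel.min() < 0 or sel.max() >= self.n_atoms):
                raise ValueError(f"selection {label!r} references invalid atom indices")
            cleaned[label] = sel
        self.named_selections = cleaned

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def selection(self, label: str) -> np.ndarray:
        try:
            return self.named_selections[label]
        except KeyError:
            raise KeyError(
                f"no selection named {label!r}; available: {sorted(self.named_selections)}"
            ) from None


# ---------------------------------------------------------------------------
# Periodic geometry
# ---------------------------------------------------------------------------

def _box_lengths(box: Box | np.ndarray) -> np.ndarray:
    if isinstance(box, Box):
        return box.lengths
    return np.asarray(box, dtype=float)


def minimum_image_displacement(
    a: np.ndarray, b: np.ndarray, box: Box | np.ndarray
) -> np.ndarray:
    """Displacement b − a folded so every component lies in [−L/2, L/2).

    Broadcasts over leading dimensions; the last axis must be 3.
    """
    L = _box_lengths(box)
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - np.floor(d / L + 0.5) * L


def wrap_positions(positions: np.ndarray, box: Box | np.ndarray) -> np.ndarray:
    """Fold coordinates into [0, L) per component."""
    L = _box_lengths(box)
    p = np.asarray(positions, dtype=float)
    return p - np.floor(p / L) * L


def unwrap(trajectory: Trajectory, topology: Topology | None = None) -> Trajectory:
    """Make per-atom coordinates continuous across frames.

    Accumulates minimum-image frame-to-frame displacements, so every atom's
    path is continuous and suitable for MSD analysis. Requires wrapped input
    with a box and frame spacing fine enough that no atom moves half a box
    edge between consecutive frames.
    """
    if not trajectory.wrapped:
        return trajectory
    if trajectory.boxes is None:
        raise ValueError("cannot unwrap a trajectory without box information")
    pos = trajectory.positions
    boxes = trajectory.boxes
    out = np.empty_like(pos)
    out[0] = pos[0]
    for t in range(1, pos.shape[0]):
        d = minimum_image_displacement(pos[t - 1], pos[t], boxes[t])
        half = boxes[t] / 2.0
        if np.any(np.abs(d) >= half - 1e-12):
            raise ValueError(
                f"frame {t}: an atom moved >= L/2 between frames; "
                "sampling too sparse to unwrap"
            )
        out[t] = out[t - 1] + d
    return Trajectory(out, trajectory.times, boxes, wrapped=False)


def make_whole(positions: np.ndarray, indices: Sequence[int], box: Box | np.ndarray) -> np.ndarray:
    """Return the selected atoms' positions shifted to be connected.

    The first atom anchors the group; every other atom is placed at its
    minimum image relative to the anchor. Suitable for compact groups
    (terminal groups, single monomers), not for whole chains longer than
    half the box.
    """
    idx = np.asarray(indices, dtype=np.intp)
    anchor = positions[idx[0]]
    rel = minimum_image_displacement(anchor, positions[idx], box)
    return anchor + rel


def make_chain_whole(positions: np.ndarray, chain: np.ndarray, box: Box | np.ndarray) -> np.ndarray:
    """Reconnect a chain by accumulating minimum-image bond vectors.

    Works for chains of arbitrary contour length as long as consecutive
    atoms are closer than half the box.
    """
    p = positions[chain]
    bonds = minimum_image_displacement(p[:-1], p[1:], box)
    out = np.empty_like(p)
    out[0] = p[0]
    out[1:] = p[0] + np.cumsum(bonds, axis=0)
    return out


def group_center(
    frame: Frame,
    indices: Sequence[int],
    masses: np.ndarray | None = None,
    mode: str = "mass",
) -> np.ndarray:
    """Periodic-aware center of an atom group, re-wrapped into the box.

    ``mode`` is ``"mass"`` (mass-weighted, default) or ``"geometric"``.
    The group is made whole under minimum image before averaging; a group
    spanning more than half the box after make-whole is rejected.
    """
    idx = np.asarray(indices, dtype=np.intp)
    if idx.size == 0:
        raise ValueError("group_center requires a non-empty atom group")
    if frame.box is None:
        whole = frame.positions[idx]
    else:
        whole = make_whole(frame.positions, idx, frame.box)
        extent = whole.max(axis=0) - whole.min(axis=0)
        if np.any(extent > frame.box.lengths / 2.0):
            raise ValueError("group spans more than half the box after make-whole")
    if mode == "geometric":
        center = whole.mean(axis=0)
    elif mode == "mass":
        if masses is None:
            raise ValueError("mass-weighted center requires masses")
        w = np.asarray(masses, dtype=float)[idx]
        total = w.sum()
        if total <= 0:
            raise ValueError("zero total mass in group")
        center = (whole * w[:, None]).sum(axis=0) / total
    else:
        raise ValueError(f"unknown center mode {mode!r}")
    if frame.box is not None:
        center = wrap_positions(center, frame.box)
    return center
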