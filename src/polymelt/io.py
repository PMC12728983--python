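"""Topology/trajectory file I/O via MDAnalysis.

MDAnalysis works in Å internally; everything crossing this module's
boundary is converted to the package's nm convention. Only orthorhombic
boxes are accepted.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .core import Topology, Trajectory

__all__ = ["load_topology", "load_trajectory", "write_system"]

_NM_PER_ANGSTROM = 0.1


def _check_orthorhombic(dimensions: np.ndarray | None) -> np.ndarray | None:
    """Return box edge lengths in nm, or None when no box is present."""
    if dimensions is None or np.all(dimensions[:3] == 0):
        return None
    angles = dimensions[3:6]
    if np.any(np.abs(angles - 90.0) > 1e-3):
        raise ValueError(
            f"triclinic box (angles {angles}) not supported; orthorhombic only"
        )
    return dimensions[:3] * _NM_PER_ANGSTROM


def _infer_chains(universe: "mda.Universe") -> list[np.ndarray]:
    """Chains from contiguous runs of equal residue id.

    Synthetic and melt topologies written by this package give each
    molecule one residue; multi-residue molecules need an explicit chain
    map in the selection config.
    """
    resids = universe.atoms.resids
    if resids.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(resids) != 0) + 1
    return [np.asarray(c, dtype=np.intp) for c in np.split(np.arange(resids.size), breaks)]


def _resolve_selection(
    universe: "mda.Universe", chains: list[np.ndarray], pattern: str
) -> np.ndarray:
    if pattern == "chain_first":
        return np.array([c[0] for c in chains], dtype=np.intp)
    if pattern == "chain_last":
        return np.array([c[-1] for c in chains], dtype=np.intp)
    try:
        group = universe.select_atoms(pattern)
    except Exception as exc:
        raise ValueError(f"selection pattern {pattern!r} failed to parse: {exc}") from exc
    return group.ix.astype(np.intp)


def load_topology(path: str | Path, selection_config: Mapping[str, str] | None = None) -> Topology:
    """Read a GRO or PDB file into a Topology.

    ``selection_config`` maps labels to either an MDAnalysis selection
    string (e.g. ``"name OA"``) or the tokens ``"chain_first"`` /
    ``"chain_last"`` selecting one endpoint atom per chain. An optional
    ``"chain_map"`` entry (list of [start, stop) atom-index pairs)
    overrides chain inference from residue numbering. A pattern resolving
    to zero atoms is an error naming the pattern.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"topology file not found: {path}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    n_atoms = len(u.atoms)
    try:
        masses = u.atoms.masses.astype(float)
    except (mda.exceptions.NoDataError, AttributeError):
        masses = np.ones(n_atoms)
    try:
        charges = u.atoms.charges.astype(float)
    except (mda.exceptions.NoDataError, AttributeError):
        charges = np.zeros(n_atoms)
    # GRO/PDB carry no masses; MDAnalysis guesses from names and may land
    # on zero for non-element names. Fall back to unit masses there.
    masses = np.where(masses > 0, masses, 1.0)

    selection_config = dict(selection_config or {})
    chain_map = selection_config.pop("chain_map", None)
    if chain_map is not None:
        chains = [np.arange(int(a), int(b), dtype=np.intp) for a, b in chain_map]
    else:
        chains = _infer_chains(u)

    named: dict[str, np.ndarray] = {}
    for label, pattern in selection_config.items():
        idx = _resolve_selection(u, chains, str(pattern))
        if idx.size == 0:
            raise ValueError(
                f"selection {label!r} with pattern {pattern!r} matched no atoms"
            )
        named[label] = idx
    return Topology(
        n_atoms=n_atoms,
        masses=masses,
        charges=charges,
        chains=chains,
        named_selections=named,
        source=str(path),
    )


def load_trajectory(
    path: str | Path,
    topology: Topology,
    wrapped: bool | None = None,
    dt_fallback: float = 1.0,
) -> Trajectory:
    """Read an XTC/TRR/DCD/XYZ/GRO trajectory against a loaded topology.

    The atom count must match the topology. ``wrapped`` overrides the
    default assumption that file coordinates are wrapped. Formats without
    time metadata get frame times 0, dt_fallback, 2·dt_fallback, ... ps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    if topology.source is None:
        raise ValueError("topology must carry its source file to open a trajectory")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(topology.source, str(path))
    except ValueError as exc:
        raise ValueError(f"atom count mismatch between topology and trajectory: {exc}") from exc
    if len(u.atoms) != topology.n_atoms:
        raise ValueError(
            f"atom count mismatch: trajectory has {len(u.atoms)}, "
            f"topology has {topology.n_atoms}"
        )
    positions, times, boxes = [], [], []
    has_box = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            positions.append(ts.positions.astype(float) * _NM_PER_ANGSTROM)
            times.append(float(ts.time))
            L = _check_orthorhombic(ts.dimensions)
            if L is None:
                has_box = False
            else:
                boxes.append(L)
    positions = np.asarray(positions)
    times = np.asarray(times)
    if times.size >= 2 and np.ptp(np.diff(times)) > 1e-9:
        times = np.arange(times.size, dtype=float) * dt_fallback
    if times.size >= 2 and times[1] <= times[0]:
        times = np.arange(times.size, dtype=float) * dt_fallback
    box_arr = np.asarray(boxes) if has_box and boxes else None
    return Trajectory(
        positions,
        times,
        box_arr,
        wrapped=True if wrapped is None else wrapped,
    )


def write_system(
    topology: Topology,
    trajectory: Trajectory,
    gro_path: str | Path,
    traj_path: str | Path | None = None,
    names: list[str] | None = None,
) -> None:
    """Write frame 0 as GRO plus (optionally) the full trajectory.

    The trajectory format follows ``traj_path``'s extension (.xtc, .trr,
    .dcd or .xyz). Residue numbering encodes the chain map: one residue
    per chain, trailing unassigned atoms (e.g. peptide beads) one residue
    each.
    """
    n = topology.n_atoms
    resindex = np.zeros(n, dtype=int)
    assigned = np.zeros(n, dtype=bool)
    for i, chain in enumerate(topology.chains):
        resindex[chain] = i
        assigned[chain] = True
    next_res = len(topology.chains)
    for i in range(n):
        if not assigned[i]:
            resindex[i] = next_res
            next_res += 1
    u = mda.Universe.empty(
        n, n_residues=next_res, atom_resindex=resindex, trajectory=True
    )
    u.add_TopologyAttr("name", names if names is not None else [f"B{i % 10}" for i in range(n)])
    u.add_TopologyAttr("resname", ["MOL"] * next_res)
    u.add_TopologyAttr("resid", np.arange(1, next_res + 1))
    u.add_TopologyAttr("masses", topology.masses)

    def _dims(i: int) -> np.ndarray | None:
        if trajectory.boxes is None:
            return None
        L = trajectory.boxes[i] / _NM_PER_ANGSTROM
        return np.array([L[0], L[1], L[2], 90.0, 90.0, 90.0])

    u.atoms.positions = trajectory.positions[0] / _NM_PER_ANGSTROM
    d = _dims(0)
    if d is not None:
        u.dimensions = d
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(gro_path))
        if traj_path is not None:
            with mda.Writer(str(traj_path), n_atoms=n) as w:
                for i in range(trajectory.n_frames):
                    u.atoms.positions = trajectory.positions[i] / _NM_PER_ANGSTROM
                    d = _dims(i)
                    if d is not None:
                        u.dimensions = d
                    u.trajectory.ts.time = trajectory.times[i]
                    u.trajectory.ts.frame = i
                    w.write(u.atoms)
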