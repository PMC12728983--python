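"""Configuration-driven pipeline runner and fixture generation.

A run configuration (YAML or a dict) names either input files or a
synthetic-system spec, a temperature, selections, and per-analysis
parameter blocks; :func:`run_pipeline` executes the requested stages in
dependency order and writes TSV/JSON artifacts plus a manifest. The
``analysis/`` scripts drive these functions; they are the package's
command-line surface.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import clustering, conformation, dynamics, kinetics, structure, synth
from .core import Topology, Trajectory, unwrap
from .io import load_topology, load_trajectory, write_system

__all__ = ["RunConfig", "run_pipeline", "generate_fixture"]

log = logging.getLogger("polymelt")

_STAGES = ("conformation", "dynamics", "structure", "clustering", "kinetics")
_SYNTH_KINDS = {
    "gaussian_melt": (synth.GaussianMeltSpec, synth.generate_gaussian_melt),
    "rouse": (synth.RouseBDSpec, synth.simulate_rouse_bd),
    "planted_clusters": (synth.PlantedClusterSpec, synth.generate_planted_clusters),
    "sticky_pair": (synth.StickyPairSpec, synth.simulate_sticky_pair),
    "exchange": (synth.ExchangeSpec, synth.generate_exchange_trajectory),
}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one of (``topology``+``trajectory`` paths, ``synthetic``
    spec) must be given. ``params`` holds optional per-stage parameter
    blocks (bin widths, r_th, cutoffs, fit windows).
    """

    output_dir: str
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    temperature: float = 360.0
    topology: str | None = None
    trajectory: str | None = None
    selections: dict[str, str] = field(default_factory=dict)
    synthetic: dict[str, Any] | None = None
    params: dict[str, dict[str, Any]] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        has_files = self.topology is not None or self.trajectory is not None
        has_synth = self.synthetic is not None
        if has_files == has_synth:
            raise ValueError(
                "exactly one of (topology+trajectory paths, synthetic spec) required"
            )
        if has_files and (self.topology is None or self.trajectory is None):
            raise ValueError("both topology and trajectory paths are required")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {_STAGES}")
        if has_synth and self.synthetic.get("kind") not in _SYNTH_KINDS:
            raise ValueError(
                f"unknown synthetic kind {self.synthetic.get('kind')!r}; "
                f"valid: {sorted(_SYNTH_KINDS)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls(**data)


def _build_synthetic(cfg: RunConfig) -> tuple[Trajectory, Topology]:
    spec_args = dict(cfg.synthetic)
    kind = spec_args.pop("kind")
    if cfg.seed is not None:
        spec_args.setdefault("seed", cfg.seed)
    spec_cls, generator = _SYNTH_KINDS[kind]
    spec = spec_cls(**spec_args)
    result = generator(spec)
    if kind == "gaussian_melt":
        return result
    if kind == "exchange":
        traj, topo, _ = result
        return traj, topo
    raise ValueError(
        f"synthetic kind {kind!r} does not produce a full melt system for the "
        "pipeline; use generate_fixture or the library API for it"
    )


def _stage_conformation(traj, topo, cfg, outdir) -> dict[str, Any]:
    p = cfg.params.get("conformation", {})
    r_max = p.get("r_max")
    if r_max is None:
        n_bonds = len(topo.chains[0]) - 1
        bond = float(
            np.linalg.norm(traj.positions[0, topo.chains[0][1]] - traj.positions[0, topo.chains[0][0]])
        )
        r_max = n_bonds * bond
    summary = conformation.summarize_conformation(traj, topo, r_max=r_max)
    import pandas as pd

    df = pd.DataFrame([{
        "mean_sq_ree_nm2": summary.mean_sq_ree,
        "se_ree": summary.se_ree,
        "mean_sq_rg_nm2": summary.mean_sq_rg,
        "se_rg": summary.se_rg,
        "ratio": summary.ratio,
        "kuhn_b_nm": summary.kuhn_b,
        "n_kuhn": summary.n_kuhn,
        "r_max_nm": summary.r_max,
    }])
    df.to_csv(outdir / "conformation_summary.tsv", sep="\t", index=False)
    return {"files": ["conformation_summary.tsv"], "ratio": summary.ratio}


def _stage_dynamics(traj, topo, cfg, outdir) -> dict[str, Any]:
    p = cfg.params.get("dynamics", {})
    ree = conformation.end_to_end_series(traj, topo)
    acf = dynamics.autocorrelate_vectors(ree, traj.dt_frame or 1.0)
    fit = dynamics.fit_relaxation(acf, model=p.get("model", "exponential"))
    import pandas as pd

    pd.DataFrame({"lag_ps": acf.lag, "C": acf.value, "n_origins": acf.n_origins}).to_csv(
        outdir / "end_to_end_acf.tsv", sep="\t", index=False
    )
    with open(outdir / "end_to_end_fit.json", "w") as fh:
        json.dump({"model": fit.model, "tau_ps": fit.tau, "beta": fit.beta,
                   "plateau": fit.plateau, "chi_sq": fit.chi_sq,
                   "tau_mean_ps": fit.tau_mean}, fh, indent=1)
    return {"files": ["end_to_end_acf.tsv", "end_to_end_fit.json"], "tau_rot": fit.tau}


def _stage_structure(traj, topo, cfg, outdir, state) -> dict[str, Any]:
    p = cfg.params.get("structure", {})
    sel = p.get("selection", "alpha_end")
    idx = topo.selection(sel)
    if traj.boxes is None:
        raise ValueError("structure stage needs a periodic box")
    from .core import wrap_positions

    centers = np.stack([
        wrap_positions(traj.positions[t][idx], traj.boxes[t]) for t in range(traj.n_frames)
    ])
    profile = structure.rdf(
        centers, centers, traj.boxes,
        bin_width=p.get("bin_width", 0.02), same_species=True,
        species=(sel, sel),
    )
    pmf_profile = structure.pmf(profile, cfg.temperature)
    try:
        structure.locate_extrema(
            pmf_profile,
            smoothing_window=p.get("smoothing_window", 5),
            min_prominence=p.get("min_prominence", 0.2),
        )
        gate = structure.stability_gate(pmf_profile, p.get("threshold_kT", 2.0))
    except ValueError:
        gate = False
    import pandas as pd

    pd.DataFrame({"r_nm": profile.bin_centers, "g": profile.g, "W_kJ_mol": pmf_profile.W}).to_csv(
        outdir / "rdf_pmf.tsv", sep="\t", index=False
    )
    sidecar = {
        "r_cut_nm": profile.r_cut,
        "extrema": [asdict(e) for e in pmf_profile.extrema],
        "barriers_kJ_mol": pmf_profile.barriers,
        "stability_gate": {f"{sel}|{sel}": gate},
        "temperature_K": cfg.temperature,
    }
    with open(outdir / "structure.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    state["gates"] = {frozenset((sel,)): gate}
    state["gate_selection"] = sel
    return {"files": ["rdf_pmf.tsv", "structure.json"], "gate": gate}


def _make_siteset(traj, topo, sel: str) -> clustering.SiteSet:
    from .core import wrap_positions

    idx = topo.selection(sel)
    pos = np.stack([
        wrap_positions(traj.positions[t][idx], traj.boxes[t]) for t in range(traj.n_frames)
    ])
    return clustering.SiteSet(
        positions=pos, boxes=traj.boxes, types=[sel] * len(idx),
        end_types=frozenset({sel}),
    )


def _stage_clustering(traj, topo, cfg, outdir, state) -> dict[str, Any]:
    p = cfg.params.get("clustering", {})
    sel = p.get("selection", "alpha_end")
    r_th = p.get("r_th", 0.6)
    if traj.boxes is None:
        raise ValueError("clustering stage needs a periodic box")
    window = max(1, int(traj.n_frames * p.get("window_fraction", 0.1)))
    sub = traj.window(traj.n_frames - window)
    sites = _make_siteset(sub, topo, sel)
    enc = clustering.encounter_fraction(sites, r_th=r_th)
    outputs = {"encounter": enc}
    if p.get("gated", False):
        if "gates" not in state:
            raise RuntimeError(
                "gated clustering requires the 'structure' stage to run first"
            )
        gates = {frozenset((sel, sel)): state["gates"].get(frozenset((sel,)), False)}
        outputs["cluster"] = clustering.cluster_fraction(sites, r_th, gates)
    df = clustering.size_distribution_report(outputs)
    df.to_csv(outdir / "cluster_fractions.tsv", sep="\t", index=False)
    return {"files": ["cluster_fractions.tsv"],
            "sum_f_enc": float(np.sum(enc.f))}


def _stage_kinetics(traj, topo, cfg, outdir, state) -> dict[str, Any]:
    p = cfg.params.get("kinetics", {})
    ref_sel = p.get("reference_selection", "reference_site")
    tgt_sel = p.get("target_selection", "exchange_particles")
    radius = p.get("sphere_radius", 0.5)
    if traj.boxes is None:
        raise ValueError("kinetics stage needs a periodic box")
    ref = traj.positions[:, topo.selection(ref_sel), :]
    tgt = traj.positions[:, topo.selection(tgt_sel), :]
    curve = kinetics.survival_probability(
        ref, tgt, traj.boxes, radius, traj.dt_frame or 1.0,
        max_lag_frames=p.get("max_lag_frames"),
    )
    import pandas as pd

    pd.DataFrame({"tau_ps": curve.tau, "P": curve.P}).to_csv(
        outdir / "survival.tsv", sep="\t", index=False
    )
    blob = {"sphere_radius_nm": radius, "n_origins": curve.n_origins}
    if curve.fit is not None:
        blob.update(tau_ps=curve.fit.tau, beta=curve.fit.beta,
                    tau_mean_ps=curve.fit.tau_mean)
    with open(outdir / "survival_fit.json", "w") as fh:
        json.dump(blob, fh, indent=1)
    return {"files": ["survival.tsv", "survival_fit.json"]}


def run_pipeline(config: RunConfig | Mapping[str, Any]) -> dict[str, Any]:
    """Execute the requested stages, writing artifacts and a manifest.

    Stages run in dependency order (conformation → dynamics → structure
    → clustering → kinetics); gated clustering requires structure's PMF
    gates. Returns the manifest dict (also written as manifest.json).
    """
    if not isinstance(config, RunConfig):
        config = RunConfig(**dict(config))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.synthetic is not None:
        traj, topo = _build_synthetic(config)
    else:
        topo = load_topology(config.topology, config.selections)
        traj = load_trajectory(config.trajectory, topo)
    ordered = [s for s in _STAGES if s in config.stages]
    manifest: dict[str, Any] = {
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stages": {},
        "errors": [],
    }
    state: dict[str, Any] = {}
    for stage in ordered:
        t0 = time.perf_counter()
        try:
            if stage == "conformation":
                info = _stage_conformation(traj, topo, config, outdir)
            elif stage == "dynamics":
                info = _stage_dynamics(traj, topo, config, outdir)
            elif stage == "structure":
                info = _stage_structure(traj, topo, config, outdir, state)
            elif stage == "clustering":
                info = _stage_clustering(traj, topo, config, outdir, state)
            else:
                info = _stage_kinetics(traj, topo, config, outdir, state)
            info["seconds"] = round(time.perf_counter() - t0, 3)
            manifest["stages"][stage] = info
            log.info("stage %s done in %.2fs", stage, info["seconds"])
        except Exception as exc:  # noqa: BLE001 - recorded and re-raised via manifest
            manifest["errors"].append({"stage": stage, "error": str(exc)})
            log.error("stage %s failed: %s", stage, exc)
            break
    manifest["ok"] = not manifest["errors"]
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    if manifest["errors"]:
        raise RuntimeError(
            f"pipeline stage {manifest['errors'][0]['stage']!r} failed: "
            f"{manifest['errors'][0]['error']}"
        )
    return manifest


def _config_dict(config: RunConfig) -> dict[str, Any]:
    d = asdict(config)
    return d


def generate_fixture(kind: str, spec: Mapping[str, Any], out_dir: str | Path) -> dict[str, str]:
    """Write a synthetic system (GRO + trajectory + ground-truth JSON).

    ``kind`` is one of gaussian_melt, rouse, planted_clusters,
    sticky_pair, exchange. Invalid spec fields raise before any file is
    written. Returns the mapping of artifact names to paths.
    """
    if kind not in _SYNTH_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; valid: {sorted(_SYNTH_KINDS)}")
    spec_cls, generator = _SYNTH_KINDS[kind]
    spec_obj = spec_cls(**dict(spec))  # validates before touching disk
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth: dict[str, Any] = {"kind": kind, "spec": _spec_to_json(spec_obj)}
    files: dict[str, str] = {}

    if kind == "gaussian_melt":
        traj, topo = generator(spec_obj)
        write_system(topo, traj, out / "system.gro", out / "trajectory.xtc")
        truth["mean_sq_ree_nm2"] = spec_obj.n_bonds * spec_obj.bond_length**2
        n = spec_obj.n_bonds
        truth["mean_sq_rg_nm2"] = spec_obj.bond_length**2 * n * (n + 2) / (6 * (n + 1))
        files.update(gro=str(out / "system.gro"), trajectory=str(out / "trajectory.xtc"))
    elif kind == "rouse":
        traj = generator(spec_obj)
        topo = Topology(
            n_atoms=spec_obj.n_beads,
            masses=np.ones(spec_obj.n_beads),
            charges=np.zeros(spec_obj.n_beads),
            chains=[np.arange(spec_obj.n_beads)],
        )
        big = Trajectory(
            traj.positions - traj.positions.min() + 1.0,
            traj.times,
            np.full((traj.n_frames, 3), float(np.ptp(traj.positions) + 2.0)),
            wrapped=False,
        )
        write_system(topo, big, out / "system.gro", out / "trajectory.xtc")
        truth["tau_p_ps"] = {p: synth.rouse_mode_time(spec_obj, p) for p in range(1, 5)}
        files.update(gro=str(out / "system.gro"), trajectory=str(out / "trajectory.xtc"))
    elif kind == "planted_clusters":
        pos, labels = generator(spec_obj)
        topo = Topology(
            n_atoms=pos.shape[0], masses=np.ones(pos.shape[0]),
            charges=np.zeros(pos.shape[0]), chains=[],
        )
        traj = Trajectory(pos[None], np.array([0.0]),
                          np.array([[spec_obj.box_length] * 3]), wrapped=True)
        write_system(topo, traj, out / "system.gro")
        truth["labels"] = labels.tolist()
        truth["sizes"] = sorted(np.bincount(labels).tolist(), reverse=True)
        files["gro"] = str(out / "system.gro")
    elif kind == "sticky_pair":
        traj = generator(spec_obj)
        topo = Topology(n_atoms=2, masses=np.ones(2), charges=np.zeros(2), chains=[])
        write_system(topo, traj, out / "system.gro", out / "trajectory.xtc")
        files.update(gro=str(out / "system.gro"), trajectory=str(out / "trajectory.xtc"))
    else:  # exchange
        traj, topo, indicator = generator(spec_obj)
        write_system(topo, traj, out / "system.gro", out / "trajectory.xtc")
        truth["indicator_sum_per_frame"] = indicator.sum(axis=1).tolist()
        files.update(gro=str(out / "system.gro"), trajectory=str(out / "trajectory.xtc"))

    truth_path = out / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1)
    files["ground_truth"] = str(truth_path)
    return files


def _spec_to_json(spec: Any) -> dict[str, Any]:
    d = asdict(spec)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
        elif isinstance(v, Mapping):
            d[k] = {str(kk): vv for kk, vv in v.items()}
    return d
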