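#!/usr/bin/env python
"""Generate the synthetic study systems and their ground truth.

Writes GRO/XTC fixtures (binary trajectories under scratch/) for the
four synthetic system families the downstream analyses consume:
a freely-jointed melt, a free-end Rouse bead-spring chain, a planted
cluster configuration, and an exchange system with known residence
kinetics. Ground-truth JSON goes with each system.
"""

from pathlib import Path

from polymelt.pipeline import generate_fixture

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "systems"

SYSTEMS = {
    "gaussian_melt": {"n_chains": 512, "n_bonds": 200, "bond_length": 0.15,
                      "box_length": 12.0, "n_frames": 50, "seed": 42},
    "rouse": {"n_beads": 12, "spring_k": 100.0, "friction": 100.0,
              "temperature": 360.0, "dt": 0.01, "n_steps": 200_000,
              "stride": 100, "seed": 7},
    "planted_clusters": {"size_counts": {3: 2, 2: 4, 1: 6}, "box_length": 30.0,
                         "seed": 3},
    "exchange": {"n_particles": 200, "sphere_radius": 0.5, "mean_residence": 50.0,
                 "dt": 1.0, "n_frames": 3000, "seed": 31},
}


def main() -> None:
    for kind, spec in SYSTEMS.items():
        outdir = SCRATCH / kind
        files = generate_fixture(kind, spec, outdir)
        print(f"{kind}: wrote {len(files)} artifacts to {outdir}")


if __name__ == "__main__":
    main()
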