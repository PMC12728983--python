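#!/usr/bin/env python
"""Encounter and stability-gated cluster fractions on planted systems.

Builds a mixed configuration of end-group sites and peptide sites with
known single-linkage structure, measures the encountering-event
fraction f_enc(s) at r_th = 0.6 nm, then applies PMF stability gates to
obtain the cluster-formation fraction f_cluster(s) under three
scenarios: no stable pair (all gates off), peptide-mediated stability
only, and all pairs stable. With all gates off only singletons remain;
with peptide gating only peptide-bridged clusters survive — the
mechanism by which a minority peptide species turns transient
encounters into persistent physical junction points.
"""

from pathlib import Path

import numpy as np

from polymelt.clustering import (SiteSet, cluster_fraction, encounter_fraction,
                                 size_distribution_report)
from polymelt.synth import PlantedClusterSpec, generate_planted_clusters

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    spec = PlantedClusterSpec(size_counts={4: 1, 3: 2, 2: 4, 1: 6},
                              box_length=40.0, seed=3)
    pos, labels = generate_planted_clusters(spec)
    # make one member of each multi-site cluster a peptide site
    types = np.array(["alpha"] * pos.shape[0], dtype=object)
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if members.size >= 3:
            types[members[members.size // 2]] = "pep"
    sites = SiteSet(pos[None], np.full((1, 3), spec.box_length), list(types),
                    end_types=frozenset({"alpha"}))

    enc = encounter_fraction(sites, r_th=0.6)
    aa, ap, pp = frozenset(("alpha",)), frozenset(("alpha", "pep")), frozenset(("pep",))
    scenarios = {
        "encounter": enc,
        "no_stable_pair": cluster_fraction(sites, 0.6, {aa: False, ap: False, pp: False}),
        "peptide_gated": cluster_fraction(sites, 0.6, {aa: False, ap: True, pp: False}),
        "all_stable": cluster_fraction(sites, 0.6, {aa: True, ap: True, pp: True}),
    }
    RESULTS.mkdir(exist_ok=True)
    df = size_distribution_report(scenarios)
    df.to_csv(RESULTS / "cluster_fractions.tsv", sep="\t", index=False)

    for name, dist in scenarios.items():
        total = float(np.sum(dist.f))
        line = ", ".join(f"f({s})={f:.3f}" for s, f in zip(dist.sizes, dist.f))
        print(f"{name:>15}: {line}  (Σf = {total:.9f})")
    print("all gates off leaves only singletons; peptide gating keeps only "
          "peptide-bridged clusters; all-stable equals the encounter fractions")


if __name__ == "__main__":
    main()
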