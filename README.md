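# polymelt

Trajectory analysis of end-group association in polymer melts.

In melts of chains whose ends carry polar groups — and especially when a
minority peptide species is present — chain ends meet, stick, and form
transient physical junction points that slow every relaxation process in
the material. `polymelt` implements the measurement chain needed to
quantify that story from a trajectory:

* **Conformation**: ⟨R²ₑₑ⟩, ⟨R²g⟩, their ratio (→ 6 for Gaussian
  coils), mean-square internal distances ⟨R²(n)⟩, and the Kuhn analysis
  b = ⟨R²ₑₑ⟩/R_max, N_RB = R_max/b.
* **Relaxation**: end-to-end vector ACF C(t) with exponential and
  stretched-exponential (KWW) fits, the single-chain dipole ACF with its
  four-part backbone/terminal decomposition, and Rouse normal-mode
  analysis — X_p = √(2/N)·Σ_j cos((j−½)pπ/N)·R_j — with the τ_p/τ_R
  spectrum tested against 1/p² (free ends) and 1/(p−½)² (fixed ends).
* **Structure**: radial distribution functions g_αβ(r) with a
  finite-cutoff normalization (mean partner density within r_c = L/2,
  not the global density), running coordination numbers
  n = 4πρ∫r²g dr, and potentials of mean force W(r) = −kB T ln g(r)
  with labelled minima (CM/SAM/SShM/SSM) and dissociation barriers.
* **Clustering**: single-linkage encounter fractions f_enc(s) at a
  0.6 nm threshold and the stability-gated cluster-formation fractions
  f_cluster(s), where contacts count only for pairs whose contact
  minimum satisfies |W(r_CM)| > 2 kB T.
* **Kinetics**: survival probability P(τ) of sites in a coordination
  sphere, self-diffusion from the Einstein relation D = lim ⟨Δr²⟩/6t,
  and continuous vs intermittent hydrogen-bond correlation functions.

Because real melt trajectories of this kind are microsecond-scale and
not portable, the package ships miniature simulators with exact ground
truth — a freely-jointed melt, an overdamped Rouse chain, planted
cluster configurations, a two-particle Metropolis sampler, and an
exchange process — and validates every estimator by parameter recovery.

## Worked example

Generate an ideal melt and run the conformation analysis:

```python
from polymelt.synth import GaussianMeltSpec, generate_gaussian_melt
from polymelt.conformation import summarize_conformation

spec = GaussianMeltSpec(n_chains=512, n_bonds=200, bond_length=0.15,
                        box_length=12.0, n_frames=50, seed=42)
traj, topo = generate_gaussian_melt(spec)
s = summarize_conformation(traj, topo, r_max=spec.n_bonds * spec.bond_length)
print(f"ratio = {s.ratio:.3f}, b = {s.kuhn_b:.4f} nm, N_RB = {s.n_kuhn:.1f}")
```

prints

```
ratio = 5.954, b = 0.1492 nm, N_RB = 201.1
```

— the ratio sits at the freely-jointed closed form 6(n+1)/(n+2) = 5.97
(the Gaussian-coil signature "close to 6"), and the Kuhn analysis
returns the generator's 0.15 nm bond length: for an ideal chain the
Kuhn segment *is* the bond.

The numbered scripts under `analysis/` run the full study on the
synthetic systems and write tables under `results/`:

```bash
python analysis/01_generate_systems.py   # fixtures + ground truth
python analysis/02_conformation.py       # Ree/Rg/Kuhn table
python analysis/03_relaxation.py         # C(t), Rouse spectrum, D
python analysis/04_structure.py          # g(r), PMF, barriers, gate
python analysis/05_clustering.py         # f_enc vs gated f_cluster
python analysis/06_kinetics.py           # survival, HB correlations
```

For instance `03_relaxation.py` reports `τ_R/τ_rot = 0.915 (expected
≃1)` — the first Rouse mode and the end-to-end vector relax on the same
clock — and `04_structure.py` locates the planted −8 kJ/mol contact
well, converts its depth to thermal units against kB T(360 K) =
2.99 kJ/mol, and passes the 2 kB T stability gate.

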