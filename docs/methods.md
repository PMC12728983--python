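# Methods

`polymelt` analyses molecular-dynamics trajectories of polymer melts in
which the chain ends (and optionally a minority peptide species) carry
polar groups that associate into transient physical junction points.
The package implements the full measurement chain — conformational
statistics, relaxation spectra, pair structure and free energies,
cluster statistics, and exchange kinetics — and ships miniature
simulators that generate trajectories with known ground truth, so every
estimator is validated by parameter recovery rather than by eye.

Units are GROMACS-native throughout: nm, ps, amu, kJ/mol, K, elementary
charges. kB = 0.0083144621 kJ mol⁻¹ K⁻¹; the default temperature is
360 K, where kB·T = 2.99 kJ/mol. Dipoles convert to Debye with
1 e·nm = 48.0321 D at reporting time only. Boxes are orthorhombic;
triclinic input is rejected because the minimum-image convention is
implemented for rectangular cells only.

## Periodic geometry

`minimum_image_displacement` folds each displacement component into
[−L/2, L/2) via `d − floor(d/L + 1/2)·L`. Unwrapping accumulates
minimum-image frame-to-frame displacements and refuses trajectories in
which an atom moves ≥ L/2 between frames (under-sampled data cannot be
unwrapped unambiguously). Group centers are computed after "make-whole"
— each member is moved to its minimum image relative to the group's
first atom — and a group whose extent still exceeds L/2 is an error.
Two center modes exist because different analyses want different
conventions: mass-weighted centers for RDFs between terminal groups,
geometric centers for survival-probability regions.

## Synthetic systems

The generators define the study conditions; their defaults are the
sizes used by the acceptance analyses.

* **Freely-jointed melt** (512 chains × 200 bonds of 0.15 nm, 50
  independent frames): each frame draws fresh chains with uniformly
  random bond orientations, so ⟨Ree²⟩ = n·b², ⟨Rg²⟩ = b²·n(n+2)/(6(n+1))
  and the ratio approaches 6 exactly as for ideal Gaussian coils.
  Frames are independent by construction — good for ensemble statistics,
  useless for dynamics, which is what the Rouse simulator is for. There
  is no excluded volume and no interchain force; passing tests on this
  system validate the estimators, not melt physics.
* **Rouse bead-spring chain** (N = 12 beads, k = 100 kJ mol⁻¹ nm⁻²,
  ζ = 100 amu/ps, dt = 0.01 ps, 2×10⁶ steps, stride 100): overdamped
  Euler–Maruyama integration of dR_j = (k/ζ)(R_{j+1} − 2R_j + R_{j−1})dt
  + √(2kBT dt/ζ)·η. The discrete free-end spectrum
  τ_p = ζ/(4k sin²(pπ/2N)) is the recovery target; Euler–Maruyama's
  O(dt) variance bias is held below the 15 % mode-time tolerance by the
  enforced stability condition dt·k/ζ < 0.1 (the defaults use 0.01).
  A first-order integrator suffices at these tolerances; the kernel is
  numba-compiled so the 2×10⁶-step run takes seconds.
* **Planted clusters**: cluster members sit on a line with consecutive
  spacing exactly `intra_spacing`; cluster anchors occupy a cubic grid
  whose pitch exceeds `inter_spacing` plus the largest cluster extent.
  Single linkage at any threshold in (intra, inter) provably returns
  the planted partition.
* **Sticky pair**: two particles in a periodic box with a tabulated
  u(r), sampled by single-particle Metropolis moves (default step
  0.3 nm, recording every 10 sweeps). For a pair at separation
  r < L/2 the configurational volume element is exactly 4πr², so
  Boltzmann inversion of the measured g(r) must return u(r) up to an
  additive constant — the oracle for the PMF pipeline. Tabulated
  potentials are linearly interpolated; well edges are smeared by one
  grid spacing, so oracle tests use fine grids (Δr ≈ 0.001 nm).
* **Exchange system**: particles alternate between "inside" a 0.5 nm
  sphere around a static site and "far outside", with exponential
  residence and absence times (both means equal `mean_residence`; the
  spec exposes one timescale and the symmetric choice keeps the
  occupancy near 1/2, which exercises the intermittent-correlation
  plateau). Strict survival then decays as exp(−τ/mean_residence) by
  memorylessness, and the ground-truth indicator series doubles as a
  hydrogen-bond-kinetics fixture.

All generators are bit-reproducible from their integer seed.

## Conformation

⟨Ree²⟩ and ⟨Rg²⟩ are averaged over chains and frames; the reported
ratio is the ratio of ensemble means, not the mean of per-chain ratios.
Chains are made whole bond-by-bond before any distance is measured.
The Kuhn analysis maps a chain onto an equivalent freely-jointed chain:
b = ⟨Ree²⟩/R_max and N_RB = R_max/b, with R_max (the fully extended
contour length) supplied by the caller — n·bond_length for synthetic
chains, an all-trans contour length from configuration for chemical
topologies, since it is a property of the chemistry, not of the
trajectory. Standard errors come from block averaging with 5 blocks
over frames, which absorbs frame autocorrelation without modelling it.

Mean-square internal distances ⟨R²(n)⟩ average |r_i − r_j|² over all
monomer pairs with |i − j| = n; monomer coordinates default to atoms
and may be redefined as mass-weighted centers of configured atom
blocks.

## Time correlation and fitting

The vector autocorrelator supports two normalizations. The default
computes ⟨R(t0+t)·R(t0)/(R(t0)·R(t0))⟩ with the normalization inside
the average (per chain, per origin), which pins C(0) = 1 exactly; the
conventional ensemble form ⟨R(t)·R(0)⟩/⟨R(0)·R(0)⟩ is selectable.
Multiple time origins use a default stride of max(1, T/200); stride-1
correlation is FFT-accelerated and verified against the O(T²) double
loop to 1e-9.

Relaxation fits minimize weighted least squares of
C(t) = P + C(0)·exp[−(t/τ)^β] with β ≡ 1 (exponential), β free (KWW),
or β and P free (plateau KWW). The KWW objective is multimodal, so
fits multi-start from β ∈ {0.3, 0.5, 0.7, 0.9}; τ is parametrized
logarithmically, weights scale with √n_origins, and lags with fewer
than 10 origins are dropped (short curves keep every lag instead of
refusing). The mean relaxation time ⟨τ⟩ = (τ/β)·Γ(1/β) is always
attached, and parameter standard errors come from the Gauss–Newton
covariance at the optimum.

The single-chain dipole ACF is decomposed into backbone (PI) and
α-terminal contributions: μ_g = Σ q_i·r_i per group, with each group
made whole first and required to be net-neutral (a charged group's
dipole is origin-dependent, so it is rejected rather than silently
wrong). The five curves ϕ_total, ϕ_PP, ϕ_αα, ϕ_Pα, ϕ_αP share one
normalization by ϕ_total(0); additivity ϕ_total = ϕ_PP + ϕ_αα + ϕ_Pα +
ϕ_αP is an algebraic identity and is asserted to 1e-9.

## Rouse mode analysis

Chains are coarse-grained into N_RB contiguous mass-weighted blocks
(remainder atoms spread over the leading blocks). Free-end normal
coordinates use X_p = √(2/N)·Σ_j cos((j−1/2)pπ/N)·R_j — the orthonormal
DCT-II, so bead positions are exactly recoverable from all modes.
Fixed-end coordinates discretize the sine-transform integral as a
midpoint sum, X_p = (1/N)·Σ_n sin((p−1/2)nπ/N)·R_n. Each mode ACF is
fitted with a single exponential; the scaling report compares
τ_p/τ_R (τ_R ≡ τ_1) against 1/p² (free) and against the fixed-end law
1/(p−1/2)² normalized to its p = 1 value, and names whichever curve has
the smaller summed deviation.

## Mean-square displacement and diffusion

The per-chain center-of-mass MSD uses the FFT multi-origin algorithm
and requires unwrapped coordinates. D = slope/6 from a straight-line
fit over a configurable lag window (default 10–50 % of the maximum
lag), reported in 10⁻⁶ cm²/s. A curvature diagnostic flags windows
whose residuals exceed 2 % of the local MSD range — a ballistic or
sub-diffusive window is reported, not hidden.

## Finite-cutoff RDF, RCN and PMF

g_αβ(r) is normalized by the mean density of β within a ball of radius
r_c (default: half the shortest box edge) around each α particle,
estimated from the same frames as the numerator — not by the global
N_β/V. For the small systems this package targets the two differ
measurably; the finite-cutoff form makes the density-weighted ball
average of g equal 1 by construction, which is asserted on every
profile. The printed equations are ambiguous about where the
same-species double-counting factor (δ_αβ + 1) sits; here it appears
symmetrically in numerator and denominator and cancels, the only
reading under which an ideal gas gives g = 1 for both same- and
cross-species pairs. Self pairs are excluded for same-species RDFs;
coincident-distance pairs are all counted. A global-density
normalization is available behind a flag for sensitivity checks.

Running coordination numbers integrate 4πρ_β·r²·g(r) bin-wise
(exact for the histogram estimator, so the full-ball integral equals
the raw mean count); the first-shell convenience mode integrates from
0 to the first minimum of g after its first peak.

The PMF is W(r) = −kB·T·ln g(r) with the natural logarithm (the
printed barrier/kBT conversions are consistent only with ln); bins
with g = 0 are masked, not −∞. Extrema are located on a centered
moving average (default 5 bins) with a prominence floor (default
0.2 kJ/mol) to suppress bin noise; minima are labelled CM, SAM, SShM,
SSM purely by radial order, and each minimum's dissociation barrier is
W at the next maximum at larger r minus W at the minimum. The cluster
stability gate is the strict inequality |W(r_CM)| > 2·kB·T
(2.99 kJ/mol × 2 at 360 K); a pair exactly at threshold fails.

## Encounter and cluster fractions

Sites closer than r_th (default 0.6 nm, strict inequality) are linked;
encounter clusters are the connected components of that graph —
single linkage with full transitive closure, including peptide sites
bridging end-groups that are not directly in contact. The
encountering-event fraction is f_enc(s) = (1/M)(1/K)·Σ_k n_s(k) with
M the number of end-group sites and K the analysed frames (default:
the final 10 % of the trajectory). A cluster's size s counts every
member including peptides, but n_s counts only end-group members —
the only reading under which Σ_s f(s) = 1 holds while mixed
peptide–end clusters exist. Singletons are included, so the
normalization is exact and asserted to 1e-9.

The cluster-formation fraction applies the same machinery but admits
contact edges only between site-type pairs whose PMF gate is true;
sites whose every potential partner is gated off fall to s = 1. Gating
can only break clusters, so the gated distribution is dominated by the
ungated one at sizes ≥ 2.

## Survival probability and hydrogen-bond kinetics

P(τ) follows the count ratio ⟨N(t, t+τ)/N(t)⟩ over origins and
reference sites. "Remaining within" is interpreted strictly — inside
at every sampled frame of [t, t+τ] — with a lenient endpoints-only
mode behind a flag, since the verbal definition permits either; strict
matches "persistently remain". Spheres are centered per reference
site by default (matching the first-coordination-shell radius choice);
centering on the group's geometric center is a flag. Origins are
restricted to t ≤ T−1−τ_max so every origin covers the full lag range,
which makes the estimator provably non-increasing; origins are thinned
uniformly above 10⁴. The KWW fit reports ⟨τ_sp⟩ = (τ/β)·Γ(1/β).

Hydrogen bonds use a geometric criterion: minimum-image H···A distance
≤ 0.25 nm and D–H···A angle ≥ 130°, both configurable. The defaults
bracket the 0.2 nm NH···O contact peak seen in the melt RDFs; the
source analyses never print their cutoffs, so these are this package's
choices. The intermittent correlation C_I(t) =
⟨Σ h(t0)h(t0+t)⟩/⟨Σ h(t0)²⟩ uses FFT autocorrelation of the indicator
series; the continuous variant requires the bond to exist at every
intermediate frame and is computed from run lengths of unbroken-bond
stretches. C_c(t) ≤ C_I(t) holds by definition and is asserted on
arbitrary indicator series. Continuous curves get a KWW fit;
intermittent curves get the plateau form P + C(0)exp[−(t/τ)^β], which
the χ² comparison favours whenever re-formation sustains a long-time
plateau.

## Pipeline

`run_pipeline` executes requested stages in dependency order
(conformation → dynamics → structure → clustering → kinetics) from a
YAML/dict configuration holding either file paths or a synthetic spec;
gated clustering fails with a dependency error when structure has not
produced its PMF gates. Outputs are TSV tables plus JSON fit/extrema
sidecars and a manifest with a config hash and seed, so a run is
reproducible byte-for-byte from config + seed. Logging goes to stderr;
results never interleave with logs. The `analysis/` scripts are the
command-line surface; there is no separate console binary.

## Problem sizes and known limitations

The shipped analyses run at desk scale: 512 × 201-bead melt frames,
2×10⁶ BD steps, 10⁷ MC sweeps, 3000-frame exchange runs — sizes chosen
so the full suite completes in minutes while keeping every stochastic
tolerance at 3σ or tighter. Known limitations: orthorhombic boxes
only; equal-length chains per system for the stacked conformational
analyses; pair distances are O(N²) per frame (fine for terminal-group
selections, wasteful for full-system RDFs of large systems); the
Gaussian melt cannot exercise dynamics; and none of the synthetic
systems model excluded volume, entanglement, or chemistry-specific
hydrogen-bond geometry beyond the three-site donor fixture used in the
angle-criterion tests.
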