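# Methods

## Model

msbind treats a membrane protein fixed in one conformational state that
exposes `s` spatially disjoint binding sites to a small ligand dissolved in
the surrounding membrane–aqueous phase. The surrounding phase is modelled
as a homogeneous dilute reservoir with number density ρ̄ and excess
chemical potential μ̄ (the ligand's solvation free energy, kcal/mol). Site
`j` holds `0 ≤ n_j ≤ n_j_max` ligands; the receptor microstate is the
occupancy vector O(n₁,…,n_s) and the state space has ∏_j (n_j_max + 1)
elements.

### Per-site constants from restrained FEP

The input to the thermodynamic machinery is, per site and occupancy level
`n`, the cumulative reversible work W*_n (kcal/mol) of transferring `n`
ligands from gas phase into the site while each ligand `i` is held by an
isotropic harmonic restraint of force constant k_i (kcal/mol/Å²). The
restraint confines the ligand centroid to an effective configurational
volume (2π/βk_i)^{3/2}, so the level-`n` equilibrium constant of a single
site is

    K_n = (1/n!) · ∏_{i=1..n} (2π/βk_i)^{3/2} · exp(−β [W*_n − n μ̄])

in Å³ⁿ (converted to mM⁻ⁿ at the interface), with 1/n! correcting for the
indistinguishability of the ligands inside one site volume. The standard
binding free energy against the C° = 1 M reference is
ΔG°_n = −β⁻¹ ln(K_n (C°)ⁿ), which the package also reports as three
additive contributions: the restrained work less the reservoir solvation
(W*_n − nμ̄), the expansion of each restrained ligand from its effective
volume to the standard volume (C°)⁻¹, and the +β⁻¹ ln n! indistinguishability
term.

Double-occupancy works are composed from a two-step protocol
(W*₂ = W*₁ + W*₂|₁: couple a first ligand to the vacant site, then a
second to the pre-occupied site), with the two steps' statistical errors
added in quadrature. The restraint-volume product for a doubly occupied
site combines the singly-occupied force constant for the first ligand
with the second step's force constant for the second ligand; a per-level
alternative (level-2 k for both ligands) can be selected by supplying the
force-constant list explicitly.

### Occupancy statistics

Sites are treated as thermodynamically independent (the defining
approximation of the framework — see Limitations), so a state's constant
factorizes, K(n₁,…,n_s) = ∏_j K_{n_j}, and its probability at reservoir
density ρ̄ is ρ(n₁,…,n_s) ∝ ρ̄ⁿ K(n₁,…,n_s) with n = Σ n_j. Everything
downstream follows from this grand-canonical-like weight:

- marginals ρ(n_j) per site, exactly equal to the per-site normalization
  of the level weights w_j(n) = ρ̄ⁿ K_{jn};
- macrostate probabilities ρ(n) over the total bound count, computed as
  the polynomial convolution of the per-site weight vectors (never by
  enumeration);
- ensemble averages ⟨A⟩, either over the enumerated distribution or from
  marginals for per-site additive properties;
- titration curves ⟨n⟩(ρ̄), monotone non-decreasing with dilute-limit
  slope Σ_j K₁ⱼ.

Full enumeration is available up to a configurable cap (default 10⁶
states; the bundled 12-site receptor has 3⁸·2⁴ ≈ 1.0×10⁵ and a fully
saturable 12-site model has 3¹² ≈ 5.3×10⁵, both well under it); above the
cap the factorized routes provide identical marginals, macrostates and
averages for independent sites.

### Symmetry averaging

For an f-fold symmetric oligomer the `s` sites group into `s′ ≤ s`
classes of indistinguishable copies. The class estimator is the
arithmetic mean of the member constants with its **population** standard
deviation (divisor f) — the spread measures subunit-to-subunit structural
heterogeneity of the finite conformational ensemble, not an independent-
sample error. Averaging is done on K (linear scale), never on ΔG°, so the
dilute-limit titration slope Σ_j K₁ⱼ is preserved exactly by
symmetrization; at finite concentration the redistribution of probability
among states is not exactly average-preserving, and no such claim is
asserted. State constants of the symmetrized receptor multiply one class
factor per member-site occupancy, with members of one class free to carry
different occupancies within a state.

### Sites and spatial densities

Docked ligand poses are reduced to heavy-atom centroids and clustered by
deterministic single-linkage agglomeration at a distance cutoff (default
6 Å). Single linkage was chosen because it is deterministic, assumes no
cluster count, and matches the "disjoint islands of poses" geometry of
well-separated sites; pose energies are not used as weights. Each site
becomes a sphere (center = member mean, radius = furthest member, floored
at 4 Å), sites are numbered by lexicographic center order so output is
permutation-invariant, and a warning is emitted when two centers come
closer than 15 Å (the separation scale at which the independence
approximation is credible). Second-round poses (docked with one ligand
pre-bound) mark a site as double-occupancy capable when their centroid
falls inside its sphere and any recorded partner site matches.

The conditional density ρ(R|n_j) is a Gaussian kernel density over the
pose centroids observed at level n_j, rescaled so its grid integral
equals n_j; the grid (default spacing 0.5 Å, padded 3 bandwidths beyond
the site radius) is the numerical realization of the site volume δV_j. A
kernel estimate was chosen over a histogram because the per-level pose
counts are small (tens). The site density is the marginal-weighted sum
ρ_j(R) = Σ_n ρ(n_j) ρ(R|n_j), which integrates to ⟨n_j⟩ by construction,
and the transmembrane profile adds the reservoir term,
ρ(z) = ρ̄·A(z) + Σ_j ρ_j(z). Grids are exported as OpenDX scalar fields
(text; readable by VMD/PyMOL).

## Parameters

| parameter | units | default | rationale |
|---|---|---|---|
| temperature | K | 298.15 | reproduces the bundled dataset's published constants to ≤ 2% when back-computed from its (k, W*, μ̄) inputs; 300 K gives ~5% deviations. Configurable. |
| k_B | kcal/mol/K | 1.987204e−3 | CODATA value in the package's energy unit |
| C° | — | 1 M ≡ (1660 Å³)⁻¹ | conventional standard state; the mM↔Å⁻³ converter is derived from the same volume so ΔG° is exactly independent of the internal unit choice |
| μ̄ | kcal/mol | −0.1 (bundled dataset) | the ligand's in-water solvation free energy; an input, not estimated |
| enumeration cap | states | 10⁶ | keeps full enumeration < 1 s and memory ~ tens of MB |
| linkage cutoff | Å | 6 | well below the ~15 Å site separations, well above the ~1–4 Å pose spreads |
| site radius floor | Å | 4 | a site sphere should at least hold one ligand |
| kernel bandwidth | Å | Scott rule on member centroids, floor 0.8 | small-sample smoothing; floor prevents spikes for near-duplicate poses |
| grid spacing | Å | 0.5 | ~½ the smallest bandwidth; integrals converge to < 1e−3 |

Concentrations at or above 1 M are accepted but emit a warning: the
weights assume a dilute reservoir.

## Numerics

All state weights are handled in log space and normalized by
log-sum-exp, so strong binders (β|W*| of tens) neither overflow nor
underflow; K values are exponentiated last. Ranked state output sorts by
descending probability with lexicographic occupancy-vector tie-breaks.
The W* statistical error ε propagates to the multiplicative factor
exp(±βε) on K, reported as asymmetric bounds. z profiles deposit each
grid slab into the nearest global bin, preserving each site column's
mass exactly regardless of grid origins. Degenerate inputs (empty pose
sets, empty classes, occupancies above a site's maximum, zero
concentration) raise informative errors or take documented shortcuts
(ρ̄ = 0 pins the empty state).

## Synthetic data

The generator emulates the study conditions of the bundled system: 3 site
classes × 4-fold symmetry = 12 sites, double occupancy in two classes,
class-mean (k, W*) values of the magnitude of the bundled table, subunit
heterogeneity as additive Gaussian noise on W* (sd 0.3 kcal/mol, the
scale of the bundled error bars) and log-normal noise on k (15%). Pose
clouds are drawn from the harmonic restraint's Boltzmann distribution
(per-axis variance 1/βk). The default cloud width uses k = 0.4
(σ ≈ 1.2 Å, inside the 0.036–0.53 range of the bundled restraints),
chosen by the single-linkage resolvability condition
separation − cutoff > 5√2·σ so that 15 Å-separated clouds of 50 poses do
not chain at a 6 Å cutoff. A Metropolis sampler over occupancy vectors
(uniform site pick, uniform level proposal, acceptance min(1, w_new/w_old),
batch-mean standard errors over 20 batches) provides a stochastic oracle
for the analytic distribution.

What the generator does **not** emulate: docking false positives and
scoring-function bias, anisotropic or multimodal pose clouds, correlated
occupancy between nearby sites, and membrane inhomogeneity of the
reservoir. Passing recovery tests therefore demonstrate the correctness
of the estimators under the model's own assumptions, not robustness of
docking-derived inputs.

## Validation problem sizes

The test suite enumerates up to 3¹² = 531,441 states, runs the Metropolis
oracle for 10⁶ steps on a 3-site toy (agreement within 3 batch-mean
standard errors), recovers the restraint variance from 10⁵ pose samples
within 2%, and recovers all 12 planted sites from 600 poses with adjusted
Rand index 1. Kernel-density integrals are verified to 10⁻³ and
factorized-versus-enumerated distributions to 10⁻¹⁰.

## Known limitations and dataset caveats

- Site independence is a 0-level approximation; it will degrade when
  nearby sites are simultaneously occupied. No correlation corrections
  are provided.
- The dilute-reservoir assumption makes estimates at ≥ 1 M qualitative.
- W* and μ̄ are consumed as inputs; nothing here estimates them from
  trajectories or docking scores.
- In the bundled dataset the doubly-occupied K column as published is
  10³ × the value implied by the same rows' ΔG° column under mM⁻ⁿ units;
  the ΔG° column is taken as authoritative and the package's K₂ values
  are consistent with it (i.e. ~10⁻³ × the published K₂ numbers). The
  published average occupancies (0.08 at 1 mM) are likewise inconsistent
  with any unit convention that reproduces the ΔG° column — the bundled
  constants imply near-saturation of the strongest sites already at
  1 mM — so msbind reports the internally consistent values and makes no
  attempt to match those figures.
- The published two-ligand work error bars equal the linear sum of the
  step errors; msbind propagates the steps in quadrature, as appropriate
  for independent estimates, so its composed error bars are smaller.
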