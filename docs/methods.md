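# Model and methods

## Coarse-grained representation

A peptide of n residues is a chain of n nodes on a simple cubic lattice of
edge L (sites indexed 0..L−1, periodic boundaries by default). Consecutive
nodes are joined by bond vectors drawn from the bond-fluctuation set:
by default the classic 3-D classes {(2,0,0), (2,1,0), (2,1,1), (2,2,1),
(3,0,0), (3,1,0)} with all sign/permutation images (108 vectors, lengths
2 … √10); a `literal_range` option admits every integer vector with
4 ≤ |v|² ≤ 10 (adds the 12 images of (2,2,0)). The classic set is the
default because, combined with cube occupancy, it preserves the
non-crossing property of the bond-fluctuation method.

Excluded volume follows the Carmesin–Kremer convention (`occupancy_mode=
"cube"`, the default): each node owns the 2×2×2 cube of sites anchored at
its corner coordinate, enforced as a minimum corner-to-corner Chebyshev
distance of 2. The nearest approach of two nodes is therefore r = 2 lattice
constants, which places the first interaction shell on the attractive flank
of the contact potential. A `site` mode (one node per site, nearest
approach r = 1) is available; with it the deep r = √2 shell freezes the
system into a glass at every temperature of interest, which is why it is
not the default. Concentration is specified as a volume fraction: in cube
mode C_p = 8·N_residues/L³ (occupied-site fraction), in site mode
C_p = N_residues/L³; chain counts round down so the realized fraction
never exceeds the request.

## Contact potential

Non-bonded (and, by default, bonded) node pairs within r_c = √8 interact
through the depth-normalized generalized Lennard-Jones potential

    u(r) = 4 [ |ε_ij| (σ/r)^12 + ε_ij (σ/r)^6 ],   σ = 1,

truncated (not shifted) at r_c. For an attractive pair (ε < 0) this is the
standard 12-6 well with minimum exactly −|ε| at r = 2^(1/6)σ; for a
like-charge pair (ε > 0) both terms are positive, a purely repulsive core.
The 4-prefactor makes the matrix entries literal well depths; with the
packaged matrix it places the assembly/dispersion crossover of P1 in the
reduced-temperature window T ≈ 0.5–1.0 (without it the same crossover sits
a factor ~4 lower, and the matrix entries would be four times the depth
they claim to be).

The packaged matrix stores the printed magnitudes of the all-atom MD
minimum pair energies verbatim; signs are applied at load time (the six
like-charge pairs positive, all else negative). Two published entries carry
explicit minus signs (H-V, H-L = −9); they are read as attractive with
magnitude 9, consistent with the stated convention, and a warning is
emitted. Matrix values are used directly as dimensionless ε_ij; the reduced
temperature T absorbs the Boltzmann constant and shares their units. No
kcal/mol→kT conversion is applied.

## Dynamics

One Monte Carlo step (MCS) makes N attempts, N the residue count. Each
attempt draws a (chain, residue) pair and one of the 6 unit move vectors
uniformly (a 26-neighbour move set is available), rejects outright if the
target violates excluded volume or either adjacent bond constraint, and
otherwise accepts with min(1, exp(−ΔE/T)). ΔE is computed from the local
energy before and after, which equals the total-energy change because the
potential is pairwise and truncated. The total energy is tracked
incrementally and verified against an O(N²) minimum-image oracle in the
tests (agreement ≤ 10⁻⁸ relative after 10³ sweeps; observed drift is at
the 10⁻¹³ level).

Sampling correctness is tested on an exactly enumerable system: a single
bonded dimer, whose states group into squared-bond-length classes
{4, 5, 6, 9, 10} with known degeneracies {6, 24, 24, 30, 24}; long-run
class frequencies must match exp(−u/T)/Z by a χ² test at 3σ.

The inner loop is numba-jitted. Per-site neighbour indices over the cutoff
ball (92 offsets, |v|² ∈ {1,…,6,8}) are precomputed once per (L, boundary),
pair energies are tabulated per (type, type, r²), and the cube-mode overlap
test scans the 26 Chebyshev-1 neighbours of the target corner. Throughput
is ≈ 2×10⁶ attempts/s on one core. Each kernel segment is seeded from a
`SeedSequence` spawned off the run seed; identical seeds give bit-identical
trajectories.

Checkpoints are log-spaced (~30 per decade, plus t = 0 and t = n_mcs) and
record unwrapped positions, per-node contact energies, cumulative hop
counts, and the running total energy.

## Observables

- **R_c(t)** — RMS displacement of chain centres of mass from t = 0,
  averaged over chains and replicates; γ is the log-log slope over a stated
  window (default: the last time decade). The reported γ uncertainty is the
  standard error of per-replicate fits — the OLS slope error on the averaged
  curve understates between-run scatter by ~5×.
- **R_g** — per-chain RMS distance from the chain centroid, averaged over
  chains; "equilibrium" means the second half of the run, where R_g(t) has
  plateaued (the plateau is the equilibration criterion).
- **Energy / mobility profiles** — per-position means over chains,
  replicates and the equilibrated window. Per-node energies attribute each
  pair to both partners (so the profile sums to twice the pair energy per
  chain); mobility is successful hops per residue per MCS.
- **Radial profile** — unnormalized residue counts in unit-width spherical
  shells about the minimum-image (circular-mean) centre of mass of the
  residue cloud; the centre can be overridden (e.g. box centre).
- **S(q)** — computed exactly on the reciprocal lattice q = (2π/L)n via an
  FFT of the integer occupancy field, direction-averaged into logarithmic
  |q| bins of 5% relative width; for free (non-periodic) configurations a
  direct sum over random directions is provided instead. The effective
  dimension D = 1/ν is minus the log-log slope over a stated window;
  D > 3 is always flagged as unphysical (mass cannot scale faster than the
  embedding dimension — such fits straddle crossover regimes).

## All-atom nonbonded energy

The residue-pair contact energies originate from an all-atom stage whose
scoring function is reproduced here for user-supplied atom records:
E = Σ SW(R_ij)·[ε_ij((Rmin/R)¹² − 2(Rmin/R)⁶) + C q_i q_j/R_ij] over
cross-group pairs, with the X-PLOR switching polynomial
SW = (R_C²−R²)²(R_C²+2R²−3R_on²)/(R_C²−R_on²)³ between R_on = 1.0 nm and
R_C = 1.2 nm (1 below, 0 beyond). Units are nm, elementary charges and
kcal/mol; C = 33.20636 kcal·mol⁻¹·nm·e⁻². Per-atom vdW parameters (well
depth, Rmin/2) combine as ε_ij = √(ε_i ε_j), Rmin_ij = Rmin_i/2 + Rmin_j/2
(AMBER/CHARMM convention). `minimum_trajectory_energy` reduces a list of
two-group frames to the minimum pair energy — the scalar that parameterizes
the lattice model. Preparing the atom records (force-field assignment, MD
sampling) is out of scope; records arrive as CSV.

## Study protocol and problem sizes

The reference conditions are a 64³ lattice, C_p = 0.1, ~100 independent
samples of 5×10⁵ MCS. The packaged protocol (`pepmc.protocols`) scales this
to a 32³ lattice with 6–8 replicates of 10⁵ MCS — 34 twelve-mers (408
residues) per box, ~15 s per run — which leaves exponents and profile
shapes unchanged while growing their error bars; a 64³ spot check at
T = 0.5 reproduced the 32³ equilibrium R_g to 1%. With this protocol and
the packaged matrix, P1 gives γ ≈ 0.48 at T = 1.0, γ ≈ 0.28 ± 0.02 at
T = 0.7, and equilibrium R_g rising 3.07 → 3.39 → 3.91 over
T = 0.5/0.7/1.0; the per-residue energy minimum sits at ¹¹K at every
temperature examined.

## What the generator does and does not emulate

Runs are in vacuum: solvent quality, hydrophobic burial preferences and
counter-ions enter only implicitly through the contact matrix. Chains are
monodisperse 12-mers; the profile machinery assumes equal chain lengths.
Passing tests therefore demonstrate the statistical mechanics of the
lattice model under its stated interaction matrix — not the behaviour of
solvated peptides.

## Known limitations

- The equilibrium R_g at the lowest reference temperature computes to
  ≈ 3.07–3.08 (vs a reported window starting at 3.2); this is a property
  of the model as implemented, not a finite-size effect (checked at 64³).
- The per-residue energy maximum computes to position 7 (A) rather than the
  reported position 10 (N): ⁷A has the weakest pair couplings of any P1
  residue, so a sum of contact energies places it at the top; position 10
  is consistently among the most negative. The reported extreme ordering
  would require positions 7 and 10 to trade places.
- Sub-diffusion at T = 0.5–0.6 is deeper (γ ≈ 0.16–0.2) than the reported
  0.3–0.4 band; at T = 0.7–0.8 the band is reproduced.
- The Miyazawa–Jernigan comparison requires the user to supply the MJ
  matrix as CSV; it is not distributed here.
- At T well below the crossover the system falls out of equilibrium on
  accessible time scales (physical aging, not an artifact); profiles there
  describe the arrested state.
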