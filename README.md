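# pepmc

Lattice Monte Carlo simulation of peptide self-assembly with an
all-atom-derived residue–residue contact potential.

`pepmc` implements a hierarchical coarse-grained model: each amino acid of a
peptide becomes a single node on a cubic lattice, chains obey the
bond-fluctuation constraints (bond lengths between 2 and √10 lattice
constants, excluded volume), and nodes interact through a generalized
Lennard-Jones contact potential

```
u(r) = 4 [ |ε_ij| (σ/r)^12 + ε_ij (σ/r)^6 ],   r ≤ r_c = √8,  σ = 1,
```

whose signed well depths ε_ij come from a packaged 20×20 matrix of minimum
pairwise residue interaction energies computed by all-atom molecular
dynamics of capped residue pairs in vacuum (like-charge pairs D-D, D-E, E-E,
R-R, R-K, K-K are repulsive, all others attractive). A knowledge-based
matrix such as Miyazawa–Jernigan can be supplied in the same CSV format.
Residues move by single-site Metropolis hops, `exp(-ΔE/T)`, with temperature
T in reduced units of the matrix entries; one Monte Carlo step (MCS)
attempts one move per residue.

The package targets the temperature response of short-peptide assembly:
chains aggregate into dense globules at low T and disperse as random coils
at high T. It provides every observable needed to quantify that crossover:

- per-residue **energy and mobility profiles** E_n, M_n;
- mean **radius of gyration** R_g(t) and its equilibrium value vs T;
- RMS centre-of-mass displacement R_c(t) and the **anomalous diffusion
  exponent** γ from R_c ∝ t^γ (γ = ½ diffusive, γ < ½ sub-diffusive);
- the **radial residue-density profile** of the aggregate;
- the **static structure factor** S(q) = |Σ_j e^{iq·r_j}|²/N and the
  effective mass-scaling dimension D = 1/ν from S(q) ∝ q^{-1/ν}
  (D ≈ 3 compact solid, D ≈ 2 ideal chain; fitted D > 3 is flagged as a
  fit-window artifact).

A separate module evaluates the switched nonbonded energy used at the
all-atom stage (X-PLOR switching between R_on = 1.0 nm and R_C = 1.2 nm,
12-6 van der Waals plus Coulomb, kcal/mol) and the trajectory-minimum
reduction that turns a sampled residue-pair encounter into one contact
energy.

## Worked example

Simulate the 12-mer P1 (HSSYWYAFNNKT, the default sequence) on a 32³
lattice at volume fraction C_p = 0.1 and reduced temperature T = 0.7:

```yaml
# demo.yaml
L: 32
C_p: 0.1
T: 0.7
n_mcs: 20000
seed: 7
```

```
$ pepmc simulate demo.yaml -o demo_run
run complete: 20000 MCS, acceptance 0.117, outputs in demo_run

$ pepmc analyze demo_run -x gamma -x rg -x profiles
{
  "gamma": {
    "value": 0.2973483954556413,
    "stderr": 0.008802429579272762,
    "window": [2000.0, 20000.0]
  },
  "rg": {
    "equilibrium_mean": 3.398372920914838
  },
  "profiles": {
    "energy_argmax_position": 7,
    "energy_argmin_position": 11,
    ...
  }
}
```

Read: at T = 0.7 the chains are sub-diffusive (γ ≈ 0.30 < ½ over the last
time decade) because they have aggregated; the mean radius of gyration of a
chain is ≈ 3.4 lattice constants; along the sequence, the strong binder
¹¹K has the lowest (most negative) mean contact energy and the weakly
interacting ⁷A the highest. At T = 1.0 the same command yields γ ≈ 0.48
(diffusive dispersion) and R_g ≈ 3.9.

`pepmc sweep demo.yaml --temps 0.5,0.7,1.0 --replicates 10 -o sweep/`
runs seeded replicates per temperature and writes a summary table with
equilibrium R_g(T), γ(T) and the S(q)-fit dimension D(T).

The library API mirrors the CLI: `load_simulated_matrix()`,
`SimulationConfig`, `run_simulation()`, `rms_com_displacement()`,
`fit_power_exponent()`, `energy_profile()`, `structure_factor()`,
`fit_effective_dimension()`, etc. See `docs/methods.md` for the model
definition, conventions, and numerical choices.

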