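# Methods

## Model and sampling procedure

The engine targets the joint expanded-ensemble distribution
P(X, λ) ∝ exp(−β[V(X, λ) + E(λ)]) over configurations X and a finite set of
discrete λ states, by Gibbs sampling: P(X | λ) is sampled with Langevin
dynamics at fixed λ, P(λ | X) by evaluating the potential of the current
configuration at every λ state and drawing from the normalized Boltzmann
weights (including the bias E). The chain is valid for any number of MD
steps per Gibbs step — the MD move is a transition kernel that leaves
P(X | λ) invariant — but the bias-invariance argument used to pool samples
(below) additionally assumes each configuration is an equilibrium draw from
its λ state. The default of 100 integrator steps per Gibbs step is a
compromise the test suite probes by shrinking the knob; for the toy wells
here (relaxation time ≈ γ/k ≈ 1 time unit, 100 × 0.05 = 5 time units per
Gibbs step) residual autocorrelation mildly tightens bootstrap errors but
does not bias estimates.

### λ-state graphs

States carry exact rational weights (numerator over 1/Δλ), which makes state
identity and the per-site sum-to-one constraint exact; floats appear only at
energy-evaluation time. Single-site graphs place (1/Δλ − 1) intermediates on
every ligand-pair edge. For multiple sites, end states are the Cartesian
combinations of one substituent per site, and each end-state pair is joined
by intermediates that interpolate **simultaneously at every differing site**
on the shared grid. This simultaneous-interpolation rule is a design choice
(one-site-at-a-time chaining would also connect the graph, at the cost of
more states); a consequence is that the two "diagonal" edges of a 2×2 layout
share their midpoint, so coinciding intermediates are stored once and
referenced by both edges — states stay distinct, connectivity is preserved.

### Two-phase dynamic bias

Phase 1 (before the first MBAR refinement): E^i = B·L_i with flat bias
B = 100 kcal/mol per visit. Any B ≥ 10 works; a large value forces each
state's probability to essentially zero once visited until all states have
been seen, sweeping the graph in roughly M Gibbs steps. Phase 2 (after the
first refinement): E^i = −ΔG^i + ε_b·2^(L_i − min L) with ε_b = 1 kcal/mol;
the −ΔG anchors are frozen between refinements while the count penalty is
recomputed for all states every step (it depends on min L, so a single-state
update would be incorrect). Counts are never reset across refinement epochs.
The count-gap exponent is capped at 500 so the penalty stays finite in
float64; a capped penalty only matters for states that would have
probability ≈ 0 anyway.

Phase 2 begins at the first scheduled refinement whether or not all states
were visited; a warning is logged if any count is still zero (with B = 100
and the default refinement interval of 1000 Gibbs steps this does not occur
for the packaged graphs of ≤ 196 states).

### MBAR

The solver works on the dimensionless energies βU after subtracting each
row's minimum (a per-sample shift that cancels identically). It alternates
the self-consistent fixed-point sweep with a Newton step on the standard
convex MBAR objective restricted to states with samples (gauge fixed at the
first such state), accepting whichever step has the smaller post-update
residual; the Newton step is only attempted once the residual is below 1 kT.
Convergence tolerance is 1e-8 kcal/mol on the max change of ΔG per sweep,
max 10 000 iterations, with the residual trace attached to the
non-convergence error. Zero-count states receive reweighted estimates from
the final mixture weights. Refinement-time solves warm-start from the
previous solution; the final solve starts from zeros so the reported result
is decoupled from the trajectory of intermediate anchors.

Samples are attributed to the state at which their configuration was
generated, and **all** accumulated samples from the start of the run enter
every refinement: per the bias-invariance property, samples drawn at the
same λ state under different scalar biases come from the same conditional
configurational distribution, so no burn-in window discards data. The short
minimization/equilibration before the first Gibbs step is excluded from the
ledger (energies are logged only when P(λ | X) is sampled).

Uncertainties: bootstrap over Gibbs-step records, resampling with
replacement stratified by replicate (each resample preserves per-replicate
sample counts), 100 resamples by default, re-solving MBAR warm-started per
resample. The bootstrap unit is the individual record; block (per-replicate)
resampling would be the conservative alternative and is the main reason
reported σ can be mildly optimistic when records are autocorrelated.

### Langevin dynamics

BAOAB splitting, unit masses, chosen for its configurational accuracy at
moderate friction; velocities are redrawn from the Maxwell distribution at
the start of each MD segment (exactly zero at kT = 0), which re-thermalizes
between Gibbs steps and makes each propagation call self-contained. For
models whose λ-weighted force is diagonal-linear (the harmonic toys) the
integrator uses precomputed spring/center arrays instead of per-step
dispatch. Non-finite coordinates abort with a diagnostic error naming the
step size.

## Potential models

All models implement the site/substituent decomposition with one addition:
a λ-independent harmonic restraint ½k_r|x − x̂|² on every substituent
coordinate, the analog of the bonds and angles that remain unscaled on
decoupled "ghost" atoms in molecular alchemy (only softer terms such as
dihedrals are λ-scaled). Without it a λ = 0 substituent would be a free
particle with a divergent partition function; because it is λ-independent
it cancels exactly in P(λ | X) and in every relative ΔG, and state-energy
vectors therefore omit it (together with the environment term) by default —
a config flag includes them for debugging.

- **Gaussian ligands**: substituent (y, c) fully coupled feels
  ½k_{y,c}|x − x̂|²; the λ-scaled internal term is defined as the difference
  from the restraint, so at coupling λ the coordinate sees stiffness
  (1−λ)k_r + λk. End-state free energies are exactly
  G = (d/2)·kT·ln k + const — ΔG = (d/2)·kT·ln(k_c/k_ref), independent of
  well centers. Optional quadratic couplings (environment spring,
  environment–substituent spring, cross-site spring) keep the model
  Gaussian; the oracle then uses the Hessian-determinant route
  (U_min + (kT/2)·ln det H), exact for quadratic potentials.
- **Double wells**: 1-D quartic h((x/a)² − 1)² + δx per substituent, the toy
  analog of slow torsional degrees of freedom; free energies by adaptive
  quadrature. Initial configurations start in the +a basin deliberately, so
  trapping of fixed-λ runs versus escape through decoupled states is
  observable.

User models register a factory by name and implement the per-term energy
and gradient methods (optionally the vectorized fast paths).

## Default parameters

| parameter | default | meaning |
|---|---|---|
| Δλ | 0.1 | grid spacing along connective edges |
| B | 100 kcal/mol | flat per-visit bias, phase 1 |
| ε_b | 1.0 kcal/mol | exponential count-penalty scale, phase 2 |
| MD steps / Gibbs step | 100 | P(X\|λ) segment length |
| refinement interval | 1000 Gibbs steps | MBAR anchor update period |
| replicates | 3 | independent seeded runs pooled at the end |
| kT | 0.59248 kcal/mol (25 °C) | toys declare kT = 1 (reduced units) |
| timestep, friction | 0.05, 1.0 (reduced) | BAOAB integration (2 fs / 10 ps⁻¹ are the molecular-scale counterparts) |
| MBAR tol / max iter | 1e-8 kcal/mol / 10 000 | self-consistency residual |
| bootstrap resamples | 100 | σ estimation |

The packaged fixtures run 5000 Gibbs steps per replicate (symmetry controls,
parameter-recovery pair) and 25 000 for the multi-ligand benchmarks — sizes
chosen so the full validation completes in minutes on one CPU while leaving
clear statistical margins; a 75 000-step profile (the 15 ns-equivalent
schedule at 100 MD steps per Gibbs step, 75 refinements) is available via
`make_benchmark_suite(seed, paper_scale=True)`.

## What the toys do and do not show

The generator emulates the structural features that matter to the sampler:
many end states on a shared graph, tunable energy-distribution overlap
between adjacent states (via spring-constant spread), exact known answers,
and metastable conformational coordinates (double wells). It does not
emulate high-dimensional coupled environments, force-field nonbondeds,
end-point singularities (hence no soft-core potentials — every toy term is
finite), constraint algorithms, or pressure/solvent effects. Passing tests
therefore certify the correctness of the sampling/bias/estimator machinery,
not force-field accuracy or performance on solvated protein–ligand systems.

## Numerical choices and degenerate inputs

- Exact rational λ weights make graph deduplication and validation exact.
- The categorical draw uses inverse-CDF on the cumulative sum with a single
  uniform variate — reproducible across platforms for a fixed generator.
- Energy vectors are computed via a precomputed (M × substituents) weight
  matrix; cross-site terms add precomputed λλ pair weights.
- M = 1 graphs degenerate cleanly: the engine reduces to plain Langevin MD
  and reports ΔG = 0.
- Identical energy columns yield exactly equal free energies (the MBAR map
  treats them symmetrically), and zero-variance ledgers bootstrap to σ = 0.
- Replicate seeds are spawned from the configuration seed via SeedSequence,
  so runs are deterministic end-to-end and replicates are independent.

## Known limitations

- Bootstrap σ assumes records are exchangeable within a replicate; with
  strongly autocorrelated MD segments it can underestimate errors (see
  above). The |ΔG| ≤ 3σ acceptance margins absorb this at the packaged
  schedules.
- The multisite edge construction is one of several defensible conventions
  (see design note above).
- No analytic MBAR covariance estimator is provided — bootstrap only.
- The TI baseline supports pairwise (two end-state) transformations only,
  matching its star-map role.
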