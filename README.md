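# ladybugs

**λ-dynamics with bias-updated Gibbs sampling** — an expanded-ensemble free
energy engine over pluggable potential-energy models, with an in-repo MBAR
solver and a fixed-λ TI/MBAR baseline.

Relative free energy differences between ligand analogs are the workhorse
quantity of structure-based drug design: ΔΔG between two compounds decides
which one binds tighter. Alchemical methods compute them by coupling each
candidate substituent to the system through a weight λ and integrating over
a schedule of λ states. This package implements that machinery for groups of
many ligands at once, on analytically tractable toy potentials, so every
estimate can be checked against a closed form or quadrature. It is aimed at
method developers and students of free-energy calculation who want a small,
fully testable implementation of the expanded-ensemble + dynamic-bias +
MBAR loop.

## The method

A **λ state** is a vector of per-site, per-substituent weights λ_{y,c} with
Σ_c λ_{y,c} = 1 at every site y; end states put weight 1 on one substituent
per site (a physical ligand). For N ligands at one site with grid spacing
Δλ, all pairwise connective edges give

    N_λ = N + N(N−1)/2 · (1/Δλ − 1)

states (95/141/196 for 5/6/7 ligands at Δλ = 0.1). The total potential is

    V(X, λ) = V(x₀) + Σ_{y,c} λ_{y,c} [V(x₀, x_{y,c}) + V(x_{y,c})]
            + Σ_{y<z} Σ_{c,d} λ_{y,c} λ_{z,d} V(x_{y,c}, x_{z,d})

Sampling alternates the two conditionals of the joint distribution
(**Gibbs sampling**): Langevin dynamics draws X at fixed λ, then a new state
is drawn from the categorical distribution

    P(λ^i | X) ∝ exp(−β [U_i(X) + E^i])

where E^i is a per-state scalar bias updated every step. Before the first
MBAR call the bias is a flat penalty E^i = B·L_i (B = 100 kcal/mol per
visit), which sweeps the sampler through all states; afterwards it is

    E^i = −ΔG^i + ε_b · 2^(L_i − min L)

anchored at the running MBAR free energies and topped by an exponential
visit-count penalty (ε_b = 1 kcal/mol) that keeps visitation uniform.
Because the bias is a scalar per state, configurations sampled at a state
are equilibrium samples of that state regardless of the bias value, so all
unbiased energies pool into a single MBAR solve; uncertainties are bootstrap
standard errors stratified by replicate. A conventional fixed-λ TI/MBAR
baseline (11 windows at Δλ = 0.1) runs on the same potentials for
cross-validation.

## Worked example

`examples/03_parameter_recovery.py` runs the engine on two harmonic wells
with stiffness k = (1, 4) at kT = 1, where the exact answer is purely
entropic, ΔG = ½·ln 4:

```
estimated ΔG = 0.6988 ± 0.0115
exact ΔG     = 0.6931  (½·ln 4)
deviation    = +0.0057  (0.49 σ)
```

The estimate is the MBAR free energy of ligand 2's end state relative to
ligand 1's, pooled over 3 replicates of 3000 Gibbs steps (100 Langevin steps
each); σ is the bootstrap standard error, and the deviation sits well inside
it. The other examples build λ-state graphs (`01`), run the symmetric
control whose exact answer is 0 (`02`), compare against the TI/MBAR baseline
(`04`), and compute sampling-smoothness diagnostics on a 141-state benchmark
(`05`). Each is a short script that prints what it computes and what the
numbers mean.

A thin CLI wraps the same library calls:

```
ladybugs run --config config.yaml --out results/
ladybugs ti --config ti.yaml
ladybugs analyze --ledger results/ledger_rep0.csv --graph results/graph.json
ladybugs symtest --seed 7
```

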