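"""The LaDyBUGS engine: Gibbs sampling over (X, λ) with a dynamic bias.

Each Gibbs step alternates the two conditionals of the joint expanded
ensemble: Langevin dynamics at fixed λ samples P(X | λ), then the potential
energy of the current configuration is evaluated at every λ state and a new
state is drawn from the categorical distribution

    P(λ^i | X) ∝ exp(−β [U_i(X) + E_i])

where E_i is a per-state scalar bias.  The bias runs in two phases: before
the first MBAR refinement a large flat penalty (+B per visit, B = 100
kcal/mol by default) forces rapid coverage of all states; afterwards the bias
anchors each state at minus its current MBAR free energy estimate plus an
exponential visit-count penalty ε_b·2^(L_i − min L), which keeps visitation
uniform while estimates refine.  Because the bias is a scalar per state, the
configurations sampled at a given state are distributed identically whatever
the bias was at the time, so all accumulated unbiased energies can be pooled
into MBAR at every refinement and at the end of the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize

from .lambda_states import LambdaStateGraph, LambdaVector, validate_state
from .mbar import MBARResult, bootstrap_uncertainty, solve_mbar
from .potentials import Configuration, PotentialModel, StateEnergyEvaluator

logger = logging.getLogger("ladybugs")

__all__ = [
    "KT_ROOM",
    "GibbsSchedule",
    "BiasState",
    "SampleLedger",
    "RunResult",
    "PhaseError",
    "InstabilityError",
    "conditional_lambda_distribution",
    "sample_next_state",
    "propagate_md",
    "update_bias_pre_mbar",
    "update_bias_post_mbar",
    "planned_refinements",
    "run_ladybugs",
]

# kT at 25 °C in kcal/mol (k_B = 1.9872041e-3 kcal/mol/K, T = 298.15 K)
KT_ROOM = 0.0019872041 * 298.15


class PhaseError(RuntimeError):
    """A bias update was requested in the wrong phase."""


class InstabilityError(RuntimeError):
    """Langevin integration produced non-finite coordinates."""


@dataclass
class GibbsSchedule:
    """Sampling schedule for one LaDyBUGS run.

    Times are in whatever unit system the potential model declares; the
    defaults suit reduced-unit toys (kT = 1, unit masses and springs).  For
    molecular systems the corresponding reference values are 100 MD steps of
    2 fs per Gibbs step, friction 10 ps⁻¹, refinement every 1000 Gibbs steps.
    """

    total_gibbs_steps: int
    md_steps_per_gibbs: int = 100
    timestep: float = 0.05
    friction: float = 1.0
    gibbs_steps_per_refinement: int = 1000
    kT: float = KT_ROOM
    seed: int = 0
    replicates: int = 3
    equilibration_steps: int = 500
    minimize_steps: int = 200
    snapshot_every: int = 0

    def __post_init__(self):
        for name in (
            "total_gibbs_steps",
            "md_steps_per_gibbs",
            "timestep",
            "friction",
            "gibbs_steps_per_refinement",
            "kT",
            "replicates",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.total_gibbs_steps < self.gibbs_steps_per_refinement:
            raise ValueError(
                "total_gibbs_steps must be ≥ gibbs_steps_per_refinement "
                "(at least one MBAR refinement must be scheduled)"
            )

    @property
    def beta(self) -> float:
        return 1.0 / self.kT

    @classmethod
    def from_total_time(
        cls, total_time: float, md_steps_per_gibbs: int = 100, timestep: float = 0.05, **kwargs
    ) -> "GibbsSchedule":
        """Build a schedule from total simulated time (same unit as timestep).

        total Gibbs steps = time / (MD steps per Gibbs step × timestep); e.g.
        15 ns at 100 × 2 fs per Gibbs step gives 75 000 Gibbs steps.
        """
        total = int(round(total_time / (md_steps_per_gibbs * timestep)))
        return cls(
            total_gibbs_steps=total,
            md_steps_per_gibbs=md_steps_per_gibbs,
            timestep=timestep,
            **kwargs,
        )


def planned_refinements(schedule: GibbsSchedule) -> int:
    """Number of MBAR bias refinements the schedule will perform.

    floor(total Gibbs steps / refinement interval); e.g. a 15 ns-equivalent
    run at 100 × 2 fs MD per Gibbs step with refinement every 1000 steps
    performs 75 refinements.
    """
    return schedule.total_gibbs_steps // schedule.gibbs_steps_per_refinement


@dataclass
class BiasState:
    """Visit counts and per-state biases of the two-phase dynamic scheme."""

    counts: np.ndarray
    biases: np.ndarray
    phase: str = "pre-MBAR"
    flat_bias: float = 100.0
    eps_b: float = 1.0
    anchored_dG: np.ndarray | None = None

    _EXP_CAP = 500.0  # cap on the count-gap exponent; keeps 2^gap finite

    @classmethod
    def initial(cls, n_states: int, flat_bias: float = 100.0, eps_b: float = 1.0):
        return cls(
            counts=np.zeros(n_states, dtype=np.int64),
            biases=np.zeros(n_states),
            flat_bias=float(flat_bias),
            eps_b=float(eps_b),
        )


def update_bias_pre_mbar(bias: BiasState, visited: int) -> BiasState:
    """Flat-phase update: count the visit, set E_i = B · L_i for all states."""
    if bias.phase != "pre-MBAR":
        raise PhaseError(f"pre-MBAR update called in phase {bias.phase!r}")
    bias.counts[visited] += 1
    bias.biases = bias.flat_bias * bias.counts.astype(float)
    return bias


def update_bias_post_mbar(bias: BiasState) -> BiasState:
    """Anchored-phase update: E_i = −ΔG_i + ε_b · 2^(L_i − min L).

    The −ΔG anchors are the latest MBAR estimates and stay fixed between
    refinements; only the exponential count-gap penalty moves every step.
    """
    if bias.phase != "post-MBAR" or bias.anchored_dG is None:
        raise PhaseError(
            f"post-MBAR update requires anchored ΔG estimates (phase {bias.phase!r})"
        )
    gap = (bias.counts - bias.counts.min()).astype(float)
    bias.biases = -bias.anchored_dG + bias.eps_b * np.exp2(np.minimum(gap, bias._EXP_CAP))
    return bias


def conditional_lambda_distribution(
    energies: np.ndarray, biases: np.ndarray, beta: float
) -> np.ndarray:
    """P(λ | X): normalized Boltzmann weights of biased state energies."""
    e = np.asarray(energies, dtype=float)
    b = np.asarray(biases, dtype=float)
    if beta <= 0:
        raise ValueError("beta must be positive")
    if not (np.isfinite(e).all() and np.isfinite(b).all()):
        raise ValueError("non-finite energies or biases")
    z = -beta * (e + b)
    z -= z.max()
    p = np.exp(z)
    return p / p.sum()


def sample_next_state(probs: np.ndarray, rng: np.random.Generator) -> int:
    """Draw a state index from a categorical distribution (inverse CDF)."""
    p = np.asarray(probs, dtype=float)
    if not np.isfinite(p).all() or (p < 0).any() or p.sum() <= 0:
        raise ValueError("probabilities must be finite, nonnegative and not all zero")
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    return int(np.searchsorted(cdf, rng.random(), side="right"))


# ---------------------------------------------------------------------------
# Langevin dynamics


def _baoab(
    model: PotentialModel,
    x: np.ndarray,
    lam: np.ndarray,
    n_steps: int,
    dt: float,
    friction: float,
    kT: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """BAOAB-split Langevin integration at fixed λ (unit masses).

    Velocities are drawn fresh from the Maxwell distribution at the start of
    each call (exactly zero at kT = 0), which re-thermalizes between Gibbs
    steps and keeps the move self-contained.
    """
    if n_steps <= 0:
        return x
    n = x.size
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1))
    v = np.sqrt(kT) * rng.standard_normal(n) if kT > 0 else np.zeros(n)
    noise = rng.standard_normal((n_steps, n)) if c2 > 0 else None
    half = 0.5 * dt

    coeffs = model.linear_force_coeffs(lam)
    if coeffs is not None:
        K, center = coeffs
        F = -K * (x - center)
        for s in range(n_steps):
            v += half * F
            x += half * v
            v *= c1
            if noise is not None:
                v += c2 * noise[s]
            x += half * v
            F = -K * (x - center)
            v += half * F
    else:
        F = -model.gradient_flat(x, lam)
        for s in range(n_steps):
            v += half * F
            x += half * v
            v *= c1
            if noise is not None:
                v += c2 * noise[s]
            x += half * v
            F = -model.gradient_flat(x, lam)
            v += half * F
    if not np.isfinite(x).all():
        raise InstabilityError(
            f"non-finite coordinates after {n_steps} steps at dt={dt} "
            f"(max |x| = {np.nanmax(np.abs(x)):.3g}); reduce the timestep"
        )
    return x


def propagate_md(
    X: Configuration,
    v: LambdaVector,
    model: PotentialModel,
    n_steps: int,
    schedule: GibbsSchedule,
    rng: np.random.Generator,
) -> Configuration:
    """Sample P(X | λ): ``n_steps`` of Langevin dynamics at fixed λ state."""
    ok, violations = validate_state(v)
    if not ok:
        raise ValueError(f"invalid λ state: {violations}")
    flat = _baoab(
        model,
        X.flat.copy(),
        v.as_array(),
        n_steps,
        schedule.timestep,
        schedule.friction,
        schedule.kT,
        rng,
    )
    return Configuration(model, flat)


# ---------------------------------------------------------------------------
# ledger and results


@dataclass
class SampleLedger:
    """Per-Gibbs-step record of one replicate.

    ``visited[t]`` is the λ-state index at which configuration t was
    generated; ``energies[t]`` the unbiased M-vector of state energies at
    that configuration.  Snapshots of full coordinates are retained every
    ``snapshot_every`` steps (if enabled) for round-trip checks.
    """

    visited: np.ndarray
    energies: np.ndarray
    replicate_id: int = 0
    snapshots: list[tuple[int, np.ndarray]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.visited)

    @property
    def n_states(self) -> int:
        return self.energies.shape[1]

    def state_counts(self) -> np.ndarray:
        return np.bincount(self.visited, minlength=self.n_states)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            self.energies, columns=[f"U_{i}" for i in range(self.n_states)]
        )
        df.insert(0, "visited", self.visited)
        df.insert(0, "step", np.arange(1, len(self) + 1))
        df.insert(0, "replicate", self.replicate_id)
        return df

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path) -> "SampleLedger":
        import pandas as pd

        df = pd.read_csv(path)
        cols = [c for c in df.columns if c.startswith("U_")]
        return cls(
            visited=df["visited"].to_numpy(),
            energies=df[cols].to_numpy(),
            replicate_id=int(df["replicate"].iloc[0]) if len(df) else 0,
        )


@dataclass
class RunResult:
    """Output of a full (multi-replicate) LaDyBUGS run."""

    ledgers: list[SampleLedger]
    mbar: MBARResult
    diagnostics: dict

    def end_state_dG(self) -> dict:
        """ΔG (and bootstrap σ) of each ligand end state vs. the reference."""
        graph: LambdaStateGraph = self.diagnostics["graph"]
        out = {}
        for lig, idx in graph.end_state_indices.items():
            sig = None if self.mbar.sigma is None else float(self.mbar.sigma[idx])
            out[lig] = (float(self.mbar.dG[idx]), sig)
        return out


# ---------------------------------------------------------------------------
# main loop


def _minimize(model, conf, lam, max_iter):
    if max_iter <= 0:
        return conf
    res = optimize.minimize(
        lambda x: _energy(model, x, lam),
        conf.flat,
        jac=lambda x: model.gradient_flat(x, lam),
        method="L-BFGS-B",
        options={"maxiter": int(max_iter)},
    )
    return Configuration(model, res.x)


def _energy(model, x, lam):
    conf = Configuration(model, x)
    return model.baseline_energy(conf) + float(lam @ model.scaled_substituent_energies(conf))


def run_replicate(
    graph: LambdaStateGraph,
    model: PotentialModel,
    schedule: GibbsSchedule,
    rng: np.random.Generator,
    flat_bias: float = 100.0,
    eps_b: float = 1.0,
    replicate_id: int = 0,
    include_env: bool = False,
    mbar_tol: float = 1e-8,
) -> tuple[SampleLedger, BiasState, list[tuple[int, np.ndarray]]]:
    """One LaDyBUGS replicate; returns its ledger, final bias state and the
    per-refinement ΔG history."""
    M = len(graph)
    evaluator = StateEnergyEvaluator(graph, model, include_env=include_env)
    lam_rows = [s.as_array() for s in graph.states]
    beta = schedule.beta

    end_indices = sorted(graph.end_state_indices.values())
    cur = int(rng.choice(end_indices))

    conf = _minimize(model, model.initial_configuration(), lam_rows[cur], schedule.minimize_steps)
    conf.flat = _baoab(
        model, conf.flat, lam_rows[cur], schedule.equilibration_steps,
        schedule.timestep, schedule.friction, schedule.kT, rng,
    )

    total = schedule.total_gibbs_steps
    refine = schedule.gibbs_steps_per_refinement
    energies = np.empty((total, M))
    visited = np.empty(total, dtype=np.int64)
    snapshots: list[tuple[int, np.ndarray]] = []
    bias = BiasState.initial(M, flat_bias=flat_bias, eps_b=eps_b)
    history: list[tuple[int, np.ndarray]] = []
    warm_f = None

    for t in range(total):
        conf.flat = _baoab(
            model, conf.flat, lam_rows[cur], schedule.md_steps_per_gibbs,
            schedule.timestep, schedule.friction, schedule.kT, rng,
        )
        U = evaluator(conf)
        energies[t] = U
        visited[t] = cur
        if schedule.snapshot_every and (t + 1) % schedule.snapshot_every == 0:
            snapshots.append((t + 1, conf.flat.copy()))

        probs = conditional_lambda_distribution(U, bias.biases, beta)
        nxt = sample_next_state(probs, rng)
        if bias.phase == "pre-MBAR":
            update_bias_pre_mbar(bias, nxt)
        else:
            bias.counts[nxt] += 1
            update_bias_post_mbar(bias)

        if (t + 1) % refine == 0:
            counts = np.bincount(visited[: t + 1], minlength=M)
            res = solve_mbar(
                energies[: t + 1], counts, beta,
                tol=mbar_tol, reference_index=graph.reference_index, initial_f=warm_f,
            )
            warm_f = res.f
            if bias.phase == "pre-MBAR":
                if (bias.counts == 0).any():
                    logger.warning(
                        "switching to post-MBAR bias with %d unvisited states",
                        int((bias.counts == 0).sum()),
                    )
                bias.phase = "post-MBAR"
            bias.anchored_dG = res.dG.copy()
            update_bias_post_mbar(bias)
            history.append((t + 1, res.dG.copy()))
        cur = nxt

    ledger = SampleLedger(
        visited=visited, energies=energies, replicate_id=replicate_id, snapshots=snapshots
    )
    return ledger, bias, history


def run_ladybugs(config, rng: np.random.Generator | None = None) -> RunResult:
    """Run LaDyBUGS per the configuration and pool replicates through MBAR.

    Each replicate starts at a uniformly random end state, is minimized and
    briefly equilibrated there, then Gibbs-sampled per the schedule with the
    two-phase dynamic bias and periodic MBAR refinements.  The final estimate
    solves MBAR (from scratch, decoupled from the refinement trajectory) on
    the pooled unbiased energies of all replicates; uncertainties are
    bootstrap standard errors stratified by replicate.
    """
    graph = config.build_graph()
    model = config.build_model()
    schedule = config.schedule
    if graph.weight_matrix().shape[1] != model.n_sub:
        raise ValueError("alchemical layout and model disagree on substituents")

    ss = np.random.SeedSequence(schedule.seed if rng is None else rng.integers(2**31))
    child_seeds = ss.spawn(schedule.replicates + 1)

    ledgers, biases, histories = [], [], []
    for r in range(schedule.replicates):
        led, bias, hist = run_replicate(
            graph,
            model,
            schedule,
            np.random.default_rng(child_seeds[r]),
            flat_bias=config.flat_bias,
            eps_b=config.eps_b,
            replicate_id=r,
            include_env=config.include_env_in_energies,
        )
        ledgers.append(led)
        biases.append(bias)
        histories.append(hist)

    pooled_U = np.vstack([l.energies for l in ledgers])
    pooled_visited = np.concatenate([l.visited for l in ledgers])
    replicate_ids = np.concatenate(
        [np.full(len(l), l.replicate_id) for l in ledgers]
    )
    counts = np.bincount(pooled_visited, minlength=len(graph))
    final = solve_mbar(
        pooled_U, counts, schedule.beta, reference_index=graph.reference_index
    )
    if config.n_boot >= 2:
        final.sigma = bootstrap_uncertainty(
            pooled_U,
            pooled_visited,
            len(graph),
            schedule.beta,
            np.random.default_rng(child_seeds[-1]),
            n_boot=config.n_boot,
            replicate_ids=replicate_ids,
            reference_index=graph.reference_index,
            initial_f=final.f,
        )
    diagnostics = {
        "graph": graph,
        "model": model,
        "bias_states": biases,
        "refinement_history": histories,
        "planned_refinements": planned_refinements(schedule),
        "schedule": asdict(schedule),
    }
    return RunResult(ledgers=ledgers, mbar=final, diagnostics=diagnostics)
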