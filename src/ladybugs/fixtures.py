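"""Packaged control and benchmark configurations.

Symmetry controls interconvert byte-identical substituents, so the exact
answer is ΔG = 0 and any systematic deviation exposes an artifact of the
dynamic-bias machinery.  The benchmark suite provides multi-ligand harmonic
groups whose graphs have 95/141/196 states (5/6/7 ligands at Δλ = 0.1) and
whose exact free energies are known in closed form, plus a tilted double-well
group exercising slow conformational degrees of freedom.

All fixtures are pure functions of the seed: rebuilding with the same seed
yields byte-identical configurations.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .sampler import GibbsSchedule, run_ladybugs

__all__ = [
    "make_symmetric_pair_config",
    "make_symmetric_multisite_config",
    "make_k14_pair_config",
    "make_benchmark_suite",
    "symmetry_control_verdict",
]

# Reduced units throughout the fixtures: kT = 1, unit masses and restraints.
_FIXTURE_KT = 1.0


def _schedule(seed: int, total: int, timestep: float = 0.05, replicates: int = 3) -> GibbsSchedule:
    return GibbsSchedule(
        total_gibbs_steps=total,
        md_steps_per_gibbs=100,
        timestep=timestep,
        friction=1.0,
        gibbs_steps_per_refinement=1000,
        kT=_FIXTURE_KT,
        seed=seed,
        replicates=replicates,
        equilibration_steps=200,
        minimize_steps=100,
    )


def make_symmetric_pair_config(seed: int, total_gibbs_steps: int = 5000) -> RunConfig:
    """Single-site symmetric control: two identical harmonic substituents.

    The 11-state graph at Δλ = 0.1 interconverts two byte-identical wells;
    the exact answer is ΔG = 0 and the run should reproduce it within its
    bootstrapped uncertainty.
    """
    return RunConfig(
        model_name="gaussian_ligands",
        model_params={"spring_constants": [2.5, 2.5]},
        substituent_counts=[2],
        delta_lambda=0.1,
        schedule=_schedule(seed, total_gibbs_steps, timestep=0.1),
        label="symmetric-pair",
    )


def make_symmetric_multisite_config(seed: int, total_gibbs_steps: int = 5000) -> RunConfig:
    """Two-site symmetric control: 2 × 2 identical substituents.

    All four end states are physically identical, so every pairwise ΔG is 0
    by construction and label swaps must leave results invariant.
    """
    return RunConfig(
        model_name="gaussian_ligands",
        model_params={"spring_constants": [[2.5, 2.5], [2.5, 2.5]]},
        substituent_counts=[2, 2],
        delta_lambda=0.1,
        schedule=_schedule(seed, total_gibbs_steps, timestep=0.1),
        label="symmetric-multisite",
    )


def make_k14_pair_config(seed: int, total_gibbs_steps: int = 5000) -> RunConfig:
    """Parameter-recovery pair: springs k = (1, 4), exact ΔG = ½ ln 4 kT."""
    return RunConfig(
        model_name="gaussian_ligands",
        model_params={"spring_constants": [1.0, 4.0]},
        substituent_counts=[2],
        delta_lambda=0.1,
        schedule=_schedule(seed, total_gibbs_steps),
        label="k14-pair",
    )


def make_benchmark_suite(seed: int, paper_scale: bool = False) -> list[RunConfig]:
    """Multi-ligand benchmark groups (desk-scale analog of a 5-system set).

    Harmonic groups of 5/6/7 ligands with spring constants 2^c (free-energy
    spread ½·ln 2^(n−1) ≈ 1.4–2.1 kT, wells overlapping through the shared
    restraint), giving graphs of 95/141/196 states at Δλ = 0.1, plus one
    tilted double-well group.  The default profile runs 25 000 Gibbs steps
    per replicate; ``paper_scale`` selects the 75 000-step profile
    (the 15 ns-equivalent schedule at 100 MD steps per Gibbs step).
    """
    total = 75_000 if paper_scale else 25_000
    configs = []
    for i, n in enumerate((5, 6, 7)):
        configs.append(
            RunConfig(
                model_name="gaussian_ligands",
                model_params={"spring_constants": [float(2**c) for c in range(n)]},
                substituent_counts=[n],
                delta_lambda=0.1,
                schedule=_schedule(seed + i, total),
                n_boot=0,
                label=f"gaussian-{n}",
            )
        )
    configs.append(
        RunConfig(
            model_name="double_well",
            model_params={
                "barrier": [2.0, 2.0, 2.0],
                "separation": [1.0, 1.2, 0.9],
                "tilts": [0.0, 0.5, -0.3],
            },
            substituent_counts=[3],
            delta_lambda=0.1,
            schedule=_schedule(seed + 3, total),
            n_boot=0,
            label="double-well-3",
        )
    )
    return configs


def symmetry_control_verdict(seed: int, multisite: bool = False, k_sigma: float = 3.0):
    """Run a symmetry control and judge |ΔG| ≤ k·σ for every end-state pair.

    Returns (passed, details) where details lists each end-state pair with
    its ΔG estimate, bootstrap σ and individual verdict.
    """
    config = (
        make_symmetric_multisite_config(seed) if multisite else make_symmetric_pair_config(seed)
    )
    result = run_ladybugs(config)
    graph = result.diagnostics["graph"]
    ends = sorted(graph.end_state_indices.items(), key=lambda kv: kv[1])
    details = []
    passed = True
    for a in range(len(ends)):
        for b in range(a + 1, len(ends)):
            (lig_a, ia), (lig_b, ib) = ends[a], ends[b]
            ddg = float(result.mbar.dG[ib] - result.mbar.dG[ia])
            sig = float(
                np.hypot(result.mbar.sigma[ia], result.mbar.sigma[ib])
                if result.mbar.sigma is not None
                else np.nan
            )
            ok = bool(abs(ddg) <= k_sigma * sig)
            passed &= ok
            details.append(
                {"pair": (lig_a, lig_b), "dG": ddg, "sigma": sig, "within": ok}
            )
    return passed, details
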