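"""Multistate Bennett acceptance ratio (MBAR) estimation.

Given n pooled configurations with the potential energy of each evaluated at
every one of M states, and the number of samples generated at each state,
MBAR solves the self-consistent equations

    f_i = −ln Σ_n exp(−u_i(x_n)) / Σ_k N_k exp(f_k − u_k(x_n))

for the dimensionless free energies f_i (u = βU).  The estimator treats the
pooled data as draws from the mixture of the sampled states, which is what
makes it applicable to expanded-ensemble data: configurations drawn at a
given λ state under any external scalar bias follow that state's conditional
configurational distribution, so unbiased energies can be pooled directly.

The solver alternates self-consistent iteration with Newton steps on the
states that contributed samples (the standard convex MBAR objective), picking
whichever step reduces the residual more; states with zero samples receive
reweighted estimates from the final mixture weights.  Uncertainties come from
bootstrap resampling of the pooled records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "MBARResult",
    "MBARConvergenceError",
    "solve_mbar",
    "bootstrap_uncertainty",
    "center_to_reference_set",
]


class MBARConvergenceError(RuntimeError):
    """Raised when the self-consistent equations fail to converge.

    Carries the residual trace in ``residuals`` (energy units per iteration).
    """

    def __init__(self, message: str, residuals: list[float]):
        super().__init__(message)
        self.residuals = residuals


@dataclass
class MBARResult:
    """Relative free energies with diagnostics.

    ``dG`` is in energy units (kcal/mol for β in mol/kcal), shifted so the
    reference state is exactly zero.  ``sigma`` holds bootstrap standard
    errors once computed (None otherwise).
    """

    dG: np.ndarray
    n_samples_per_state: np.ndarray
    reference_index: int
    converged: bool
    residual: float
    n_iterations: int
    beta: float
    sigma: np.ndarray | None = None
    residual_trace: list[float] = field(default_factory=list)

    @property
    def f(self) -> np.ndarray:
        """Dimensionless free energies β·ΔG."""
        return self.beta * self.dG


def _self_consistent_update(u, f, counted, log_N, N):
    """One sweep of the MBAR fixed-point map over counted states."""
    # log denominator per sample: ln Σ_k N_k exp(f_k − u_k)
    log_denom = logsumexp(f[counted] - u[:, counted] + log_N, axis=1)
    return -logsumexp(-u[:, counted] - log_denom[:, None], axis=0)


def _gradient_hessian(u, f, counted, log_N, N):
    log_denom = logsumexp(f[counted] - u[:, counted] + log_N, axis=1)
    logW = f[counted] - u[:, counted] - log_denom[:, None]
    W = np.exp(logW)  # n × K, Σ_i N_i W_ni = 1
    Nc = N[counted]
    g = Nc * (W.sum(axis=0)) - Nc
    H = np.diag(Nc * W.sum(axis=0)) - (Nc[:, None] * Nc[None, :]) * (W.T @ W)
    return g, H, W


def solve_mbar(
    energy_matrix: np.ndarray,
    counts: np.ndarray,
    beta: float,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    reference_index: int = 0,
    initial_f: np.ndarray | None = None,
) -> MBARResult:
    """Solve the MBAR equations on pooled state energies.

    Parameters
    ----------
    energy_matrix
        (n, M) array: energy of sample row at every state column (kcal/mol).
    counts
        (M,) number of samples generated at each state; must sum to n.
        Zero-count states still receive reweighted free energy estimates.
    beta
        Inverse temperature (mol/kcal).
    tol
        Convergence tolerance on the max change of ΔG per sweep, in energy
        units (kcal/mol).
    """
    U = np.asarray(energy_matrix, dtype=float)
    if U.ndim != 2 or U.size == 0:
        raise ValueError(f"energy matrix must be nonempty 2-D, got shape {U.shape}")
    n, M = U.shape
    N = np.asarray(counts, dtype=float)
    if N.shape != (M,):
        raise ValueError(f"counts must have length {M}")
    if int(round(N.sum())) != n:
        raise ValueError(f"counts sum to {N.sum()}, expected {n} samples")
    if not np.isfinite(U[:, N > 0]).all():
        raise ValueError("non-finite energies in a sampled state's column")

    u = beta * U
    u = u - u.min(axis=1, keepdims=True)  # row shift: cancels in the equations
    counted = np.flatnonzero(N > 0)
    log_N = np.log(N[counted])

    f = np.zeros(M) if initial_f is None else np.array(initial_f, dtype=float)
    fc = f[counted].copy()
    fc -= fc[0]

    trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        f_sc = _self_consistent_update(u, _expand(f, fc, counted, M), counted, log_N, N)
        f_sc -= f_sc[0]
        resid_sc = np.max(np.abs(f_sc - fc)) / beta

        f_new, resid = f_sc, resid_sc
        if resid_sc < 1.0 and len(counted) > 1:
            # Newton step on the convex MBAR objective (gauge: first state fixed)
            g, H, _ = _gradient_hessian(u, _expand(f, fc, counted, M), counted, log_N, N)
            try:
                step = np.linalg.solve(
                    H[1:, 1:] + 1e-12 * np.eye(len(counted) - 1), g[1:]
                )
                f_nt = fc.copy()
                f_nt[1:] -= step
                f_chk = _self_consistent_update(
                    u, _expand(f, f_nt, counted, M), counted, log_N, N
                )
                f_chk -= f_chk[0]
                resid_nt = np.max(np.abs(f_chk - f_nt)) / beta
                if np.isfinite(resid_nt) and resid_nt < resid_sc:
                    f_new, resid = f_nt, resid_nt
            except np.linalg.LinAlgError:
                pass

        trace.append(resid)
        fc = f_new
        if resid < tol:
            converged = True
            break

    if not converged:
        raise MBARConvergenceError(
            f"MBAR did not converge in {max_iter} iterations "
            f"(final residual {trace[-1]:.3e} kcal/mol)",
            trace,
        )

    # reweighted estimates for every state, including zero-count ones
    log_denom = logsumexp(fc - u[:, counted] + log_N, axis=1)
    f_all = -logsumexp(-u - log_denom[:, None], axis=0)
    f_all -= f_all[reference_index]
    return MBARResult(
        dG=f_all / beta,
        n_samples_per_state=np.asarray(counts),
        reference_index=reference_index,
        converged=converged,
        residual=trace[-1],
        n_iterations=iterations,
        beta=beta,
        residual_trace=trace,
    )


def _expand(f_template, fc, counted, M):
    f = np.zeros(M)
    f[counted] = fc
    return f


def bootstrap_uncertainty(
    energy_matrix: np.ndarray,
    visited: np.ndarray,
    n_states: int,
    beta: float,
    rng: np.random.Generator,
    n_boot: int = 100,
    replicate_ids: np.ndarray | None = None,
    reference_index: int = 0,
    initial_f: np.ndarray | None = None,
    tol: float = 1e-8,
) -> np.ndarray:
    """Bootstrap standard errors of the MBAR free energies.

    Gibbs-step records (rows of the pooled energy matrix, with the state each
    was generated at) are resampled with replacement, stratified by replicate
    so each resample preserves the replicate structure; MBAR is re-solved per
    resample and the standard deviation of ΔG across resamples is returned.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be ≥ 2")
    U = np.asarray(energy_matrix, dtype=float)
    visited = np.asarray(visited)
    n = len(visited)
    if replicate_ids is None:
        replicate_ids = np.zeros(n, dtype=int)
    strata = [np.flatnonzero(replicate_ids == r) for r in np.unique(replicate_ids)]
    if n < np.unique(visited).size:
        import warnings

        warnings.warn("fewer samples than sampled states: degenerate resamples likely")

    samples = np.empty((n_boot, n_states))
    warm = initial_f
    for b in range(n_boot):
        rows = np.concatenate([s[rng.integers(0, len(s), size=len(s))] for s in strata])
        counts = np.bincount(visited[rows], minlength=n_states)
        res = solve_mbar(
            U[rows],
            counts,
            beta,
            tol=tol,
            reference_index=reference_index,
            initial_f=warm,
        )
        warm = res.f
        samples[b] = res.dG
    return samples.std(axis=0, ddof=1)


def center_to_reference_set(ddG_comp: np.ndarray, dG_expt: np.ndarray) -> np.ndarray:
    """Shift computed relative free energies onto an experimental reference set.

    ΔG_comp,i = ΔΔG_comp,i − (mean ΔΔG_comp − mean ΔG_expt), so the computed
    values share the experimental mean exactly and can be compared one-to-one.
    """
    a = np.asarray(ddG_comp, dtype=float)
    b = np.asarray(dG_expt, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("ΔΔG_comp and ΔG_expt must be equal-length 1-D vectors")
    return a - (a.mean() - b.mean())
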