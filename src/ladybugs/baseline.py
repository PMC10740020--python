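"""Fixed-λ TI/MBAR baseline: the conventional comparator method.

A pairwise alchemical transformation is split into independent fixed-λ
windows on a uniform Δλ grid (11 windows at Δλ = 0.1).  Each window is
minimized, equilibrated and sampled on its own; saved frames are evaluated
at every window's potential and the pooled energies go through the same MBAR
solver as the expanded-ensemble engine.  Because each window is an
independent trajectory, slow conformational degrees of freedom can stay
trapped near their starting basin — the behaviour the dynamic-bias sampler
is designed to avoid.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml

from .lambda_states import LambdaVector, InvalidGridError, _grid_divisions
from .mbar import MBARResult, bootstrap_uncertainty, solve_mbar
from .potentials import Configuration, build_model
from .sampler import KT_ROOM, _baoab, _minimize

__all__ = ["TIConfig", "TIResult", "window_schedule", "run_ti_mbar", "efficiency_ratio"]


def window_schedule(delta_lambda: float) -> np.ndarray:
    """Ordered λ values (0, Δλ, …, 1): 1/Δλ + 1 fixed windows."""
    m = _grid_divisions(delta_lambda)
    return np.arange(m + 1) / m


@dataclass
class TIConfig:
    """Configuration of a pairwise fixed-λ baseline calculation."""

    model_name: str
    model_params: dict
    delta_lambda: float = 0.1
    md_steps_per_window: int = 20_000
    save_every: int = 100
    timestep: float = 0.05
    friction: float = 1.0
    kT: float = KT_ROOM
    seed: int = 0
    replicates: int = 3
    equilibration_steps: int = 500
    minimize_steps: int = 200
    n_boot: int = 100

    def build_model(self):
        return build_model(self.model_name, self.model_params)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TIConfig":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "TIConfig":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class TIResult:
    """Pooled MBAR estimate over fixed-λ windows (reference: window λ=0)."""

    mbar: MBARResult
    windows: np.ndarray
    positions: dict
    total_md_steps: int

    @property
    def ddG(self) -> float:
        """ΔG of the fully transformed end state (λ=1) vs. the start (λ=0)."""
        return float(self.mbar.dG[-1])

    @property
    def sigma_ddG(self) -> float | None:
        return None if self.mbar.sigma is None else float(self.mbar.sigma[-1])


def run_ti_mbar(config: TIConfig, rng: np.random.Generator | None = None) -> TIResult:
    """Run independent fixed-λ Langevin windows and pool them through MBAR.

    Requires a pairwise model (one site, two substituents).  Every saved
    frame is evaluated at all window potentials; frames from all windows and
    replicates are pooled into one MBAR solve with bootstrap errors
    (resampling stratified by replicate).
    """
    model = config.build_model()
    if model.substituent_counts != (2,):
        raise ValueError(
            "TI baseline does pairwise alchemy: need one site with two substituents, "
            f"got sites of {model.substituent_counts}"
        )
    lams = window_schedule(config.delta_lambda)
    W = np.column_stack([1.0 - lams, lams])  # (n_windows, 2) substituent weights
    n_win = len(lams)
    n_frames = config.md_steps_per_window // config.save_every

    ss = np.random.SeedSequence(config.seed if rng is None else rng.integers(2**31))
    seeds = ss.spawn(config.replicates + 1)

    energy_rows, visited, rep_ids = [], [], []
    positions: dict[int, list[np.ndarray]] = {w: [] for w in range(n_win)}
    for r in range(config.replicates):
        rep_rng = np.random.default_rng(seeds[r])
        for w in range(n_win):
            lam = W[w]
            conf = _minimize(
                model, model.initial_configuration(), lam, config.minimize_steps
            )
            x = _baoab(
                model, conf.flat, lam, config.equilibration_steps,
                config.timestep, config.friction, config.kT, rep_rng,
            )
            for _ in range(n_frames):
                x = _baoab(
                    model, x, lam, config.save_every,
                    config.timestep, config.friction, config.kT, rep_rng,
                )
                e = model.scaled_substituent_energies(Configuration(model, x))
                energy_rows.append(W @ e)
                visited.append(w)
                rep_ids.append(r)
                positions[w].append(x.copy())

    U = np.asarray(energy_rows)
    visited = np.asarray(visited)
    rep_ids = np.asarray(rep_ids)
    counts = np.bincount(visited, minlength=n_win)
    result = solve_mbar(U, counts, 1.0 / config.kT, reference_index=0)
    if config.n_boot >= 2:
        result.sigma = bootstrap_uncertainty(
            U, visited, n_win, 1.0 / config.kT,
            np.random.default_rng(seeds[-1]),
            n_boot=config.n_boot, replicate_ids=rep_ids, initial_f=result.f,
        )
    total_md = config.replicates * n_win * (
        config.md_steps_per_window + config.equilibration_steps
    )
    return TIResult(
        mbar=result,
        windows=lams,
        positions={w: np.asarray(p) for w, p in positions.items()},
        total_md_steps=total_md,
    )


def efficiency_ratio(ladybugs_total_md_steps: float, ti_total_md_steps: float) -> float:
    """How many times less MD sampling the expanded-ensemble run used.

    Bookkeeping ratio (TI total MD steps) / (LaDyBUGS total MD steps) for the
    same set of perturbations.
    """
    if ladybugs_total_md_steps <= 0 or ti_total_md_steps <= 0:
        raise ValueError("total MD step counts must be positive")
    return float(ti_total_md_steps) / float(ladybugs_total_md_steps)
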