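"""Pluggable potential-energy models with a λ-scaled alchemical decomposition.

The total potential of a configuration ``X = (x0, {x_{y,c}})`` at λ state ``λ``
is assembled from site/substituent terms::

    V(X, λ) = V_env(x0)
            + Σ_y Σ_c λ_{y,c} [ V_coupled(x0, x_{y,c}) + V_internal(x_{y,c}) ]
            + Σ_y Σ_c V_restraint(x_{y,c})
            + Σ_{y<z} Σ_{c,d} λ_{y,c} λ_{z,d} V_cross(x_{y,c}, x_{z,d})

The single-site double sum is the per-substituent (environment-coupled plus
internal) energy scaled linearly by λ; the bilinear double sum couples
substituents on different sites.  ``V_restraint`` is a λ-independent term on
each alchemical coordinate — the analog of the bonds and angles that remain
unscaled on decoupled (λ=0) "ghost" substituents in molecular alchemy.  It
keeps every partition function finite without soft-core potentials, and being
λ-independent it cancels both in the conditional λ distribution and in all
relative free energies.

Toy models in this module are low-dimensional and analytically tractable, so
they serve as ground-truth oracles for the sampler: harmonic ("Gaussian
ligand") wells with closed-form free energies, and quartic double wells whose
free energies come from 1-D quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, optimize

from .lambda_states import LambdaStateGraph, LambdaVector, validate_state

__all__ = [
    "Configuration",
    "PotentialModel",
    "GaussianLigandModel",
    "DoubleWellModel",
    "UnsupportedOracleError",
    "total_potential",
    "total_gradient",
    "state_energy_vector",
    "StateEnergyEvaluator",
    "make_gaussian_ligand_model",
    "make_double_well_model",
    "analytic_end_state_dG",
    "MODEL_REGISTRY",
    "register_model",
    "build_model",
]


class UnsupportedOracleError(TypeError):
    """Raised when an analytic/quadrature free energy is requested from a
    model that does not provide one."""


# ---------------------------------------------------------------------------
# configurations


class Configuration:
    """Coordinates of environment and all alchemical substituents.

    Stored as one flat float vector ``[x0 | x_{0,0} | x_{0,1} | ...]`` in
    (site, substituent) order; views are provided per component.
    """

    def __init__(self, model: "PotentialModel", flat: np.ndarray | None = None):
        self.model = model
        if flat is None:
            flat = np.zeros(model.n_dof)
        flat = np.asarray(flat, dtype=float)
        if flat.shape != (model.n_dof,):
            raise ValueError(f"expected {model.n_dof} coordinates, got {flat.shape}")
        self.flat = flat

    @property
    def x0(self) -> np.ndarray:
        return self.flat[: self.model.x0_dim]

    def sub(self, y: int, c: int) -> np.ndarray:
        lo, hi = self.model._sub_slices[self.model._sub_index[(y, c)]]
        return self.flat[lo:hi]

    def copy(self) -> "Configuration":
        return Configuration(self.model, self.flat.copy())


# ---------------------------------------------------------------------------
# model base class


class PotentialModel:
    """Base class: per-term energies/gradients plus optional fast paths.

    Subclasses define the energy decomposition by overriding the per-term
    methods; the generic drivers (:func:`total_potential`, MD forces, state
    energy vectors) work for any subclass.  Performance-sensitive subclasses
    additionally override the vectorized ``scaled_substituent_energies`` and
    ``gradient_flat`` fast paths.
    """

    def __init__(self, x0_dim: int, sub_dims: Sequence[Sequence[int]]):
        self.x0_dim = int(x0_dim)
        self.sub_dims = [list(map(int, site)) for site in sub_dims]
        self._sub_index: dict[tuple[int, int], int] = {}
        self._sub_slices: list[tuple[int, int]] = []
        pos = self.x0_dim
        for y, site in enumerate(self.sub_dims):
            for c, d in enumerate(site):
                self._sub_index[(y, c)] = len(self._sub_slices)
                self._sub_slices.append((pos, pos + d))
                pos += d
        self.n_dof = pos
        self.n_sub = len(self._sub_slices)

    # -- structure ------------------------------------------------------

    @property
    def site_count(self) -> int:
        return len(self.sub_dims)

    @property
    def substituent_counts(self) -> tuple[int, ...]:
        return tuple(len(site) for site in self.sub_dims)

    def initial_configuration(self) -> Configuration:
        return Configuration(self)

    def sub_pairs(self):
        """All cross-site substituent pairs ((y,c),(z,d)) with y < z."""
        keys = list(self._sub_index)
        for i, (y, c) in enumerate(keys):
            for z, d in keys[i + 1 :]:
                if z > y:
                    yield (y, c), (z, d)

    # -- energy terms (defaults: absent) --------------------------------

    def env_energy(self, x0: np.ndarray) -> float:
        return 0.0

    def env_grad(self, x0: np.ndarray) -> np.ndarray:
        return np.zeros_like(x0)

    def coupled_energy(self, y: int, c: int, x0: np.ndarray, x: np.ndarray) -> float:
        return 0.0

    def coupled_grads(self, y, c, x0, x) -> tuple[np.ndarray, np.ndarray]:
        return np.zeros_like(x0), np.zeros_like(x)

    def internal_energy(self, y: int, c: int, x: np.ndarray) -> float:
        raise NotImplementedError

    def internal_grad(self, y: int, c: int, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def restraint_energy(self, y: int, c: int, x: np.ndarray) -> float:
        return 0.0

    def restraint_grad(self, y: int, c: int, x: np.ndarray) -> np.ndarray:
        return np.zeros_like(x)

    def cross_energy(self, y, c, z, d, xa: np.ndarray, xb: np.ndarray) -> float:
        return 0.0

    def cross_grads(self, y, c, z, d, xa, xb) -> tuple[np.ndarray, np.ndarray]:
        return np.zeros_like(xa), np.zeros_like(xb)

    @property
    def has_cross(self) -> bool:
        return False

    # -- vectorized fast paths (generic fallbacks) ----------------------

    def scaled_substituent_energies(self, conf: Configuration) -> np.ndarray:
        """Per-substituent λ-scaled energy [coupled + internal], flat (y,c)."""
        x0 = conf.x0
        out = np.empty(self.n_sub)
        for (y, c), i in self._sub_index.items():
            x = conf.sub(y, c)
            out[i] = self.coupled_energy(y, c, x0, x) + self.internal_energy(y, c, x)
        return out

    def baseline_energy(self, conf: Configuration) -> float:
        """λ-independent part: environment plus restraints."""
        x0 = conf.x0
        e = self.env_energy(x0)
        for (y, c) in self._sub_index:
            e += self.restraint_energy(y, c, conf.sub(y, c))
        return e

    def linear_force_coeffs(self, lam: np.ndarray):
        """Optional fast path for linear forces.

        If the λ-weighted force is exactly −K ⊙ (x − c) with diagonal K,
        return the per-dof arrays (K, c); otherwise None.  The Langevin
        integrator uses this to avoid per-step Python dispatch.
        """
        return None

    def gradient_flat(self, flat: np.ndarray, lam: np.ndarray) -> np.ndarray:
        """Gradient of the full λ-weighted potential w.r.t. all coordinates.

        ``lam`` is the flat per-substituent weight vector of the current state.
        """
        conf = Configuration(self, flat)
        g = np.zeros_like(flat)
        x0 = conf.x0
        g[: self.x0_dim] += self.env_grad(x0)
        for (y, c), i in self._sub_index.items():
            lo, hi = self._sub_slices[i]
            x = conf.sub(y, c)
            g[lo:hi] += self.restraint_grad(y, c, x)
            if lam[i] != 0.0:
                g0, gx = self.coupled_grads(y, c, x0, x)
                g[: self.x0_dim] += lam[i] * g0
                g[lo:hi] += lam[i] * (gx + self.internal_grad(y, c, x))
        if self.has_cross:
            for (y, c), (z, d) in self.sub_pairs():
                i, j = self._sub_index[(y, c)], self._sub_index[(z, d)]
                w = lam[i] * lam[j]
                if w != 0.0:
                    ga, gb = self.cross_grads(y, c, z, d, conf.sub(y, c), conf.sub(z, d))
                    (la, ha), (lb, hb) = self._sub_slices[i], self._sub_slices[j]
                    g[la:ha] += w * ga
                    g[lb:hb] += w * gb
        return g


# ---------------------------------------------------------------------------
# generic drivers


def total_potential(conf: Configuration, v: LambdaVector, model: PotentialModel) -> float:
    """Full potential energy of configuration ``conf`` at λ state ``v``."""
    ok, violations = validate_state(v)
    if not ok:
        raise ValueError(f"invalid λ state: {violations}")
    lam = v.as_array()
    if lam.shape != (model.n_sub,):
        raise ValueError(
            f"λ vector has {lam.size} substituents, model has {model.n_sub}"
        )
    e = model.baseline_energy(conf)
    e += float(lam @ model.scaled_substituent_energies(conf))
    if model.has_cross:
        for (y, c), (z, d) in model.sub_pairs():
            i, j = model._sub_index[(y, c)], model._sub_index[(z, d)]
            w = lam[i] * lam[j]
            if w != 0.0:
                e += w * model.cross_energy(y, c, z, d, conf.sub(y, c), conf.sub(z, d))
    return float(e)


def total_gradient(conf: Configuration, v: LambdaVector, model: PotentialModel) -> np.ndarray:
    """Gradient of :func:`total_potential`; forces are its negative."""
    return model.gradient_flat(conf.flat, v.as_array())


class StateEnergyEvaluator:
    """Precomputed evaluator for the M-vector of λ-state energies.

    Caches the (M × n_sub) weight matrix and cross-pair weight products so the
    per-step cost during sampling is one vectorized substituent-energy call
    plus a matrix–vector product.  By default the λ-independent environment
    and restraint terms are omitted uniformly: they cancel in the conditional
    λ distribution and in all relative free energies.
    """

    def __init__(self, graph: LambdaStateGraph, model: PotentialModel, include_env: bool = False):
        if graph.weight_matrix().shape[1] != model.n_sub:
            raise ValueError("graph and model disagree on substituent layout")
        self.graph = graph
        self.model = model
        self.include_env = include_env
        self.W = graph.weight_matrix()
        self._cross_pairs = []
        if model.has_cross:
            for (y, c), (z, d) in model.sub_pairs():
                i, j = model._sub_index[(y, c)], model._sub_index[(z, d)]
                self._cross_pairs.append(((y, c, z, d), i, j, self.W[:, i] * self.W[:, j]))

    def __call__(self, conf: Configuration) -> np.ndarray:
        u = self.W @ self.model.scaled_substituent_energies(conf)
        for (y, c, z, d), i, j, w in self._cross_pairs:
            u = u + w * self.model.cross_energy(y, c, z, d, conf.sub(y, c), conf.sub(z, d))
        if self.include_env:
            u = u + self.model.baseline_energy(conf)
        return u


def state_energy_vector(
    conf: Configuration,
    graph: LambdaStateGraph,
    model: PotentialModel,
    include_env: bool = False,
) -> np.ndarray:
    """Potential energy of ``conf`` at every λ state of ``graph``."""
    return StateEnergyEvaluator(graph, model, include_env=include_env)(conf)


# ---------------------------------------------------------------------------
# Gaussian-ligand toy model


class GaussianLigandModel(PotentialModel):
    """Harmonic-well "ligands": substituent c at site y is a particle whose
    fully coupled potential is ½ k_{y,c} |x − x̂_{y,c}|².

    Each coordinate always carries the λ-independent restraint
    ½ k_r |x − x̂|²; the λ-scaled internal term is the difference
    ½ (k − k_r)|x − x̂|², so that at coupling λ the coordinate feels a
    harmonic well of stiffness (1−λ) k_r + λ k.  End-state free energies then
    have the closed form G_c = (d/2)·kT·ln k_c + const, i.e. relative free
    energies are ΔG = (d/2)·kT·ln(k_c / k_ref) — purely entropic, independent
    of the well centers.

    Optional terms: a harmonic environment coordinate (½ k_env |x0|²), a
    coupling spring ½ κ |x0 − x|² between environment and each substituent,
    and a cross-site spring ½ κ_x |x_a − x_b|².  With any of these switched on
    the model stays quadratic, so exact free energies remain available through
    the Hessian-determinant route used by :meth:`analytic_dG`.
    """

    def __init__(
        self,
        spring_constants: Sequence[Sequence[float]],
        offsets: Sequence[Sequence[np.ndarray]] | None = None,
        restraint_k: float = 1.0,
        env_spring: float = 1.0,
        x0_dim: int = 1,
        sub_dim: int = 1,
        coupling: float | None = None,
        cross_spring: float | None = None,
    ):
        springs = [list(map(float, site)) for site in spring_constants]
        if any(k <= 0 for site in springs for k in site):
            raise ValueError("all spring constants must be > 0")
        if restraint_k <= 0:
            raise ValueError("restraint_k must be > 0")
        sub_dims = [[sub_dim] * len(site) for site in springs]
        super().__init__(x0_dim=x0_dim, sub_dims=sub_dims)
        self.springs = springs
        self.restraint_k = float(restraint_k)
        self.env_spring = float(env_spring)
        self.coupling = None if coupling is None else float(coupling)
        self.cross_spring = None if cross_spring is None else float(cross_spring)
        self.sub_dim = int(sub_dim)
        if offsets is None:
            offsets = [[np.zeros(sub_dim) for _ in site] for site in springs]
        self.offsets = [
            [np.asarray(o, dtype=float).reshape(sub_dim) for o in site] for site in offsets
        ]
        # flattened per-dof parameter arrays for the vectorized fast paths
        self._k_flat = np.repeat([k for site in springs for k in site], sub_dim)
        self._c_flat = np.concatenate(
            [o for site in self.offsets for o in site]
        ) if self.n_sub else np.zeros(0)
        self._kr_flat = np.full(self.n_sub * sub_dim, self.restraint_k)

    # -- decomposition terms --------------------------------------------

    def env_energy(self, x0):
        return 0.5 * self.env_spring * float(x0 @ x0)

    def env_grad(self, x0):
        return self.env_spring * x0

    def internal_energy(self, y, c, x):
        d = x - self.offsets[y][c]
        return 0.5 * (self.springs[y][c] - self.restraint_k) * float(d @ d)

    def internal_grad(self, y, c, x):
        return (self.springs[y][c] - self.restraint_k) * (x - self.offsets[y][c])

    def restraint_energy(self, y, c, x):
        d = x - self.offsets[y][c]
        return 0.5 * self.restraint_k * float(d @ d)

    def restraint_grad(self, y, c, x):
        return self.restraint_k * (x - self.offsets[y][c])

    def coupled_energy(self, y, c, x0, x):
        if self.coupling is None:
            return 0.0
        d = x0 - x
        return 0.5 * self.coupling * float(d @ d)

    def coupled_grads(self, y, c, x0, x):
        if self.coupling is None:
            return np.zeros_like(x0), np.zeros_like(x)
        d = x0 - x
        return self.coupling * d, -self.coupling * d

    def cross_energy(self, y, c, z, d, xa, xb):
        if self.cross_spring is None:
            return 0.0
        r = xa - xb
        return 0.5 * self.cross_spring * float(r @ r)

    def cross_grads(self, y, c, z, d, xa, xb):
        if self.cross_spring is None:
            return np.zeros_like(xa), np.zeros_like(xb)
        r = xa - xb
        return self.cross_spring * r, -self.cross_spring * r

    @property
    def has_cross(self) -> bool:
        return self.cross_spring is not None

    # -- fast paths ------------------------------------------------------

    def scaled_substituent_energies(self, conf):
        xs = conf.flat[self.x0_dim :]
        d = xs - self._c_flat
        per_dof = 0.5 * (self._k_flat - self._kr_flat) * d * d
        e = per_dof.reshape(self.n_sub, self.sub_dim).sum(axis=1)
        if self.coupling is not None:
            x0 = conf.x0
            dc = x0[None, :] - xs.reshape(self.n_sub, self.sub_dim)
            e = e + 0.5 * self.coupling * (dc * dc).sum(axis=1)
        return e

    def gradient_flat(self, flat, lam):
        lam_dof = np.repeat(lam, self.sub_dim)
        xs = flat[self.x0_dim :]
        d = xs - self._c_flat
        g_sub = (self._kr_flat + lam_dof * (self._k_flat - self._kr_flat)) * d
        g0 = self.env_spring * flat[: self.x0_dim]
        if self.coupling is not None:
            x0 = flat[: self.x0_dim]
            dc = x0[None, :] - xs.reshape(self.n_sub, self.sub_dim)
            w = lam[:, None] * self.coupling * dc
            g0 = g0 + w.sum(axis=0)
            g_sub = g_sub - w.reshape(-1)
        if self.has_cross:
            # generic path covers the rare cross-spring case
            return PotentialModel.gradient_flat(self, flat, lam)
        return np.concatenate([g0, g_sub])

    def linear_force_coeffs(self, lam):
        if self.coupling is not None or self.cross_spring is not None:
            return None
        lam_dof = np.repeat(lam, self.sub_dim)
        K = np.concatenate(
            [
                np.full(self.x0_dim, self.env_spring),
                self._kr_flat + lam_dof * (self._k_flat - self._kr_flat),
            ]
        )
        center = np.concatenate([np.zeros(self.x0_dim), self._c_flat])
        return K, center

    def initial_configuration(self):
        conf = Configuration(self)
        for (y, c), i in self._sub_index.items():
            lo, hi = self._sub_slices[i]
            conf.flat[lo:hi] = self.offsets[y][c]
        return conf

    # -- analytic oracle -------------------------------------------------

    def analytic_dG(self, graph: LambdaStateGraph, kT: float):
        """Exact end-state free energies relative to the graph reference.

        Without coupling/cross springs the coordinates separate and
        G_end = Σ_y (d/2)·kT·ln k_{y,c_y} up to an end-state-independent
        constant.  With quadratic couplings the Hessian-determinant route
        (still exact for quadratic models) is used instead.
        """
        if self.coupling is not None or self.cross_spring is not None:
            return quadratic_end_state_dG(self, graph, kT)
        ids, G = [], []
        for lig, idx in graph.end_state_indices.items():
            combo = (lig,) if isinstance(lig, int) else tuple(lig)
            g = sum(
                0.5 * self.sub_dim * kT * np.log(self.springs[y][c])
                for y, c in enumerate(combo)
            )
            ids.append((lig, idx))
            G.append(g)
        G = np.array(G)
        ref = [i for i, (_, idx) in enumerate(ids) if idx == graph.reference_index][0]
        dG = G - G[ref]
        return [lig for lig, _ in ids], dG, np.zeros_like(dG)


def quadratic_end_state_dG(model: PotentialModel, graph: LambdaStateGraph, kT: float):
    """Free energies of end states for any quadratic model.

    G = U_min + (kT/2)·ln det H, with H the Hessian at the minimum, up to a
    constant shared by all end states of equal dimensionality.  The Hessian is
    assembled by central differences of the analytic gradient, which is exact
    (to rounding) for quadratic potentials.
    """
    ids, G = [], []
    for lig, idx in graph.end_state_indices.items():
        v = graph.states[idx]
        lam = v.as_array()
        res = optimize.minimize(
            lambda x: float(
                total_potential(Configuration(model, x), v, model)
            ),
            model.initial_configuration().flat,
            jac=lambda x: model.gradient_flat(x, lam),
            method="BFGS",
            options={"gtol": 1e-12},
        )
        x_min = res.x
        n = model.n_dof
        H = np.empty((n, n))
        h = 1e-4
        for i in range(n):
            xp, xm = x_min.copy(), x_min.copy()
            xp[i] += h
            xm[i] -= h
            H[i] = (model.gradient_flat(xp, lam) - model.gradient_flat(xm, lam)) / (2 * h)
        H = 0.5 * (H + H.T)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            raise UnsupportedOracleError("non-positive-definite Hessian at end state")
        ids.append((lig, idx))
        G.append(res.fun + 0.5 * kT * logdet)
    G = np.array(G)
    ref = [i for i, (_, idx) in enumerate(ids) if idx == graph.reference_index][0]
    dG = G - G[ref]
    return [lig for lig, _ in ids], dG, np.full_like(dG, 1e-9)


# ---------------------------------------------------------------------------
# double-well toy model


class DoubleWellModel(PotentialModel):
    """Quartic double wells: one alchemical site, 1-D substituent coordinates.

    Substituent c fully coupled feels U_c(x) = h_c ((x/a_c)² − 1)² + δ_c·x,
    a symmetric double well of barrier h_c with minima near ±a_c, tilted by
    δ_c.  The λ-independent restraint is ½ k_r x²; the λ-scaled internal term
    is U_c − restraint.  Free energies are obtained by 1-D quadrature, making
    this the toy analog of slow conformational (ring-flip / dihedral) degrees
    of freedom.
    """

    def __init__(
        self,
        barriers: Sequence[float],
        separations: Sequence[float],
        tilts: Sequence[float] | None = None,
        restraint_k: float = 1.0,
    ):
        barriers = list(map(float, barriers))
        separations = list(map(float, separations))
        if len(barriers) != len(separations):
            raise ValueError("need one separation per barrier")
        if any(h < 0 for h in barriers):
            raise ValueError("barriers must be ≥ 0")
        if any(a <= 0 for a in separations):
            raise ValueError("separations must be > 0")
        if restraint_k <= 0:
            raise ValueError("restraint_k must be > 0")
        if tilts is None:
            tilts = [0.0] * len(barriers)
        super().__init__(x0_dim=0, sub_dims=[[1] * len(barriers)])
        self.barriers = barriers
        self.separations = separations
        self.tilts = list(map(float, tilts))
        self.restraint_k = float(restraint_k)

    def well_potential(self, c: int, x):
        a, h, t = self.separations[c], self.barriers[c], self.tilts[c]
        u = (x / a) ** 2 - 1.0
        return h * u * u + t * x

    def _well_grad(self, c: int, x):
        a, h, t = self.separations[c], self.barriers[c], self.tilts[c]
        return h * 4.0 * x * ((x / a) ** 2 - 1.0) / a**2 + t

    def internal_energy(self, y, c, x):
        return float(self.well_potential(c, x[0]) - 0.5 * self.restraint_k * x[0] ** 2)

    def internal_grad(self, y, c, x):
        return np.array([self._well_grad(c, x[0]) - self.restraint_k * x[0]])

    def restraint_energy(self, y, c, x):
        return 0.5 * self.restraint_k * float(x[0] ** 2)

    def restraint_grad(self, y, c, x):
        return self.restraint_k * x

    # fast paths

    def scaled_substituent_energies(self, conf):
        xs = conf.flat
        a = np.asarray(self.separations)
        h = np.asarray(self.barriers)
        t = np.asarray(self.tilts)
        u = (xs / a) ** 2 - 1.0
        return h * u * u + t * xs - 0.5 * self.restraint_k * xs * xs

    def gradient_flat(self, flat, lam):
        a = np.asarray(self.separations)
        h = np.asarray(self.barriers)
        t = np.asarray(self.tilts)
        well = 4.0 * h * flat * ((flat / a) ** 2 - 1.0) / a**2 + t
        restr = self.restraint_k * flat
        return restr + lam * (well - restr)

    def initial_configuration(self):
        conf = Configuration(self)
        conf.flat[:] = np.asarray(self.separations)  # start in the +a well
        return conf

    def analytic_dG(self, graph: LambdaStateGraph, kT: float):
        """End-state free energies by adaptive 1-D quadrature.

        Restraint-only coordinates contribute identically to every end state
        and cancel; only each end state's own well integral matters.
        """
        ids, G, E = [], [], []
        for lig, idx in graph.end_state_indices.items():
            c = lig if isinstance(lig, int) else lig[0]
            span = 8.0 * max(self.separations[c], np.sqrt(kT / self.restraint_k))
            val, err = integrate.quad(
                lambda x: np.exp(-self.well_potential(c, x) / kT), -span, span, limit=200
            )
            ids.append((lig, idx))
            G.append(-kT * np.log(val))
            E.append(kT * err / val)
        G = np.array(G)
        ref = [i for i, (_, idx) in enumerate(ids) if idx == graph.reference_index][0]
        return [lig for lig, _ in ids], G - G[ref], np.asarray(E)

    def well_populations(self, c: int, kT: float) -> tuple[float, float]:
        """Equilibrium probability of the (−a, +a) wells of substituent c."""
        span = 8.0 * self.separations[c]
        left, _ = integrate.quad(lambda x: np.exp(-self.well_potential(c, x) / kT), -span, 0)
        right, _ = integrate.quad(lambda x: np.exp(-self.well_potential(c, x) / kT), 0, span)
        z = left + right
        return left / z, right / z


# ---------------------------------------------------------------------------
# factories, oracle dispatch and registry


def make_gaussian_ligand_model(
    spring_constants: Sequence[float] | Sequence[Sequence[float]],
    offsets=None,
    coupling: float | None = None,
    **kwargs,
) -> GaussianLigandModel:
    """Build a harmonic-well ligand model; flat input means one site."""
    if len(spring_constants) and np.ndim(spring_constants[0]) == 0:
        spring_constants = [list(spring_constants)]
        if offsets is not None:
            offsets = [list(offsets)]
    return GaussianLigandModel(spring_constants, offsets=offsets, coupling=coupling, **kwargs)


def make_double_well_model(
    barrier: float | Sequence[float],
    separation: float | Sequence[float],
    tilts=None,
    n_substituents: int | None = None,
    **kwargs,
) -> DoubleWellModel:
    """Build a quartic double-well model (scalars broadcast to all substituents)."""
    if np.isscalar(barrier):
        n = n_substituents or (len(tilts) if tilts is not None else 2)
        barrier = [barrier] * n
    if np.isscalar(separation):
        separation = [separation] * len(barrier)
    return DoubleWellModel(barrier, separation, tilts=tilts, **kwargs)


def analytic_end_state_dG(model: PotentialModel, graph: LambdaStateGraph, kT: float):
    """Ground-truth ΔG of every end state relative to the graph reference.

    Returns (ligand ids, ΔG vector, error estimates).  Supported for models
    exposing an ``analytic_dG`` method (closed form or quadrature); other
    models raise :class:`UnsupportedOracleError`.
    """
    fn = getattr(model, "analytic_dG", None)
    if fn is None:
        raise UnsupportedOracleError(
            f"{type(model).__name__} provides no analytic free-energy oracle"
        )
    return fn(graph, kT)


MODEL_REGISTRY: dict[str, Callable[..., PotentialModel]] = {
    "gaussian_ligands": make_gaussian_ligand_model,
    "double_well": make_double_well_model,
}


def register_model(name: str, factory: Callable[..., PotentialModel]) -> None:
    """Register a user model factory for use in run configurations."""
    MODEL_REGISTRY[name] = factory


def build_model(name: str, params: dict) -> PotentialModel:
    if name not in MODEL_REGISTRY:
        raise KeyError(f"unknown model {name!r}; registered: {sorted(MODEL_REGISTRY)}")
    return MODEL_REGISTRY[name](**params)
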