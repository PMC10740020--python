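"""Discrete λ-state graphs for multi-ligand alchemical sampling.

A λ state assigns each substituent ``c`` at each site ``y`` a coupling weight
``λ_{y,c} ∈ [0, 1]``; within every site the weights sum to exactly 1 so that
one "ligand's worth" of interaction is present at all times.  End states put
weight 1 on a single substituent per site (a physical ligand).  Pairs of end
states are joined by edges of intermediate states on a uniform grid with
spacing ``Δλ``, which yields a strongly connected graph over which the
expanded-ensemble sampler can hop between all ligands in one run.

Weights are stored as exact :class:`fractions.Fraction` values on the
``1/Δλ`` grid, so state identity and the per-site sum-to-one invariant are
exact rather than floating-point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations, product
from typing import Sequence

import numpy as np

__all__ = [
    "LambdaVector",
    "LambdaStateGraph",
    "InvalidGridError",
    "count_states",
    "build_single_site_graph",
    "build_multisite_graph",
    "validate_state",
]


class InvalidGridError(ValueError):
    """Raised when Δλ is not the reciprocal of an integer ≥ 2."""


def _grid_divisions(delta_lambda: float | Fraction) -> int:
    """Return m = 1/Δλ, validating that Δλ is a reciprocal integer."""
    if isinstance(delta_lambda, Fraction):
        if delta_lambda.numerator != 1:
            raise InvalidGridError(f"Δλ={delta_lambda} is not 1/m for integer m")
        m = delta_lambda.denominator
    else:
        if not (0.0 < float(delta_lambda) < 1.0):
            raise InvalidGridError(f"Δλ={delta_lambda} outside (0, 1)")
        m = round(1.0 / float(delta_lambda))
        if abs(m * float(delta_lambda) - 1.0) > 1e-9:
            raise InvalidGridError(f"1/Δλ={1.0 / delta_lambda} is not an integer")
    if m < 2:
        raise InvalidGridError("Δλ must be ≤ 0.5 (at least one grid division)")
    return m


@dataclass(frozen=True)
class LambdaVector:
    """One discrete λ state: per-site tuples of exact substituent weights."""

    weights: tuple[tuple[Fraction, ...], ...]

    @property
    def site_count(self) -> int:
        return len(self.weights)

    @property
    def substituent_counts(self) -> tuple[int, ...]:
        return tuple(len(site) for site in self.weights)

    def as_array(self) -> np.ndarray:
        """Flatten to a float array in (site, substituent) order."""
        return np.array([float(w) for site in self.weights for w in site])

    def __iter__(self):
        return iter(self.weights)


def validate_state(v: LambdaVector) -> tuple[bool, list[str]]:
    """Check the λ-state invariants; returns (ok, list of violations).

    Invariants: every weight in [0, 1]; weights at each site sum to exactly 1
    (so no more than one ligand's interactions are fully present); at most two
    substituents per site carry nonzero weight (the edge representation).
    """
    violations: list[str] = []
    for y, site in enumerate(v.weights):
        for c, w in enumerate(site):
            if not (0 <= w <= 1):
                violations.append(f"site {y} substituent {c}: weight {w} outside [0, 1]")
        total = sum(site, Fraction(0))
        if total != 1:
            violations.append(f"site {y}: weights sum to {total}, expected 1")
        nonzero = sum(1 for w in site if w != 0)
        if nonzero > 2:
            violations.append(f"site {y}: {nonzero} substituents active, at most 2 allowed")
    return (not violations, violations)


@dataclass
class LambdaStateGraph:
    """Ordered collection of λ states with end-state/edge bookkeeping.

    ``edges`` maps each unordered end-state pair to the ordered indices of its
    intermediate states (increasing coupling of the second end state of the
    pair).  ``end_state_indices`` maps a ligand id — an int for single-site
    layouts, a tuple of per-site substituent indices for multisite — to the
    index of its end state in ``states``.
    """

    states: list[LambdaVector]
    end_state_indices: dict
    edges: list[tuple[tuple[int, int], list[int]]]
    delta_lambda: Fraction
    reference_index: int = 0
    substituent_counts: tuple[int, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def weight_matrix(self) -> np.ndarray:
        """(M, total substituents) float matrix of λ weights, flattened (y, c)."""
        return np.array([s.as_array() for s in self.states])

    def adjacency(self) -> list[tuple[int, int]]:
        """Undirected adjacency along edge chains (consecutive grid neighbours)."""
        pairs: list[tuple[int, int]] = []
        for (a, b), inter in self.edges:
            chain = [a, *inter, b]
            pairs.extend(zip(chain[:-1], chain[1:]))
        return pairs

    # -- serialization --------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "delta_lambda": [self.delta_lambda.numerator, self.delta_lambda.denominator],
            "sites": list(self.substituent_counts),
            "states": [
                [[w.numerator, w.denominator] for site in s.weights for w in site]
                for s in self.states
            ],
            "end_state_indices": {str(k): v for k, v in self.end_state_indices.items()},
            "edges": [[list(pair), inter] for pair, inter in self.edges],
            "reference_index": self.reference_index,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "LambdaStateGraph":
        payload = json.loads(text)
        counts = tuple(payload["sites"])
        states = []
        for flat in payload["states"]:
            fracs = [Fraction(n, d) for n, d in flat]
            sites, pos = [], 0
            for n in counts:
                sites.append(tuple(fracs[pos : pos + n]))
                pos += n
            states.append(LambdaVector(tuple(sites)))
        end_idx = {}
        for key, v in payload["end_state_indices"].items():
            try:
                end_idx[int(key)] = v
            except ValueError:
                end_idx[tuple(json.loads(key.replace("(", "[").replace(")", "]")))] = v
        return cls(
            states=states,
            end_state_indices=end_idx,
            edges=[((int(p[0]), int(p[1])), list(i)) for p, i in payload["edges"]],
            delta_lambda=Fraction(*payload["delta_lambda"]),
            reference_index=payload["reference_index"],
            substituent_counts=counts,
        )


def count_states(n_ligands: int, delta_lambda: float | Fraction) -> int:
    """Closed-form number of λ states for a single-site, all-pairs layout.

    N_λ = N_s + N_s(N_s − 1)/2 · (1/Δλ − 1): one end state per ligand plus
    (1/Δλ − 1) intermediates on each of the N_s(N_s−1)/2 connective edges.
    """
    m = _grid_divisions(delta_lambda)
    if n_ligands < 1:
        raise ValueError(f"n_ligands must be ≥ 1, got {n_ligands}")
    return n_ligands + n_ligands * (n_ligands - 1) // 2 * (m - 1)


def build_single_site_graph(
    n_ligands: int, delta_lambda: float | Fraction, reference_ligand: int = 0
) -> LambdaStateGraph:
    """Enumerate the strongly connected λ-state graph for one alchemical site.

    Canonical ordering: end states first (ligand order), then edges in
    lexicographic pair order with intermediates in increasing weight of the
    higher-indexed ligand.  The reference state λ¹ defaults to ligand 0's end
    state.
    """
    m = _grid_divisions(delta_lambda)
    if n_ligands < 1:
        raise ValueError(f"n_ligands must be ≥ 1, got {n_ligands}")

    def vec(weights: Sequence[Fraction]) -> LambdaVector:
        return LambdaVector((tuple(weights),))

    zero = Fraction(0)
    states: list[LambdaVector] = []
    for i in range(n_ligands):
        w = [zero] * n_ligands
        w[i] = Fraction(1)
        states.append(vec(w))
    end_idx = {i: i for i in range(n_ligands)}

    edges = []
    for i, j in combinations(range(n_ligands), 2):
        inter: list[int] = []
        for k in range(1, m):
            w = [zero] * n_ligands
            w[j] = Fraction(k, m)
            w[i] = 1 - w[j]
            inter.append(len(states))
            states.append(vec(w))
        edges.append(((i, j), inter))

    graph = LambdaStateGraph(
        states=states,
        end_state_indices=end_idx,
        edges=edges,
        delta_lambda=Fraction(1, m),
        reference_index=end_idx[reference_ligand],
        substituent_counts=(n_ligands,),
    )
    assert len(graph) == count_states(n_ligands, delta_lambda)
    return graph


def build_multisite_graph(
    substituent_counts_per_site: Sequence[int],
    delta_lambda: float | Fraction,
    reference_ligand: tuple[int, ...] | None = None,
) -> LambdaStateGraph:
    """λ-state graph over full-ligand end states for several alchemical sites.

    End states are the Cartesian combinations of one substituent per site.
    Every unordered pair of end states is joined by an edge whose
    intermediates interpolate linearly and *simultaneously* at every site
    where the pair differs, on the shared Δλ grid.  Intermediates that
    coincide (e.g. the shared midpoint of the two diagonal edges of a 2×2
    layout) are stored once and referenced by both edges, keeping states
    distinct while preserving strong connectivity.
    """
    counts = tuple(int(n) for n in substituent_counts_per_site)
    if len(counts) == 0:
        raise ValueError("need at least one site")
    if any(n < 1 for n in counts):
        raise ValueError(f"every site needs ≥ 1 substituent, got {counts}")
    m = _grid_divisions(delta_lambda)

    zero, one = Fraction(0), Fraction(1)

    def end_vec(combo: tuple[int, ...]) -> LambdaVector:
        sites = []
        for y, n in enumerate(counts):
            w = [zero] * n
            w[combo[y]] = one
            sites.append(tuple(w))
        return LambdaVector(tuple(sites))

    combos = list(product(*(range(n) for n in counts)))
    states: list[LambdaVector] = []
    index_of: dict[tuple, int] = {}

    def intern(v: LambdaVector) -> int:
        key = v.weights
        if key not in index_of:
            index_of[key] = len(states)
            states.append(v)
        return index_of[key]

    end_idx = {combo: intern(end_vec(combo)) for combo in combos}

    edges = []
    for ca, cb in combinations(combos, 2):
        inter: list[int] = []
        for k in range(1, m):
            t = Fraction(k, m)
            sites = []
            for y, n in enumerate(counts):
                w = [zero] * n
                if ca[y] == cb[y]:
                    w[ca[y]] = one
                else:
                    w[ca[y]] = 1 - t
                    w[cb[y]] = t
                sites.append(tuple(w))
            inter.append(intern(LambdaVector(tuple(sites))))
        edges.append(((end_idx[ca], end_idx[cb]), inter))

    if reference_ligand is None:
        reference_ligand = combos[0]
    return LambdaStateGraph(
        states=states,
        end_state_indices=end_idx,
        edges=edges,
        delta_lambda=Fraction(1, m),
        reference_index=end_idx[tuple(reference_ligand)],
        substituent_counts=counts,
    )
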