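"""Sampling-quality diagnostics for expanded-ensemble ledgers.

Three views of how smoothly the sampler moved through λ space: the running
spread between the most- and least-visited states (flat-histogram quality),
the distribution of hop distances between consecutively visited states, and
the energy-distribution overlap of grid-adjacent states (which controls how
far hops can reach).
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .lambda_states import LambdaStateGraph
from .sampler import SampleLedger

__all__ = [
    "count_gap_timeseries",
    "transition_distance_stats",
    "overlap_histograms",
]


def _visited_of(ledger) -> np.ndarray:
    if isinstance(ledger, SampleLedger):
        return np.asarray(ledger.visited)
    return np.asarray(ledger)


def count_gap_timeseries(ledger, n_states: int | None = None):
    """Running max−min visit-count gap after each Gibbs step.

    Returns (steps, gap series, time average).  A flat-histogram bias keeps
    the gap at a few counts even as per-state counts grow into the hundreds.
    """
    visited = _visited_of(ledger)
    if visited.size == 0:
        raise ValueError("empty ledger")
    if n_states is None:
        n_states = (
            ledger.n_states if isinstance(ledger, SampleLedger) else int(visited.max()) + 1
        )
    counts = np.zeros(n_states, dtype=np.int64)
    gaps = np.empty(len(visited), dtype=np.int64)
    for t, s in enumerate(visited):
        counts[s] += 1
        gaps[t] = counts.max() - counts.min()
    steps = np.arange(1, len(visited) + 1)
    return steps, gaps, float(gaps.mean())


def transition_distance_stats(ledger, graph: LambdaStateGraph):
    """Histogram of graph-path distances between consecutive visited states.

    Distance is the shortest-path length over the grid adjacency (consecutive
    states along connective edges are neighbours).  Returns a dict with the
    raw distances, a normalized histogram over 0..max distance, and the mean.
    """
    visited = _visited_of(ledger)
    if visited.size == 0:
        raise ValueError("empty ledger")
    G = nx.Graph()
    G.add_nodes_from(range(len(graph)))
    G.add_edges_from(graph.adjacency())
    dist = dict(nx.all_pairs_shortest_path_length(G))
    d = np.array(
        [dist[int(a)][int(b)] for a, b in zip(visited[:-1], visited[1:])], dtype=np.int64
    ) if len(visited) > 1 else np.zeros(0, dtype=np.int64)
    if d.size:
        hist = np.bincount(d)
        probs = hist / hist.sum()
        mean = float(d.mean())
    else:
        probs = np.array([1.0])
        mean = 0.0
    return {"distances": d, "probabilities": probs, "mean": mean}


def overlap_histograms(ledger, graph: LambdaStateGraph, bins: int = 40, low_overlap: float = 0.01):
    """Per-adjacent-pair energy distributions and their overlap.

    For each grid-adjacent state pair (i, j), the own-state energies of the
    configurations generated at i and at j are histogrammed on a common grid;
    the overlap coefficient is Σ min(p_i, p_j) of the normalized histograms.
    Pairs with overlap below ``low_overlap`` (or with no samples on a side)
    are flagged — they starve MBAR of information and signal that Δλ is too
    coarse for the energy gap.
    """
    if not isinstance(ledger, SampleLedger):
        raise TypeError("overlap_histograms needs a SampleLedger with energies")
    if len(ledger) == 0:
        raise ValueError("empty ledger")
    visited = ledger.visited
    out: dict[tuple[int, int], dict] = {}
    flagged: list[tuple[int, int]] = []
    for i, j in sorted(set(tuple(sorted(p)) for p in graph.adjacency())):
        ei = ledger.energies[visited == i, i]
        ej = ledger.energies[visited == j, j]
        if ei.size == 0 or ej.size == 0:
            out[(i, j)] = {"overlap": np.nan, "n_i": ei.size, "n_j": ej.size}
            flagged.append((i, j))
            continue
        lo = min(ei.min(), ej.min())
        hi = max(ei.max(), ej.max())
        if hi <= lo:
            hi = lo + 1e-12
        edges = np.linspace(lo, hi, bins + 1)
        pi = np.histogram(ei, bins=edges)[0] / ei.size
        pj = np.histogram(ej, bins=edges)[0] / ej.size
        ov = float(np.minimum(pi, pj).sum())
        out[(i, j)] = {
            "hist_i": pi,
            "hist_j": pj,
            "bin_edges": edges,
            "overlap": ov,
            "n_i": ei.size,
            "n_j": ej.size,
        }
        if ov < low_overlap:
            flagged.append((i, j))
    return {"pairs": out, "low_overlap_pairs": flagged}
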