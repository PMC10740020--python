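"""Build λ-state graphs and count their states.

A group of N ligands sharing one alchemical site is connected by an edge of
intermediate λ states between every ligand pair, giving a strongly connected
graph the sampler can traverse in a single run.  The closed-form count is
N + N(N−1)/2 · (1/Δλ − 1).
"""

import networkx as nx

from ladybugs import build_multisite_graph, build_single_site_graph, count_states

for n in (2, 5, 6, 7):
    graph = build_single_site_graph(n, 0.1)
    assert len(graph) == count_states(n, 0.1)
    G = nx.Graph(graph.adjacency())
    print(
        f"{n} ligands at Δλ=0.1: {len(graph):3d} λ states, "
        f"{len(graph.edges):2d} edges, connected={nx.is_connected(G)}"
    )

ms = build_multisite_graph([2, 2], 0.1)
print(f"2 sites × 2 substituents: {len(ms)} states, {len(ms.end_state_indices)} end states")
print("Each end state is a physical ligand; every other state is a mixing")
print("intermediate on the Δλ grid with per-site weights summing to 1.")
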