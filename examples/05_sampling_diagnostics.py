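"""Sampling-smoothness diagnostics on a 6-ligand, 141-state benchmark.

The count gap (max − min per-state visits) measures flat-histogram quality:
the exponential count penalty keeps it at a few counts even as every state
accumulates hundreds of visits.  Transition distances show how far the
sampler hops per Gibbs step; energy-distribution overlap of adjacent states
is what makes longer hops possible.
"""

from ladybugs import (
    count_gap_timeseries,
    make_benchmark_suite,
    overlap_histograms,
    run_ladybugs,
    transition_distance_stats,
)

config = make_benchmark_suite(seed=3)[1]  # 6 ligands, 141 states
config.schedule.total_gibbs_steps = 5000
config.schedule.replicates = 1
result = run_ladybugs(config)

ledger = result.ledgers[0]
graph = result.diagnostics["graph"]

_, gaps, avg = count_gap_timeseries(ledger)
print(f"visit-count gap: time-average {avg:.2f}, final {gaps[-1]}, max {gaps.max()}")
print(f"per-state visits: mean {ledger.state_counts().mean():.1f}, min {ledger.state_counts().min()}")

stats = transition_distance_stats(ledger, graph)
print(f"mean hop distance between consecutive λ states: {stats['mean']:.2f}")
print(f"hop-distance distribution (first 5): {stats['probabilities'][:5].round(3)}")

out = overlap_histograms(ledger, graph)
vals = [d["overlap"] for d in out["pairs"].values() if "hist_i" in d]
print(f"adjacent-state energy overlap: mean {sum(vals)/len(vals):.2f} over {len(vals)} pairs")
print(f"pairs flagged for near-zero overlap: {len(out['low_overlap_pairs'])}")
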