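"""Is a gene pair unusually close in a weighted functional network?

Generates a 200-node background network with a planted high-weight module
containing the two seed genes, then tests every node's average shortest-path
distance to the seeds against a degree- and weight-preserving randomization
null (1000 simulations in batches of 200).
"""

from coseg.netnull import bh_adjust, null_pvalues, results_frame, significant_nodes
from coseg.synthetic import simulate_network

graph, labels = simulate_network(n_nodes=200, planted_module_size=8, seed=0)
seeds = ["EHHADH", "MASP1"]
module = sorted(n for n, v in labels.items() if v)

result = null_pvalues(graph, seeds, n_sim=1000, batch_size=200, rng_seed=17)
frame = results_frame(result).sort_values("p_raw")

print(f"network: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges")
print(f"planted module: {module}")
print()
print("top 10 nodes by raw empirical p-value:")
print(frame.head(10).to_string(index=False, float_format=lambda v: f"{v:.4f}"))

called = significant_nodes(result, alpha=0.01)
print()
print(f"nodes called significant (raw p < 0.01): {sorted(called)}")
print("planted module recovered:", set(module) <= set(called) | set(seeds))
print()
print("Edge length is 1/weight, so strong functional associations are short;")
print("the null rewires topology (degree-preserving double-edge swaps) and")
print("permutes the weight multiset, so proximity must come from structure.")
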