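"""Node importance in a directed gene network, plus overlap enrichment.

Builds a reproducible 20-node toy network shaped like an inferred
CEI regulatory network (20% end-nodes), computes outdegree weights and the
ASPL/end-node-scaled impact score, and runs the hypergeometric overlap test
with the CEI differential-expression set sizes.
"""

from rootniche import (
    end_node_proportion,
    hypergeometric_enrichment,
    node_impact,
)
from rootniche.synthetic import generate_toy_network

network = generate_toy_network(20, 0.12, seed=5, n_end_nodes=4)
print(f"nodes: {len(network)}, edges: {network.graph.number_of_edges()}, "
      f"end-node proportion R = {end_node_proportion(network):.2f}")

table = node_impact(network)
print("\ntop 5 nodes by impact (ASPL-scaled outgoing + R-scaled incoming "
      "neighbour weights):")
print(table.head(5).to_string(index=False,
      formatters={"weight": "{:.2f}".format, "impact": "{:.2f}".format}))
print("High-impact nodes are hubs whose perturbation propagates farthest "
      "through the network — the candidates to test experimentally first.")

result = hypergeometric_enrichment(163, 213, 46, 27020)
print(f"\noverlap enrichment: 46 shared genes between sets of 163 and 213 "
      f"against a background of 27020")
print(f"  fold enrichment = {result.fold:.1f}, p = {result.p_value:.3e} "
      "(upper-tail hypergeometric)")
print("A fold of ~36 at vanishing p shows the two differential-expression "
      "sets share far more genes than chance allows.")
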