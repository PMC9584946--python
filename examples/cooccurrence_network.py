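"""Spearman co-occurrence network and hub taxa.

Builds the co-occurrence graph on relative abundances (|rho| > 0.5,
p < 0.01), then looks for hub OTUs in the joint upper tail of degree and
betweenness centrality.
"""

import coremicro as cm
from coremicro.network import edge_table

spec = cm.SyntheticSpec(
    n_studies=8, samples_per_study=(20, 20), n_otus=120, n_core=18,
    n_subcore=3, seed=3,
)
table, meta, taxonomy, tree, truth = cm.generate_dataset(spec)

relab = cm.rra(table, depth=5000, seed=0)
net = cm.build_network(relab, rho_min=0.5, p_max=0.01)
edges = edge_table(net)
n_pos = (edges["sign"] == "positive").sum()
print(f"network: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges "
      f"({n_pos} positive / {len(edges) - n_pos} negative)")

hubs = cm.detect_hubs(net, quantile=0.95)
cent = cm.centralities(net)
print(f"hub OTUs (joint 95th percentile of degree and betweenness): {hubs}")
if hubs:
    print(cent.loc[hubs].round(1).to_string())
print("-> hubs are the few taxa that both connect many partners and bridge")
print("   otherwise separate parts of the co-occurrence graph.")
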