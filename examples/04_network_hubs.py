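"""Co-occurrence networks, modules and Zi/Pi hub classification.

Edges are significant positive Spearman correlations (rho > 0.6,
BH-FDR q < 0.05).  Modules come from greedy modularity maximization;
nodes are classified by within-module degree z-score (Zi) and
participation coefficient (Pi): module hubs (Zi > 2.5), connectors
(Pi > 0.62), network hubs (both), else peripherals.
"""

import pandas as pd

from droughtnet import correlations, io_prep, networks, synth

data = synth.generate_counts(
    synth.DesignSpec(compartments=("rhizosphere",)), synth.EffectSpec(),
    n_bacteria=60, n_fungi=40, seed=4,
)
bact = io_prep.rarefy(data.bacteria, 10_000, seed=0)
fung = io_prep.rarefy(data.fungi, 10_000, seed=1)
combined = pd.concat([bact, fung], axis=1)
win, wmeta = io_prep.split_windows(combined, data.metadata)["drought"]
kingdoms = data.taxonomy["kingdom"]

nets = {}
for treatment in ("control", "drought"):
    table = io_prep.filter_occurrence(win.loc[wmeta.treatment == treatment], 8)
    recs = correlations.partition_link_classes(
        correlations.spearman_records(table), kingdoms
    )
    nets[treatment] = networks.build_network(recs, data.taxonomy)
    stats = networks.size_stats(nets[treatment])
    print(f"{treatment:8s} {stats['n_vertices']} vertices, "
          f"{stats['n_edges']} edges {stats['edges_per_class']}")

cmp_df = networks.compare_networks(nets["control"], nets["drought"])
print("\ndrought vs control (per link class):")
print(cmp_df.to_string(index=False))
# 'disrupted' = fewer edges under drought, 'enhanced' = more.

net = nets["drought"]
if net.number_of_edges():
    partition, q = networks.greedy_modules(net)
    print(f"\ndrought network modularity Q = {q:.3f}, "
          f"{len(set(partition.values()))} modules")
    topo = networks.classify_roles(networks.zi_pi(net, partition))
    roles = topo["role"].value_counts().to_dict()
    print(f"roles: {roles}")
    amf_f, amf_b, amf_amf = networks.amf_subnetwork(net)
    print(f"AMF-fungus edges: {amf_f.number_of_edges()}, "
          f"AMF-bacterium edges: {amf_b.number_of_edges()}, "
          f"AMF-AMF (excluded): {amf_amf}")
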