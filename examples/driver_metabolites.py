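"""Detect and classify driver metabolites in a small reaction model.

Builds the 7-node network from three toy reactions plus a 4-node star,
samples randomized maximum matchings, and prints each node's driver
frequency f_d: the fraction of distinct minimum driver-metabolite sets
(MDMSs) the node appears in.  f_d = 1 marks critical drivers (inputs
must always attach there), 0.6 <= f_d < 1 high-frequency drivers.
"""

from netctrl import (
    FIG1_REACTIONS,
    build_network,
    driver_frequency,
    fixture_gallery,
    parse_reactions,
    sample_mdms,
)

net = build_network(parse_reactions(FIG1_REACTIONS))
print(f"toy model: {net.n_nodes} metabolites, {net.n_links} links")
sample = sample_mdms(net, n_samples=500, seed=42)
print(f"distinct MDMSs found: {len(sample)}, each of size {len(sample[0])}")
table = driver_frequency(sample, nodes=net.nodes)
for node, row in table.as_frame().sort_values("f_d", ascending=False).iterrows():
    print(f"  {node:12s} f_d={row.f_d:5.3f}  {row['class']}")

# the star shows a non-trivial frequency spectrum: the hub is critical,
# each leaf appears in 2 of the 3 possible driver sets
star = fixture_gallery()["star4"]
freq = driver_frequency(sample_mdms(star, 500, seed=0), nodes=star.nodes)
print("\nstar h -> l1, l2, l3:")
for node, row in freq.as_frame().iterrows():
    print(f"  {node:3s} f_d={row.f_d:5.3f}  {row['class']}")
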