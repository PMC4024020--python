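"""Profile a driver set against centrality tertiles.

Computes degree, betweenness and (harmonic) closeness centralities on a
synthetic model, splits the nodes into low/medium/high tertiles per
centrality, and reports where the driver metabolites fall.  Driver sets
skewed toward low in-degree / high out-closeness indicate nodes that
influence others but are hard to influence.
"""

from netctrl import (
    SyntheticModelSpec,
    build_network,
    chi_square,
    compute_centralities,
    driver_frequency,
    fraction_profile,
    generate_reactions,
    sample_mdms,
    tertile_split,
)
from netctrl.centrality import CENTRALITY_COLUMNS

net = build_network(generate_reactions(SyntheticModelSpec(
    n_metabolites=150, n_reactions=220, fraction_boundary=0.05,
    fraction_transport=0.25, seed=11,
)))
cent = compute_centralities(net)
families = {c: tertile_split(cent[c].to_dict()) for c in CENTRALITY_COLUMNS}

sample = sample_mdms(net, 300, seed=5)
freq = driver_frequency(sample, nodes=net.nodes)
set_a = sorted({n for s in sample for n in s})  # union of sampled driver sets
print(f"set A (union of {len(sample)} driver sets): {len(set_a)} of {net.n_nodes} nodes")

prof = fraction_profile(set_a, families)
print("\nfraction of set A per centrality tertile (low/medium/high):")
print(prof[["frac_low", "frac_medium", "frac_high"]].round(3).to_string())

fam = families["InD"]
expected = [len(s) / net.n_nodes for s in fam.sets()]
observed = [int(prof.loc["InD", f"count_{b}"]) for b in ("low", "medium", "high")]
res = chi_square(observed, expected)
print(f"\nin-degree tertile test: chi2={res.statistic:.2f} "
      f"(critical {res.critical_value:.2f}), significant={res.significant}")
print("drivers concentrating in the low in-degree tertile is the expected "
      "signature: inputs attach to nodes other metabolites cannot reach")
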