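"""Score perturbation sets for connectedness (CTD) in a fixed network.

A patient whose perturbed metabolites form a clique compresses well under
the network-adaptive code and gets a small p-value; scattered perturbations
compress no better than chance and score near 1.
"""

import itertools

from ctdnet import CoPerturbationNetwork, ctd_pvalue

ids = [f"met{i:02d}" for i in range(32)]
net = CoPerturbationNetwork(ids)
for a, b in itertools.combinations(ids[:5], 2):   # a tight disease module
    net.add_edge(a, b, 0.8)
for a, b in zip(ids[5:], ids[6:]):                # weak background chain
    net.add_edge(a, b, 0.3)
net.add_edge(ids[4], ids[5], 0.2)

clustered = set(ids[:5])
scattered = {ids[6], ids[12], ids[18], ids[24], ids[30]}

for name, s in (("clustered", clustered), ("scattered", scattered)):
    res = ctd_pvalue(net, s)
    print(f"{name} set: {sorted(s)}")
    print(f"  encoding {res.encoding_bits:.2f} bits vs fixed "
          f"{res.fixed_bits:.2f} bits -> {res.bits_saved:.2f} bits saved")
    print(f"  optimal subset: {sorted(res.optimal_subset)}")
    print(f"  p = {res.p_value:.4g}")
# The clustered set saves ~10 bits (p ~ 1e-3); the scattered set saves
# nothing and is indistinguishable from a random draw (p = 1).
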