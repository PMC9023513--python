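"""Learn a disease-specific co-perturbation network from a synthetic cohort.

Pipeline: presence filter -> minimum-z imputation -> graphical lasso with
StARS penalty selection on pooled disease+control and on controls alone ->
partial-correlation weights -> differential pruning.  The pruned network
should concentrate on the planted module's clique.
"""

import itertools

from ctdnet import CohortSpec, NetworkConfig, learn_disease_network, make_cohort

spec = CohortSpec(seed=7)
matrix, metadata = make_cohort(spec)
dis = matrix.select_samples([m.sample_id for m in metadata
                             if m.role == "disease"])
ref = matrix.select_samples([m.sample_id for m in metadata
                             if m.role == "reference"])

net = learn_disease_network(dis, ref, NetworkConfig(seed=7),
                            disease_label="demo_disease")

planted = {tuple(sorted(p))
           for p in itertools.combinations(spec.resolved_module(), 2)}
found = set(net.edges())
recovered = planted & found

print(f"selected lambda (pooled): {net.provenance['lambda_selected']:.3f}")
print(f"selected lambda (control): {net.provenance['lambda_control']:.3f}")
print(f"edges after differential pruning: {net.n_edges()}")
print(f"planted module edges recovered: {len(recovered)}/{len(planted)} "
      f"(recall {len(recovered) / len(planted):.2f})")
print(f"edge precision: {len(recovered) / len(found):.2f}")
strongest = sorted(net.edges().items(), key=lambda kv: -abs(kv[1]))[:5]
print("strongest edges (partial correlation):")
for (a, b), w in strongest:
    print(f"  {a} -- {b}   {w:+.3f}")
# Most of the module clique is recovered: the latent factor makes all 15
# within-module pairs conditionally dependent.  StARS drops the weakest
# pairs, and min-z imputation of randomly missing cells adds a few
# spurious edges -- the recall/precision trade-off of the learner.
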