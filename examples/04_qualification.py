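"""Direction-of-change qualification against a (synthetic) expression table.

Predicts each node's direction of change under a perturbation (here the
proteasome-inhibition condition), generates a probe-level differential-
expression table that agrees with the predictions except for a 20% discordance
rate, collapses probes to genes, and scores directional agreement.
"""

from neuroqsp import (
    collapse_probes,
    direction_agreement,
    generate_de_table,
    predict_node_directions,
    toy_cipn_network,
)

network = toy_cipn_network()
calls = predict_node_directions(network, {"Proteasome": 0})
print(f"{len(calls)} directional calls, e.g.:")
for call in calls[:4]:
    print(f"  {call.node:10s} {call.call} (final activity {call.final:.2f})")

table, truth = generate_de_table(calls, discordance=0.2, seed=11)
genes = collapse_probes(table, mode="min_adj_p")
report = direction_agreement(calls, genes, truth["node_gene_map"])
print(f"agreement: {report['n_agree']}/{report['n_total']} "
      f"({report['fraction']:.0%})")
print(f"(the generator flipped {len(truth['flipped_genes'])} gene(s); every")
print("unflipped gene agrees, so the fraction reflects the discordance rate)")
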