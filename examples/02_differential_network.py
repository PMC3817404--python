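"""Call synthetic sick/lethal interactions and assemble the DiE network.

Scores the query and parental screens, computes dGARP = zGARP(query) −
zGARP(parental) with a joint-permutation p-value, applies the expression
presence filter, and assembles the differential-essentiality network.
"""

from dienet import differential as diff
from dienet import scoring, simulate

cfg = simulate.ScreenSimConfig(n_genes=200, seed=1, n_queries=1)
screen = simulate.generate_screen(cfg)
expression, _ = simulate.generate_expression(cfg, screen.truth)

normalized = scoring.normalize_counts(screen.counts)
sharp_q = scoring.compute_sharp(normalized, "query1")
sharp_p = scoring.compute_sharp(normalized, "parental")
zq = scoring.compute_zgarp(scoring.compute_garp(sharp_q, screen.hairpin_map))
zp = scoring.compute_zgarp(scoring.compute_garp(sharp_p, screen.hairpin_map))

dgarp = diff.compute_dgarp(zq, zp)
pvals = diff.dgarp_pvalues(sharp_q, sharp_p, screen.hairpin_map, B=200, seed=2)
presence = diff.expression_presence(expression)
records = diff.call_ssl(
    dgarp, pvals.loc[dgarp.index], presence.loc[dgarp.index, "query1"],
    "query1", alpha=0.05,
)

network = diff.assemble_network(records)
print(f"DiE network: {network.n_nodes} nodes, {network.n_edges} edges "
      "(query + genes called SSL at dGARP<0, p<0.05, expressed in query)")

truth = set(screen.truth.ssl_genes("query1"))
called = set(network.edges["gene"])
print(f"planted SSL genes recovered: {len(called & truth)}/{len(truth)}; "
      f"false calls: {len(called - truth)}")

module = diff.propagate_module(network, "query1")
print(f"functional module around query1: {module.number_of_nodes()} nodes, "
      f"{module.number_of_edges()} edges (star of DiE edges; external "
      "genetic/physical evidence edges would densify it)")
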