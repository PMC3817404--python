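"""Predict conserved genetic interactions from model-organism networks.

Builds a most-probable ortholog map from orthologous-group and similarity
tables (keeping near-best in-group matches, discarding weak paralogs), then
projects model-organism negative interactions onto human SSL edges.
"""

import pandas as pd

from dienet import conservation as cons
from dienet import simulate

planted = [("query1", f"g{i:03d}") for i in range(8)]
cfg = simulate.OrthologySimConfig(conserved_pairs=planted, seed=4)
groups, sims, gi = simulate.generate_orthology(cfg)
print(f"orthology fixture: {groups['group'].nunique()} groups, "
      f"{len(sims)} similarity rows, {len(gi)} model-organism edges")

omap_all = cons.build_ortholog_map(groups, sims, mode="group_all")
omap = cons.build_ortholog_map(groups, sims, mode="most_probable", f=0.9)
print(f"ortholog pairs: {len(omap_all)} by group co-membership, "
      f"{len(omap)} after the most-probable filter "
      "(score ≥ 0.9 × best per human gene and organism)")

ssl = pd.DataFrame({"query": [q for q, _ in planted],
                    "gene": [g for _, g in planted], "ssl_call": True})
predictions, report = cons.project_interactions(ssl, omap, gi)
nonred = cons.deduplicate_conserved(predictions)
print(f"conserved predictions: {report['n_predictions']} evidence rows → "
      f"{len(nonred)} non-redundant (query, gene) pairs; "
      f"{report['n_model_edges_unmapped']} model edges ignored (no mapped ortholog)")
print("each prediction means: the human SSL pair has orthologs with a "
      "negative interaction in a model organism.")
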