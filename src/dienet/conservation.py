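"""Cross-species projection of genetic interactions via orthologous groups.

Human genes are mapped to model-organism genes through shared orthologous
groups. Because group co-membership alone overestimates orthology (groups
mix orthologs and paralogs), a *most-probable* filter keeps, per (human
gene, organism), only the model genes whose similarity score is at least a
fraction ``f`` of the best score for that human gene in that organism —
less stringent than bidirectional-best mapping (which drops established
functional orthologs) but resistant to paralog inflation. Ties at the best
similarity are all retained.

A human SSL edge (query, gene) is predicted *conserved* when some organism
carries a negative genetic-interaction edge between mapped orthologs of
the two human genes.
"""

from __future__ import annotations

import pandas as pd

from .errors import AnalysisError, ConfigError, IntegrityError
from .differential import DiENetwork

__all__ = [
    "build_ortholog_map",
    "project_interactions",
    "deduplicate_conserved",
    "merge_confidence",
]

HUMAN = "human"

MAP_COLUMNS = [
    "human_gene", "organism", "model_gene", "group", "score", "is_most_probable",
]


def build_ortholog_map(
    groups: pd.DataFrame,
    similarities: pd.DataFrame | None = None,
    mode: str = "most_probable",
    f: float = 0.9,
) -> pd.DataFrame:
    """Build the human → model-organism ortholog map from group tables.

    ``groups`` has columns (group, organism, gene); rows with organism
    ``human`` are the human side. ``similarities`` (human_gene, organism,
    model_gene, score) must only score pairs that share a group; pairs
    without a similarity row score 0. ``mode="group_all"`` returns every
    within-group cross-species pair; ``mode="most_probable"`` keeps, per
    (human gene, organism), pairs with score ≥ f × best score (ties all
    retained). The returned map always carries the ``is_most_probable``
    flag; in most_probable mode only flagged rows are returned.
    """
    if mode not in ("group_all", "most_probable"):
        raise ConfigError(f"unknown orthology mode {mode!r}")
    if not 0 < f <= 1:
        raise ConfigError("f must be in (0, 1]")
    humans = groups.loc[groups["organism"] == HUMAN, ["group", "gene"]].rename(
        columns={"gene": "human_gene"}
    )
    models = groups.loc[groups["organism"] != HUMAN].rename(
        columns={"gene": "model_gene"}
    )
    pairs = humans.merge(models, on="group")
    if pairs.empty:
        return pd.DataFrame(columns=MAP_COLUMNS)

    if similarities is not None and not similarities.empty:
        keyed = pairs.merge(
            similarities, on=["human_gene", "organism", "model_gene"], how="left"
        )
        unmatched = similarities.merge(
            pairs, on=["human_gene", "organism", "model_gene"], how="left",
            indicator=True,
        )
        orphan = unmatched["_merge"] == "left_only"
        if orphan.any():
            row = unmatched.loc[orphan].iloc[0]
            raise IntegrityError(
                "similarity row for pair not sharing a group: "
                f"({row['human_gene']}, {row['model_gene']})"
            )
        pairs = keyed
        pairs["score"] = pairs["score"].fillna(0.0)
    else:
        pairs["score"] = 0.0

    best = pairs.groupby(["human_gene", "organism"])["score"].transform("max")
    pairs["is_most_probable"] = pairs["score"] >= f * best
    out = pairs[MAP_COLUMNS].sort_values(
        ["human_gene", "organism", "model_gene"], kind="stable"
    ).reset_index(drop=True)
    if out.duplicated(subset=["human_gene", "organism", "model_gene"]).any():
        dup = out.loc[
            out.duplicated(subset=["human_gene", "organism", "model_gene"])
        ].iloc[0]
        raise IntegrityError(
            f"duplicate ortholog pair ({dup['human_gene']}, {dup['model_gene']})"
        )
    if mode == "most_probable":
        out = out.loc[out["is_most_probable"]].reset_index(drop=True)
    return out


def project_interactions(
    ssl_records: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    model_gi: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Project model-organism negative interactions onto human SSL edges.

    A human SSL edge (query, gene) is predicted conserved iff some
    organism has mapped orthologs q′ of the query and g′ of the gene with
    a negative edge (q′, g′) in ``model_gi`` (columns organism, geneA,
    geneB, sign; edges are unordered). Returns all supporting evidence
    rows plus a report counting negative model edges that reference no
    mapped gene.
    """
    ssl = ssl_records.loc[
        ssl_records["ssl_call"] if "ssl_call" in ssl_records else slice(None),
        ["query", "gene"],
    ].drop_duplicates()
    negative = model_gi.loc[model_gi["sign"] == "negative"].reset_index()
    negative = negative.rename(columns={"index": "evidence_id"})
    mapped_genes = {
        (o, m)
        for o, m in zip(ortholog_map["organism"], ortholog_map["model_gene"])
    }
    unmapped = sum(
        (row.organism, row.geneA) not in mapped_genes
        and (row.organism, row.geneB) not in mapped_genes
        for row in negative.itertuples(index=False)
    )
    # unordered edges: consider both orientations
    both = pd.concat(
        [
            negative.rename(columns={"geneA": "model_q", "geneB": "model_g"}),
            negative.rename(columns={"geneB": "model_q", "geneA": "model_g"}),
        ],
        ignore_index=True,
    )
    qmap = ortholog_map.rename(
        columns={"human_gene": "query", "model_gene": "model_q"}
    )[["query", "organism", "model_q"]]
    gmap = ortholog_map.rename(
        columns={"human_gene": "gene", "model_gene": "model_g"}
    )[["gene", "organism", "model_g"]]
    hits = (
        ssl.merge(qmap, on="query")
        .merge(gmap, on=["gene", "organism"])
        .merge(both, on=["organism", "model_q", "model_g"])
    )
    predictions = hits[
        ["query", "gene", "organism", "model_q", "model_g", "evidence_id"]
    ].drop_duplicates().sort_values(
        ["query", "gene", "organism", "model_q", "model_g"], kind="stable"
    ).reset_index(drop=True)
    report = {
        "n_model_edges_negative": len(negative),
        "n_model_edges_unmapped": int(unmapped),
        "n_predictions": len(predictions),
    }
    return predictions, report


def deduplicate_conserved(predictions: pd.DataFrame) -> pd.DataFrame:
    """Collapse predictions to non-redundant (query, human gene) pairs.

    Evidence rows are aggregated per pair as counts and joined organism
    lists.
    """
    if predictions.empty:
        return pd.DataFrame(columns=["query", "gene", "n_evidence", "organisms"])
    grouped = predictions.groupby(["query", "gene"], sort=True)
    out = grouped.agg(
        n_evidence=("evidence_id", "size"),
        organisms=("organism", lambda s: ",".join(sorted(set(s)))),
    ).reset_index()
    return out


def merge_confidence(
    network: DiENetwork, confirmed: set, conserved: set
) -> DiENetwork:
    """High-confidence subnetwork of confirmed and/or conserved edges.

    ``confirmed`` and ``conserved`` are sets of (query, gene) pairs; each
    must reference an edge of the network. Flags are set on the retained
    edges.
    """
    edge_keys = set(zip(network.edges["query"], network.edges["gene"]))
    for name, s in (("confirmed", confirmed), ("conserved", conserved)):
        stray = set(s) - edge_keys
        if stray:
            raise IntegrityError(f"{name} pair {sorted(stray)[0]} is not a network edge")
    edges = network.edges.copy()
    keys = list(zip(edges["query"], edges["gene"]))
    edges["confirmed"] = [k in confirmed for k in keys]
    edges["conserved"] = [k in conserved for k in keys]
    keep = edges["confirmed"] | edges["conserved"]
    return DiENetwork(edges=edges.loc[keep].reset_index(drop=True))
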