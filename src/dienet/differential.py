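"""Differential essentiality (dGARP) calls and DiE network assembly.

A negative genetic interaction (synthetic sick/lethal, SSL) between a
query mutation and a gene is called when the gene is differentially
essential in the query line: dGARP = zGARP(query) − zGARP(parental) is
negative, its permutation p-value beats alpha (strict), and the gene's
mRNA is present in the query line (a gene must be expressed to be knocked
down where the differential phenotype is scored).

The dGARP null permutes the hairpin→gene assignment identically in both
screens, preserving each gene's hairpin count and the hairpin pairing
across screens so that hairpin-specific efficacy and shared hairpin
artifacts cancel under the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigError, IntegrityError
from .scoring import _garp_from_segments, _gene_layout

__all__ = [
    "compute_dgarp",
    "dgarp_pvalues",
    "expression_presence",
    "call_ssl",
    "select_confirmation_candidates",
    "DiENetwork",
    "assemble_network",
    "propagate_module",
    "essentiality_vs_expression",
]

RECORD_COLUMNS = ["query", "gene", "dgarp", "p", "expressed_in_query", "ssl_call"]


def compute_dgarp(zgarp_query: pd.Series, zgarp_parent: pd.Series) -> pd.Series:
    """dGARP per gene: zGARP(query) − zGARP(parental).

    Genes present in only one screen are omitted with a warning; an empty
    intersection is an error.
    """
    common = zgarp_query.index.intersection(zgarp_parent.index)
    if len(common) == 0:
        raise AnalysisError("query and parental screens share no genes")
    dropped = (len(zgarp_query) - len(common)) + (len(zgarp_parent) - len(common))
    if dropped:
        warnings.warn(f"{dropped} gene(s) present in only one screen omitted")
    return (zgarp_query.loc[common] - zgarp_parent.loc[common]).rename("dgarp")


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise AnalysisError("zero spread; z-scores undefined")
    return (values - values.mean()) / sd


def dgarp_pvalues(
    sharp_query: pd.DataFrame | pd.Series,
    sharp_parent: pd.DataFrame | pd.Series,
    hairpin_map: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Left-tail empirical dGARP p-values from joint hairpin permutations.

    One shared permutation of the hairpin→gene labels is applied to both
    screens; GARP → zGARP → dGARP is recomputed ``B`` times and each
    gene's observed dGARP is compared to the pooled null of genes with
    the same hairpin count (add-one rule).
    """
    if B < 100:
        raise ConfigError("B must be ≥ 100 for a usable permutation null")
    sq = sharp_query["sharp"] if isinstance(sharp_query, pd.DataFrame) else sharp_query
    sp = sharp_parent["sharp"] if isinstance(sharp_parent, pd.DataFrame) else sharp_parent
    common = sq.index.intersection(sp.index)
    if len(common) == 0:
        raise AnalysisError("screens share no scored hairpins")

    genes, vq, starts, sizes = _gene_layout(sq.loc[common], hairpin_map)
    genes_p, vp, starts_p, _ = _gene_layout(sp.loc[common], hairpin_map)
    assert np.array_equal(genes, genes_p) and np.array_equal(starts, starts_p)

    def dgarp_of(q_vals: np.ndarray, p_vals: np.ndarray) -> np.ndarray:
        zq = _zscore(_garp_from_segments(q_vals, starts, sizes))
        zp = _zscore(_garp_from_segments(p_vals, starts, sizes))
        return zq - zp

    obs = dgarp_of(vq, vp)
    rng = np.random.default_rng(seed)
    pools: dict[int, list] = {int(k): [] for k in np.unique(sizes)}
    n = len(vq)
    for _ in range(B):
        perm = rng.permutation(n)
        null = dgarp_of(vq[perm], vp[perm])
        for k in pools:
            pools[k].append(null[sizes == k])
    p = np.empty(len(genes))
    for k, chunks in pools.items():
        pool = np.sort(np.concatenate(chunks))
        mask = sizes == k
        count = np.searchsorted(pool, obs[mask], side="right")
        p[mask] = (1.0 + count) / (len(pool) + 1.0)
    return pd.Series(p, index=pd.Index(genes, name="gene"), name="p")


def expression_presence(
    expression: pd.DataFrame, method: str = "mixture"
) -> pd.DataFrame:
    """Call genes present/absent per line from log2 expression values.

    ``method="mixture"`` fits a two-component Gaussian mixture per line
    and calls a gene present when the posterior probability of the high
    component is ≥ 0.5. A degenerate (effectively unimodal) fit falls
    back, with a warning, to ``quantile:40`` — present iff the value is
    at or above the line's 40th percentile. ``method="quantile:q"``
    applies the percentile rule directly.
    """
    presence = pd.DataFrame(index=expression.index, columns=expression.columns,
                            dtype=bool)
    for line in expression.columns:
        values = expression[line].to_numpy(dtype=float)
        presence[line] = _presence_one_line(values, method, line)
    return presence


def _presence_one_line(values: np.ndarray, method: str, line) -> np.ndarray:
    if method.startswith("quantile:"):
        q = float(method.split(":", 1)[1])
        if not 0 <= q <= 100:
            raise ConfigError("quantile must be in [0, 100]")
        return values >= np.percentile(values, q)
    if method != "mixture":
        raise ConfigError(f"unknown presence method {method!r}")
    from sklearn.mixture import GaussianMixture

    fallback = "quantile:40"
    if len(np.unique(values)) < 2:
        warnings.warn(f"line {line!r}: degenerate expression; quantile fallback")
        return _presence_one_line(values, fallback, line)
    try:
        gm = GaussianMixture(n_components=2, n_init=2, random_state=0)
        gm.fit(values.reshape(-1, 1))
    except Exception:  # singular fits on pathological inputs
        warnings.warn(f"line {line!r}: mixture fit failed; quantile fallback")
        return _presence_one_line(values, fallback, line)
    means = gm.means_.ravel()
    if abs(means[0] - means[1]) < 1.0:  # modes < 1 log2 apart: not bimodal
        warnings.warn(f"line {line!r}: unimodal expression; quantile fallback")
        return _presence_one_line(values, fallback, line)
    hi = int(np.argmax(means))
    post = gm.predict_proba(values.reshape(-1, 1))[:, hi]
    return post >= 0.5


def call_ssl(
    dgarp: pd.Series,
    p: pd.Series,
    expressed_in_query: pd.Series,
    query: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assemble per-gene differential-essentiality records for one query.

    ``ssl_call`` is true iff dGARP < 0, p < alpha (strict) and the gene
    is expressed in the query line. All three inputs must cover the same
    gene ids.
    """
    idx = dgarp.index
    if set(idx) != set(p.index) or set(idx) != set(expressed_in_query.index):
        raise IntegrityError("dgarp, p and presence tables cover different genes")
    p = p.loc[idx]
    expressed = expressed_in_query.loc[idx].astype(bool)
    records = pd.DataFrame(
        {
            "query": query,
            "gene": idx,
            "dgarp": dgarp.to_numpy(dtype=float),
            "p": p.to_numpy(dtype=float),
            "expressed_in_query": expressed.to_numpy(),
        }
    )
    records["ssl_call"] = (
        (records["dgarp"] < 0) & (records["p"] < alpha) & records["expressed_in_query"]
    )
    return records.reset_index(drop=True)


def select_confirmation_candidates(
    records: pd.DataFrame,
    garp_p: pd.Series,
    sharp_p: pd.Series,
    hairpin_map: pd.DataFrame,
    log2fc: pd.Series | None = None,
    has_ortholog: pd.Series | None = None,
    garp_alpha: float = 0.05,
    sharp_alpha: float = 0.01,
) -> pd.DataFrame:
    """Select SSL calls worth testing in the secondary competition assay.

    A candidate is an SSL-called gene whose query-screen GARP p-value
    beats ``garp_alpha`` and which carries ≥1 hairpin with shARP p below
    ``sharp_alpha``; differential expression magnitude and ortholog
    availability are annotations, not filters. Deterministic ordering:
    dGARP ascending, then gene id.
    """
    ssl = records.loc[records["ssl_call"]].copy()
    if ssl.empty:
        return ssl.assign(log2fc=[], has_ortholog=[])
    mapping = hairpin_map.set_index("hairpin")["gene"]
    best_sharp_p = (
        sharp_p.groupby(mapping.reindex(sharp_p.index)).min().rename("best_sharp_p")
    )
    keep = (
        ssl["gene"].map(garp_p).lt(garp_alpha)
        & ssl["gene"].map(best_sharp_p).lt(sharp_alpha)
    )
    out = ssl.loc[keep].copy()
    out["log2fc"] = (
        out["gene"].map(log2fc).to_numpy() if log2fc is not None else np.nan
    )
    out["has_ortholog"] = (
        out["gene"].map(has_ortholog).fillna(False).to_numpy()
        if has_ortholog is not None
        else False
    )
    return out.sort_values(["dgarp", "gene"], kind="stable").reset_index(drop=True)


@dataclass
class DiENetwork:
    """Bipartite-plus network of differential essentiality edges.

    ``edges`` has one row per (query, gene) SSL call with its dGARP,
    p-value and confirmed/conserved flags. Nodes are the queries plus all
    genes with at least one edge.
    """

    edges: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["query", "gene", "dgarp", "p", "confirmed", "conserved"]
        )
    )

    @property
    def queries(self) -> set:
        return set(self.edges["query"])

    @property
    def genes(self) -> set:
        return set(self.edges["gene"])

    @property
    def n_nodes(self) -> int:
        return len(self.queries) + len(self.genes - self.queries)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.queries, kind="query")
        g.add_nodes_from(self.genes - self.queries, kind="gene")
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.query, row.gene, dgarp=row.dgarp, p=row.p,
                       confirmed=bool(row.confirmed), conserved=bool(row.conserved))
        return g


def assemble_network(records: pd.DataFrame | list[pd.DataFrame]) -> DiENetwork:
    """Assemble the DiE network from SSL-called records across queries.

    Duplicate (query, gene) records are an integrity error; edges start
    with confirmed/conserved flags false.
    """
    if isinstance(records, list):
        records = (
            pd.concat(records, ignore_index=True)
            if records
            else pd.DataFrame(columns=RECORD_COLUMNS)
        )
    ssl = records.loc[records.get("ssl_call", pd.Series(dtype=bool))].copy()
    if ssl.duplicated(subset=["query", "gene"]).any():
        dup = ssl.loc[ssl.duplicated(subset=["query", "gene"]), ["query", "gene"]]
        raise IntegrityError(f"duplicate SSL record {tuple(dup.iloc[0])}")
    edges = ssl[["query", "gene", "dgarp", "p"]].reset_index(drop=True)
    edges["confirmed"] = False
    edges["conserved"] = False
    return DiENetwork(edges=edges)


def propagate_module(
    network: DiENetwork, query: str, external: pd.DataFrame | None = None
) -> nx.MultiGraph:
    """Induce the functional module around one query.

    The module contains the query, its DiE neighbors and the DiE edges
    between them, plus every external evidence edge (columns geneA,
    geneB, source) whose both endpoints lie in that node set. Evidence
    source labels are preserved verbatim on the edges.
    """
    if query not in network.queries:
        raise AnalysisError(f"query {query!r} has no edges in the network")
    sub = network.edges.loc[network.edges["query"] == query]
    nodes = {query} | set(sub["gene"])
    g = nx.MultiGraph()
    g.add_nodes_from(nodes)
    for row in sub.itertuples(index=False):
        g.add_edge(row.query, row.gene, source="DiE", dgarp=row.dgarp)
    if external is not None:
        for row in external.itertuples(index=False):
            if row.geneA in nodes and row.geneB in nodes:
                g.add_edge(row.geneA, row.geneB, source=row.source)
    return g


def essentiality_vs_expression(
    records: pd.DataFrame, log2fc: pd.Series, fc_cut: float = 1.0
) -> pd.DataFrame:
    """Joint differential-essentiality / differential-expression table.

    Per gene: dGARP, log2 fold-change (query vs parental transcript
    level) and a category — ``both`` (SSL call and log2FC ≥ cut),
    ``ssl_only``, ``up_in_query_only`` or ``neither``.
    """
    out = records[["query", "gene", "dgarp", "ssl_call"]].copy()
    out["log2fc"] = out["gene"].map(log2fc)
    up = out["log2fc"] >= fc_cut
    ssl = out["ssl_call"]
    out["category"] = np.select(
        [ssl & up, ssl & ~up, ~ssl & up],
        ["both", "ssl_only", "up_in_query_only"],
        default="neither",
    )
    return out.drop(columns="ssl_call")
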