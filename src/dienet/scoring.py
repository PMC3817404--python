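"""Hairpin and gene essentiality scoring for one pooled shRNA screen.

A screen here is one cell line measured in replicate over several
timepoints. The scores:

* **shARP** — per hairpin, the least-squares slope of log2 relative
  abundance against day, fit jointly across all replicate × timepoint
  observations of the screen (units: log2/day; negative = dropout).
* **GARP** — per gene, the mean shARP of its two most-depleting hairpins
  (a single scored hairpin is used as-is and flagged ``n_hairpins=1``).
* **zGARP** — GARP standardized across all genes of the screen
  (sample sd, ddof=1).

Significance is empirical: the null GARP distribution is built by
permuting the hairpin→gene assignment (preserving each gene's hairpin
count), pooled across genes with the same hairpin count, with the add-one
rule, left tail.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigError

__all__ = [
    "normalize_counts",
    "compute_sharp",
    "compute_garp",
    "compute_zgarp",
    "garp_pvalues",
    "sharp_pvalues",
    "replicate_correlation",
    "score_screen",
]


def normalize_counts(
    counts: pd.DataFrame, pseudocount: float = 0.5, per_million: bool = True
) -> pd.DataFrame:
    """Convert read counts to log2 relative abundance.

    Each sample (column) is scaled to reads-per-million and transformed
    as ``log2(RPM + pseudocount)``, removing sequencing-depth differences
    between samples. ``per_million=False`` skips the per-sample rescaling
    for inputs already on a common absolute scale (e.g. noiseless
    simulated clone abundances, where forcing every sample to a fixed
    total would inject the pool-composition drift into every slope).
    """
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be > 0")
    values = counts.to_numpy(dtype=float)
    if per_million:
        totals = values.sum(axis=0)
        if (totals <= 0).any():
            col = counts.columns[int(np.argmax(totals <= 0))]
            raise AnalysisError(f"all-zero sample column {col}")
        values = values / totals * 1e6
    return pd.DataFrame(
        np.log2(values + pseudocount), index=counts.index, columns=counts.columns
    )


def _line_columns(matrix: pd.DataFrame, line: str) -> pd.DataFrame:
    if "line" not in (matrix.columns.names or []):
        raise ConfigError("matrix columns must carry a (line, replicate, day) index")
    sub = matrix.loc[:, matrix.columns.get_level_values("line") == line]
    if sub.shape[1] == 0:
        raise ConfigError(f"no samples for line {line!r}")
    return sub


def compute_sharp(
    normalized: pd.DataFrame,
    line: str,
    counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit per-hairpin dropout slopes (shARP) for one screen.

    All replicate × timepoint observations of ``line`` enter a single
    least-squares regression of log2 relative abundance on day. When the
    raw ``counts`` are supplied, hairpins with zero reads in every sample
    of the line are excluded with a warning (their trend is undefined).

    Returns a DataFrame indexed by hairpin with columns ``sharp``,
    ``n_obs`` and ``rss``.
    """
    sub = _line_columns(normalized, line)
    days = sub.columns.get_level_values("day").to_numpy(dtype=float)
    if len(np.unique(days)) < 2:
        raise AnalysisError(f"line {line!r} has <2 distinct timepoints")

    y = sub.to_numpy(dtype=float)
    keep = np.ones(y.shape[0], dtype=bool)
    if counts is not None:
        raw = _line_columns(counts, line).reindex(sub.index)
        keep = raw.to_numpy(dtype=float).sum(axis=1) > 0
        if not keep.all():
            warnings.warn(
                f"{(~keep).sum()} hairpin(s) with zero reads across line "
                f"{line!r} excluded from shARP"
            )
    y = y[keep]
    xc = days - days.mean()
    sxx = float(xc @ xc)
    slope = (y @ xc) / sxx
    resid = y - y.mean(axis=1, keepdims=True) - np.outer(slope, xc)
    rss = np.einsum("ij,ij->i", resid, resid)
    return pd.DataFrame(
        {"sharp": slope, "n_obs": y.shape[1], "rss": rss},
        index=sub.index[keep],
    )


def _gene_layout(sharp: pd.Series, hairpin_map: pd.DataFrame):
    """Align shARP values into contiguous per-gene segments.

    Returns (genes, values, starts, sizes) with hairpins of each gene
    occupying one contiguous block of ``values`` (stable hairpin-id order
    within a gene, giving a deterministic tie-break for the top two).
    """
    mapping = hairpin_map.set_index("hairpin")["gene"]
    scored = sharp.index.intersection(mapping.index)
    if len(scored) == 0:
        raise AnalysisError("no scored hairpin appears in the hairpin map")
    mapped = pd.DataFrame(
        {"gene": mapping.loc[scored].to_numpy(), "sharp": sharp.loc[scored].to_numpy()},
        index=pd.Index(scored, name="hairpin"),
    ).sort_values(["gene", "hairpin"], kind="stable")
    genes, starts = np.unique(mapped["gene"].to_numpy(), return_index=True)
    values = mapped["sharp"].to_numpy()
    sizes = np.diff(np.append(starts, len(values)))
    return genes, values, starts, sizes


def _garp_from_segments(values: np.ndarray, starts: np.ndarray,
                        sizes: np.ndarray) -> np.ndarray:
    """GARP per segment: mean of the two smallest values (one if size 1)."""
    gene_idx = np.repeat(np.arange(len(starts)), sizes)
    order = np.lexsort((values, gene_idx))
    sv = values[order]
    first = sv[starts]
    garp = first.copy()
    multi = sizes >= 2
    garp[multi] = (first[multi] + sv[starts[multi] + 1]) / 2.0
    return garp


def compute_garp(sharp: pd.DataFrame | pd.Series,
                 hairpin_map: pd.DataFrame) -> pd.DataFrame:
    """Per-gene GARP: mean shARP of the two most-depleting hairpins.

    Genes with a single scored hairpin use that score (``n_hairpins=1``);
    genes with no scored hairpin are omitted with a warning.
    """
    sharp_s = sharp["sharp"] if isinstance(sharp, pd.DataFrame) else sharp
    genes, values, starts, sizes = _gene_layout(sharp_s, hairpin_map)
    garp = _garp_from_segments(values, starts, sizes)
    n_used = np.minimum(sizes, 2)
    all_genes = hairpin_map["gene"].unique()
    missing = len(all_genes) - len(genes)
    if missing:
        warnings.warn(f"{missing} gene(s) had no scored hairpin and were omitted")
    return pd.DataFrame({"garp": garp, "n_hairpins": n_used}, index=pd.Index(genes, name="gene"))


def compute_zgarp(garp: pd.Series | pd.DataFrame) -> pd.Series:
    """Standardize GARP across the genes of one screen (sample sd)."""
    g = garp["garp"] if isinstance(garp, pd.DataFrame) else garp
    if len(g) < 3:
        raise AnalysisError("zGARP needs ≥3 genes")
    sd = g.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise AnalysisError("zGARP undefined: zero spread in GARP scores")
    return ((g - g.mean()) / sd).rename("zgarp")


def _null_garp_pools(values: np.ndarray, starts: np.ndarray, sizes: np.ndarray,
                     B: int, rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Null GARP values per hairpin-count class from B label permutations."""
    pools: dict[int, list] = {int(k): [] for k in np.unique(sizes)}
    for _ in range(B):
        perm = values[rng.permutation(len(values))]
        null = _garp_from_segments(perm, starts, sizes)
        for k in pools:
            pools[k].append(null[sizes == k])
    return {k: np.sort(np.concatenate(v)) for k, v in pools.items()}


def garp_pvalues(
    sharp: pd.DataFrame | pd.Series,
    hairpin_map: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Left-tail empirical GARP p-values from hairpin-label permutations.

    The hairpin→gene assignment is permuted ``B`` times (gene hairpin
    counts preserved); each gene's observed GARP is compared against the
    pooled null of all genes sharing its hairpin count, with the add-one
    rule: ``p = (1 + #{null ≤ observed}) / (pool size + 1)``.
    """
    if B < 100:
        raise ConfigError("B must be ≥ 100 for a usable permutation null")
    sharp_s = sharp["sharp"] if isinstance(sharp, pd.DataFrame) else sharp
    genes, values, starts, sizes = _gene_layout(sharp_s, hairpin_map)
    obs = _garp_from_segments(values, starts, sizes)
    rng = np.random.default_rng(seed)
    pools = _null_garp_pools(values, starts, sizes, B, rng)
    p = np.empty(len(genes))
    for k, pool in pools.items():
        mask = sizes == k
        count = np.searchsorted(pool, obs[mask], side="right")
        p[mask] = (1.0 + count) / (len(pool) + 1.0)
    return pd.Series(p, index=pd.Index(genes, name="gene"), name="p")


def sharp_pvalues(sharp: pd.DataFrame | pd.Series) -> pd.Series:
    """Left-tail empirical rank p per hairpin against the screen's shARP
    distribution: ``p = rank(ascending) / n`` (most depleting → 1/n).

    A stand-in hairpin-level significance used to require that a
    confirmation candidate carries at least one strongly depleting
    hairpin.
    """
    sharp_s = sharp["sharp"] if isinstance(sharp, pd.DataFrame) else sharp
    n = len(sharp_s)
    if n == 0:
        raise AnalysisError("empty shARP table")
    return (sharp_s.rank(method="max") / n).rename("p")


def replicate_correlation(normalized: pd.DataFrame,
                          line: str | None = None) -> pd.DataFrame:
    """Pearson correlation of replicate pairs at matching timepoints.

    QC report with one row per (line, day, replicate pair). Lines with a
    single replicate yield no rows (with a warning).
    """
    lines = (
        [line]
        if line is not None
        else list(dict.fromkeys(normalized.columns.get_level_values("line")))
    )
    rows = []
    for ln in lines:
        sub = _line_columns(normalized, ln)
        reps = sorted(set(sub.columns.get_level_values("replicate")))
        if len(reps) < 2:
            warnings.warn(f"line {ln!r} has a single replicate; no correlations")
            continue
        for day in sorted(set(sub.columns.get_level_values("day"))):
            cols = {
                r: sub.loc[:, (ln, r, day)]
                for r in reps
                if (ln, r, day) in sub.columns
            }
            for i, ra in enumerate(reps):
                for rb in reps[i + 1:]:
                    if ra in cols and rb in cols:
                        r = float(np.corrcoef(cols[ra], cols[rb])[0, 1])
                        rows.append((ln, day, ra, rb, r))
    return pd.DataFrame(rows, columns=["line", "day", "rep_a", "rep_b", "r"])


def score_screen(
    counts: pd.DataFrame,
    hairpin_map: pd.DataFrame,
    line: str,
    B: int = 1000,
    seed: int = 0,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-screen scoring: counts → shARP → GARP/zGARP/p.

    Convenience wrapper returning ``(gene score table, shARP table)``
    where the gene table has columns garp, zgarp, p, n_hairpins.
    """
    normalized = normalize_counts(counts, pseudocount=pseudocount)
    sharp = compute_sharp(normalized, line, counts=counts)
    garp = compute_garp(sharp, hairpin_map)
    zgarp = compute_zgarp(garp)
    p = garp_pvalues(sharp, hairpin_map, B=B, seed=seed)
    table = garp.assign(zgarp=zgarp, p=p)[["garp", "zgarp", "p", "n_hairpins"]]
    return table, sharp
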