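"""DiE gene-set signatures and classification of cell-line panels.

The significant negative interactors of one query form its DiE profile, a
gene-set fingerprint of pathway dependency. Overlap of that profile with
each non-isogenic line's essential-gene set (Jaccard index: intersection
over union) separates lines known to depend on the pathway from
independent lines; the mean shift between the two groups gets a one-sided
label-permutation p-value. A complementary hypergeometric test asks
whether the profile is enriched in the top fraction of genes ranked by
how much more frequently they are essential in dependent lines.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ConfigError

__all__ = [
    "build_die_profile",
    "jaccard",
    "classify_panel",
    "top_fraction_enrichment",
    "frequency_difference",
    "essential_frequency",
]


def build_die_profile(records: pd.DataFrame, query: str, alpha: float = 0.05) -> set:
    """DiE profile of one query: SSL-called genes with p < alpha."""
    sub = records.loc[records["query"] == query]
    if sub.empty:
        raise AnalysisError(f"no records for query {query!r}")
    profile = set(sub.loc[sub["ssl_call"] & (sub["p"] < alpha), "gene"])
    if not profile:
        warnings.warn(f"empty DiE profile for {query!r}; unusable for classification")
    return profile


def jaccard(a: set, b: set) -> float:
    """Jaccard index |A∩B| / |A∪B|; 0 when both sets are empty."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def classify_panel(
    profile: set,
    essential_sets: dict,
    labels: pd.Series,
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[pd.Series, float]:
    """Mean-shift permutation test of profile overlap across a panel.

    Computes the Jaccard index between the profile and each line's
    essential set, then tests whether the dependent group's mean index
    exceeds the independent group's by permuting the dependence labels
    ``n_perm`` times (one-sided, add-one rule). Returns (per-line Jaccard
    series, p-value).
    """
    if n_perm < 999:
        raise ConfigError("n_perm must be ≥ 999")
    lines = list(labels.index)
    j = pd.Series({ln: jaccard(profile, essential_sets[ln]) for ln in lines},
                  name="jaccard")
    is_dep = (labels == "dependent").to_numpy()
    is_ind = (labels == "independent").to_numpy()
    if is_dep.sum() < 2 or is_ind.sum() < 2:
        raise AnalysisError("each labeled group needs ≥2 lines")
    values = j.loc[lines].to_numpy()
    used = is_dep | is_ind
    values_u, is_dep_u = values[used], is_dep[used]
    observed = values_u[is_dep_u].mean() - values_u[~is_dep_u].mean()
    rng = np.random.default_rng(seed)
    n_dep = int(is_dep_u.sum())
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(values_u))
        stat = values_u[perm[:n_dep]].mean() - values_u[perm[n_dep:]].mean()
        if stat >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return j, float(p)


def top_fraction_enrichment(
    profile: set, ranking: pd.Series, fraction: float = 0.05
) -> float:
    """Hypergeometric enrichment of the profile in the top-ranked genes.

    ``ranking`` scores every gene in the universe (higher = more
    essential in dependent lines); the top ``fraction`` of the universe
    is the target set. Returns the upper-tail probability of observing at
    least the actual overlap.
    """
    if not 0 < fraction <= 1:
        raise ConfigError("fraction must be in (0, 1]")
    universe = list(ranking.index)
    m = len(universe)
    if m == 0:
        raise AnalysisError("empty ranking")
    n_top = max(1, int(round(fraction * m)))
    top = set(ranking.sort_values(ascending=False, kind="stable").index[:n_top])
    profile_in_universe = profile & set(universe)
    k = len(profile_in_universe & top)
    # P(X ≥ k), X ~ Hypergeom(M=m, n=|profile|, N=n_top)
    return float(stats.hypergeom.sf(k - 1, m, len(profile_in_universe), n_top))


def essential_frequency(essential_sets: dict, labels: pd.Series,
                        universe: list) -> pd.DataFrame:
    """Per-gene essential-call frequency within each labeled line group."""
    out = {}
    for group in ("dependent", "independent"):
        members = [ln for ln in labels.index if labels[ln] == group]
        if not members:
            raise AnalysisError(f"no lines labeled {group!r}")
        counts = pd.Series(0.0, index=pd.Index(universe, name="gene"))
        for ln in members:
            hits = counts.index.isin(essential_sets[ln])
            counts[hits] += 1
        out[f"freq_{group[:3]}"] = counts / len(members)
    return pd.DataFrame(out)


def frequency_difference(
    profile: set,
    freq_dependent: pd.Series,
    freq_independent: pd.Series,
    min_diff: float = 0.1,
) -> pd.DataFrame:
    """Profile genes more frequently essential in dependent lines.

    Keeps profile genes with ``freq_dep − freq_indep > min_diff``
    (strict), sorted by the difference descending. Frequencies must lie
    in [0, 1].
    """
    genes = [g for g in profile if g in freq_dependent.index]
    fd = freq_dependent.loc[genes]
    fi = freq_independent.reindex(genes)
    for name, s in (("dependent", fd), ("independent", fi)):
        vals = s.dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ConfigError(f"{name} frequencies outside [0, 1]")
    table = pd.DataFrame(
        {"gene": genes, "freq_dep": fd.to_numpy(), "freq_ind": fi.to_numpy()}
    )
    table["diff"] = table["freq_dep"] - table["freq_ind"]
    table = table.loc[table["diff"] > min_diff]
    return table.sort_values(["diff", "gene"], ascending=[False, True],
                             kind="stable").reset_index(drop=True)
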