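"""Synthetic screen, expression, competition, orthology and panel generators.

Every generator in this module plants a known ground truth and is
bit-reproducible from its config (which carries a mandatory seed), so each
downstream stage of the pipeline can be tested for recovery of planted
signal without any external data.

The dropout model: each hairpin's expected log2 relative abundance declines
linearly in time at ``rate(gene class, line) × hairpin efficacy`` (i.e.
exponential clone decay). General-essential genes deplete in every line;
synthetic-sick/lethal (SSL) genes deplete only in their query line; neutral
genes have rate 0. Under ``noise_model="multinomial"`` a per-observation
log-normal biological jitter (culture/passage variability) perturbs the
expected abundance before reads are drawn multinomially at fixed depth —
this is what puts replicate correlations in the 0.9–0.99 range seen in real
pooled screens. Under ``noise_model="none"`` the counts are the exact
expected relative abundances (floats), which makes hairpin dropout slopes
analytically recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

PARENTAL = "parental"
MOCK = "MOCK"


# ---------------------------------------------------------------------------
# screen generator


@dataclass(kw_only=True)
class ScreenSimConfig:
    """Conditions for one simulated isogenic screen family.

    Defaults mirror a scaled-down genome-wide pooled shRNA screen:
    ~5 hairpins per gene, biological triplicates over four timepoints,
    a fixed sequencing depth per sample, ~5% general-essential genes
    dropping out at −0.5 log2/day and ~5% query-specific SSL genes per
    query at −0.25 log2/day (≈ −2 screen-sd of zGARP under these
    conditions), with per-hairpin knockdown efficacy drawn uniformly
    from ``hairpin_efficacy_range``.
    """

    n_genes: int
    seed: int
    hairpins_per_gene: int = 5
    n_queries: int = 1
    timepoints: tuple = (0.0, 3.0, 6.0, 9.0)
    n_replicates: int = 3
    depth: int = 5_000_000
    frac_general_essential: float = 0.05
    frac_ssl_per_query: float = 0.05
    frac_not_expressed: float = 0.10
    essential_dropout_rate: float = -0.5
    ssl_dropout_rate: float = -0.25
    hairpin_efficacy_range: tuple = (0.7, 1.0)
    baseline_log2_sd: float = 1.0
    bio_noise_log2_sd: float = 0.25
    noise_model: str = "multinomial"
    expr_present_mean: float = 8.0
    expr_absent_mean: float = 2.0
    expr_sd: float = 1.0

    @property
    def queries(self) -> list[str]:
        return [f"query{i + 1}" for i in range(self.n_queries)]

    @property
    def lines(self) -> list[str]:
        return [PARENTAL] + self.queries

    def validate(self) -> None:
        if self.n_genes < 1 or self.hairpins_per_gene < 1 or self.n_replicates < 1:
            raise ConfigError("n_genes, hairpins_per_gene, n_replicates must be ≥1")
        if self.depth <= 0:
            raise ConfigError("depth must be > 0")
        planted = (
            self.frac_general_essential
            + self.frac_ssl_per_query * self.n_queries
            + self.frac_not_expressed
        )
        if not 0 <= planted <= 1:
            raise ConfigError(
                f"planted class fractions sum to {planted:.3f}, outside [0, 1]"
            )
        if self.essential_dropout_rate > 0 or self.ssl_dropout_rate > 0:
            raise ConfigError("dropout rates of depleting classes must be ≤ 0")
        days = list(self.timepoints)
        if len(set(days)) < 2 or sorted(days) != days:
            raise ConfigError("timepoints must be ≥2 strictly increasing day offsets")
        lo, hi = self.hairpin_efficacy_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError("hairpin_efficacy_range must satisfy 0 ≤ lo ≤ hi ≤ 1")
        if self.noise_model not in ("none", "multinomial"):
            raise ConfigError(f"unknown noise_model {self.noise_model!r}")


@dataclass
class PlantedTruth:
    """Ground truth of one simulated screen family.

    ``gene_class`` maps each gene to exactly one of ``neutral``,
    ``general_essential``, ``ssl:<query>`` or ``not_expressed:<line>``;
    ``efficacy`` holds one knockdown efficacy per hairpin in [0, 1].
    """

    gene_class: pd.Series
    efficacy: pd.Series

    def genes_of_class(self, cls: str) -> list[str]:
        return list(self.gene_class.index[self.gene_class == cls])

    def ssl_genes(self, query: str) -> list[str]:
        return self.genes_of_class(f"ssl:{query}")


@dataclass
class ScreenDataset:
    """A simulated screen: hairpin map, count tensor, sample index, truth."""

    hairpin_map: pd.DataFrame
    counts: pd.DataFrame  # hairpin × (line, replicate, day)
    truth: PlantedTruth
    config: ScreenSimConfig


def _assign_classes(config: ScreenSimConfig, genes: np.ndarray,
                    rng: np.random.Generator) -> pd.Series:
    n = len(genes)
    order = rng.permutation(n)
    classes = np.array(["neutral"] * n, dtype=object)
    pos = 0
    n_ess = round(config.frac_general_essential * n)
    classes[order[pos:pos + n_ess]] = "general_essential"
    pos += n_ess
    for q in config.queries:
        n_ssl = round(config.frac_ssl_per_query * n)
        classes[order[pos:pos + n_ssl]] = f"ssl:{q}"
        pos += n_ssl
    # not-expressed genes are picked among the remaining neutral genes so
    # that planted SSL genes are always expressed in their query line
    n_ne = round(config.frac_not_expressed * n)
    ne_lines = rng.choice(config.lines, size=n_ne)
    for idx, ln in zip(order[pos:pos + n_ne], ne_lines):
        classes[idx] = f"not_expressed:{ln}"
    return pd.Series(classes, index=genes, name="class")


def _rate_matrix(config: ScreenSimConfig, gene_class: pd.Series) -> pd.DataFrame:
    """Per-gene, per-line dropout rate in log2-units/day."""
    rates = pd.DataFrame(
        0.0, index=gene_class.index, columns=config.lines, dtype=float
    )
    rates.loc[gene_class == "general_essential", :] = config.essential_dropout_rate
    for q in config.queries:
        rates.loc[gene_class == f"ssl:{q}", q] = config.ssl_dropout_rate
    return rates


def generate_screen(config: ScreenSimConfig) -> ScreenDataset:
    """Simulate pooled shRNA dropout screens for the parental and query lines.

    Returns a :class:`ScreenDataset` whose count tensor covers all lines,
    replicates and timepoints of ``config``. Fully reproducible from
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 0])

    width = max(4, len(str(config.n_genes)))
    genes = np.array([f"g{i:0{width}d}" for i in range(config.n_genes)])
    hairpins = np.array(
        [f"{g}_h{j + 1}" for g in genes for j in range(config.hairpins_per_gene)]
    )
    gene_of_hairpin = np.repeat(genes, config.hairpins_per_gene)
    hairpin_map = pd.DataFrame({"hairpin": hairpins, "gene": gene_of_hairpin})

    gene_class = _assign_classes(config, genes, rng)
    lo, hi = config.hairpin_efficacy_range
    efficacy = pd.Series(
        rng.uniform(lo, hi, size=len(hairpins)), index=hairpins, name="efficacy"
    )
    truth = PlantedTruth(gene_class=gene_class, efficacy=efficacy)

    rates = _rate_matrix(config, gene_class)
    hp_rates = rates.loc[gene_of_hairpin].to_numpy()  # hairpin × line
    baseline = rng.normal(0.0, config.baseline_log2_sd, size=len(hairpins))

    samples = pd.MultiIndex.from_tuples(
        [
            (line, f"r{r + 1}", float(day))
            for line in config.lines
            for r in range(config.n_replicates)
            for day in config.timepoints
        ],
        names=("line", "replicate", "day"),
    )
    line_idx = {line: i for i, line in enumerate(config.lines)}

    n_h, n_s = len(hairpins), len(samples)
    log2_abund = np.empty((n_h, n_s))
    eff = efficacy.to_numpy()
    for j, (line, _rep, day) in enumerate(samples):
        log2_abund[:, j] = baseline + hp_rates[:, line_idx[line]] * eff * day

    if config.noise_model == "multinomial":
        log2_abund = log2_abund + rng.normal(
            0.0, config.bio_noise_log2_sd, size=log2_abund.shape
        )
        counts = np.empty((n_h, n_s), dtype=np.int64)
        for j in range(n_s):
            p = np.exp2(log2_abund[:, j] - log2_abund[:, j].max())
            counts[:, j] = rng.multinomial(config.depth, p / p.sum())
        counts_df = pd.DataFrame(counts, index=hairpins, columns=samples)
    else:
        # exact absolute abundances on a common scale across samples: one
        # fixed factor, no per-sample renormalization, so planted log2
        # trajectories stay exactly linear (clone populations shrink as
        # genes deplete; totals are not forced to the sequencing depth)
        scale = config.depth / 1e6
        counts_df = pd.DataFrame(
            scale * np.exp2(log2_abund), index=hairpins, columns=samples
        )

    counts_df.index.name = "hairpin"
    return ScreenDataset(hairpin_map=hairpin_map, counts=counts_df,
                         truth=truth, config=config)


# ---------------------------------------------------------------------------
# expression generator


def generate_expression(
    config: ScreenSimConfig, truth: PlantedTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a bimodal gene × line log2 expression matrix.

    Genes classed ``not_expressed:<line>`` draw from a low mode in that
    line; all other (gene, line) cells draw from a high mode. Returns
    ``(expression, presence_truth)`` where presence_truth is boolean.
    """
    rng = np.random.default_rng([int(config.seed), 1])
    genes = truth.gene_class.index
    lines = config.lines
    present = pd.DataFrame(True, index=genes, columns=lines)
    for line in lines:
        absent = truth.gene_class == f"not_expressed:{line}"
        present.loc[absent, line] = False
    means = np.where(
        present.to_numpy(), config.expr_present_mean, config.expr_absent_mean
    )
    values = rng.normal(means, config.expr_sd)
    expression = pd.DataFrame(values, index=genes, columns=lines)
    expression.index.name = "gene"
    return expression, present


# ---------------------------------------------------------------------------
# competition-assay generator


@dataclass(kw_only=True)
class CompetitionSimConfig:
    """Conditions for simulated red/green co-culture competition assays.

    Each (gene, query) knockdown is run in two replicate wells alongside
    ``n_mock`` mock-transfected wells per query (matching the 25 mock
    wells used to calibrate the confirmation interval). Parental (red)
    and query (green) cells are seeded 1:1; the green:red ratio carries a
    fixed per-day geometric drift (baseline growth differences between
    the lines) plus log-normal day-level noise. In true-SSL wells the
    green population additionally declines to ``ssl_fold`` of baseline at
    ``nadir_day`` and partially recovers (transient siRNA effect).
    """

    pairs: list  # of (gene, query)
    seed: int
    n_mock: int = 25
    n_replicates: int = 2
    days: tuple = (1, 2, 3, 4, 5, 6, 7)
    ssl_fold: float = 0.5
    nadir_day: float = 4.0
    drift_per_day: float = 0.97
    growth_per_day: float = 1.6
    n0: float = 1000.0
    noise_log2_sd: float = 0.08

    def validate(self) -> None:
        if len(self.days) < 2:
            raise ConfigError("competition assays need ≥2 distinct days")
        if not 0 < self.ssl_fold <= 1:
            raise ConfigError("ssl_fold must be in (0, 1]")
        if self.n_mock < 2:
            raise ConfigError("need ≥2 mock wells per query")


def _effect_trajectory(fold: float, days: np.ndarray, nadir: float) -> np.ndarray:
    """Transient knockdown effect: reaches ``fold`` at the nadir day, then
    recovers halfway (in log space) by the final day."""
    if fold == 1.0:
        return np.ones_like(days, dtype=float)
    last = days.max()
    expo = np.where(
        days <= nadir,
        days / nadir,
        1.0 - 0.5 * (days - nadir) / max(last - nadir, 1e-12),
    )
    return fold ** expo


def generate_competition(
    config: CompetitionSimConfig, truth: PlantedTruth | None = None
) -> pd.DataFrame:
    """Simulate competition-assay well trajectories.

    A well's green population carries the SSL effect (fold
    ``config.ssl_fold``) when ``truth`` classes its gene as
    ``ssl:<query>``; pairs may also be given as ``(gene, query, fold)``
    to set the planted fold explicitly. Returns a long-format table with
    columns well, gene, query, replicate, day, red, green (counts are
    image-analysis cell estimates, kept as floats).
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 2])
    days = np.asarray(config.days, dtype=float)
    rows = []

    def add_well(well: str, gene: str, query: str, rep: str, fold: float) -> None:
        effect = _effect_trajectory(fold, days, config.nadir_day)
        growth = config.growth_per_day ** days
        drift = config.drift_per_day ** days
        if config.noise_log2_sd > 0:
            eps_g = np.exp2(rng.normal(0, config.noise_log2_sd, size=len(days)))
            eps_r = np.exp2(rng.normal(0, config.noise_log2_sd, size=len(days)))
        else:
            eps_g = eps_r = np.ones(len(days))
        green = config.n0 * growth * drift * effect * eps_g
        red = config.n0 * growth * eps_r
        for d, r, g in zip(days, red, green):
            rows.append((well, gene, query, rep, d, r, g))

    queries = sorted({q for pair in config.pairs for q in [pair[1]]})
    for query in queries:
        for k in range(config.n_mock):
            add_well(f"{query}:{MOCK}:m{k + 1}", MOCK, query, f"m{k + 1}", 1.0)
    for pair in config.pairs:
        if len(pair) == 3:
            gene, query, fold = pair
        else:
            gene, query = pair
            is_ssl = truth is not None and truth.gene_class.get(gene) == f"ssl:{query}"
            fold = config.ssl_fold if is_ssl else 1.0
        for r in range(config.n_replicates):
            add_well(f"{query}:{gene}:r{r + 1}", gene, query, f"r{r + 1}", fold)

    return pd.DataFrame(
        rows, columns=["well", "gene", "query", "replicate", "day", "red", "green"]
    )


# ---------------------------------------------------------------------------
# orthology generator


@dataclass(kw_only=True)
class OrthologySimConfig:
    """Toy orthologous-group fixture with planted conserved interactions.

    Each human gene involved in a planted pair gets its own unambiguous
    orthologous group holding one true model-organism ortholog (top
    similarity) and, optionally, one lower-similarity in-group paralog
    that the most-probable filter should discard. Planted pairs appear as
    negative edges in the model-organism genetic-interaction table.
    """

    conserved_pairs: list  # of (query gene/id, human partner gene)
    seed: int
    organism: str = "yeast"
    n_decoy_groups: int = 10
    with_paralogs: bool = True
    best_similarity: float = 100.0
    paralog_similarity: float = 50.0

    def validate(self) -> None:
        if self.n_decoy_groups < 0:
            raise ConfigError("n_decoy_groups must be ≥ 0")


def generate_orthology(
    config: OrthologySimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (group table, similarity table, model GI table).

    The planted conserved pairs project back exactly onto themselves
    through the most-probable ortholog map; decoy groups and positive
    model edges exercise the filters without adding predictions.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 3])
    org = config.organism
    humans = sorted({g for pair in config.conserved_pairs for g in pair})
    groups, sims, gi = [], [], []

    def model_name(h: str) -> str:
        return f"{org[:1]}_{h}"

    for i, h in enumerate(humans):
        gid = f"OG{i + 1:04d}"
        groups.append((gid, "human", h))
        groups.append((gid, org, model_name(h)))
        sims.append((h, org, model_name(h), config.best_similarity))
        if config.with_paralogs:
            par = f"{model_name(h)}_par"
            groups.append((gid, org, par))
            sims.append((h, org, par, config.paralog_similarity))

    for q, g in config.conserved_pairs:
        gi.append((org, model_name(q), model_name(g), "negative"))
    # decoy groups (model-only) and decoy positive / unmapped edges
    for i in range(config.n_decoy_groups):
        gid = f"OGD{i + 1:04d}"
        groups.append((gid, org, f"{org[:1]}_decoy{i + 1}"))
        gi.append((org, f"{org[:1]}_decoy{i + 1}",
                   f"{org[:1]}_unmapped{i + 1}", "negative"))
    if humans and config.n_decoy_groups:
        h = humans[int(rng.integers(len(humans)))]
        gi.append((org, model_name(h), f"{org[:1]}_decoy1", "positive"))

    groups_df = pd.DataFrame(groups, columns=["group", "organism", "gene"])
    sims_df = pd.DataFrame(
        sims, columns=["human_gene", "organism", "model_gene", "score"]
    )
    gi_df = pd.DataFrame(gi, columns=["organism", "geneA", "geneB", "sign"])
    return groups_df, sims_df, gi_df


# ---------------------------------------------------------------------------
# cell-line panel generator


@dataclass(kw_only=True)
class PanelSimConfig:
    """Conditions for a simulated non-isogenic cell-line panel.

    ``enrichment`` is the additive boost, on the probability scale, that
    signature genes receive in dependent lines' essential-call rate:
    P(essential) = base_rate + enrichment·(1 − base_rate). At the
    defaults (base 0.1, enrichment 0.2) signature genes are called
    essential ~3× more often in dependent lines.
    """

    seed: int
    n_lines: int = 72
    frac_dependent: float = 1 / 3
    base_rate: float = 0.10
    enrichment: float = 0.20

    def validate(self) -> None:
        if not 0 <= self.enrichment <= 1:
            raise ConfigError("enrichment must be in [0, 1]")
        if not 0 < self.base_rate < 1:
            raise ConfigError("base_rate must be in (0, 1)")
        if self.n_lines < 4 or not 0 < self.frac_dependent < 1:
            raise ConfigError("need ≥4 lines and frac_dependent in (0, 1)")


def generate_cell_line_panel(
    config: PanelSimConfig, signature: set, universe: list
) -> tuple[dict, pd.Series]:
    """Simulate per-line essential-gene sets with planted dependence.

    Returns ``(essential_sets, labels)`` where essential_sets maps line
    id → set of essential genes and labels is a Series of
    ``dependent``/``independent`` per line.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 4])
    universe = list(universe)
    sig_mask = np.array([g in signature for g in universe])
    n_dep = round(config.frac_dependent * config.n_lines)
    lines = [f"line{i + 1:03d}" for i in range(config.n_lines)]
    labels = pd.Series(
        ["dependent"] * n_dep + ["independent"] * (config.n_lines - n_dep),
        index=lines, name="label",
    )
    boosted = config.base_rate + config.enrichment * (1 - config.base_rate)
    essential_sets = {}
    for line in lines:
        p = np.full(len(universe), config.base_rate)
        if labels[line] == "dependent":
            p[sig_mask] = boosted
        draw = rng.random(len(universe)) < p
        essential_sets[line] = {g for g, e in zip(universe, draw) if e}
    return essential_sets, labels
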