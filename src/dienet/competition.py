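"""Scoring of red/green co-culture competition assays.

Parental (red) and query (green) cells are mixed 1:1, a candidate SSL
gene is knocked down, and the red:green composition is imaged daily for a
week. Because siRNA knockdown is transient, the signal is the *deepest*
drop of the normalized green:red ratio across the timecourse, not the
terminal value. Baseline growth differences between the two lines are
removed by dividing by the mock-well mean ratio per day.

A knockdown is *confirmed* as a negative genetic interaction when its
relative fitness falls strictly below the lower bound of the central 80%
band (10th–90th percentile) of the per-well scores of the mock wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigError, IntegrityError

__all__ = [
    "growth_normalizer",
    "well_score",
    "fitness_score",
    "mock_interval",
    "call_confirmed",
    "score_competition",
    "MOCK",
]

MOCK = "MOCK"

WELL_COLUMNS = ["well", "gene", "query", "replicate", "day", "red", "green"]


def growth_normalizer(mock_wells: pd.DataFrame) -> pd.Series:
    """Per-day baseline green:red ratio from a query's mock wells.

    ``g0(t)`` is the across-mock-well mean of green/red at day t. Needs
    ≥2 mock wells; a day with zero red cells in every mock is an error.
    """
    if mock_wells["well"].nunique() < 2:
        raise AnalysisError("growth normalization needs ≥2 mock wells")
    ok = mock_wells["red"] > 0
    if not ok.any():
        raise AnalysisError("no mock observation with red cells")
    ratios = mock_wells.loc[ok, "green"] / mock_wells.loc[ok, "red"]
    g0 = ratios.groupby(mock_wells.loc[ok, "day"]).mean()
    missing = set(mock_wells["day"]) - set(g0.index)
    if missing:
        raise AnalysisError(f"day(s) {sorted(missing)} have zero red cells in all mocks")
    if (g0 <= 0).any():
        raise AnalysisError("baseline ratio must be strictly positive")
    return g0.rename("g0")


def well_score(well: pd.DataFrame, g0: pd.Series) -> float:
    """Per-well replicate score: the deepest normalized green:red drop.

    ``r(t) = (green/red)(t) / g0(t)``; the score is ``min_t r(t)`` (the
    greatest fold-change, robust to transient-knockdown recovery). Days
    with zero red cells are skipped with a warning.
    """
    usable = well["red"] > 0
    if not usable.all():
        warnings.warn(
            f"well {well['well'].iloc[0]!r}: {(~usable).sum()} day(s) with zero "
            "red cells skipped"
        )
    well = well.loc[usable]
    if well.empty:
        raise AnalysisError("no usable day in well")
    r = (well["green"] / well["red"]).to_numpy() / g0.reindex(well["day"]).to_numpy()
    if np.isnan(r).any():
        raise AnalysisError("well measured on a day absent from the mock baseline")
    return float(np.min(r))


@dataclass
class FitnessResult:
    """Relative fitness of query vs parental cells for one knockdown."""

    gene: str
    query: str
    fitness: float
    confirmed: bool | None = None
    lower: float | None = None
    upper: float | None = None


def fitness_score(wells: pd.DataFrame, g0: pd.Series) -> FitnessResult:
    """Fitness of one (gene, query) knockdown from its two replicate wells.

    Each replicate well is reduced to its deepest normalized drop; the
    fitness score is the mean of the two replicate scores (1 = neutral).
    """
    gene = wells["gene"].iloc[0]
    query = wells["query"].iloc[0]
    scores = [well_score(w, g0) for _, w in wells.groupby("well", sort=True)]
    if len(scores) != 2:
        raise AnalysisError(
            f"knockdown ({gene}, {query}) has {len(scores)} wells; expected 2"
        )
    return FitnessResult(gene=gene, query=query, fitness=float(np.mean(scores)))


def mock_interval(
    mock_wells: pd.DataFrame, level: float = 0.80, g0: pd.Series | None = None
) -> tuple[float, float, float]:
    """Central percentile band of the mock wells' per-well lowest drops.

    Each mock well is scored by the same deepest-drop statistic as a
    knockdown well; the interval is the central ``level`` band of that
    score distribution (linear interpolation), e.g. the 10th and 90th
    percentiles at level 0.80, together with the mean.
    """
    if not 0 < level <= 1:
        raise ConfigError("level must be in (0, 1]")
    if mock_wells["well"].nunique() < 5:
        raise AnalysisError("mock interval needs ≥5 mock wells")
    if g0 is None:
        g0 = growth_normalizer(mock_wells)
    scores = np.array(
        [well_score(w, g0) for _, w in mock_wells.groupby("well", sort=True)]
    )
    tail = 100 * (1 - level) / 2
    lower, upper = np.percentile(scores, [tail, 100 - tail])
    return float(lower), float(upper), float(scores.mean())


def call_confirmed(
    results: list[FitnessResult] | pd.DataFrame,
    interval: tuple[float, float, float],
) -> tuple[pd.DataFrame, float]:
    """Flag confirmed interactions and compute the confirmation rate.

    A knockdown is confirmed iff its fitness is strictly below the lower
    interval bound. The rate is ``100 × unique confirmed genes / tested
    interactions``, reported to one decimal (the statistic the screen's
    secondary-assay summary quotes, e.g. 200 unique of 826 tested → 24.2).
    """
    if isinstance(results, list):
        table = pd.DataFrame(
            [(r.gene, r.query, r.fitness) for r in results],
            columns=["gene", "query", "fitness"],
        )
    else:
        table = results[["gene", "query", "fitness"]].copy()
    if table.empty:
        raise AnalysisError("no tested interactions; confirmation rate undefined")
    if table.duplicated(subset=["gene", "query"]).any():
        dup = table.loc[table.duplicated(subset=["gene", "query"]), ["gene", "query"]]
        raise IntegrityError(f"duplicate fitness result {tuple(dup.iloc[0])}")
    lower, upper, _mean = interval
    table["confirmed"] = table["fitness"] < lower
    table["lower"] = lower
    table["upper"] = upper
    n_tested = len(table)
    n_confirmed = table.loc[table["confirmed"], "gene"].nunique()
    rate = round(100.0 * n_confirmed / n_tested, 1)
    return table, rate


def score_competition(
    dataset: pd.DataFrame, level: float = 0.80
) -> tuple[pd.DataFrame, float]:
    """Score a full competition dataset, one mock interval per query.

    Returns the per-knockdown fitness table with confirmed flags and the
    overall confirmation rate (%). The mock interval is computed per
    query from that query's own mock wells.
    """
    all_results = []
    for query, qwells in dataset.groupby("query", sort=True):
        mocks = qwells.loc[qwells["gene"] == MOCK]
        g0 = growth_normalizer(mocks)
        interval = mock_interval(mocks, level=level, g0=g0)
        results = [
            fitness_score(w, g0)
            for _, w in qwells.loc[qwells["gene"] != MOCK].groupby("gene", sort=True)
        ]
        if results:
            table, _ = call_confirmed(results, interval)
            all_results.append(table)
    if not all_results:
        raise AnalysisError("dataset contains no knockdown wells")
    combined = pd.concat(all_results, ignore_index=True)
    n_tested = len(combined)
    n_confirmed = combined.loc[combined["confirmed"], "gene"].nunique()
    rate = round(100.0 * n_confirmed / n_tested, 1)
    return combined, rate
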