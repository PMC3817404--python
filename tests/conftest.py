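import numpy as np
import pandas as pd
import pytest

from dienet import scoring, simulate


@pytest.fixture(scope="session")
def small_screen():
    """Noisy 120-gene screen with planted essentials and SSL genes."""
    cfg = simulate.ScreenSimConfig(n_genes=120, seed=11, n_queries=1,
                                   depth=500_000)
    return simulate.generate_screen(cfg)


@pytest.fixture(scope="session")
def noiseless_screen():
    """Deterministic screen: absolute abundances, exact planted slopes."""
    cfg = simulate.ScreenSimConfig(n_genes=40, seed=3, n_queries=1,
                                   noise_model="none")
    return simulate.generate_screen(cfg)


@pytest.fixture(scope="session")
def scored_screens(small_screen):
    """Per-line (score table, shARP table) for the small noisy screen."""
    out = {}
    for i, line in enumerate(small_screen.config.lines):
        out[line] = scoring.score_screen(
            small_screen.counts, small_screen.hairpin_map, line,
            B=100, seed=100 + i,
        )
    return out


def planted_rate(screen, gene: str, line: str) -> float:
    """Oracle: the planted dropout rate of a gene in a line."""
    cls = screen.truth.gene_class[gene]
    cfg = screen.config
    if cls == "general_essential":
        return cfg.essential_dropout_rate
    if cls == f"ssl:{line}":
        return cfg.ssl_dropout_rate
    return 0.0
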