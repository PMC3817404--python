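"""shARP/GARP/zGARP scoring: closed-form oracles and invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dienet import scoring
from dienet.errors import AnalysisError, ConfigError


def _tensor(values, samples, hairpins=None):
    cols = pd.MultiIndex.from_tuples(samples, names=("line", "replicate", "day"))
    idx = hairpins or [f"h{i}" for i in range(len(values))]
    return pd.DataFrame(values, index=pd.Index(idx, name="hairpin"), columns=cols)


SAMPLES_1REP = [("L", "r1", 0.0), ("L", "r1", 3.0), ("L", "r1", 6.0)]


class TestNormalize:
    def test_depth_invariance(self):
        t = _tensor([[100, 200], [300, 600], [600, 1200]],
                    [("L", "r1", 0.0), ("L", "r1", 3.0)])
        norm = scoring.normalize_counts(t)
        assert np.allclose(norm.iloc[:, 0], norm.iloc[:, 1])

    def test_zero_count_value_forced_by_formula(self):
        t = _tensor([[0], [1_000_000]], [("L", "r1", 0.0)])
        norm = scoring.normalize_counts(t, pseudocount=0.5)
        assert norm.iloc[0, 0] == pytest.approx(np.log2(0.5))

    def test_rpm_identity(self):
        rng = np.random.default_rng(0)
        t = _tensor(rng.integers(0, 1000, size=(50, 3)),
                    [("L", "r1", 0.0), ("L", "r1", 3.0), ("L", "r2", 0.0)])
        norm = scoring.normalize_counts(t, pseudocount=0.5)
        back = (2.0 ** norm).sum(axis=0) - 0.5 * len(t)
        assert np.allclose(back, 1e6)

    def test_all_zero_sample_rejected(self):
        t = _tensor([[0, 5], [0, 5]], [("L", "r1", 0.0), ("L", "r1", 3.0)])
        with pytest.raises(AnalysisError):
            scoring.normalize_counts(t)
        with pytest.raises(ConfigError):
            scoring.normalize_counts(t, pseudocount=0.0)


class TestSharp:
    def test_constant_abundance_zero_slope(self):
        norm = _tensor([[4.0, 4.0, 4.0]], SAMPLES_1REP)
        sharp = scoring.compute_sharp(norm, "L")
        assert sharp["sharp"].iloc[0] == 0.0

    def test_collinear_closed_form(self):
        # log2 values {10, 9, 8} at days {0, 3, 6}: slope −1/3, zero residual
        norm = _tensor([[10.0, 9.0, 8.0]], SAMPLES_1REP)
        sharp = scoring.compute_sharp(norm, "L")
        assert sharp["sharp"].iloc[0] == pytest.approx(-1 / 3)
        assert sharp["rss"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert sharp["n_obs"].iloc[0] == 3

    def test_balanced_replicate_duplication_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(20, 3))
        single = scoring.compute_sharp(_tensor(y, SAMPLES_1REP), "L")
        doubled = scoring.compute_sharp(
            _tensor(np.hstack([y, y]),
                    SAMPLES_1REP + [("L", "r2", d) for _, _, d in SAMPLES_1REP]),
            "L",
        )
        assert np.allclose(single["sharp"], doubled["sharp"])

    def test_single_timepoint_rejected(self):
        norm = _tensor([[1.0, 2.0]], [("L", "r1", 0.0), ("L", "r2", 0.0)])
        with pytest.raises(AnalysisError):
            scoring.compute_sharp(norm, "L")

    def test_all_zero_hairpin_excluded_with_warning(self):
        counts = _tensor([[0, 0, 0], [10, 10, 10]], SAMPLES_1REP)
        norm = scoring.normalize_counts(counts)
        with pytest.warns(UserWarning, match="zero reads"):
            sharp = scoring.compute_sharp(norm, "L", counts=counts)
        assert list(sharp.index) == ["h1"]


class TestGarp:
    @staticmethod
    def _map(genes):
        return pd.DataFrame({"hairpin": [f"h{i}" for i in range(len(genes))],
                             "gene": genes})

    def test_mean_of_two_most_negative(self):
        sharp = pd.Series([-3.0, -1.0, 0.0, 2.0],
                          index=[f"h{i}" for i in range(4)])
        garp = scoring.compute_garp(sharp, self._map(["g1"] * 4))
        assert garp.loc["g1", "garp"] == pytest.approx(-2.0)
        assert garp.loc["g1", "n_hairpins"] == 2

    def test_equal_pair(self):
        sharp = pd.Series([-2.0, -2.0], index=["h0", "h1"])
        garp = scoring.compute_garp(sharp, self._map(["g1", "g1"]))
        assert garp.loc["g1", "garp"] == -2.0

    def test_single_hairpin_flagged(self):
        sharp = pd.Series([-1.5], index=["h0"])
        garp = scoring.compute_garp(sharp, self._map(["g1"]))
        assert garp.loc["g1", "garp"] == -1.5
        assert garp.loc["g1", "n_hairpins"] == 1

    def test_brute_force_oracle_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n_genes = int(rng.integers(2, 10))
            genes, scores = [], []
            for g in range(n_genes):
                k = int(rng.integers(1, 6))
                genes += [f"g{g}"] * k
                scores += list(rng.normal(size=k))
            sharp = pd.Series(scores, index=[f"h{i}" for i in range(len(scores))])
            garp = scoring.compute_garp(sharp, self._map(genes))
            for g in set(genes):
                vals = sorted(
                    s for s, gg in zip(scores, genes) if gg == g
                )
                expected = np.mean(vals[:2]) if len(vals) >= 2 else vals[0]
                assert garp.loc[g, "garp"] == pytest.approx(expected)

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=4))
    @settings(deadline=None, max_examples=50)
    def test_invariant_to_hairpins_above_top_two(self, extra):
        """Adding hairpins less depleting than the top two leaves GARP fixed."""
        base = pd.Series([-4.0, -3.0], index=["h0", "h1"])
        extras = pd.Series([abs(x) for x in extra],
                           index=[f"x{i}" for i in range(len(extra))])
        sharp = pd.concat([base, extras])
        hp = pd.DataFrame({"hairpin": sharp.index, "gene": "g1"})
        garp = scoring.compute_garp(sharp, hp)
        assert garp.loc["g1", "garp"] == pytest.approx(-3.5)


class TestZgarp:
    def test_arithmetic_oracle(self):
        garp = pd.Series([-4.0, 0.0, 4.0], index=["a", "b", "c"])
        z = scoring.compute_zgarp(garp)
        assert z["a"] == pytest.approx(-1.0)  # sample sd is 4
        assert z["b"] == pytest.approx(0.0)

    def test_normalization_identity(self):
        rng = np.random.default_rng(5)
        z = scoring.compute_zgarp(pd.Series(rng.normal(size=100)))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    @given(st.floats(0.1, 10), st.floats(-5, 5))
    @settings(deadline=None, max_examples=30)
    def test_affine_invariance(self, scale, shift):
        garp = pd.Series([-2.0, -0.5, 0.3, 1.0, 2.2])
        z1 = scoring.compute_zgarp(garp)
        z2 = scoring.compute_zgarp(garp * scale + shift)
        assert np.allclose(z1, z2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(AnalysisError):
            scoring.compute_zgarp(pd.Series([1.0, 2.0]))
        with pytest.raises(AnalysisError):
            scoring.compute_zgarp(pd.Series([1.0, 1.0, 1.0]))


class TestGarpPvalues:
    def test_same_seed_identical(self, small_screen):
        norm = scoring.normalize_counts(small_screen.counts)
        sharp = scoring.compute_sharp(norm, "parental")
        p1 = scoring.garp_pvalues(sharp, small_screen.hairpin_map, B=100, seed=7)
        p2 = scoring.garp_pvalues(sharp, small_screen.hairpin_map, B=100, seed=7)
        assert p1.equals(p2)
        assert ((p1 > 0) & (p1 <= 1)).all()

    def test_most_extreme_gene_add_one_rule(self):
        # one gene far more depleting than anything the null can produce
        sharp = pd.Series([-50.0, -50.0] + [0.1 * i for i in range(18)],
                          index=[f"h{i}" for i in range(20)])
        hp = pd.DataFrame({"hairpin": sharp.index,
                           "gene": [f"g{i // 2}" for i in range(20)]})
        p = scoring.garp_pvalues(sharp, hp, B=100, seed=1)
        pool = 100 * 10  # B × genes in the 2-hairpin class
        # extreme gene: only permutations re-pairing the two -50 hairpins tie
        assert 0 < p["g0"] <= (1 + 100) / (pool + 1)

    def test_b_too_small_rejected(self, small_screen):
        sharp = pd.Series([-1.0, 0.0], index=["h1", "h2"])
        hp = pd.DataFrame({"hairpin": ["h1", "h2"], "gene": ["g1", "g2"]})
        with pytest.raises(ConfigError):
            scoring.garp_pvalues(sharp, hp, B=50, seed=0)


def test_sharp_pvalues_rank_form():
    sharp = pd.Series([-3.0, -1.0, 0.0, 2.0], index=list("abcd"))
    p = scoring.sharp_pvalues(sharp)
    assert list(p) == [0.25, 0.5, 0.75, 1.0]


class TestReplicateCorrelation:
    def test_identical_columns_r1(self):
        y = np.random.default_rng(0).normal(size=10)
        norm = _tensor(np.column_stack([y, y]),
                       [("L", "r1", 0.0), ("L", "r2", 0.0)])
        qc = scoring.replicate_correlation(norm)
        assert qc["r"].iloc[0] == pytest.approx(1.0)

    def test_anticorrelated_toy(self):
        norm = _tensor(np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]]),
                       [("L", "r1", 0.0), ("L", "r2", 0.0)])
        qc = scoring.replicate_correlation(norm)
        assert qc["r"].iloc[0] == pytest.approx(-1.0)

    def test_single_replicate_warns_empty(self):
        norm = _tensor([[1.0, 2.0]], [("L", "r1", 0.0), ("L", "r1", 3.0)])
        with pytest.warns(UserWarning):
            qc = scoring.replicate_correlation(norm)
        assert qc.empty
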