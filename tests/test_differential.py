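"""dGARP calls, presence filter, network assembly and module propagation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dienet import differential as diff
from dienet import scoring, simulate
from dienet.errors import AnalysisError, IntegrityError


class TestDgarp:
    def test_identical_screens_zero(self):
        z = pd.Series([-1.0, 0.5], index=["g1", "g2"])
        assert (diff.compute_dgarp(z, z) == 0).all()

    def test_arithmetic_and_antisymmetry(self):
        zq = pd.Series([-3.0, 1.0], index=["g1", "g2"])
        zp = pd.Series([-1.0, 1.0], index=["g1", "g2"])
        d = diff.compute_dgarp(zq, zp)
        assert d["g1"] == pytest.approx(-2.0)
        assert np.allclose(diff.compute_dgarp(zp, zq), -d)

    def test_partial_overlap_warns_empty_errors(self):
        zq = pd.Series([1.0, 2.0], index=["g1", "g2"])
        zp = pd.Series([1.0, 3.0], index=["g1", "g3"])
        with pytest.warns(UserWarning):
            d = diff.compute_dgarp(zq, zp)
        assert list(d.index) == ["g1"]
        with pytest.raises(AnalysisError):
            diff.compute_dgarp(zq, pd.Series([1.0], index=["g9"]))


class TestDgarpPvalues:
    def test_same_seed_identical(self, small_screen):
        norm = scoring.normalize_counts(small_screen.counts)
        sq = scoring.compute_sharp(norm, "query1")
        sp = scoring.compute_sharp(norm, "parental")
        p1 = diff.dgarp_pvalues(sq, sp, small_screen.hairpin_map, B=100, seed=3)
        p2 = diff.dgarp_pvalues(sq, sp, small_screen.hairpin_map, B=100, seed=3)
        assert p1.equals(p2)
        assert ((p1 > 0) & (p1 <= 1)).all()

    def test_planted_ssl_genes_significant(self, small_screen, scored_screens):
        _, sq = scored_screens["query1"]
        _, sp = scored_screens["parental"]
        p = diff.dgarp_pvalues(sq, sp, small_screen.hairpin_map, B=150, seed=5)
        ssl = small_screen.truth.ssl_genes("query1")
        assert (p.loc[ssl] < 0.05).mean() >= 0.8


class TestPresence:
    def test_bimodal_recovery(self):
        cfg = simulate.ScreenSimConfig(n_genes=1000, seed=21,
                                       frac_not_expressed=0.2)
        screen = simulate.generate_screen(cfg)
        expr, truth = simulate.generate_expression(cfg, screen.truth)
        called = diff.expression_presence(expr)
        accuracy = (called == truth).to_numpy().mean()
        assert accuracy >= 0.99

    def test_degenerate_fallback_all_identical(self):
        expr = pd.DataFrame({"L": [5.0] * 20},
                            index=[f"g{i}" for i in range(20)])
        with pytest.warns(UserWarning):
            called = diff.expression_presence(expr)
        # values equal the 40th-percentile threshold: present by ≥ rule
        assert called["L"].all()

    def test_quantile_method_threshold_boundary(self):
        expr = pd.DataFrame({"L": np.arange(10, dtype=float)},
                            index=[f"g{i}" for i in range(10)])
        called = diff.expression_presence(expr, method="quantile:40")
        thr = np.percentile(expr["L"], 40)
        assert called["L"].equals(expr["L"] >= thr)
        # top 60% of a tie-free ladder is present
        assert called["L"].sum() == 6


class TestCallSsl:
    GENES = pd.Index(["g1", "g2", "g3", "g4"])

    def _records(self, dgarp, p, expressed, alpha=0.05):
        return diff.call_ssl(
            pd.Series(dgarp, index=self.GENES),
            pd.Series(p, index=self.GENES),
            pd.Series(expressed, index=self.GENES),
            "Q1", alpha=alpha,
        )

    def test_rule_and_boundaries(self):
        rec = self._records(
            dgarp=[-2.5, -2.5, -2.5, 1.0],
            p=[0.01, 0.05, 0.01, 0.01],
            expressed=[True, True, False, True],
        ).set_index("gene")
        assert rec.loc["g1", "ssl_call"]           # all three conditions met
        assert not rec.loc["g2", "ssl_call"]       # p = alpha exactly: strict
        assert not rec.loc["g3", "ssl_call"]       # not expressed
        assert not rec.loc["g4", "ssl_call"]       # positive dGARP

    def test_misaligned_ids_rejected(self):
        with pytest.raises(IntegrityError):
            diff.call_ssl(
                pd.Series([-1.0], index=["g1"]),
                pd.Series([0.01], index=["g2"]),
                pd.Series([True], index=["g1"]),
                "Q1",
            )

    @given(st.floats(0.001, 0.2), st.floats(0.001, 0.2))
    @settings(deadline=None, max_examples=30)
    def test_monotone_in_alpha(self, a1, a2):
        lo, hi = sorted([a1, a2])
        rng = np.random.default_rng(0)
        dgarp = pd.Series(rng.normal(size=50), index=range(50))
        p = pd.Series(rng.uniform(0.001, 0.3, size=50), index=range(50))
        ex = pd.Series(True, index=range(50))
        small = diff.call_ssl(dgarp, p, ex, "Q", alpha=lo)
        large = diff.call_ssl(dgarp, p, ex, "Q", alpha=hi)
        s = set(small.loc[small["ssl_call"], "gene"])
        l = set(large.loc[large["ssl_call"], "gene"])
        assert s <= l


class TestCandidates:
    def _inputs(self):
        records = pd.DataFrame(
            {
                "query": "Q1",
                "gene": ["g1", "g2", "g3"],
                "dgarp": [-2.0, -2.0, -3.0],
                "p": [0.01, 0.01, 0.01],
                "expressed_in_query": True,
                "ssl_call": [True, True, True],
            }
        )
        garp_p = pd.Series([0.01, 0.01, 0.01], index=["g1", "g2", "g3"])
        hp = pd.DataFrame({"hairpin": ["h1", "h2", "h3"],
                           "gene": ["g1", "g2", "g3"]})
        sharp_p = pd.Series([0.005, 0.005, 0.005], index=["h1", "h2", "h3"])
        return records, garp_p, sharp_p, hp

    def test_ordering_and_tiebreak(self):
        records, garp_p, sharp_p, hp = self._inputs()
        out = diff.select_confirmation_candidates(records, garp_p, sharp_p, hp)
        assert list(out["gene"]) == ["g3", "g1", "g2"]  # dGARP asc, then gene

    def test_sharp_filter_excludes(self):
        records, garp_p, sharp_p, hp = self._inputs()
        sharp_p["h3"] = 0.5  # no strong hairpin for g3
        out = diff.select_confirmation_candidates(records, garp_p, sharp_p, hp)
        assert "g3" not in set(out["gene"])

    def test_empty_input(self):
        records, garp_p, sharp_p, hp = self._inputs()
        records["ssl_call"] = False
        out = diff.select_confirmation_candidates(records, garp_p, sharp_p, hp)
        assert out.empty


class TestNetwork:
    def _records(self, pairs):
        return pd.DataFrame(
            {
                "query": [q for q, _ in pairs],
                "gene": [g for _, g in pairs],
                "dgarp": -1.0,
                "p": 0.01,
                "expressed_in_query": True,
                "ssl_call": True,
            }
        )

    def test_hand_enumeration(self):
        net = diff.assemble_network(
            self._records([("Q1", "g1"), ("Q1", "g2"), ("Q2", "g1")])
        )
        assert net.n_nodes == 4 and net.n_edges == 3
        g = net.to_networkx()
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 3

    def test_counts_recomputable_from_edge_list(self, small_screen):
        net = diff.assemble_network(
            self._records([("Q1", "g1"), ("Q2", "g2"), ("Q2", "g3")])
        )
        edges = net.edges
        assert net.n_edges == len(edges)
        assert net.n_nodes == len(set(edges["query"]) | set(edges["gene"]))

    def test_empty_and_duplicate(self):
        assert diff.assemble_network(self._records([])).n_edges == 0
        with pytest.raises(IntegrityError):
            diff.assemble_network(self._records([("Q1", "g1"), ("Q1", "g1")]))


class TestModulePropagation:
    def _network(self):
        return diff.assemble_network(
            TestNetwork()._records([("Q1", "a"), ("Q1", "b"), ("Q1", "c")])
        )

    def test_star_without_external(self):
        g = diff.propagate_module(self._network(), "Q1")
        assert g.number_of_edges() == 3
        assert all(d == 1 or n == "Q1" for n, d in g.degree())

    def test_external_edges_inside_only(self):
        ext = pd.DataFrame(
            {"geneA": ["a", "b"], "geneB": ["b", "d"], "source": ["y2h", "lit"]}
        )
        g = diff.propagate_module(self._network(), "Q1", ext)
        assert g.number_of_edges() == 4  # 3 DiE + (a, b)
        assert g.has_edge("a", "b") and not g.has_node("d")
        labels = {d["source"] for _, _, d in g.edges(data=True)}
        assert labels == {"DiE", "y2h"}

    def test_unknown_query_rejected(self):
        with pytest.raises(AnalysisError):
            diff.propagate_module(self._network(), "Q9")


def test_essentiality_vs_expression_categories():
    records = pd.DataFrame(
        {
            "query": "Q1",
            "gene": [f"g{i}" for i in range(6)],
            "dgarp": [-2, -2, -2, 1, 1, 0],
            "ssl_call": [True, True, False, False, False, False],
        }
    )
    fc = pd.Series([2.0, 0.0, 2.0, 2.0, -1.0, 0.5],
                   index=[f"g{i}" for i in range(6)])
    out = diff.essentiality_vs_expression(records, fc).set_index("gene")
    assert out.loc["g0", "category"] == "both"
    assert out.loc["g1", "category"] == "ssl_only"
    assert out.loc["g2", "category"] == "up_in_query_only"
    assert out["category"].value_counts().to_dict() == {
        "both": 1, "ssl_only": 1, "up_in_query_only": 2, "neither": 2
    }
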