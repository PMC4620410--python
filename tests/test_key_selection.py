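"""Key-protein selection: Top-k tie policy, set algebra, pruning, overlap."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seednet import keys as km
from seednet.exceptions import ValidationError
from seednet.io import AnnotationTable, DapRecord, OrthologHit
from seednet.network import SeedMapping


class TestTopK:
    def test_boundary_ties_included(self):
        assert km.top_k({"a": 5, "b": 4, "c": 4, "d": 3}, 2) == {"a", "b", "c"}

    def test_k_at_least_n_returns_all(self):
        vals = {"a": 1, "b": 2, "c": 3}
        assert km.top_k(vals, 3) == set(vals)
        assert km.top_k(vals, 10) == set(vals)

    def test_empty_values(self):
        assert km.top_k({}, 5) == frozenset()

    def test_k_below_one_rejected(self):
        with pytest.raises(ValidationError):
            km.top_k({"a": 1}, 0)

    def test_tie_spill_to_57(self):
        """49 distinct leaders + 8 nodes tied at the rank-50 value -> 57."""
        values = {f"lead{i:02d}": 1000.0 - i for i in range(49)}
        values.update({f"tie{i}": 900.0 for i in range(8)})
        values.update({f"tail{i:03d}": 100.0 - i for i in range(60)})
        result = km.top_k(values, 50)
        assert len(result) == 57
        assert {f"tie{i}" for i in range(8)} <= result

    @given(st.dictionaries(st.text(st.characters(codec="ascii"), min_size=1,
                                   max_size=4),
                           st.integers(-50, 50), max_size=30),
           st.integers(1, 25))
    def test_monotone_in_k(self, values, k):
        assert km.top_k(values, k) <= km.top_k(values, k + 1)

    @given(st.dictionaries(st.integers(0, 40).map(str),
                           st.floats(0.01, 100, allow_nan=False),
                           min_size=1, max_size=30),
           st.integers(1, 10),
           st.floats(0.01, 1000, allow_nan=False))
    def test_positive_scaling_leaves_set_unchanged(self, values, k, c):
        scaled = {v: c * x for v, x in values.items()}
        assert km.top_k(values, k) == km.top_k(scaled, k)


class TestCorrelations:
    def _table(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "degree": rng.integers(1, 20, n).astype(float),
            "betweenness": rng.random(n),
        }, index=[f"v{i}" for i in range(n)])

    def test_duplicated_metric_r_is_one(self):
        t = self._table()
        t["degree2"] = t["degree"]
        corr = km.metric_correlations(t, ["degree", "degree2"])
        assert corr.loc["degree", "degree2"] == pytest.approx(1.0)

    def test_negated_metric_r_is_minus_one(self):
        t = self._table()
        t["neg"] = -t["degree"]
        corr = km.metric_correlations(t, ["degree", "neg"])
        assert corr.loc["degree", "neg"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        t = self._table(seed=5)
        corr = km.metric_correlations(t)
        x = t["degree"].to_numpy()
        y = t["betweenness"].to_numpy()
        cov = ((x - x.mean()) * (y - y.mean())).mean()
        expected = cov / (x.std() * y.std())
        assert corr.loc["degree", "betweenness"] == pytest.approx(expected, abs=1e-12)

    def test_matrix_properties(self):
        t = self._table(seed=7)
        corr = km.metric_correlations(t)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        assert ((corr.to_numpy() >= -1 - 1e-12) &
                (corr.to_numpy() <= 1 + 1e-12)).all()

    def test_zero_variance_metric_named(self):
        t = self._table()
        t["flat"] = 1.0
        with pytest.raises(ValidationError, match="flat"):
            km.metric_correlations(t)

    def test_too_few_nodes(self):
        with pytest.raises(ValidationError):
            km.metric_correlations(self._table(n=2))


class TestSetAlgebra:
    def test_pair_union(self):
        topk = {"x": frozenset({"a", "b"}), "y": frozenset({"b", "c"})}
        assert km.pair_union(topk, ("x", "y")) == {"a", "b", "c"}
        assert km.pair_union(topk, ("x", "x")) == {"a", "b"}

    def test_pair_union_unknown_metric(self):
        with pytest.raises(ValidationError):
            km.pair_union({"x": frozenset()}, ("x", "zzz"))

    def test_pool_candidates_is_union(self):
        pair_sets = {"p1": frozenset({"a", "b"}), "p2": frozenset({"b", "c"})}
        assert km.pool_candidates(pair_sets) == {"a", "b", "c"}

    def test_disjoint_pair_sets_add_up(self):
        a = frozenset(f"a{i}" for i in range(74))
        b = frozenset(f"b{i}" for i in range(50))
        pooled = km.pool_candidates({"p1": a, "p2": b})
        assert len(pooled) == 124

    @given(st.sets(st.integers(0, 30).map(str)),
           st.sets(st.integers(0, 30).map(str)))
    def test_venn_partitions_the_union(self, a, b):
        only_a, only_b, both = km.venn_counts(a, b)
        assert only_a + only_b + both == len(a | b)
        assert (only_a, only_b, both) == (len(a - b), len(b - a), len(a & b))

    def test_venn_examples(self):
        assert km.venn_counts({"1", "2", "3"}, {"3", "4"}) == (2, 1, 1)
        assert km.venn_counts({"1"}, {"2"}) == (1, 1, 0)


class TestPruning:
    ANN = AnnotationTable(
        [("p1", "GO:0001", "BP"), ("p2", "GO:0002", "MF"), ("p3", "GO:0003", "BP")],
        term_labels={"GO:0001": "cell cycle regulation",
                     "GO:0002": "generic annotation",
                     "GO:0003": "hormone signaling"})

    def test_keyword_match_on_term_label(self):
        kept, matched = km.prune_by_relevance(
            {"p1", "p2"}, self.ANN, ["cell cycle"])
        assert kept == {"p1"}
        assert matched["p1"] == "cell cycle"

    def test_unannotated_candidate_dropped(self):
        kept, _ = km.prune_by_relevance({"orphan"}, self.ANN, ["cell cycle"])
        assert kept == frozenset()

    def test_wildcard_keeps_everything(self):
        kept, _ = km.prune_by_relevance({"p1", "p2", "orphan"}, self.ANN, ["*"])
        assert kept == {"p1", "p2", "orphan"}

    def test_protein_label_matching(self):
        kept, _ = km.prune_by_relevance(
            {"p2"}, self.ANN, ["glucanase"],
            protein_labels={"p2": "beta-1,3-glucanase"})
        assert kept == {"p2"}

    def test_empty_keywords_rejected(self):
        with pytest.raises(ValidationError):
            km.prune_by_relevance({"p1"}, self.ANN, [])


class TestDapOverlap:
    # eight mapped seed proteins, four up- and four down-accumulated
    TABLE = [
        ("007", "Internal NAD(P)H dehydrogenase", "At1g07180", "up"),
        ("049", "Heat shock protein 60-3A", "At3g13860", "up"),
        ("056", "RAS-related nuclear protein", "At5g20010", "up"),
        ("059", "Enhancer of glabra 3", "At1g63650", "up"),
        ("017", "Cyclin-dependent kinase A-1", "At3g48750", "down"),
        ("045", "Geminivirus rep interacting kinase 1", "At3g45240", "down"),
        ("081", "30S ribosomal protein S3", "AtCg00800", "down"),
        ("087", "Cell division control protein 2 homolog 1", "At3g54180", "down"),
    ]

    def _fixture(self):
        daps = [DapRecord(s, name, reg, f"q{s}") for s, name, node, reg in self.TABLE]
        mapping = SeedMapping(
            mapped={f"q{s}": node for s, _, node, _ in self.TABLE},
            unmapped=[],
            hit_used={f"q{s}": OrthologHit(f"q{s}", node, 1e-30, 200.0)
                      for s, _, node, _ in self.TABLE})
        return daps, mapping

    def test_eight_overlaps_split_four_four(self):
        daps, mapping = self._fixture()
        keys = {node for _, _, node, _ in self.TABLE} | {"extraA", "extraB"}
        overlap = km.overlap_with_daps(keys, mapping, daps)
        assert len(overlap) == 8
        counts = km.regulation_counts(overlap)
        assert counts == {"up": 4, "down": 4}

    def test_disjoint_key_set_gives_empty_overlap(self):
        daps, mapping = self._fixture()
        assert km.overlap_with_daps({"nothing"}, mapping, daps) == ()

    def test_all_seeds_in_key_set(self):
        daps, mapping = self._fixture()
        overlap = km.overlap_with_daps(set(mapping.mapped.values()), mapping, daps)
        assert {o.node for o in overlap} == set(mapping.mapped.values())


class TestReport:
    def test_report_invariants_on_synthetic_table(self):
        rng = np.random.default_rng(9)
        n = 120
        table = pd.DataFrame({
            "degree": rng.integers(1, 40, n).astype(float),
            "betweenness": rng.random(n),
            "closeness": rng.random(n),
            "radiality": rng.random(n) + 1,
        }, index=[f"v{i:03d}" for i in range(n)])
        report = km.build_key_report(table, k=20, keywords=["*"])
        report.check_invariants()
        assert report.key_proteins == report.candidates
        assert sum(report.venn) == len(
            (report.pair_sets["degree+betweenness"] |
             report.pair_sets["closeness+radiality"]) & report.key_proteins)
        for m, s in report.topk.items():
            assert len(s) >= 20
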