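"""Fisher over-representation, elim decorrelation and the ratio/FDR filter."""

from itertools import combinations
from math import comb

import numpy as np
import pytest

from fermtx.enrichment import (
    EnrichmentRecord,
    OntologyDAG,
    elim_decorrelate,
    finalize,
    fisher_ora,
)


def star_dag(term_genes, genes):
    """All terms children of a root; annotation per term."""
    parents = {"root": set()}
    annotation = {g: set() for g in genes}
    for term, members in term_genes.items():
        parents[term] = {"root"}
        for g in members:
            annotation[g].add(term)
    return OntologyDAG(parents, annotation)


class TestFisher:
    def test_whole_background_term_is_null(self):
        genes = [f"g{i}" for i in range(20)]
        dag = star_dag({"T1": genes}, genes)
        recs = fisher_ora(set(genes[:5]), set(genes), dag, min_term_size=10)
        (rec,) = [r for r in recs if r.term_id == "T1"]
        assert rec.ratio == pytest.approx(1.0)
        assert rec.p == pytest.approx(1.0)

    def test_closed_form_extreme_enrichment(self):
        # N=20, K=10, n=10, observed=10: p = 1 / C(20,10)
        genes = [f"g{i}" for i in range(20)]
        dag = star_dag({"T1": genes[:10]}, genes)
        recs = fisher_ora(set(genes[:10]), set(genes), dag, min_term_size=10)
        (rec,) = [r for r in recs if r.term_id == "T1"]
        assert rec.p == pytest.approx(1 / comb(20, 10), rel=1e-12)
        assert rec.expected == pytest.approx(5.0)
        assert rec.ratio == pytest.approx(2.0)

    def test_matches_exhaustive_enumeration_for_small_backgrounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            N = int(rng.integers(5, 13))
            genes = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            term = set(rng.choice(genes, size=K, replace=False))
            query = set(rng.choice(genes, size=n, replace=False))
            dag = star_dag({"T1": term}, genes)
            recs = fisher_ora(query, set(genes), dag, min_term_size=1)
            (rec,) = [r for r in recs if r.term_id == "T1"]
            obs = len(term & query)
            # exhaustive oracle: enumerate every possible draw of size n
            hits = sum(
                1 for draw in combinations(genes, n) if len(term & set(draw)) >= obs
            )
            assert rec.p == pytest.approx(hits / comb(N, n), rel=1e-9)

    def test_query_outside_background_rejected(self):
        genes = [f"g{i}" for i in range(12)]
        dag = star_dag({"T1": genes}, genes)
        with pytest.raises(ValueError, match="subset"):
            fisher_ora({"missing"}, set(genes), dag)

    def test_min_term_size_excludes_small_terms(self):
        genes = [f"g{i}" for i in range(20)]
        dag = star_dag({"small": genes[:3], "big": genes[:12]}, genes)
        recs = fisher_ora(set(genes[:4]), set(genes), dag, min_term_size=10)
        assert {r.term_id for r in recs} >= {"big"}
        assert "small" not in {r.term_id for r in recs}


class TestElim:
    def test_significant_child_strips_parent(self):
        # all query signal lives in the child; after elimination the
        # parent's observed count drops to the residual and it loses
        # significance
        child_genes = [f"c{i}" for i in range(10)]
        extra = [f"p{i}" for i in range(10)]
        others = [f"o{i}" for i in range(80)]
        genes = child_genes + extra + others
        parents = {"root": set(), "parent": {"root"}, "child": {"parent"}}
        annotation = {g: set() for g in genes}
        for g in child_genes:
            annotation[g].add("child")
        for g in extra:
            annotation[g].add("parent")
        dag = OntologyDAG(parents, annotation)
        query = set(child_genes)
        raw = {r.term_id: r for r in fisher_ora(query, set(genes), dag, min_term_size=5)}
        elim = {
            r.term_id: r
            for r in elim_decorrelate(query, set(genes), dag, min_term_size=5, elim_alpha=0.01)
        }
        assert raw["child"].p < 0.01
        assert raw["parent"].observed == 10
        assert elim["parent"].observed == 0
        assert elim["parent"].p > 0.5
        assert elim["child"].p == raw["child"].p  # leaves untouched

    def test_no_significance_means_no_change(self):
        genes = [f"g{i}" for i in range(30)]
        parents = {"root": set(), "a": {"root"}, "b": {"a"}}
        annotation = {g: ({"b"} if i < 12 else set()) for i, g in enumerate(genes)}
        dag = OntologyDAG(parents, annotation)
        query = set(genes[10:14])  # weak overlap, nothing significant
        raw = fisher_ora(query, set(genes), dag, min_term_size=5)
        elim = elim_decorrelate(query, set(genes), dag, min_term_size=5, elim_alpha=0.01)
        assert {(r.term_id, r.observed, r.p) for r in raw} == {
            (r.term_id, r.observed, r.p) for r in elim
        }

    def test_flat_dag_siblings_untouched(self):
        genes = [f"g{i}" for i in range(40)]
        dag = star_dag({"A": genes[:10], "B": genes[10:20]}, genes)
        query = set(genes[:10])
        raw = {r.term_id: r.p for r in fisher_ora(query, set(genes), dag, min_term_size=5)}
        elim = {
            r.term_id: r.p
            for r in elim_decorrelate(query, set(genes), dag, min_term_size=5)
        }
        assert elim["A"] == raw["A"] and elim["B"] == raw["B"]

    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cycle"):
            OntologyDAG({"a": {"b"}, "b": {"a"}}, {})


class TestFinalize:
    def _rec(self, term, ratio, p):
        return EnrichmentRecord(
            term_id=term, contrast="c", direction="up",
            observed=4, expected=4 / ratio if ratio else 1, ratio=ratio, p=p,
        )

    def test_single_strong_record_significant(self):
        (out,) = finalize([self._rec("T1", 4.0, 0.001)])
        assert out.fdr == pytest.approx(0.001) and out.significant

    def test_low_ratio_records_filtered_from_report(self):
        out = finalize([self._rec("T1", 1.5, 1e-10), self._rec("T2", 3.0, 0.02)])
        # the low-ratio record is dropped from the report and can never be
        # significant, but it still counts toward the BH family size
        assert [r.term_id for r in out] == ["T2"]
        assert out[0].fdr == pytest.approx(0.02)

    def test_empty_input(self):
        assert finalize([]) == []
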