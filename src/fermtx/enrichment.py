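"""Gene-set over-representation on an ontology DAG with elim decorrelation.

For each contrast, the significantly up- and down-regulated genes are
tested separately against the background of expressed genes with a
one-sided Fisher (hypergeometric tail) test per term.  The hierarchy of
the ontology is decorrelated bottom-up with the elim strategy: once a
term tests below the elimination cutoff, its genes are removed from all
ancestors' gene sets before those are tested.  Records below a minimum
observed/expected ratio are dropped before Benjamini-Hochberg adjustment
(the ratio filter precedes the FDR step).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


class OntologyDAG:
    """A rooted acyclic term hierarchy plus direct gene annotations.

    ``parents`` maps each term to its is-a parents; gene annotation is
    closed upward on demand (a gene annotated to a term is annotated to
    every ancestor).
    """

    def __init__(
        self,
        parents: Dict[str, Set[str]],
        annotation: Dict[str, Set[str]],
        names: Optional[Dict[str, str]] = None,
    ) -> None:
        self.graph = nx.DiGraph()  # edges child -> parent
        terms = set(parents)
        for ps in parents.values():
            terms |= ps
        self.graph.add_nodes_from(terms)
        for child, ps in parents.items():
            for p in ps:
                self.graph.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology contains a cycle")
        self.annotation = {g: set(ts) for g, ts in annotation.items()}
        self.names = names or {}
        unknown = set().union(*self.annotation.values()) - terms if annotation else set()
        if unknown:
            raise ValueError(f"annotation references unknown terms: {sorted(unknown)[:5]}")
        self._closure: Dict[str, FrozenSet[str]] = {}

    @property
    def terms(self) -> List[str]:
        return sorted(self.graph.nodes)

    def ancestors(self, term: str) -> Set[str]:
        return set(nx.descendants(self.graph, term))  # edges point child->parent

    def term_closure(self, term: str) -> Set[str]:
        """The term and everything above it."""
        return {term} | self.ancestors(term)

    def gene_terms(self, gene: str) -> FrozenSet[str]:
        """All terms a gene is annotated to, after upward closure."""
        if gene not in self._closure:
            direct = self.annotation.get(gene, set())
            closed: Set[str] = set()
            for t in direct:
                closed |= self.term_closure(t)
            self._closure[gene] = frozenset(closed)
        return self._closure[gene]

    def genes_of_term(self, term: str, universe: Iterable[str]) -> Set[str]:
        """Genes of ``universe`` annotated (after closure) to ``term``."""
        return {g for g in universe if term in self.gene_terms(g)}

    def depths(self) -> Dict[str, int]:
        """Longest path from each term up to a root (roots have depth 0)."""
        order = list(nx.topological_sort(self.graph))  # children before parents
        depth: Dict[str, int] = {}
        for node in reversed(order):  # roots first
            preds = list(self.graph.successors(node))  # parents
            depth[node] = 0 if not preds else 1 + max(depth[p] for p in preds)
        return depth

    @classmethod
    def from_edge_list(
        cls, path: str, annotation: Dict[str, Set[str]]
    ) -> "OntologyDAG":
        """Read a (child, parent) two-column TSV."""
        parents: Dict[str, Set[str]] = {}
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                child, parent = line.split("\t")[:2]
                parents.setdefault(child, set()).add(parent)
                parents.setdefault(parent, set())
        return cls(parents, annotation)

    @classmethod
    def from_obo_lite(cls, path: str, annotation: Dict[str, Set[str]]) -> "OntologyDAG":
        """Read a minimal OBO dialect: [Term] stanzas with id/name/is_a."""
        parents: Dict[str, Set[str]] = {}
        names: Dict[str, str] = {}
        current: Optional[str] = None
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if line == "[Term]":
                    current = None
                elif line.startswith("id:"):
                    current = line[3:].strip()
                    parents.setdefault(current, set())
                elif line.startswith("name:") and current:
                    names[current] = line[5:].strip()
                elif line.startswith("is_a:") and current:
                    target = line[5:].strip().split("!")[0].strip()
                    parents[current].add(target)
                    parents.setdefault(target, set())
        return cls(parents, annotation, names)


def read_gene_annotation(path: str) -> Dict[str, Set[str]]:
    """Read a gene<TAB>term mapping (one pair per line)."""
    mapping: Dict[str, Set[str]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            mapping.setdefault(gene, set()).add(term)
    return mapping


@dataclass
class EnrichmentRecord:
    term_id: str
    contrast: str
    direction: str  # "up" or "down"
    observed: int
    expected: float
    ratio: float
    p: float
    fdr: float = float("nan")
    significant: bool = False


def split_gene_sets(
    results, contrast: str, genes: Optional[Iterable[str]] = None
) -> Tuple[Set[str], Set[str], Set[str]]:
    """(up, down, background) gene sets for one contrast.

    up/down = significant in the contrast with positive/negative log2FC;
    background = the expressed features.  ``genes`` optionally restricts
    everything to a subset (e.g. coding genes with ontology coverage).
    """
    sig = results.significant[contrast]
    lfc = results.log2fc[contrast]
    expressed = results.expressed
    universe = set(expressed.index[expressed])
    if genes is not None:
        universe &= set(genes)
    up = {g for g in universe if sig.get(g, False) and lfc.get(g, 0) > 0}
    down = {g for g in universe if sig.get(g, False) and lfc.get(g, 0) < 0}
    return up, down, universe


def _fisher_term(
    term: str, term_genes: Set[str], query: Set[str], n_bg: int
) -> Tuple[int, float, float, float]:
    K = len(term_genes)
    obs = len(term_genes & query)
    n = len(query)
    expected = n * K / n_bg
    p = float(hypergeom.sf(obs - 1, n_bg, K, n))
    ratio = obs / expected if expected > 0 else float("inf")
    return obs, expected, ratio, p


def fisher_ora(
    query: Set[str],
    background: Set[str],
    dag: OntologyDAG,
    min_term_size: int = 10,
) -> List[EnrichmentRecord]:
    """One-sided hypergeometric over-representation per term (no elim).

    Terms with fewer than ``min_term_size`` background genes (after upward
    closure of the annotation) are skipped.
    """
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    records = []
    for term in dag.terms:
        term_genes = dag.genes_of_term(term, background)
        if len(term_genes) < min_term_size:
            continue
        obs, expected, ratio, p = _fisher_term(term, term_genes, query, len(background))
        records.append(
            EnrichmentRecord(
                term_id=term, contrast="", direction="",
                observed=obs, expected=expected, ratio=ratio, p=p,
            )
        )
    return records


def elim_decorrelate(
    query: Set[str],
    background: Set[str],
    dag: OntologyDAG,
    min_term_size: int = 10,
    elim_alpha: float = 0.01,
) -> List[EnrichmentRecord]:
    """Fisher tests with bottom-up elim decorrelation of the hierarchy.

    Terms are processed from the deepest level upward.  Whenever a term's
    p-value (on its current, possibly reduced gene set) falls below
    ``elim_alpha``, its genes are removed from every ancestor's gene set
    before the ancestors are tested.  Term eligibility (minimum size) is
    determined on the original closed sets.
    """
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    n_bg = len(background)
    depth = dag.depths()
    current: Dict[str, Set[str]] = {}
    eligible: List[str] = []
    for term in dag.terms:
        genes = dag.genes_of_term(term, background)
        if len(genes) >= min_term_size:
            eligible.append(term)
            current[term] = set(genes)
    records = []
    for term in sorted(eligible, key=lambda t: (-depth[t], t)):
        obs, expected, ratio, p = _fisher_term(term, current[term], query, n_bg)
        records.append(
            EnrichmentRecord(
                term_id=term, contrast="", direction="",
                observed=obs, expected=expected, ratio=ratio, p=p,
            )
        )
        if p < elim_alpha:
            removed = dag.genes_of_term(term, background)
            for anc in dag.ancestors(term):
                if anc in current:
                    current[anc] -= removed
    records.sort(key=lambda r: r.term_id)
    return records


def finalize(
    records: Sequence[EnrichmentRecord],
    ratio_min: float = 2.0,
    fdr_alpha: float = 0.01,
) -> List[EnrichmentRecord]:
    """BH-adjust the run's records and keep those passing the ratio filter.

    The Benjamini-Hochberg family is the full set of terms tested in the
    run; the observed/expected ratio filter then decides which records are
    reported and eligible for significance (``significant`` requires both
    ratio >= ratio_min and fdr < fdr_alpha).  Adjusting over the full
    family keeps the FDR guarantee intact — shrinking the family to the
    high-ratio survivors first would select for small p-values and inflate
    the error rate.
    """
    records = list(records)
    if not records:
        return []
    fdr = multipletests([r.p for r in records], method="fdr_bh")[1]
    out = []
    for r, q in zip(records, fdr):
        if r.ratio < ratio_min:
            continue
        out.append(
            EnrichmentRecord(
                term_id=r.term_id, contrast=r.contrast, direction=r.direction,
                observed=r.observed, expected=r.expected, ratio=r.ratio,
                p=r.p, fdr=float(q), significant=bool(q < fdr_alpha),
            )
        )
    return out


def enrichment_analysis(
    results,
    dag: OntologyDAG,
    contrasts: Optional[Sequence[str]] = None,
    genes: Optional[Iterable[str]] = None,
    min_term_size: int = 10,
    elim_alpha: float = 0.01,
    ratio_min: float = 2.0,
    fdr_alpha: float = 0.01,
) -> pd.DataFrame:
    """Run the full per-(contrast, direction) over-representation cascade."""
    if contrasts is None:
        contrasts = [c.label for c in results.contrasts]
    rows = []
    for contrast in contrasts:
        up, down, background = split_gene_sets(results, contrast, genes=genes)
        for direction, query in (("up", up), ("down", down)):
            if not query:
                continue
            recs = elim_decorrelate(
                query, background, dag,
                min_term_size=min_term_size, elim_alpha=elim_alpha,
            )
            for r in finalize(recs, ratio_min=ratio_min, fdr_alpha=fdr_alpha):
                rows.append(
                    {
                        "term_id": r.term_id,
                        "contrast": contrast,
                        "direction": direction,
                        "observed": r.observed,
                        "expected": r.expected,
                        "ratio": r.ratio,
                        "p": r.p,
                        "fdr": r.fdr,
                        "significant": r.significant,
                    }
                )
    columns = [
        "term_id", "contrast", "direction", "observed",
        "expected", "ratio", "p", "fdr", "significant",
    ]
    return pd.DataFrame(rows, columns=columns)
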