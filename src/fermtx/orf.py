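"""ORF prediction benchmarking and ORF-vs-gap overlap tabulation.

Predicted open reading frames are scored against known coding genes by
interval Jaccard similarity (same strand, similarity strictly above a
cutoff, default 0.9): recall is the fraction of genes matched by some ORF,
precision the fraction of ORFs matching some gene.  ORFs that match no
gene are then tabulated against unannotated gaps (strand-agnostic, since
antisense placements occur) with the overlap expressed as a percent of
the ORF length, annotated by the gap's expression category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd

from .annotation import AnnotationSet, Feature, GapRegion
from .intervals import Interval, jaccard, overlap_fraction


@dataclass(frozen=True)
class ORFRecord:
    orf_id: str
    interval: Interval

    @property
    def length(self) -> int:
        return self.interval.length


def as_orf_records(orfs: Iterable[Feature]) -> List[ORFRecord]:
    return [ORFRecord(f.feature_id, f.interval) for f in orfs]


@dataclass
class BenchmarkReport:
    n_orfs: int
    n_genes: int
    n_recalled: int
    n_matching_orfs: int
    recalled_gene_ids: List[str]
    matching_orf_ids: List[str]

    @property
    def recall_pct(self) -> float:
        return round(100.0 * self.n_recalled / self.n_genes, 1)

    @property
    def precision_pct(self) -> float:
        return round(100.0 * self.n_matching_orfs / self.n_orfs, 1)


def benchmark_orfs(
    orfs: Sequence[ORFRecord],
    genes: Sequence[Feature],
    jaccard_min: float = 0.9,
) -> BenchmarkReport:
    """Score ORF predictions against coding genes by Jaccard similarity.

    A gene is recalled iff some same-strand ORF overlaps it with Jaccard
    strictly greater than ``jaccard_min``; an ORF matches iff it recalls
    some gene.  Percentages are rounded to one decimal.
    """
    by_key: Dict[tuple, List[ORFRecord]] = {}
    for orf in orfs:
        by_key.setdefault((orf.interval.contig, orf.interval.strand), []).append(orf)
    for lst in by_key.values():
        lst.sort(key=lambda o: o.interval.start)

    recalled: List[str] = []
    matching: set = set()
    for gene in genes:
        gi = gene.interval
        hit = False
        for orf in by_key.get((gi.contig, gi.strand), []):
            if orf.interval.start >= gi.end:
                break
            if jaccard(orf.interval, gi) > jaccard_min:
                hit = True
                matching.add(orf.orf_id)
        if hit:
            recalled.append(gene.feature_id)
    return BenchmarkReport(
        n_orfs=len(orfs),
        n_genes=len(genes),
        n_recalled=len(recalled),
        n_matching_orfs=len(matching),
        recalled_gene_ids=recalled,
        matching_orf_ids=sorted(matching),
    )


def orf_gap_table(
    orfs: Sequence[ORFRecord],
    gaps: Sequence[GapRegion],
    nptr_status: Mapping[str, bool],
    de_status: Optional[Mapping[str, bool]] = None,
) -> pd.DataFrame:
    """Tabulate positive ORF-gap overlaps for gene-free ORFs.

    Overlaps are strand-agnostic.  One row per (ORF, gap) pair with
    positive overlap: gap id and length, ORF coordinates and length, the
    percent of the ORF inside the gap (1 decimal), and a category derived
    from the gap's NPTR call and differential-expression status.
    """
    de_status = de_status or {}
    rows = []
    for orf in orfs:
        for gap in gaps:
            pct = overlap_fraction(orf.interval, gap.interval, denominator="query")
            if pct <= 0:
                continue
            if nptr_status.get(gap.gap_id, False):
                if de_status.get(gap.gap_id, False):
                    category = "NPTR with diff. expr."
                else:
                    category = "NPTR without diff. expr."
            else:
                category = "Low expression"
            rows.append(
                {
                    "category": category,
                    "gap_id": gap.gap_id,
                    "gap_length": gap.length,
                    "orf_id": orf.orf_id,
                    "orf_start": orf.interval.start,
                    "orf_end": orf.interval.end,
                    "orf_strand": orf.interval.strand,
                    "orf_length": orf.length,
                    "pct_orf_within_gap": pct,
                }
            )
    columns = [
        "category", "gap_id", "gap_length", "orf_id", "orf_start",
        "orf_end", "orf_strand", "orf_length", "pct_orf_within_gap",
    ]
    out = pd.DataFrame(rows, columns=columns)
    return out.sort_values(
        ["pct_orf_within_gap", "gap_id", "orf_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
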