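"""Count normalization, gap expression and novel-transcribed-region calls.

Counts live in a pandas DataFrame (features x samples, non-negative
integers) accompanied by a sample sheet describing the 2-strain x
6-timepoint x 3-replicate fed-batch design and the sequencing batches.
Normalization is the median-of-ratios size-factor estimator; a gap is
called a novel potentially transcribed region (NPTR) when its mean
size-factor-normalized read coverage across all samples reaches a fold
threshold (default 4x at 50 bp reads).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, GapRegion
from .intervals import Interval

TIMEPOINTS = (21, 26, 45, 71, 94, 118)
STRAINS = ("control", "prsA")

SAMPLESHEET_COLUMNS = ("sample_id", "strain", "timepoint", "replicate", "batch")


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check and normalize a sample sheet.

    Requires unique sample ids, strains from {control, prsA}, and at least
    one replicate for every (strain, timepoint) combination present.
    """
    missing = set(SAMPLESHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    sheet = sheet.copy()
    sheet["timepoint"] = sheet["timepoint"].astype(int)
    sheet["replicate"] = sheet["replicate"].astype(int)
    sheet["sample_id"] = sheet["sample_id"].astype(str)
    if sheet["sample_id"].duplicated().any():
        raise ValueError("sample_ids must be unique")
    bad = set(sheet["strain"]) - set(STRAINS)
    if bad:
        raise ValueError(f"unknown strains {sorted(bad)}; expected {STRAINS}")
    if sheet["batch"].isna().any():
        raise ValueError("every sample needs a batch label")
    return sheet


def read_sample_sheet(path: str) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t"))


def read_counts(path: str) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    return validate_counts(counts)


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.isna().any().any():
        raise ValueError("count matrix has missing cells")
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    return counts.astype(np.int64)


def write_counts(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over reference features i of k_ij / g_i where g_i is the
    geometric mean of feature i across samples; features with any zero
    count are excluded from the reference.  Errors out if no feature is
    positive in every sample (no pseudo-reference fallback is provided).
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in all samples; size factors are "
            "undefined (pseudo-reference fallback is disabled)"
        )
    ref = arr[positive]
    log_geo = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geo[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    return counts / sf.reindex(counts.columns)


def assign_reads(
    read_alignments: Iterable[Interval],
    features: AnnotationSet,
    min_overlap_fraction: float = 0.5,
) -> pd.Series:
    """Count reads per feature under the fractional-overlap rule.

    A read increments a feature when their strands match and the overlap
    covers at least ``min_overlap_fraction`` of the read length.  A read
    satisfying the rule for several features (e.g. a cis-regulatory RNA
    structure overlapping a CDS) increments each of them, so such reads are
    deliberately counted more than once.
    """
    counts = {f.feature_id: 0 for f in features}
    feats = sorted(features, key=lambda f: (f.interval.contig, f.interval.start))
    for read in read_alignments:
        need = min_overlap_fraction * read.length
        for f in feats:
            if f.interval.contig != read.contig or f.interval.strand != read.strand:
                continue
            if read.overlap_length(f.interval) >= need:
                counts[f.feature_id] += 1
    return pd.Series(counts, name="count", dtype=np.int64)


@dataclass(frozen=True)
class CoverageSummary:
    """Mean normalized expression of one gap and its NPTR call."""

    gap_id: str
    mean_normalized_count: float
    mean_coverage: float
    is_nptr: bool


def call_nptrs(
    gap_counts: pd.DataFrame,
    gaps: Sequence[GapRegion],
    sf: pd.Series,
    read_length: int = 50,
    coverage_threshold: float = 4.0,
    statistic: str = "mean",
) -> List[CoverageSummary]:
    """Call novel potentially transcribed regions by mean coverage.

    coverage(g) = statistic over samples j of (k_gj / s_j) * read_length /
    length(g); the call is inclusive (coverage >= threshold).  The gap is
    the unit — no narrowing to covered sub-regions.  ``statistic`` is
    "mean" (default, averaging over all samples) or "max".
    """
    if statistic not in ("mean", "max"):
        raise ValueError("statistic must be 'mean' or 'max'")
    if set(gap_counts.columns) != set(sf.index):
        raise ValueError("size factors do not match gap count samples")
    by_id = {g.gap_id: g for g in gaps}
    missing = set(gap_counts.index) - set(by_id)
    if missing:
        raise ValueError(f"gap counts for unknown gaps: {sorted(missing)[:5]}")
    norm = gap_counts / sf.reindex(gap_counts.columns)
    summaries = []
    for gap_id in sorted(gap_counts.index):
        gap = by_id[gap_id]
        per_sample_cov = norm.loc[gap_id] * read_length / gap.length
        cov = float(per_sample_cov.mean() if statistic == "mean" else per_sample_cov.max())
        summaries.append(
            CoverageSummary(
                gap_id=gap_id,
                mean_normalized_count=float(norm.loc[gap_id].mean()),
                mean_coverage=cov,
                is_nptr=cov >= coverage_threshold,
            )
        )
    return summaries


def coverage_table(summaries: Sequence[CoverageSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gap_id": [s.gap_id for s in summaries],
            "mean_normalized_count": [s.mean_normalized_count for s in summaries],
            "mean_coverage": [s.mean_coverage for s in summaries],
            "is_nptr": [s.is_nptr for s in summaries],
        }
    ).set_index("gap_id")
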