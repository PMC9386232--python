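"""Genome annotation container, GFF3/BED I/O and stranded gap extraction.

The annotation model is deliberately small: features carry a closed biotype
vocabulary (coding sequences, the non-coding RNA classes of a bacterial
transcript atlas, and ``other`` for everything else).  Gaps are the maximal
per-strand unannotated stretches between features; regions longer than a
minimum length are candidate novel transcribed regions for the coverage
caller in :mod:`fermtx.quantify`.

GFF3 is read and written with an in-package 9-column parser so that
``write_gff(read_gff(f))`` is byte-identical on canonically written files;
coordinates convert between GFF3's 1-based inclusive convention and the
internal 0-based half-open one at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Tuple, Union

from .intervals import STRANDS, Interval, complement_intervals

#: Closed biotype vocabulary.
BIOTYPES = (
    "CDS",
    "NPTR",
    "putative_ncRNA",
    "riboswitch",
    "tRNA",
    "sRNA",
    "asRNA",
    "SRP",
    "UTR",
    "transcript",
    "other",
)

# GFF3 feature-type column -> biotype.  Anything unlisted maps to "other"
# unless a biotype=... attribute overrides it.
_TYPE_TO_BIOTYPE = {
    "CDS": "CDS",
    "NPTR": "NPTR",
    "putative_ncRNA": "putative_ncRNA",
    "ncRNA": "putative_ncRNA",
    "riboswitch": "riboswitch",
    "tRNA": "tRNA",
    "sRNA": "sRNA",
    "asRNA": "asRNA",
    "antisense_RNA": "asRNA",
    "SRP": "SRP",
    "SRP_RNA": "SRP",
    "UTR": "UTR",
    "five_prime_UTR": "UTR",
    "three_prime_UTR": "UTR",
    "transcript": "transcript",
    "mRNA": "transcript",
}
_BIOTYPE_TO_TYPE = {
    "CDS": "CDS",
    "NPTR": "NPTR",
    "putative_ncRNA": "putative_ncRNA",
    "riboswitch": "riboswitch",
    "tRNA": "tRNA",
    "sRNA": "sRNA",
    "asRNA": "asRNA",
    "SRP": "SRP",
    "UTR": "UTR",
    "transcript": "transcript",
    "other": "region",
}


@dataclass(frozen=True)
class Feature:
    """One annotated element: an interval plus identity and biotype."""

    interval: Interval
    feature_id: str
    biotype: str = "other"
    name: str = ""

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")


@dataclass
class AnnotationSet:
    """A collection of features plus the lengths of their contigs."""

    features: List[Feature] = field(default_factory=list)
    contig_lengths: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for f in self.features:
            if f.feature_id in seen:
                raise ValueError(f"duplicate feature_id {f.feature_id!r}")
            seen.add(f.feature_id)
            self._check_fits(f)

    def _check_fits(self, f: Feature) -> None:
        length = self.contig_lengths.get(f.interval.contig)
        if length is not None and f.interval.end > length:
            raise ValueError(
                f"feature {f.feature_id!r} ends at {f.interval.end} beyond "
                f"contig {f.interval.contig!r} length {length}"
            )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def by_biotype(self, biotype: str) -> List[Feature]:
        return [f for f in self.features if f.biotype == biotype]


@dataclass(frozen=True)
class GapRegion:
    """A maximal stranded unannotated stretch between features."""

    gap_id: str
    interval: Interval

    @property
    def length(self) -> int:
        return self.interval.length


class GFFError(ValueError):
    pass


def _parse_attributes(text: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise GFFError(f"malformed attribute {part!r}")
        key, value = part.split("=", 1)
        attrs[key] = value
    return attrs


def read_gff(path_or_handle: Union[str, TextIO]) -> AnnotationSet:
    """Read a GFF3 file (1-based inclusive) into an :class:`AnnotationSet`.

    Contig lengths come from ``##sequence-region`` pragmas.  The biotype is
    taken from a ``biotype=`` attribute when present, otherwise mapped from
    the feature-type column; unknown types become ``other``.
    """
    if isinstance(path_or_handle, str):
        with open(path_or_handle) as handle:
            return _read_gff_handle(handle)
    return _read_gff_handle(path_or_handle)


def _read_gff_handle(handle: TextIO) -> AnnotationSet:
    contig_lengths: Dict[str, int] = {}
    features: List[Feature] = []
    n_anon = 0
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) != 4:
                raise GFFError(f"line {lineno}: malformed ##sequence-region")
            contig_lengths[parts[1]] = int(parts[3])
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GFFError(f"line {lineno}: expected 9 tab-separated columns")
        contig, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = cols
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise GFFError(f"line {lineno}: non-integer coordinates") from exc
        if end1 < start1:
            raise GFFError(f"line {lineno}: end {end1} < start {start1}")
        if strand not in STRANDS:
            raise GFFError(f"line {lineno}: strand must be + or -, got {strand!r}")
        attrs = _parse_attributes(attr_s)
        biotype = attrs.get("biotype", _TYPE_TO_BIOTYPE.get(ftype, "other"))
        if biotype not in BIOTYPES:
            biotype = "other"
        feature_id = attrs.get("ID")
        if feature_id is None:
            n_anon += 1
            feature_id = f"feature-{n_anon}"
        features.append(
            Feature(
                interval=Interval(contig, start1 - 1, end1, strand),
                feature_id=feature_id,
                biotype=biotype,
                name=attrs.get("Name", ""),
            )
        )
    return AnnotationSet(features=features, contig_lengths=contig_lengths)


def write_gff(annotations: AnnotationSet, path_or_handle: Union[str, TextIO]) -> None:
    """Write an :class:`AnnotationSet` as canonical GFF3 (1-based inclusive).

    Features are sorted by (contig, start, end, strand, id) and attributes
    are emitted in a fixed order, so read→write is a fixed point.
    """
    if isinstance(path_or_handle, str):
        with open(path_or_handle, "w") as handle:
            _write_gff_handle(annotations, handle)
    else:
        _write_gff_handle(annotations, path_or_handle)


def _write_gff_handle(annotations: AnnotationSet, handle: TextIO) -> None:
    handle.write("##gff-version 3\n")
    for contig in sorted(annotations.contig_lengths):
        handle.write(
            f"##sequence-region {contig} 1 {annotations.contig_lengths[contig]}\n"
        )
    ordered = sorted(
        annotations.features,
        key=lambda f: (
            f.interval.contig,
            f.interval.start,
            f.interval.end,
            f.interval.strand,
            f.feature_id,
        ),
    )
    for f in ordered:
        attrs = f"ID={f.feature_id}"
        if f.name:
            attrs += f";Name={f.name}"
        attrs += f";biotype={f.biotype}"
        handle.write(
            "\t".join(
                (
                    f.interval.contig,
                    "fermtx",
                    _BIOTYPE_TO_TYPE[f.biotype],
                    str(f.interval.start + 1),
                    str(f.interval.end),
                    ".",
                    f.interval.strand,
                    ".",
                    attrs,
                )
            )
            + "\n"
        )


def stranded_gaps(
    annotations: AnnotationSet, min_gap_length: int = 100
) -> List[GapRegion]:
    """Maximal per-strand unannotated regions strictly longer than a cutoff.

    Gap calling is stranded: a region counts as unannotated on a strand even
    if the opposite strand carries features there, so antisense placements
    are possible.  All biotypes (including UTRs and transcripts) occupy
    their strand; overlapping features are merged first.  Only gaps with
    ``length > min_gap_length`` are returned, numbered ``gap-1``, ``gap-2``,
    ... in (contig, strand, start) order.
    """
    occupied: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for f in annotations.features:
        length = annotations.contig_lengths.get(f.interval.contig)
        if length is None:
            raise ValueError(f"unknown contig length for {f.interval.contig!r}")
        if f.interval.end > length:
            raise ValueError(
                f"feature {f.feature_id!r} extends beyond contig length {length}"
            )
        occupied.setdefault((f.interval.contig, f.interval.strand), []).append(
            (f.interval.start, f.interval.end)
        )

    gaps: List[GapRegion] = []
    n = 0
    for contig in sorted(annotations.contig_lengths):
        length = annotations.contig_lengths[contig]
        for strand in STRANDS:
            for s, e in complement_intervals(occupied.get((contig, strand), []), length):
                if e - s > min_gap_length:
                    n += 1
                    gaps.append(GapRegion(f"gap-{n}", Interval(contig, s, e, strand)))
    return gaps


def write_bed6(
    rows: Iterable[Tuple[Interval, str, float]], path_or_handle: Union[str, TextIO]
) -> None:
    """Write (interval, name, score) rows as BED6 (native 0-based)."""
    if isinstance(path_or_handle, str):
        with open(path_or_handle, "w") as handle:
            write_bed6(rows, handle)
        return
    for interval, name, score in rows:
        path_or_handle.write(
            "\t".join(
                (
                    interval.contig,
                    str(interval.start),
                    str(interval.end),
                    name,
                    str(int(round(score))),
                    interval.strand,
                )
            )
            + "\n"
        )


def read_orfs(path: str) -> List[Feature]:
    """Read predicted ORFs from GFF3 or BED6, by file content."""
    with open(path) as handle:
        first = handle.readline()
    if first.startswith("#") or first.count("\t") == 8:
        return list(read_gff(path).features)
    orfs: List[Feature] = []
    with open(path) as handle:
        for i, line in enumerate(handle, start=1):
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 6:
                raise GFFError(f"BED line {i}: expected >= 6 columns")
            orfs.append(
                Feature(
                    interval=Interval(cols[0], int(cols[1]), int(cols[2]), cols[5]),
                    feature_id=cols[3],
                    biotype="other",
                )
            )
    return orfs
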