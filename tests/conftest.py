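import numpy as np
import pytest

from fermtx.annotation import AnnotationSet, Feature
from fermtx.intervals import Interval
from fermtx.synth import SimConfig, gen_annotation, gen_counts, gen_sample_sheet


@pytest.fixture(scope="session")
def tiny_annotation() -> AnnotationSet:
    """One 1000-bp contig with two plus-strand features."""
    return AnnotationSet(
        features=[
            Feature(Interval("chr1", 100, 200, "+"), "f1", "CDS"),
            Feature(Interval("chr1", 400, 600, "+"), "f2", "CDS"),
        ],
        contig_lengths={"chr1": 1000},
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated count dataset with planted effects."""
    cfg = SimConfig(seed=11, n_features=100, contig_length=250_000)
    annotation = gen_annotation(cfg)
    counts, sheet, truth = gen_counts(cfg, annotation)
    return cfg, annotation, counts, sheet, truth


def random_annotation(rng: np.random.Generator, contig_length: int = 2000) -> AnnotationSet:
    """A random feature layout for oracle comparisons (overlaps allowed)."""
    n = int(rng.integers(0, 12))
    features = []
    for i in range(n):
        start = int(rng.integers(0, contig_length - 2))
        end = int(rng.integers(start + 1, contig_length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(
            Feature(Interval("c", start, end, strand), f"f{i}", "CDS")
        )
    return AnnotationSet(features=features, contig_lengths={"c": contig_length})


def gap_oracle(annotation: AnnotationSet, min_gap_length: int = 100):
    """Per-base occupancy scan: the independent gap-extraction oracle."""
    out = []
    for contig in sorted(annotation.contig_lengths):
        length = annotation.contig_lengths[contig]
        for strand in ("+", "-"):
            occupied = np.zeros(length, dtype=bool)
            for f in annotation.features:
                if f.interval.contig == contig and f.interval.strand == strand:
                    occupied[f.interval.start : f.interval.end] = True
            start = None
            for pos in range(length + 1):
                free = pos < length and not occupied[pos]
                if free and start is None:
                    start = pos
                elif not free and start is not None:
                    if pos - start > min_gap_length:
                        out.append((contig, strand, start, pos))
                    start = None
    return out
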