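"""Amino-acid composition backgrounds and outlier flagging.

CDS nucleotide sequences are translated with the bacterial genetic code
(translation table 11; the alternative initiators GTG/TTG are rendered as
methionine).  A sequence is *complete* when its length is a codon
multiple, it starts with a valid initiator, ends with a stop codon, and
contains no internal stop.  Complete proteins contribute a per-amino-acid
percent composition; a background (mean +/- SD over a gene set) turns an
individual protein's composition into SD-unit z-scores, and residues more
than a flagging threshold (default 2 SD) away are marked as skewed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

_TABLE11 = unambiguous_dna_by_id[11]
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = tuple(_TABLE11.stop_codons)


@dataclass(frozen=True)
class ProteinComposition:
    """Percent amino-acid composition of one protein."""

    protein_id: str
    proportions: Mapping[str, float]  # percent, keys = the 20 amino acids
    complete: bool

    def as_vector(self) -> np.ndarray:
        return np.array([self.proportions[a] for a in AMINO_ACIDS])


def translate_check(sequence: str, seq_id: str = "") -> Tuple[str, bool]:
    """Translate a CDS and decide whether it is complete.

    Returns (protein string without the stop, complete flag).  The first
    codon is rendered as Met when it is a valid bacterial initiator.
    Raises on characters outside ACGT, naming the first bad position.
    """
    seq = sequence.upper()
    for pos, ch in enumerate(seq):
        if ch not in "ACGT":
            raise ValueError(
                f"non-ACGT character {ch!r} at position {pos}"
                + (f" in {seq_id}" if seq_id else "")
            )
    n_codons = len(seq) // 3
    frame = seq[: n_codons * 3]
    protein = str(Seq(frame).translate(table=11))
    starts_ok = frame[:3] in START_CODONS
    if protein and starts_ok:
        protein = "M" + protein[1:]
    ends_with_stop = protein.endswith("*")
    body = protein[:-1] if ends_with_stop else protein
    complete = (
        len(seq) % 3 == 0
        and starts_ok
        and ends_with_stop
        and "*" not in body
    )
    return body.split("*")[0] if "*" in body else body, complete


def protein_composition(protein_id: str, protein: str, complete: bool) -> ProteinComposition:
    counts = {a: 0 for a in AMINO_ACIDS}
    for aa in protein:
        if aa in counts:
            counts[aa] += 1
    total = sum(counts.values())
    props = {a: (100.0 * c / total if total else 0.0) for a, c in counts.items()}
    return ProteinComposition(protein_id=protein_id, proportions=props, complete=complete)


def compositions_from_cds(
    sequences: Mapping[str, str]
) -> Dict[str, ProteinComposition]:
    """Translate a dict of CDS sequences into compositions."""
    out = {}
    for seq_id, seq in sequences.items():
        protein, complete = translate_check(seq, seq_id)
        out[seq_id] = protein_composition(seq_id, protein, complete)
    return out


@dataclass
class CompositionBackground:
    """Mean and SD percent per amino acid over a set of complete proteins."""

    label: str
    mean: Mapping[str, float]
    sd: Mapping[str, float]
    n: int


def background_stats(
    proteins: Iterable[ProteinComposition], label: str = "all"
) -> CompositionBackground:
    """Per-amino-acid mean and sample SD over the complete proteins."""
    complete = [p for p in proteins if p.complete]
    if len(complete) < 2:
        raise ValueError("need at least two complete proteins for a background")
    arr = np.array([p.as_vector() for p in complete])
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    return CompositionBackground(
        label=label,
        mean=dict(zip(AMINO_ACIDS, mean)),
        sd=dict(zip(AMINO_ACIDS, sd)),
        n=len(complete),
    )


@dataclass
class CompositionZ:
    """SD-unit deviations of one protein from a background."""

    protein_id: str
    z: Mapping[str, float]  # rounded to 1 decimal; NaN where SD = 0
    flagged: Tuple[str, ...]  # amino acids with |z| > flag_sd (unrounded)


def z_flags(
    protein: ProteinComposition,
    background: CompositionBackground,
    flag_sd: float = 2.0,
) -> CompositionZ:
    """z_a = (x_a - mu_a) / sigma_a per amino acid, flagged beyond ``flag_sd``."""
    z: Dict[str, float] = {}
    flagged: List[str] = []
    for a in AMINO_ACIDS:
        sd = background.sd[a]
        if sd == 0:
            z[a] = float("nan")
            continue
        raw = (protein.proportions[a] - background.mean[a]) / sd
        z[a] = round(raw, 1)
        if abs(raw) > flag_sd:
            flagged.append(a)
    return CompositionZ(protein_id=protein.protein_id, z=z, flagged=tuple(flagged))


def top_expressed(
    counts: pd.DataFrame, sf: pd.Series, fraction: float = 0.10
) -> List[str]:
    """The ceil(fraction * n) genes with highest mean normalized count.

    Ties break deterministically by feature id (lexicographic).
    """
    means = (counts / sf.reindex(counts.columns)).mean(axis=1)
    n_top = math.ceil(fraction * len(means))
    order = sorted(means.index, key=lambda g: (-means[g], g))
    return order[:n_top]


def read_fasta(path: str) -> Dict[str, str]:
    """Plain FASTA into an ordered id -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as handle:
        for seq_id, seq in sequences.items():
            handle.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def composition_table(
    backgrounds: Sequence[CompositionBackground],
    proteins: Sequence[Tuple[ProteinComposition, CompositionZ]] = (),
) -> pd.DataFrame:
    """Wide per-amino-acid table: one mean +/- SD pair per background and,
    optionally, percent (z) columns for individual proteins."""
    data: Dict[str, List] = {"amino_acid": list(AMINO_ACIDS)}
    for bg in backgrounds:
        data[f"{bg.label}_mean_pct"] = [round(bg.mean[a], 2) for a in AMINO_ACIDS]
        data[f"{bg.label}_sd"] = [round(bg.sd[a], 2) for a in AMINO_ACIDS]
    for comp, cz in proteins:
        data[f"{comp.protein_id}_pct"] = [
            round(comp.proportions[a], 2) for a in AMINO_ACIDS
        ]
        data[f"{comp.protein_id}_z"] = [cz.z[a] for a in AMINO_ACIDS]
    return pd.DataFrame(data)
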