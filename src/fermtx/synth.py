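"""Synthetic datasets with planted truth for every pipeline stage.

The generator emulates the study conditions end to end: a bacterial
genome annotation with stranded features and unannotated gaps, a
2-strain x 6-timepoint x 3-replicate count matrix sequenced in three
round-robin batches, negative-binomial counts with planted condition
effects, gap counts pinned to chosen coverage levels (straddling the 4x
NPTR threshold), a small rooted ontology with planted enriched terms,
and CDS sequences with planted amino-acid skew.  Every emitted file is a
format the consuming modules read back (GFF3, TSV, FASTA), and all
randomness flows from integer-seeded numpy generators, so one seed gives
one dataset, byte for byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, Feature, GapRegion, stranded_gaps, write_gff
from .composition import AMINO_ACIDS, CompositionBackground
from .diffexpr import ContrastSpec, condition_label, default_contrasts
from .intervals import Interval
from .quantify import STRAINS, TIMEPOINTS

# Biotype sampling weights mirror the relative abundance of annotation
# classes in a bacterial transcript atlas (coding genes dominate).
BIOTYPE_WEIGHTS = {
    "CDS": 2674,
    "putative_ncRNA": 107,
    "riboswitch": 37,
    "tRNA": 22,
    "sRNA": 9,
    "asRNA": 1,
    "SRP": 1,
}

# Average percent composition of bacterial proteins used as the sampling
# distribution for synthetic proteomes.
BACKGROUND_AA_PCT = {
    "A": 7.36, "C": 0.91, "D": 5.11, "E": 7.37, "F": 4.63,
    "G": 6.67, "H": 2.30, "I": 7.50, "K": 7.50, "L": 9.70,
    "M": 2.46, "N": 4.07, "P": 3.48, "Q": 3.87, "R": 4.19,
    "S": 6.22, "T": 5.32, "V": 6.75, "W": 1.03, "Y": 3.57,
}


@dataclass
class SimConfig:
    """Everything the generator needs; one seed fixes the whole dataset."""

    seed: int = 0
    # genome / annotation
    n_contigs: int = 1
    contig_length: int = 200_000
    n_features: int = 120
    feature_length_range: Tuple[int, int] = (200, 1200)
    intergap_range: Tuple[int, int] = (30, 500)
    # design
    strains: Tuple[str, ...] = STRAINS
    timepoints: Tuple[int, ...] = TIMEPOINTS
    replicates: int = 3
    n_batches: int = 3
    # counts
    dispersion: float = 0.05
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    de_fraction: float = 0.10
    de_log2fc: float = 1.5
    batch_log2fc: float = 0.2
    size_factor_range: Tuple[float, float] = (0.7, 1.4)
    # gaps
    gap_coverages: Tuple[float, ...] = (2.0, 8.0)
    read_length: int = 50
    # ontology
    n_terms_per_level: Tuple[int, ...] = (4, 12)
    term_size_range: Tuple[int, int] = (10, 25)
    n_enriched_terms: int = 1
    # proteins
    n_proteins: int = 60
    protein_length: int = 200  # codons, excluding start and stop
    skew_targets: Dict[str, Dict[str, float]] = field(default_factory=dict)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed) % (2**31), stream])


def gen_annotation(cfg: SimConfig) -> AnnotationSet:
    """Place non-overlapping same-strand features along each contig.

    Features and the unannotated stretches between them are laid out by a
    coordinate walk; an infeasible packing (features cannot fit) raises.
    """
    rng = _rng(cfg, 1)
    biotypes = list(BIOTYPE_WEIGHTS)
    weights = np.array([BIOTYPE_WEIGHTS[b] for b in biotypes], dtype=float)
    weights /= weights.sum()
    max_need = cfg.n_features * (
        cfg.feature_length_range[1] + cfg.intergap_range[1]
    )
    if cfg.n_features and max_need > cfg.n_contigs * cfg.contig_length:
        raise ValueError(
            f"cannot place {cfg.n_features} features of up to "
            f"{cfg.feature_length_range[1]} bp in {cfg.n_contigs} x "
            f"{cfg.contig_length} bp"
        )
    contigs = [f"chr{i + 1}" for i in range(cfg.n_contigs)]
    features: List[Feature] = []
    per_contig = int(np.ceil(cfg.n_features / cfg.n_contigs)) if cfg.n_features else 0
    n_made = 0
    for contig in contigs:
        pos = 0
        for _ in range(per_contig):
            if n_made >= cfg.n_features:
                break
            pos += int(rng.integers(*cfg.intergap_range))
            length = int(rng.integers(*cfg.feature_length_range))
            if pos + length > cfg.contig_length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = str(rng.choice(biotypes, p=weights))
            n_made += 1
            features.append(
                Feature(
                    interval=Interval(contig, pos, pos + length, strand),
                    feature_id=f"feat-{n_made:04d}",
                    biotype=biotype,
                    name=f"gene{n_made}",
                )
            )
            pos += length
    if n_made < cfg.n_features:
        raise ValueError(
            f"placed only {n_made} of {cfg.n_features} features; "
            "increase contig_length"
        )
    return AnnotationSet(
        features=features,
        contig_lengths={c: cfg.contig_length for c in contigs},
    )


def gen_sample_sheet(cfg: SimConfig) -> pd.DataFrame:
    """The fed-batch design: strains x timepoints x replicates, batches
    assigned round-robin across samples."""
    rows = []
    i = 0
    for strain in cfg.strains:
        for t in cfg.timepoints:
            for rep in range(1, cfg.replicates + 1):
                i += 1
                rows.append(
                    {
                        "sample_id": f"s{i:02d}",
                        "strain": strain,
                        "timepoint": t,
                        "replicate": rep,
                        "batch": f"b{(i - 1) % cfg.n_batches + 1}",
                    }
                )
    return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 draws with variance mu + alpha*mu^2 (Poisson when alpha ~ 0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def gen_counts(
    cfg: SimConfig, annotation: AnnotationSet
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """NB counts with planted effects.

    Returns (counts, sample sheet, truth).  Truth has one row per feature:
    the effect type ("none", "strain", "time"), the planted log2FC, and
    the true log2FC of every default contrast.  Strain effects raise all
    +prsA conditions; time effects raise the later half of the time course
    in both strains.
    """
    rng = _rng(cfg, 2)
    sheet = gen_sample_sheet(cfg)
    n_samples = len(sheet)
    features = [f.feature_id for f in annotation]
    n = len(features)

    sf = rng.uniform(*cfg.size_factor_range, size=n_samples)
    batches = sorted(set(sheet["batch"]))
    batch_fx = {
        b: (rng.uniform(-cfg.batch_log2fc, cfg.batch_log2fc) if i else 0.0)
        for i, b in enumerate(batches)
    }
    q = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)

    n_de = int(round(cfg.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    effect_type = np.array(["none"] * n, dtype=object)
    effect_lfc = np.zeros(n)
    t_cut = cfg.timepoints[len(cfg.timepoints) // 2]
    for i in de_idx:
        effect_type[i] = "strain" if rng.random() < 0.5 else "time"
        effect_lfc[i] = cfg.de_log2fc * (1 if rng.random() < 0.5 else -1)

    log2fx = np.zeros((n, n_samples))
    is_prsa = (sheet["strain"] == cfg.strains[1]).to_numpy()
    is_late = (sheet["timepoint"] >= t_cut).to_numpy()
    for i in range(n):
        if effect_type[i] == "strain":
            log2fx[i, is_prsa] = effect_lfc[i]
        elif effect_type[i] == "time":
            log2fx[i, is_late] = effect_lfc[i]
    batch_vec = np.array([batch_fx[b] for b in sheet["batch"]])
    mean = q[:, None] * sf[None, :] * 2.0 ** (log2fx + batch_vec[None, :])
    counts = pd.DataFrame(
        _nb_draw(rng, mean, cfg.dispersion),
        index=pd.Index(features, name="feature_id"),
        columns=list(sheet["sample_id"]),
    )

    contrasts = default_contrasts(cfg.strains, cfg.timepoints)
    truth = pd.DataFrame(
        {"effect_type": effect_type, "planted_log2fc": effect_lfc},
        index=pd.Index(features, name="feature_id"),
    )
    for c in contrasts:
        col = np.zeros(n)
        if c.kind == "between_strain":
            col[effect_type == "strain"] = effect_lfc[effect_type == "strain"]
        else:
            t0 = int(c.condition_b.split("_")[1][:-1])
            t1 = int(c.condition_a.split("_")[1][:-1])
            crosses = t0 < t_cut <= t1
            if crosses:
                col[effect_type == "time"] = effect_lfc[effect_type == "time"]
        truth[f"true_log2fc_{c.label}"] = col
    truth["is_null"] = effect_type == "none"
    return counts, sheet, truth


def gen_gap_counts(
    cfg: SimConfig,
    gaps: Sequence[GapRegion],
    sheet: pd.DataFrame,
    sf: Optional[np.ndarray] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Gap counts pinned to planted coverage levels (cycled over gaps).

    expected count = coverage * gap_length / read_length * s_j; draws are
    NB with the configured dispersion.  Returns (gap counts, truth with
    planted coverage and transcribed flag at the 4x threshold).
    """
    rng = _rng(cfg, 3)
    n_samples = len(sheet)
    if sf is None:
        sf = np.ones(n_samples)
    coverages = [cfg.gap_coverages[i % len(cfg.gap_coverages)] for i in range(len(gaps))]
    rows = []
    for gap, cov in zip(gaps, coverages):
        mean = cov * gap.length / cfg.read_length * sf
        rows.append(_nb_draw(rng, mean, cfg.dispersion))
    gap_counts = pd.DataFrame(
        np.array(rows, dtype=np.int64) if rows else np.zeros((0, n_samples), dtype=np.int64),
        index=pd.Index([g.gap_id for g in gaps], name="feature_id"),
        columns=list(sheet["sample_id"]),
    )
    truth = pd.DataFrame(
        {
            "planted_coverage": coverages,
            "transcribed": [c >= 4.0 for c in coverages],
        },
        index=pd.Index([g.gap_id for g in gaps], name="feature_id"),
    )
    return gap_counts, truth


def gen_ontology(
    cfg: SimConfig,
    genes: Sequence[str],
    de_genes: Sequence[str],
) -> Tuple[Dict[str, Set[str]], Dict[str, Set[str]], pd.DataFrame]:
    """A rooted DAG with planted enriched terms.

    Returns (parents, gene->terms annotation, truth).  Leaf terms draw
    genes uniformly; each planted enriched term instead draws almost all
    of its genes from ``de_genes``, which guarantees an observed/expected
    ratio of at least 2 at the configured sizes.
    """
    rng = _rng(cfg, 4)
    parents: Dict[str, Set[str]] = {"root": set()}
    level_terms: List[List[str]] = [["root"]]
    t = 0
    for level, width in enumerate(cfg.n_terms_per_level, start=1):
        terms = []
        for _ in range(width):
            t += 1
            term = f"T{t:03d}"
            parent = level_terms[level - 1][int(rng.integers(len(level_terms[level - 1])))]
            parents[term] = {parent}
            terms.append(term)
        level_terms.append(terms)
    leaves = level_terms[-1]

    de_pool = [g for g in de_genes if g in set(genes)]
    enriched = leaves[: cfg.n_enriched_terms]
    annotation: Dict[str, Set[str]] = {g: set() for g in genes}
    for term in leaves:
        size = int(rng.integers(*cfg.term_size_range))
        if term in enriched and de_pool:
            n_de = min(len(de_pool), max(size - 2, int(np.ceil(0.8 * size))))
            members = list(rng.choice(de_pool, size=min(n_de, len(de_pool)), replace=False))
            others = [g for g in genes if g not in set(members)]
            n_rest = min(size - len(members), len(others))
            if n_rest > 0:
                members += list(rng.choice(others, size=n_rest, replace=False))
        else:
            members = list(rng.choice(genes, size=min(size, len(genes)), replace=False))
        for g in members:
            annotation[g].add(term)
    truth = pd.DataFrame(
        {"enriched": [term in enriched for term in sorted(parents)]},
        index=pd.Index(sorted(parents), name="term_id"),
    )
    return parents, annotation, truth


# deterministic codon choice per amino acid (first codon in table order)
from Bio.Data.CodonTable import unambiguous_dna_by_id as _codon_tables

_AA_TO_CODON: Dict[str, str] = {}
for _codon, _aa in sorted(_codon_tables[11].forward_table.items()):
    _AA_TO_CODON.setdefault(_aa, _codon)


def _protein_to_cds(protein: str) -> str:
    return "ATG" + "".join(_AA_TO_CODON[a] for a in protein) + "TAA"


def gen_proteins(cfg: SimConfig) -> Tuple[Dict[str, str], pd.DataFrame]:
    """CDS sequences: i.i.d.-composition background plus skewed targets.

    Background proteins sample residues from a fixed bacterial
    composition.  For every entry of ``cfg.skew_targets`` (protein id ->
    {amino acid: SD units}) a protein is built whose target residues sit
    the requested number of background SDs above the background mean.
    All sequences are complete (ATG start, TAA stop, no internal stop).
    Returns (id -> CDS, truth listing the skewed residues per protein).
    """
    rng = _rng(cfg, 5)
    aas = list(BACKGROUND_AA_PCT)
    probs = np.array([BACKGROUND_AA_PCT[a] for a in aas])
    probs = probs / probs.sum()
    L = cfg.protein_length

    sequences: Dict[str, str] = {}
    prot_strings: Dict[str, str] = {}
    for i in range(cfg.n_proteins):
        protein = "".join(rng.choice(aas, size=L, p=probs))
        pid = f"prot-{i + 1:03d}"
        prot_strings[pid] = protein
        sequences[pid] = _protein_to_cds(protein)

    # empirical background over the generated proteins (incl. start Met)
    mat = np.array(
        [
            [(("M" + p).count(a)) / (L + 1) * 100.0 for a in AMINO_ACIDS]
            for p in prot_strings.values()
        ]
    )
    mean = dict(zip(AMINO_ACIDS, mat.mean(axis=0)))
    sd = dict(zip(AMINO_ACIDS, mat.std(axis=0, ddof=1)))

    truth_rows = []
    for pid, targets in cfg.skew_targets.items():
        counts = {a: int(round((L + 1) * probs[aas.index(a)])) for a in aas}
        for a, n_sd in targets.items():
            target_pct = mean[a] + n_sd * sd[a]
            counts[a] = int(np.ceil((L + 1) * target_pct / 100.0))
        # pad/trim via the most common residue; skewed residues go first so
        # any trimming to the exact length never eats into them
        total = sum(counts.values())
        filler = "L"
        counts[filler] = max(0, counts[filler] + (L + 1 - total))
        order = sorted(counts, key=lambda a: (a not in targets, a))
        protein = "".join(a * counts[a] for a in order)
        protein = "M" + protein[:L]
        sequences[pid] = _protein_to_cds(protein[1:])
        truth_rows.append({"protein_id": pid, "skewed": ",".join(sorted(targets))})
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "skewed"])
    return sequences, truth


def gen_orfs(
    cfg: SimConfig, annotation: AnnotationSet, jitter: int = 0
) -> List[Feature]:
    """ORF predictions derived from the coding genes (optionally jittered),
    trimmed to a codon multiple; useful for benchmarking at known truth."""
    rng = _rng(cfg, 6)
    orfs = []
    i = 0
    for f in annotation.by_biotype("CDS"):
        i += 1
        start = f.interval.start + (int(rng.integers(-jitter, jitter + 1)) if jitter else 0)
        start = max(0, start)
        length = ((f.interval.end - start) // 3) * 3
        if length < 60:
            continue
        orfs.append(
            Feature(
                interval=Interval(f.interval.contig, start, start + length, f.interval.strand),
                feature_id=f"orf-{i:04d}",
                biotype="other",
            )
        )
    return orfs


def gen_dataset(cfg: SimConfig, outdir: str) -> Dict[str, str]:
    """Generate and write a complete dataset; returns the path map.

    Files: annotation.gff3, counts.tsv, gap_counts.tsv, samples.tsv,
    orfs.gff3, cds.fasta, ontology_edges.tsv, gene2term.tsv, and planted
    truth under truth/.
    """
    os.makedirs(outdir, exist_ok=True)
    truth_dir = os.path.join(outdir, "truth")
    os.makedirs(truth_dir, exist_ok=True)
    paths: Dict[str, str] = {}

    annotation = gen_annotation(cfg)
    paths["annotation"] = os.path.join(outdir, "annotation.gff3")
    write_gff(annotation, paths["annotation"])

    counts, sheet, de_truth = gen_counts(cfg, annotation)
    paths["counts"] = os.path.join(outdir, "counts.tsv")
    counts.to_csv(paths["counts"], sep="\t")
    paths["samples"] = os.path.join(outdir, "samples.tsv")
    sheet.to_csv(paths["samples"], sep="\t", index=False)
    de_truth.to_csv(os.path.join(truth_dir, "de_truth.tsv"), sep="\t")

    gaps = stranded_gaps(annotation)
    gap_counts, gap_truth = gen_gap_counts(cfg, gaps, sheet)
    paths["gap_counts"] = os.path.join(outdir, "gap_counts.tsv")
    gap_counts.to_csv(paths["gap_counts"], sep="\t")
    gap_truth.to_csv(os.path.join(truth_dir, "gap_truth.tsv"), sep="\t")

    de_genes = list(de_truth.index[~de_truth["is_null"]])
    parents, gene_terms, term_truth = gen_ontology(cfg, list(counts.index), de_genes)
    paths["ontology"] = os.path.join(outdir, "ontology_edges.tsv")
    with open(paths["ontology"], "w") as handle:
        for child in sorted(parents):
            for parent in sorted(parents[child]):
                handle.write(f"{child}\t{parent}\n")
    paths["gene2term"] = os.path.join(outdir, "gene2term.tsv")
    with open(paths["gene2term"], "w") as handle:
        for gene in sorted(gene_terms):
            for term in sorted(gene_terms[gene]):
                handle.write(f"{gene}\t{term}\n")
    term_truth.to_csv(os.path.join(truth_dir, "term_truth.tsv"), sep="\t")

    orfs = gen_orfs(cfg, annotation)
    paths["orfs"] = os.path.join(outdir, "orfs.gff3")
    write_gff(
        AnnotationSet(features=orfs, contig_lengths=dict(annotation.contig_lengths)),
        paths["orfs"],
    )

    sequences, prot_truth = gen_proteins(cfg)
    paths["cds"] = os.path.join(outdir, "cds.fasta")
    from .composition import write_fasta

    write_fasta(sequences, paths["cds"])
    prot_truth.to_csv(os.path.join(truth_dir, "protein_truth.tsv"), sep="\t", index=False)
    return paths
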