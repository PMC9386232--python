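"""End-to-end orchestration: gaps -> NPTRs -> DE -> profiles -> enrichment
-> ORF benchmark -> composition, with a tabular summary report.

A :class:`PipelineConfig` is a flat key=value text file naming the input
paths and thresholds.  :func:`run_all` executes the stages in order,
writes every artifact as TSV/BED/GFF3 under an output directory, and
records parameters and seeds in a JSON manifest.  Outputs are
deterministic for fixed inputs and seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, fields
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import composition as comp
from . import enrichment as enr
from . import orf as orfmod
from . import profiles as prof
from . import quantify
from .annotation import AnnotationSet, read_gff, read_orfs, stranded_gaps, write_bed6
from .diffexpr import TimecourseDEModel

logger = logging.getLogger("fermtx")


class ConfigError(ValueError):
    """Raised before any compute when the configuration is unusable."""


@dataclass
class PipelineConfig:
    # input paths
    annotation: str = ""
    counts: str = ""
    samples: str = ""
    gap_counts: str = ""
    orfs: str = ""
    cds: str = ""
    ontology_edges: str = ""
    gene2term: str = ""
    outdir: str = "fermtx_out"
    # parameters
    min_gap_length: int = 100
    read_length: int = 50
    coverage_threshold: float = 4.0
    alpha: float = 0.01
    min_term_size: int = 10
    ratio_min: float = 2.0
    jaccard_min: float = 0.9
    k: int = 10
    restarts: int = 25
    flag_sd: float = 2.0
    top_fraction: float = 0.10
    pseudocount: float = 1.0
    seed: int = 0

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Parse a flat ``key = value`` (or ``key=value``) text file."""
        if not os.path.exists(path):
            raise ConfigError(f"config file not found: {path}")
        values: Dict[str, str] = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ConfigError(f"config line {lineno}: expected key=value")
                key, val = (s.strip() for s in line.split("=", 1))
                values[key] = val
        return cls.from_mapping(values)

    @classmethod
    def from_mapping(cls, values: Dict[str, str]) -> "PipelineConfig":
        kwargs = {}
        by_name = {f.name: f for f in fields(cls)}
        for key, val in values.items():
            if key not in by_name:
                raise ConfigError(f"unknown config key {key!r}")
            ftype = by_name[key].type
            if ftype == "int":
                kwargs[key] = int(val)
            elif ftype == "float":
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def validate(self, require: List[str]) -> None:
        for name in (
            "min_gap_length", "read_length", "coverage_threshold", "alpha",
            "min_term_size", "ratio_min", "jaccard_min", "k", "flag_sd",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"parameter {name} must be positive")
        for key in require:
            path = getattr(self, key)
            if not path:
                raise ConfigError(f"config key {key!r} is required for this stage")
            if not os.path.exists(path):
                raise ConfigError(f"{key} path does not exist: {path}")


@dataclass
class SummaryReport:
    """Per-biotype counts mirroring the differential-expression table."""

    table: pd.DataFrame  # biotype, considered, de, de_pct, strain_specific, ss_pct

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def biotype_percentages(considered: int, de: int, strain_specific: int):
    """The two report percentages, each relative to the column to its left:
    DE as a percent of considered, strain-specific as a percent of DE.
    Blank when the denominator is zero; rounded to 1 decimal."""
    de_pct = round(100.0 * de / considered, 1) if considered else ""
    ss_pct = round(100.0 * strain_specific / de, 1) if de else ""
    return de_pct, ss_pct


def summarize(per_feature: pd.DataFrame, biotypes: Dict[str, str]) -> SummaryReport:
    """Count expressed / DE / strain-specific features per biotype.

    The two percentage columns are relative to the column to their left:
    DE% of considered, strain-specific% of DE; blank when the denominator
    is zero.  ``considered`` are the features passing independent
    filtering.
    """
    rows = []
    biotype_series = pd.Series(
        [biotypes.get(f, "other") for f in per_feature.index], index=per_feature.index
    )
    for biotype in sorted(set(biotype_series)):
        sub = per_feature[biotype_series == biotype]
        considered = int(sub["expressed"].sum())
        de = int((sub["expressed"] & sub["differentially_expressed"]).sum())
        ss = int((sub["expressed"] & sub["strain_specific"]).sum())
        de_pct, ss_pct = biotype_percentages(considered, de, ss)
        rows.append(
            {
                "biotype": biotype,
                "considered": considered,
                "differentially_expressed": de,
                "de_pct": de_pct,
                "strain_specific": ss,
                "strain_specific_pct": ss_pct,
            }
        )
    rows.sort(key=lambda r: -r["considered"])
    return SummaryReport(table=pd.DataFrame(rows))


def run_all(config: PipelineConfig) -> SummaryReport:
    """Execute the full pipeline; artifacts land under ``config.outdir``."""
    required = ["annotation", "counts", "samples"]
    config.validate(require=[k for k in required if True])
    os.makedirs(config.outdir, exist_ok=True)

    def out(name: str) -> str:
        return os.path.join(config.outdir, name)

    manifest = {
        "parameters": {
            f.name: getattr(config, f.name)
            for f in fields(PipelineConfig)
            if f.type in ("int", "float")
        },
        "stages": [],
    }

    # --- gaps ---------------------------------------------------------
    logger.info("stage gaps: extracting stranded unannotated regions")
    annotation = read_gff(config.annotation)
    gaps = stranded_gaps(annotation, min_gap_length=config.min_gap_length)
    gap_rows = pd.DataFrame(
        {
            "gap_id": [g.gap_id for g in gaps],
            "contig": [g.interval.contig for g in gaps],
            "start": [g.interval.start for g in gaps],
            "end": [g.interval.end for g in gaps],
            "strand": [g.interval.strand for g in gaps],
            "length": [g.length for g in gaps],
        }
    )
    gap_rows.to_csv(out("gaps.tsv"), sep="\t", index=False)
    manifest["stages"].append({"name": "gaps", "n_gaps": len(gaps)})

    # --- counts / normalization --------------------------------------
    counts = quantify.read_counts(config.counts)
    sheet = quantify.read_sample_sheet(config.samples)
    sf = quantify.size_factors(counts)
    sf.to_csv(out("size_factors.tsv"), sep="\t", header=True)

    # --- NPTR calling -------------------------------------------------
    nptr_ids: List[str] = []
    gap_counts = None
    if config.gap_counts:
        logger.info("stage nptr: calling novel potentially transcribed regions")
        gap_counts = quantify.read_counts(config.gap_counts)
        summaries = quantify.call_nptrs(
            gap_counts, gaps, sf,
            read_length=config.read_length,
            coverage_threshold=config.coverage_threshold,
        )
        cov_table = quantify.coverage_table(summaries)
        cov_table.to_csv(out("nptr_summary.tsv"), sep="\t")
        by_id = {g.gap_id: g for g in gaps}
        nptr_ids = [s.gap_id for s in summaries if s.is_nptr]
        write_bed6(
            [
                (by_id[s.gap_id].interval, s.gap_id, s.mean_coverage * 100.0)
                for s in summaries
                if s.is_nptr
            ],
            out("nptrs.bed"),
        )
        manifest["stages"].append({"name": "nptr", "n_nptrs": len(nptr_ids)})

    # --- differential expression -------------------------------------
    logger.info("stage de: stage-wise NB time-course testing")
    de_counts = counts
    biotype_map = {f.feature_id: f.biotype for f in annotation}
    if gap_counts is not None and nptr_ids:
        de_counts = pd.concat([counts, gap_counts.loc[nptr_ids]])
        biotype_map.update({g: "NPTR" for g in nptr_ids})
    model = TimecourseDEModel(de_counts, sheet)
    results = model.fit(alpha=config.alpha)
    results.tidy().to_csv(out("de_contrasts.tsv"), sep="\t", index=False)
    per_feature = results.per_feature()
    per_feature.to_csv(out("de_features.tsv"), sep="\t")
    manifest["stages"].append(
        {
            "name": "de",
            "n_expressed": int(per_feature["expressed"].sum()),
            "n_de": int(per_feature["differentially_expressed"].sum()),
        }
    )

    # --- expression profiles -----------------------------------------
    n_de = int(per_feature["differentially_expressed"].sum())
    if n_de >= 2:
        logger.info("stage profiles: clustering expression profiles")
        matrix = prof.build_profiles(results, pseudocount=config.pseudocount)
        k = min(config.k, len(matrix))
        clusters = prof.kmeans_cluster(
            matrix, k=k, restarts=config.restarts, seed=config.seed
        )
        cl = clusters.assignment.reset_index()
        cl.to_csv(out("profile_clusters.tsv"), sep="\t", index=False)
        k_max = min(15, len(matrix))
        if k_max >= 3:
            wss = prof.wss_curve(
                matrix, k_max=k_max, restarts=max(5, config.restarts // 5),
                seed=config.seed,
            )
            wss.to_frame().to_csv(out("wss_curve.tsv"), sep="\t", index_label="k")
        manifest["stages"].append({"name": "profiles", "k": k})

    # --- enrichment ---------------------------------------------------
    if config.ontology_edges and config.gene2term:
        logger.info("stage enrich: ontology over-representation")
        gene_terms = enr.read_gene_annotation(config.gene2term)
        dag = enr.OntologyDAG.from_edge_list(config.ontology_edges, gene_terms)
        coding = {f for f, b in biotype_map.items() if b == "CDS"}
        covered = coding & set(gene_terms)
        table = enr.enrichment_analysis(
            results, dag, genes=covered,
            min_term_size=config.min_term_size,
            elim_alpha=config.alpha,
            ratio_min=config.ratio_min,
            fdr_alpha=config.alpha,
        )
        table.to_csv(out("enrichment.tsv"), sep="\t", index=False)
        manifest["stages"].append(
            {"name": "enrich", "n_significant": int(table["significant"].sum())}
        )

    # --- ORF benchmark ------------------------------------------------
    if config.orfs:
        logger.info("stage orf: benchmarking ORF predictions")
        orfs = orfmod.as_orf_records(read_orfs(config.orfs))
        genes = annotation.by_biotype("CDS")
        report = orfmod.benchmark_orfs(orfs, genes, jaccard_min=config.jaccard_min)
        pd.DataFrame(
            [
                {
                    "n_orfs": report.n_orfs,
                    "n_genes": report.n_genes,
                    "n_recalled": report.n_recalled,
                    "n_matching_orfs": report.n_matching_orfs,
                    "recall_pct": report.recall_pct,
                    "precision_pct": report.precision_pct,
                }
            ]
        ).to_csv(out("orf_benchmark.tsv"), sep="\t", index=False)
        unmatched = [o for o in orfs if o.orf_id not in set(report.matching_orf_ids)]
        nptr_status = {g: g in set(nptr_ids) for g in (x.gap_id for x in gaps)}
        de_status = {
            g: bool(per_feature["differentially_expressed"].get(g, False))
            for g in nptr_status
        }
        orfmod.orf_gap_table(unmatched, gaps, nptr_status, de_status).to_csv(
            out("orf_gap_overlaps.tsv"), sep="\t", index=False
        )
        manifest["stages"].append(
            {"name": "orf", "recall_pct": report.recall_pct,
             "precision_pct": report.precision_pct}
        )

    # --- composition --------------------------------------------------
    if config.cds:
        logger.info("stage composition: amino-acid composition z-scores")
        cds = comp.read_fasta(config.cds)
        comps = comp.compositions_from_cds(cds)
        complete = [c for c in comps.values() if c.complete]
        backgrounds = []
        if len(complete) >= 2:
            backgrounds.append(comp.background_stats(complete, label="all"))
            de_ids = set(per_feature.index[per_feature["differentially_expressed"]])
            de_sub = [c for c in complete if c.protein_id in de_ids]
            if len(de_sub) >= 2:
                backgrounds.append(comp.background_stats(de_sub, "diff_expressed"))
            top = set(comp.top_expressed(counts, sf, fraction=config.top_fraction))
            top_sub = [c for c in complete if c.protein_id in top]
            if len(top_sub) >= 2:
                backgrounds.append(comp.background_stats(top_sub, "top10_expressed"))
        if backgrounds:
            bg_all = backgrounds[0]
            z_rows = []
            for c in complete:
                cz = comp.z_flags(c, bg_all, flag_sd=config.flag_sd)
                for a in comp.AMINO_ACIDS:
                    z_rows.append(
                        {
                            "protein_id": c.protein_id,
                            "amino_acid": a,
                            "pct": round(c.proportions[a], 2),
                            "z": cz.z[a],
                            "flagged": a in cz.flagged,
                        }
                    )
            pd.DataFrame(z_rows).to_csv(out("composition_z.tsv"), sep="\t", index=False)
            comp.composition_table(backgrounds).to_csv(
                out("composition_backgrounds.tsv"), sep="\t", index=False
            )
            manifest["stages"].append(
                {"name": "composition", "n_complete": len(complete)}
            )

    # --- summary ------------------------------------------------------
    report = summarize(per_feature, biotype_map)
    report.to_tsv(out("summary.tsv"))
    with open(out("manifest.json"), "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return report
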