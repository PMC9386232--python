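"""The synthetic-data generator: determinism, moments, planted truth."""

import io

import numpy as np
import pytest

from fermtx.annotation import read_gff, stranded_gaps, write_gff
from fermtx.composition import background_stats, compositions_from_cds, z_flags
from fermtx.quantify import call_nptrs, validate_counts, validate_sample_sheet
from fermtx.synth import (
    SimConfig,
    gen_annotation,
    gen_counts,
    gen_gap_counts,
    gen_ontology,
    gen_proteins,
    gen_sample_sheet,
)


def _gff_bytes(ann):
    buf = io.StringIO()
    write_gff(ann, buf)
    return buf.getvalue()


class TestAnnotation:
    def test_zero_features(self):
        cfg = SimConfig(seed=0, n_features=0, contig_length=5000)
        ann = gen_annotation(cfg)
        assert len(ann) == 0
        gaps = stranded_gaps(ann)
        assert {g.length for g in gaps} == {5000}

    def test_same_seed_identical_bytes(self):
        cfg = SimConfig(seed=42, n_features=40, contig_length=100_000)
        assert _gff_bytes(gen_annotation(cfg)) == _gff_bytes(gen_annotation(cfg))

    def test_requested_feature_count_emitted(self):
        cfg = SimConfig(seed=1, n_features=50, contig_length=150_000)
        assert len(gen_annotation(cfg)) == 50

    def test_infeasible_packing_errors(self):
        cfg = SimConfig(seed=1, n_features=500, contig_length=10_000)
        with pytest.raises(ValueError):
            gen_annotation(cfg)


class TestCounts:
    def test_design_matches_study_layout(self):
        sheet = gen_sample_sheet(SimConfig(seed=0))
        validate_sample_sheet(sheet)
        assert len(sheet) == 36
        assert sheet.groupby(["strain", "timepoint"]).size().eq(3).all()
        assert sheet["batch"].nunique() == 3

    def test_poisson_limit_moments(self):
        cfg = SimConfig(seed=2, n_features=40, contig_length=80_000,
                        dispersion=1e-12, de_fraction=0.0,
                        size_factor_range=(1.0, 1.0), batch_log2fc=0.0,
                        baseline_log2_mean=10.0, baseline_log2_sd=0.0)
        ann = gen_annotation(cfg)
        counts, sheet, truth = gen_counts(cfg, ann)
        arr = counts.to_numpy(dtype=float)
        ratio = arr.var(axis=1, ddof=1) / arr.mean(axis=1)
        # Poisson: var/mean = 1; chi-square spread at 36 samples
        assert abs(np.mean(ratio) - 1.0) < 0.15

    def test_null_feature_means_match_baseline(self):
        cfg = SimConfig(seed=3, n_features=60, contig_length=120_000,
                        de_fraction=0.0, batch_log2fc=0.0,
                        size_factor_range=(1.0, 1.0), dispersion=0.02,
                        baseline_log2_mean=9.0, baseline_log2_sd=0.0)
        ann = gen_annotation(cfg)
        counts, sheet, truth = gen_counts(cfg, ann)
        q = 2.0 ** 9.0
        means = counts.mean(axis=1).to_numpy()
        se = np.sqrt((q + 0.02 * q * q) / 36)
        assert (np.abs(means - q) < 4 * se).mean() > 0.95

    def test_truth_table_consistent(self):
        cfg = SimConfig(seed=4, n_features=50, contig_length=100_000)
        ann = gen_annotation(cfg)
        counts, sheet, truth = gen_counts(cfg, ann)
        validate_counts(counts)
        n_de = (~truth["is_null"]).sum()
        assert n_de == round(cfg.de_fraction * 50)
        between_cols = [c for c in truth.columns if c.startswith("true_log2fc_between")]
        strain_rows = truth["effect_type"] == "strain"
        assert (truth.loc[strain_rows, between_cols].abs() == cfg.de_log2fc).all().all()
        assert (truth.loc[~strain_rows, between_cols] == 0).all().all()


class TestGapCounts:
    def test_planted_coverage_inverts_formula(self):
        cfg = SimConfig(seed=5, gap_coverages=(4.0,), dispersion=1e-12)
        sheet = gen_sample_sheet(cfg)
        from fermtx.annotation import GapRegion
        from fermtx.intervals import Interval

        gaps = [GapRegion("gap-1", Interval("c", 0, 500, "+"))]
        gap_counts, truth = gen_gap_counts(cfg, gaps, sheet)
        # expected count = 4 * 500 / 50 = 40 per sample
        assert abs(gap_counts.loc["gap-1"].mean() - 40.0) < 4 * np.sqrt(40 / 36)
        assert truth.loc["gap-1", "transcribed"]

    def test_planted_two_and_eight_fold_separate_cleanly(self):
        cfg = SimConfig(seed=6, n_features=40, contig_length=100_000,
                        gap_coverages=(2.0, 8.0))
        ann = gen_annotation(cfg)
        gaps = stranded_gaps(ann)
        sheet = gen_sample_sheet(cfg)
        gap_counts, truth = gen_gap_counts(cfg, gaps, sheet)
        import pandas as pd

        sf = pd.Series(1.0, index=gap_counts.columns)
        calls = {s.gap_id: s.is_nptr for s in call_nptrs(gap_counts, gaps, sf)}
        for gap_id, row in truth.iterrows():
            assert calls[gap_id] == row["transcribed"]


class TestOntology:
    def test_depth_one_is_star(self):
        cfg = SimConfig(seed=7, n_terms_per_level=(5,), term_size_range=(3, 6))
        genes = [f"g{i}" for i in range(30)]
        parents, annotation, truth = gen_ontology(cfg, genes, genes[:5])
        non_root = [t for t in parents if t != "root"]
        assert all(parents[t] == {"root"} for t in non_root)

    def test_planted_term_carries_de_excess(self):
        cfg = SimConfig(seed=8, n_enriched_terms=1, term_size_range=(10, 15))
        genes = [f"g{i}" for i in range(100)]
        de = genes[:20]
        parents, annotation, truth = gen_ontology(cfg, genes, de)
        enriched = truth.index[truth["enriched"]]
        assert len(enriched) == 1
        term = enriched[0]
        members = {g for g, ts in annotation.items() if term in ts}
        frac_de = len(members & set(de)) / len(members)
        assert frac_de >= 0.6  # observed/expected ratio >= 2 vs the 20% base rate


class TestProteins:
    def test_all_cds_complete_and_skew_flagged(self):
        cfg = SimConfig(seed=9, n_proteins=40,
                        skew_targets={"prot-amy": {"W": 3.0}, "prot-prsa": {"K": 3.5}})
        sequences, truth = gen_proteins(cfg)
        comps = compositions_from_cds(sequences)
        assert all(c.complete for c in comps.values())
        background = [c for cid, c in comps.items() if not cid.startswith("prot-a")
                      and not cid.startswith("prot-p")]
        bg = background_stats(background)
        assert "W" in z_flags(comps["prot-amy"], bg).flagged
        assert "K" in z_flags(comps["prot-prsa"], bg).flagged

    def test_unskewed_proteins_flag_at_background_rate(self):
        # without planted skew the per-residue flag rate stays near the
        # nominal 2-SD two-sided tail, far below what planted skew produces
        n_flags = 0
        n_pairs = 0
        for seed in range(5):
            cfg = SimConfig(seed=seed, n_proteins=30)
            sequences, _ = gen_proteins(cfg)
            comps = list(compositions_from_cds(sequences).values())
            bg = background_stats(comps)
            for c in comps:
                n_flags += len(z_flags(c, bg, flag_sd=2.0).flagged)
                n_pairs += 20
        assert n_flags / n_pairs < 0.10

    def test_deterministic_per_seed(self):
        cfg = SimConfig(seed=10, n_proteins=10)
        assert gen_proteins(cfg)[0] == gen_proteins(cfg)[0]


def test_emitted_gff_parses_back():
    cfg = SimConfig(seed=11, n_features=20, contig_length=60_000)
    ann = gen_annotation(cfg)
    text = _gff_bytes(ann)
    ann2 = read_gff(io.StringIO(text))
    assert len(ann2) == 20
    assert ann2.contig_lengths == ann.contig_lengths
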