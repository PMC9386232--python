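"""NB GLM fitting, screening LRT, Wald contrasts, filtering and the
stage-wise adjustment."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from fermtx.diffexpr import (
    ContrastSpec,
    TimecourseDEModel,
    build_design,
    contrast_vector,
    default_contrasts,
    independent_filter,
    screen_lrt,
    stagewise_adjust,
    wald_contrast,
)
from fermtx.glm import fit_nbglm
from fermtx.synth import SimConfig, gen_sample_sheet


def poisson_irls_oracle(y, X, offset, tol=1e-12, max_iter=200):
    """Self-contained Poisson IRLS, the alpha -> 0 reference."""
    beta = np.linalg.lstsq(X, np.log(y + 0.5) - offset, rcond=None)[0]
    for _ in range(max_iter):
        mu = np.exp(X @ beta + offset)
        W = mu
        z = (X @ beta) + (y - mu) / mu
        new = np.linalg.solve((X.T * W) @ X, (X.T * W) @ z)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


@pytest.fixture(scope="module")
def design36():
    sheet = gen_sample_sheet(SimConfig(seed=0))
    Xf, Xr, levels, colidx = build_design(sheet)
    return sheet, Xf, Xr, levels, colidx


class TestNBGLM:
    def test_poisson_limit_matches_poisson_irls_oracle(self, design36):
        _, Xf, _, _, _ = design36
        rng = np.random.default_rng(1)
        sf = np.exp(rng.normal(0, 0.2, Xf.shape[0]))
        y = rng.poisson(np.exp(rng.normal(5, 0.3, Xf.shape[0]))).astype(float)
        fit = fit_nbglm(y, sf, Xf, alpha=1e-8)
        oracle = poisson_irls_oracle(y, Xf, np.log(sf))
        assert np.max(np.abs(fit.beta - oracle)) < 1e-6

    def test_group_means_equal_normalized_sample_means(self):
        # saturated two-group model, no batch: the MLE fits the group means
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(6), np.repeat([0, 1], 3)])
        sf = np.array([1.0, 1.2, 0.8, 1.1, 0.9, 1.0])
        y = rng.poisson([100, 120, 80, 300, 280, 310]).astype(float)
        fit = fit_nbglm(y, sf, X, alpha=0.05)
        # Poisson limit with offsets: fitted group mean solves the weighted
        # score equation sum(y) = q * sum(sf)
        fit0 = fit_nbglm(y, sf, X, alpha=1e-8)
        assert np.exp(fit0.beta[0]) == pytest.approx(
            y[:3].sum() / sf[:3].sum(), rel=1e-6
        )
        assert np.exp(fit0.beta[0] + fit0.beta[1]) == pytest.approx(
            y[3:].sum() / sf[3:].sum(), rel=1e-6
        )
        # with unit size factors the NB group MLE is the plain sample mean
        # for any dispersion (the score equation is sum(y - mu) = 0)
        fit1 = fit_nbglm(y, np.ones(6), X, alpha=0.05)
        assert np.exp(fit1.beta[0]) == pytest.approx(y[:3].mean(), rel=1e-6)
        assert np.exp(fit1.beta[0] + fit1.beta[1]) == pytest.approx(y[3:].mean(), rel=1e-6)

    def test_constant_counts_give_zero_effects(self, design36):
        _, Xf, _, _, _ = design36
        y = np.full(Xf.shape[0], 50.0)
        fit = fit_nbglm(y, np.ones_like(y), Xf, alpha=1e-8)
        assert np.max(np.abs(fit.beta[1:])) < 1e-8

    def test_matches_statsmodels_at_fixed_dispersion(self, design36):
        _, Xf, _, _, _ = design36
        rng = np.random.default_rng(3)
        y = rng.negative_binomial(20, 20 / (20 + 200.0), Xf.shape[0]).astype(float)
        fit = fit_nbglm(y, np.ones_like(y), Xf, alpha=0.05)
        ref = sm.GLM(y, Xf, family=sm.families.NegativeBinomial(alpha=0.05)).fit()
        assert np.max(np.abs(fit.beta - ref.params)) < 1e-4
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((6, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_nbglm(np.ones(6), np.ones(6), X, alpha=0.1)


class TestScreenLRT:
    def test_identical_fits_give_p_one(self, design36):
        _, Xf, _, _, _ = design36
        y = np.full(Xf.shape[0], 30.0)
        fit = fit_nbglm(y, np.ones_like(y), Xf, alpha=1e-8)
        assert screen_lrt(fit, fit, df=11) == pytest.approx(1.0)

    def test_non_nested_rejected(self, design36):
        _, Xf, _, _, _ = design36
        y = np.full(Xf.shape[0], 30.0)
        fit = fit_nbglm(y, np.ones_like(y), Xf, alpha=1e-8)
        with pytest.raises(ValueError):
            screen_lrt(fit, fit, df=0)

    def test_null_screening_p_approximately_uniform(self, design36):
        # no condition effect: LRT p-values follow U(0,1) closely enough
        # for a KS test at a few hundred features
        from scipy.stats import kstest

        sheet, Xf, Xr, _, _ = design36
        rng = np.random.default_rng(4)
        sf = np.ones(Xf.shape[0])
        pvals = []
        for _ in range(300):
            mu = 2.0 ** rng.normal(7, 1)
            size = 1 / 0.05
            y = rng.negative_binomial(size, size / (size + mu), Xf.shape[0]).astype(float)
            full = fit_nbglm(y, sf, Xf)
            red = fit_nbglm(y, sf, Xr, alpha=full.alpha)
            pvals.append(screen_lrt(full, red, df=11, resid_df=Xf.shape[0] - Xf.shape[1]))
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_condition_effect_detected(self, design36):
        sheet, Xf, Xr, levels, colidx = design36
        rng = np.random.default_rng(5)
        is_prsa = (sheet["strain"] == "prsA").to_numpy()
        sf = np.ones(Xf.shape[0])
        pvals = []
        for _ in range(50):
            mu = 2.0 ** (8 + 2.0 * is_prsa)
            size = 1 / 0.05
            y = rng.negative_binomial(size, size / (size + mu)).astype(float)
            full = fit_nbglm(y, sf, Xf)
            red = fit_nbglm(y, sf, Xr, alpha=full.alpha)
            pvals.append(screen_lrt(full, red, df=11, resid_df=Xf.shape[0] - Xf.shape[1]))
        assert np.median(pvals) < 1e-4


class TestWald:
    def test_sign_antisymmetry(self, design36):
        _, Xf, _, levels, colidx = design36
        rng = np.random.default_rng(6)
        y = rng.poisson(100, Xf.shape[0]).astype(float)
        fit = fit_nbglm(y, np.ones_like(y), Xf, alpha=0.05)
        a, b = levels[2], levels[5]
        fwd = contrast_vector(
            ContrastSpec("f", "between_strain", a, b), colidx, Xf.shape[1]
        )
        lfc1, se1, p1 = wald_contrast(fit, fwd)
        lfc2, se2, p2 = wald_contrast(fit, -fwd)
        assert lfc1 == -lfc2 and se1 == se2 and p1 == p2

    def test_zero_contrast_is_null(self, design36):
        _, Xf, _, _, _ = design36
        y = np.full(Xf.shape[0], 40.0)
        fit = fit_nbglm(y, np.ones_like(y), Xf, alpha=1e-8)
        lfc, se, p = wald_contrast(fit, np.zeros(Xf.shape[1]))
        assert lfc == 0.0 and p == 1.0

    def test_contrast_requires_distinct_conditions(self):
        with pytest.raises(ValueError):
            ContrastSpec("x", "between_strain", "a", "a")

    def test_default_contrast_plan(self):
        contrasts = default_contrasts()
        assert len(contrasts) == 16
        assert sum(c.kind == "between_strain" for c in contrasts) == 6
        assert sum(c.kind == "within_strain" for c in contrasts) == 10


class TestIndependentFilter:
    def test_no_gain_keeps_everything(self):
        rng = np.random.default_rng(7)
        p = pd.Series(rng.uniform(0, 1, 50), index=[f"f{i}" for i in range(50)])
        means = pd.Series(rng.uniform(10, 100, 50), index=p.index)
        expressed, thr = independent_filter(p, means)
        assert expressed.all()
        assert thr == pytest.approx(float(np.percentile(means, 0)))

    def test_low_count_null_block_filtered(self):
        # 100 low-count nulls dilute 50 high-count true positives; the
        # exhaustive-scan optimum excludes the null block
        idx = [f"f{i}" for i in range(150)]
        p = pd.Series(
            np.concatenate([np.random.default_rng(8).uniform(0.2, 1, 100),
                            np.full(50, 0.004)]),
            index=idx,
        )
        means = pd.Series(np.concatenate([np.full(100, 1.0), np.full(50, 100.0)]), index=idx)
        expressed, thr = independent_filter(p, means, alpha=0.01)
        assert not expressed.iloc[:100].any()
        assert expressed.iloc[100:].all()
        # exhaustive oracle over every distinct threshold
        from statsmodels.stats.multitest import multipletests

        best = -1
        for cand in sorted(set(means)):
            mask = means >= cand
            rej = multipletests(p[mask], alpha=0.01, method="fdr_bh")[0].sum()
            best = max(best, rej)
        kept = multipletests(p[expressed], alpha=0.01, method="fdr_bh")[0].sum()
        assert kept == best

    def test_identical_means_all_expressed(self):
        p = pd.Series([0.5, 0.01, 0.9], index=list("abc"))
        means = pd.Series([10.0, 10.0, 10.0], index=list("abc"))
        expressed, _ = independent_filter(p, means)
        assert expressed.all()


class TestStagewise:
    def test_failed_screening_gives_all_na(self):
        screening = pd.Series({"a": 0.001, "b": 0.9})
        contrast_p = pd.DataFrame(
            0.0001, index=["a", "b"], columns=[f"c{i}" for i in range(16)]
        )
        adj, screened = stagewise_adjust(screening, contrast_p, alpha=0.01)
        assert screened["a"] and not screened["b"]
        assert adj.loc["b"].isna().all()

    def test_hand_traced_example(self):
        """m=3 features, BH screen keeps two, Holm within feature then
        scaled by m/|S| = 3/2."""
        screening = pd.Series({"f1": 0.001, "f2": 0.5, "f3": 0.004})
        cols = [f"c{i}" for i in range(16)]
        contrast_p = pd.DataFrame(1.0, index=["f1", "f2", "f3"], columns=cols)
        contrast_p.loc["f1", "c0"] = 0.0001
        contrast_p.loc["f1", "c1"] = 0.02
        adj, screened = stagewise_adjust(screening, contrast_p, alpha=0.01)
        assert list(screened[screened].index) == ["f1", "f3"]
        assert adj.loc["f1", "c0"] == pytest.approx(0.0001 * 16 * 1.5)
        assert adj.loc["f1", "c1"] == pytest.approx(0.02 * 15 * 1.5)
        assert (adj.loc["f1", cols[2:]] == 1.0).all()
        assert int((adj.loc["f1"] < 0.01).sum()) == 1

    def test_decision_monotonicity(self):
        rng = np.random.default_rng(9)
        screening = pd.Series(rng.uniform(0, 0.02, 20), index=[f"f{i}" for i in range(20)])
        contrast_p = pd.DataFrame(
            rng.uniform(0, 1, size=(20, 16)),
            index=screening.index,
            columns=[f"c{i}" for i in range(16)],
        )
        adj, _ = stagewise_adjust(screening, contrast_p, alpha=0.01)
        lowered = contrast_p.copy()
        lowered.iloc[:, 0] = lowered.iloc[:, 0] / 10
        adj2, _ = stagewise_adjust(screening, lowered, alpha=0.01)
        sig1 = (adj < 0.01).fillna(False)
        sig2 = (adj2 < 0.01).fillna(False)
        assert bool((sig2 | ~sig1).all().all())

    def test_empty_screen_returns_all_na(self):
        screening = pd.Series({"a": 0.9, "b": 0.95})
        contrast_p = pd.DataFrame(0.5, index=["a", "b"], columns=["c0"])
        adj, screened = stagewise_adjust(screening, contrast_p, alpha=0.01)
        assert not screened.any() and adj.isna().all().all()


class TestModelEndToEnd:
    def test_planted_strain_effect_recovered(self, small_sim):
        cfg, annotation, counts, sheet, truth = small_sim
        model = TimecourseDEModel(counts, sheet)
        results = model.fit(alpha=0.01)
        pf = results.per_feature()
        strain_planted = truth.index[truth["effect_type"] == "strain"]
        strain_planted = [f for f in strain_planted if f in pf.index]
        assert len(strain_planted) > 0
        # planted strain effects show up as strain-specific calls
        recovered = pf.loc[strain_planted, "strain_specific"]
        assert recovered.mean() >= 0.6
        # and estimated between-strain log2FCs carry the planted sign
        between = [c.label for c in results.contrasts if c.kind == "between_strain"]
        est = results.log2fc.loc[strain_planted, between].mean(axis=1)
        planted = truth.loc[strain_planted, "planted_log2fc"]
        assert (np.sign(est) == np.sign(planted)).all()

    def test_summary_mentions_counts(self, small_sim):
        cfg, annotation, counts, sheet, truth = small_sim
        results = TimecourseDEModel(counts, sheet).fit()
        text = results.summary()
        assert "differentially expressed" in text
        assert str(len(sheet)) in text
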