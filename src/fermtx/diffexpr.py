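"""Stage-wise time-course differential expression.

The model: per feature, counts follow a negative-binomial GLM with a
12-level condition factor (2 strains x 6 timepoints), an additive
sequencing-batch factor, and size factors as offsets.  Testing proceeds in
two stages so that the overall false-discovery rate is controlled at the
feature level rather than per hypothesis:

* screening — a likelihood-ratio test of the full condition model against a
  static model (intercept + batch), i.e. "does this feature move at all";
* confirmation — for features that pass a Benjamini-Hochberg screen, the 16
  pairwise Wald contrasts (6 between-strain, 2 x 5 consecutive
  within-strain) are Holm-adjusted within the feature and rescaled by
  m/|S|, the stage-wise correction that preserves the overall FDR.

Features with low average normalized counts are removed beforehand by the
independent-filtering scan that maximizes the number of discoveries.

The public surface follows the statsmodels convention: build a
:class:`TimecourseDEModel` from a count matrix and sample sheet, call
:meth:`~TimecourseDEModel.fit`, and read estimates and flags off the
returned :class:`TimecourseDEResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import quantify
from .glm import NBFit, fit_nbglm
from .quantify import STRAINS, TIMEPOINTS


@dataclass(frozen=True)
class ContrastSpec:
    """A pairwise comparison between two condition levels.

    ``log2FC`` is reported as condition_a minus condition_b: positive
    values mean higher expression in ``condition_a``.
    """

    label: str
    kind: str  # "between_strain" or "within_strain"
    condition_a: str
    condition_b: str

    def __post_init__(self) -> None:
        if self.kind not in ("between_strain", "within_strain"):
            raise ValueError(f"unknown contrast kind {self.kind!r}")
        if self.condition_a == self.condition_b:
            raise ValueError("contrast requires two distinct conditions")


def condition_label(strain: str, timepoint: int) -> str:
    return f"{strain}_{timepoint}h"


def default_contrasts(
    strains: Sequence[str] = STRAINS, timepoints: Sequence[int] = TIMEPOINTS
) -> List[ContrastSpec]:
    """The 16 standard tests: strain differences per timepoint, and
    consecutive-timepoint changes within each strain (later vs earlier)."""
    contrasts: List[ContrastSpec] = []
    for t in timepoints:
        contrasts.append(
            ContrastSpec(
                label=f"between_{t}h",
                kind="between_strain",
                condition_a=condition_label(strains[1], t),
                condition_b=condition_label(strains[0], t),
            )
        )
    for strain in strains:
        for t0, t1 in zip(timepoints[:-1], timepoints[1:]):
            contrasts.append(
                ContrastSpec(
                    label=f"{strain}_{t0}to{t1}h",
                    kind="within_strain",
                    condition_a=condition_label(strain, t1),
                    condition_b=condition_label(strain, t0),
                )
            )
    return contrasts


def build_design(
    sheet: pd.DataFrame,
) -> Tuple[np.ndarray, np.ndarray, List[str], Dict[str, int]]:
    """Full and reduced (static) design matrices from a sample sheet.

    Full: intercept + condition dummies (reference = first condition) +
    batch dummies.  Reduced: intercept + batch dummies.  Returns
    (X_full, X_reduced, condition levels, condition -> column index with
    -1 for the reference level).
    """
    cond = [
        condition_label(s, t) for s, t in zip(sheet["strain"], sheet["timepoint"])
    ]
    levels = sorted(set(cond))
    n = len(sheet)
    cond_cols = {lvl: i for i, lvl in enumerate(levels[1:])}
    batches = sorted(set(sheet["batch"].astype(str)))
    batch_cols = {b: i for i, b in enumerate(batches[1:])}

    X_cond = np.zeros((n, len(cond_cols)))
    for j, c in enumerate(cond):
        if c in cond_cols:
            X_cond[j, cond_cols[c]] = 1.0
    X_batch = np.zeros((n, len(batch_cols)))
    for j, b in enumerate(sheet["batch"].astype(str)):
        if b in batch_cols:
            X_batch[j, batch_cols[b]] = 1.0

    intercept = np.ones((n, 1))
    X_full = np.hstack([intercept, X_cond, X_batch])
    X_reduced = np.hstack([intercept, X_batch])
    col_index = {levels[0]: -1}
    col_index.update({lvl: 1 + i for lvl, i in cond_cols.items()})
    return X_full, X_reduced, levels, col_index


def contrast_vector(
    contrast: ContrastSpec, col_index: Dict[str, int], p: int
) -> np.ndarray:
    c = np.zeros(p)
    for cond, sign in ((contrast.condition_a, 1.0), (contrast.condition_b, -1.0)):
        if cond not in col_index:
            raise ValueError(f"condition {cond!r} not in design")
        idx = col_index[cond]
        if idx >= 0:
            c[idx] += sign
    return c


def screen_lrt(
    full: NBFit, reduced: NBFit, df: int, resid_df: Optional[int] = None
) -> float:
    """Likelihood-ratio p-value of the condition model vs the static model.

    Both fits must use the same dispersion.  The statistic is clipped at 0
    (the reduced model is nested, but finite-tolerance IRLS can leave a
    tiny negative difference).  With ``resid_df`` the statistic is referred
    to an F(df, resid_df) distribution (statistic / df), the
    quasi-likelihood-style small-sample reference that accounts for the
    per-feature estimated dispersion; without it, the asymptotic chi-square
    is used.
    """
    if df <= 0:
        raise ValueError("reduced design must be strictly nested in the full design")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if resid_df is not None:
        if resid_df <= 0:
            raise ValueError("resid_df must be positive")
        return float(stats.f.sf(stat / df, df, resid_df))
    return float(stats.chi2.sf(stat, df))


def wald_contrast(
    fit: NBFit, c: np.ndarray, resid_df: Optional[int] = None
) -> Tuple[float, float, float]:
    """(log2FC, SE, two-sided p) for a linear contrast of coefficients.

    With ``resid_df`` the statistic is referred to a t distribution (the
    small-sample companion of the F screening reference); otherwise to
    the normal.
    """
    if not np.any(c):
        return (0.0, 0.0, 1.0)  # a condition contrasted with itself
    if fit.cov is None:
        return (np.nan, np.nan, np.nan)
    est = float(c @ fit.beta)
    var = float(c @ fit.cov @ c)
    if var <= 0:
        return (np.nan, np.nan, np.nan)
    se = np.sqrt(var)
    z = est / se
    if resid_df is not None:
        p = 2.0 * stats.t.sf(abs(z), resid_df)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    ln2 = np.log(2.0)
    return (est / ln2, se / ln2, float(p))


def independent_filter(
    screening_p: pd.Series,
    mean_normalized_count: pd.Series,
    alpha: float = 0.01,
) -> Tuple[pd.Series, float]:
    """Choose the expression filter that maximizes screening discoveries.

    Candidate thresholds are the 0th..95th percentiles (step 1) of the
    mean normalized count.  For each, screening p-values of passing
    features are BH-adjusted and rejections at ``alpha`` counted; the
    smallest threshold achieving the maximum count wins.  Returns
    (expressed flags, chosen threshold).
    """
    means = mean_normalized_count.reindex(screening_p.index).to_numpy(dtype=float)
    pvals = screening_p.to_numpy(dtype=float)
    thresholds = np.percentile(means, np.arange(0, 96))
    best_count, best_thr = -1, thresholds[0]
    for thr in thresholds:
        mask = means >= thr
        p_sub = pvals[mask]
        ok = ~np.isnan(p_sub)
        if not ok.any():
            count = 0
        else:
            rej = multipletests(p_sub[ok], alpha=alpha, method="fdr_bh")[0]
            count = int(rej.sum())
        if count > best_count:
            best_count, best_thr = count, thr
    expressed = pd.Series(means >= best_thr, index=screening_p.index, name="expressed")
    return expressed, float(best_thr)


def stagewise_adjust(
    screening_p: pd.Series,
    contrast_p: pd.DataFrame,
    alpha: float = 0.01,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Two-stage adjustment of per-contrast p-values.

    Stage I: BH across the ``m`` entering features' screening p-values at
    ``alpha`` gives the screened set S.  Stage II: within each screened
    feature, Holm across its contrast p-values, then multiplied by m/|S|
    and capped at 1.  Features outside S get NA everywhere.  Returns
    (adjusted p matrix, screened flags).
    """
    contrast_p = contrast_p.reindex(screening_p.index)
    m = int(screening_p.notna().sum())
    screened = pd.Series(False, index=screening_p.index, name="screened")
    adj = pd.DataFrame(
        np.nan, index=contrast_p.index, columns=contrast_p.columns
    )
    if m == 0:
        return adj, screened
    ok = screening_p.notna()
    rej = multipletests(screening_p[ok], alpha=alpha, method="fdr_bh")[0]
    screened.loc[screening_p.index[ok]] = rej
    n_s = int(screened.sum())
    if n_s == 0:
        return adj, screened
    scale = m / n_s
    for feature in screened.index[screened]:
        row = contrast_p.loc[feature].to_numpy(dtype=float)
        valid = ~np.isnan(row)
        if not valid.any():
            continue
        holm = multipletests(row[valid], method="holm")[1]
        out = np.full(row.shape, np.nan)
        out[valid] = np.minimum(holm * scale, 1.0)
        adj.loc[feature] = out
    return adj, screened


class TimecourseDEModel:
    """NB time-course model over a count matrix and its sample sheet.

    Parameters
    ----------
    counts : DataFrame, features x samples, non-negative integers.
    sample_sheet : DataFrame with sample_id/strain/timepoint/replicate/batch.
    contrasts : the pairwise tests to confirm; defaults to the 16-test plan.
    size_factors : optional precomputed size factors (else median-of-ratios).

    Features with zero counts in every sample are dropped before fitting.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        sample_sheet: pd.DataFrame,
        contrasts: Optional[Sequence[ContrastSpec]] = None,
        size_factors: Optional[pd.Series] = None,
    ) -> None:
        sheet = quantify.validate_sample_sheet(sample_sheet)
        counts = quantify.validate_counts(counts)
        if list(counts.columns) != list(sheet["sample_id"]):
            counts = counts.loc[:, list(sheet["sample_id"])]
        nonzero = counts.sum(axis=1) > 0
        self.counts = counts.loc[nonzero]
        self.n_dropped_allzero = int((~nonzero).sum())
        self.sample_sheet = sheet
        timepoints = sorted(set(sheet["timepoint"]))
        strains = [s for s in STRAINS if s in set(sheet["strain"])]
        self.contrasts = (
            list(contrasts)
            if contrasts is not None
            else default_contrasts(strains, timepoints)
        )
        self.size_factors = (
            size_factors
            if size_factors is not None
            else quantify.size_factors(self.counts)
        )
        (
            self.X_full,
            self.X_reduced,
            self.condition_levels,
            self._col_index,
        ) = build_design(sheet)
        self.df_screen = (
            np.linalg.matrix_rank(self.X_full) - np.linalg.matrix_rank(self.X_reduced)
        )
        self.resid_df = self.X_full.shape[0] - np.linalg.matrix_rank(self.X_full)
        self._condition_of_sample = [
            condition_label(s, t) for s, t in zip(sheet["strain"], sheet["timepoint"])
        ]

    @classmethod
    def from_files(
        cls, counts_path: str, sample_sheet_path: str, **kwargs
    ) -> "TimecourseDEModel":
        return cls(
            quantify.read_counts(counts_path),
            quantify.read_sample_sheet(sample_sheet_path),
            **kwargs,
        )

    def fit(self, alpha: float = 0.01, profile_maxiter: int = 30) -> "TimecourseDEResults":
        """Fit every feature and run the full testing cascade at ``alpha``."""
        sf = self.size_factors.to_numpy(dtype=float)
        features = list(self.counts.index)
        n_contrasts = len(self.contrasts)
        cvecs = [
            contrast_vector(c, self._col_index, self.X_full.shape[1])
            for c in self.contrasts
        ]

        screening_p = pd.Series(np.nan, index=features, name="screening_p")
        dispersions = pd.Series(np.nan, index=features, name="dispersion")
        convergence = pd.Series(False, index=features, name="converged")
        log2fc = pd.DataFrame(np.nan, index=features, columns=[c.label for c in self.contrasts])
        se = log2fc.copy()
        wald_p = log2fc.copy()
        cond_means = pd.DataFrame(
            np.nan, index=features, columns=self.condition_levels
        )
        cond_arr = np.asarray(self._condition_of_sample)

        for feature in features:
            y = self.counts.loc[feature].to_numpy(dtype=float)
            full = fit_nbglm(y, sf, self.X_full, profile_maxiter=profile_maxiter)
            if not full.converged:
                continue
            reduced = fit_nbglm(y, sf, self.X_reduced, alpha=full.alpha)
            convergence.loc[feature] = True
            dispersions.loc[feature] = full.alpha
            screening_p.loc[feature] = screen_lrt(
                full, reduced, self.df_screen, resid_df=self.resid_df
            )
            for k, c in enumerate(cvecs):
                lfc, s_e, p = wald_contrast(full, c, resid_df=self.resid_df)
                label = self.contrasts[k].label
                log2fc.loc[feature, label] = lfc
                se.loc[feature, label] = s_e
                wald_p.loc[feature, label] = p
            norm_mu = full.mu / sf
            for lvl in self.condition_levels:
                cond_means.loc[feature, lvl] = float(norm_mu[cond_arr == lvl].mean())

        mean_norm = quantify.normalized_counts(self.counts, self.size_factors).mean(axis=1)
        expressed, filter_threshold = independent_filter(
            screening_p, mean_norm, alpha=alpha
        )
        entering = expressed & screening_p.notna()
        adj, screened_sub = stagewise_adjust(
            screening_p[entering], wald_p.loc[entering], alpha=alpha
        )
        stagewise_p = pd.DataFrame(
            np.nan, index=log2fc.index, columns=log2fc.columns
        )
        stagewise_p.loc[adj.index] = adj
        screened = pd.Series(False, index=log2fc.index, name="screened")
        screened.loc[screened_sub.index] = screened_sub

        return TimecourseDEResults(
            model=self,
            alpha=alpha,
            screening_p=screening_p,
            dispersions=dispersions,
            converged=convergence,
            log2fc=log2fc,
            se=se,
            wald_p=wald_p,
            stagewise_p=stagewise_p,
            expressed=expressed,
            screened=screened,
            filter_threshold=filter_threshold,
            mean_normalized_count=mean_norm,
            condition_means=cond_means,
        )


class TimecourseDEResults:
    """Estimates, adjusted p-values and flags from a fitted time course."""

    def __init__(
        self,
        model: TimecourseDEModel,
        alpha: float,
        screening_p: pd.Series,
        dispersions: pd.Series,
        converged: pd.Series,
        log2fc: pd.DataFrame,
        se: pd.DataFrame,
        wald_p: pd.DataFrame,
        stagewise_p: pd.DataFrame,
        expressed: pd.Series,
        screened: pd.Series,
        filter_threshold: float,
        mean_normalized_count: pd.Series,
        condition_means: pd.DataFrame,
    ) -> None:
        self.model = model
        self.alpha = alpha
        self.screening_p = screening_p
        self.dispersions = dispersions
        self.converged = converged
        self.log2fc = log2fc
        self.se = se
        self.wald_p = wald_p
        self.stagewise_p = stagewise_p
        self.expressed = expressed
        self.screened = screened
        self.filter_threshold = filter_threshold
        self.mean_normalized_count = mean_normalized_count
        self.condition_means = condition_means
        self.significant = (stagewise_p < alpha).fillna(False)

    @property
    def contrasts(self) -> List[ContrastSpec]:
        return self.model.contrasts

    def per_feature(self) -> pd.DataFrame:
        """One row per feature: flags and significant-contrast counts."""
        between = [c.label for c in self.contrasts if c.kind == "between_strain"]
        n_sig = self.significant.sum(axis=1)
        out = pd.DataFrame(
            {
                "mean_normalized_count": self.mean_normalized_count,
                "dispersion": self.dispersions,
                "screening_p": self.screening_p,
                "expressed": self.expressed,
                "screened": self.screened,
                "n_significant_contrasts": n_sig,
                "differentially_expressed": n_sig > 0,
                "strain_specific": self.significant[between].any(axis=1),
            }
        )
        out.index.name = "feature_id"
        return out

    def tidy(self) -> pd.DataFrame:
        """Long-format table: one row per feature x contrast."""
        rows = []
        for c in self.contrasts:
            rows.append(
                pd.DataFrame(
                    {
                        "feature_id": self.log2fc.index,
                        "contrast": c.label,
                        "kind": c.kind,
                        "log2fc": self.log2fc[c.label].to_numpy(),
                        "se": self.se[c.label].to_numpy(),
                        "wald_p": self.wald_p[c.label].to_numpy(),
                        "stagewise_adj_p": self.stagewise_p[c.label].to_numpy(),
                        "significant": self.significant[c.label].to_numpy(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> str:
        pf = self.per_feature()
        lines = [
            "Time-course differential expression (stage-wise NB GLM)",
            "=" * 56,
            f"features fitted:          {int(self.converged.sum())}"
            f" (of {len(self.converged)}; {int((~self.converged).sum())} not converged)",
            f"samples:                  {len(self.model.sample_sheet)}",
            f"contrasts:                {len(self.contrasts)}"
            f" ({sum(c.kind == 'between_strain' for c in self.contrasts)} between-strain)",
            f"overall FDR level:        {self.alpha}",
            f"independent filter:       mean normalized count >= {self.filter_threshold:.3f}",
            f"expressed features:       {int(pf['expressed'].sum())}",
            f"screened (stage I):       {int(pf['screened'].sum())}",
            f"differentially expressed: {int(pf['differentially_expressed'].sum())}",
            f"strain-specific:          {int(pf['strain_specific'].sum())}",
        ]
        return "\n".join(lines)
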