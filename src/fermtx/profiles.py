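"""Expression-profile construction and k-means clustering.

For every differentially expressed feature, a per-strain profile is built
from the model's expected normalized mean at each timepoint, log2-
transformed with a pseudocount and z-scaled across the timepoints.  The
two strain rows of one feature enter a single joint matrix, so a feature
may land in different clusters per strain.  Clustering is Lloyd k-means
(best of several random restarts); the cluster number can be picked from
the within-cluster sum-of-squares curve by maximum curvature (the "elbow").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .diffexpr import TimecourseDEResults, condition_label


def zscale_rows(matrix: pd.DataFrame) -> Tuple[pd.DataFrame, pd.Series]:
    """Row-wise z-scaling with sample (n-1) SD.

    Constant rows cannot be scaled; they become all-zero and are flagged.
    Returns (scaled matrix, constant-row flags).
    """
    arr = matrix.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant, 0] = 1.0
    scaled = (arr - mean) / sd
    scaled[constant] = 0.0
    return (
        pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns),
        pd.Series(constant, index=matrix.index, name="constant"),
    )


@dataclass
class ProfileMatrix:
    """Rows = (feature, strain); columns = timepoints; z-scaled log2 means."""

    values: pd.DataFrame  # MultiIndex (feature_id, strain) x timepoints
    constant: pd.Series  # flags for rows that were constant before scaling

    def __len__(self) -> int:
        return len(self.values)


def build_profiles(
    results: TimecourseDEResults,
    pseudocount: float = 1.0,
    features: Optional[Sequence[str]] = None,
) -> ProfileMatrix:
    """Z-scaled log2 expected-mean profiles per (feature, strain).

    By default profiles are built for the differentially expressed
    features.  The expected mean per timepoint is the fitted normalized
    mean of that (strain, timepoint) condition.
    """
    pf = results.per_feature()
    if features is None:
        features = list(pf.index[pf["differentially_expressed"]])
    sheet = results.model.sample_sheet
    strains = sorted(set(sheet["strain"]))
    timepoints = sorted(set(sheet["timepoint"]))
    rows = []
    index = []
    for feature in features:
        for strain in strains:
            cols = [condition_label(strain, t) for t in timepoints]
            rows.append(results.condition_means.loc[feature, cols].to_numpy(dtype=float))
            index.append((feature, strain))
    raw = pd.DataFrame(
        np.log2(np.asarray(rows, dtype=float) + pseudocount),
        index=pd.MultiIndex.from_tuples(index, names=["feature_id", "strain"]),
        columns=timepoints,
    )
    scaled, constant = zscale_rows(raw)
    return ProfileMatrix(values=scaled, constant=constant)


@dataclass
class ClusterResult:
    assignment: pd.Series  # row -> cluster id in 1..k
    wss: float
    k: int
    seed: int


def kmeans_cluster(
    profiles: ProfileMatrix, k: int = 10, restarts: int = 25, seed: int = 0
) -> ClusterResult:
    """Lloyd k-means on profile rows, best of ``restarts`` random inits."""
    arr = profiles.values.to_numpy(dtype=float)
    if k > arr.shape[0]:
        raise ValueError(f"k={k} exceeds the {arr.shape[0]} profile rows")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=restarts,
        algorithm="lloyd",
        random_state=seed,
    ).fit(arr)
    assignment = pd.Series(
        km.labels_ + 1, index=profiles.values.index, name="cluster"
    )
    return ClusterResult(assignment=assignment, wss=float(km.inertia_), k=k, seed=seed)


def wss_curve(
    profiles: ProfileMatrix, k_max: int = 15, restarts: int = 25, seed: int = 0
) -> pd.Series:
    """Total within-cluster sum of squares for k = 1..k_max."""
    ks = range(1, k_max + 1)
    return pd.Series(
        [kmeans_cluster(profiles, k=k, restarts=restarts, seed=seed).wss for k in ks],
        index=list(ks),
        name="wss",
    )


def elbow_select(wss: pd.Series) -> Tuple[int, bool]:
    """Pick k at the maximum curvature of the WSS curve.

    chosen_k = argmax over k in 2..k_max-1 of the second difference
    wss[k-1] - 2*wss[k] + wss[k+1]; ties resolve to the smallest k and are
    flagged.  Returns (chosen_k, tie_flag).
    """
    ks = sorted(wss.index)
    if len(ks) < 3:
        raise ValueError("elbow selection needs WSS for at least k = 1..3")
    curvature = {
        k: wss[k - 1] - 2.0 * wss[k] + wss[k + 1] for k in ks[1:-1]
    }
    best = max(curvature.values())
    winners = sorted(k for k, v in curvature.items() if v == best)
    return winners[0], len(winners) > 1
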