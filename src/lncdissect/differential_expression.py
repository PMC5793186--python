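"""Stage-wise differential expression, multi-comparison intersections, K-means archetypes.

The per-comparison test is a Welch (unequal-variance) two-sample t-test on
log2(FPKM + 1) replicate values, with Benjamini-Hochberg adjustment within
the comparison.  Fold change is computed from stage-mean FPKM with a
pseudocount of 1, so zero expression yields bounded log2 fold changes.
A feature is called up/down when |log2FC| strictly exceeds the fold-change
threshold AND the adjusted p is strictly below the significance level;
otherwise it is 'ns'.

Temporal archetypes: differentially expressed features are K-means-clustered
(Euclidean metric, multiple restarts) on per-feature standardised stage-mean
profiles, and the k=4 centroids are mapped to the four named archetypes:
K1 decreasing, K2 late-rising, K3 early-rising, K4 peaked at the second
stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .annotation_io import ExpressionMatrix
from .exceptions import ValidationError

DEFAULT_COMPARISONS = (("A1", "A0"), ("A3", "A1"), ("A5", "A3"), ("A5", "A0"))


def comparison_name(comparison: tuple[str, str]) -> str:
    b, a = comparison
    return f"{b}v{a}"


def differential_test(
    expr: ExpressionMatrix,
    comparison: tuple[str, str],
    epsilon: float = 1.0,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Test one stage pair ``(b, a)`` meaning "b vs a" for every feature.

    Returns a DataFrame indexed by feature id with columns ``log2fc``, ``p``,
    ``p_adjust`` and ``call`` (up/down/ns).  Features identical across both
    stages get p = 1; features with zero replicate variance but different
    means get p = 0 (the noise-free limit).
    """
    b, a = comparison
    samples_b, samples_a = expr.samples_of(b), expr.samples_of(a)
    if len(samples_b) < 2 or len(samples_a) < 2:
        raise ValidationError("both stages need >= 2 replicates")

    vb = expr.values[samples_b].to_numpy(dtype=float)
    va = expr.values[samples_a].to_numpy(dtype=float)
    log2fc = np.log2(vb.mean(axis=1) + epsilon) - np.log2(va.mean(axis=1) + epsilon)

    lb, la = np.log2(vb + 1.0), np.log2(va + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    # exact all-equal test: np.std of identical values can round away from 0
    zero_var = ((lb == lb[:, :1]).all(axis=1)) & ((la == la[:, :1]).all(axis=1))
    mean_diff = lb.mean(axis=1) - la.mean(axis=1)
    p = np.where(np.isnan(p), np.where(np.abs(mean_diff) > 0, 0.0, 1.0), p)
    p = np.where(zero_var & (np.abs(mean_diff) > 0), 0.0, p)
    p = np.where(zero_var & (np.abs(mean_diff) == 0), 1.0, p)

    p_adjust = multipletests(p, method="fdr_bh")[1]
    call = np.where(
        (np.abs(log2fc) > lfc_threshold) & (p_adjust < alpha),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "p_adjust": p_adjust, "call": call},
        index=expr.values.index,
    )


def call_de_sets(
    tables: Mapping[str, pd.DataFrame]
) -> dict[str, dict[str, set[str]]]:
    """Extract deterministic up/down id sets from per-comparison DE tables."""
    out: dict[str, dict[str, set[str]]] = {}
    for name, table in tables.items():
        out[name] = {
            "up": set(table.index[table["call"] == "up"]),
            "down": set(table.index[table["call"] == "down"]),
        }
    return out


def run_comparisons(
    expr: ExpressionMatrix,
    comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """differential_test over a list of comparisons, keyed by 'BvA' names."""
    return {comparison_name(c): differential_test(expr, c, **kwargs)
            for c in comparisons}


def venn_intersections(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts for 2-5 named sets.

    Keys are tuples of the set names an element belongs to (in input order);
    all 2^k - 1 membership patterns are present, zero counts included.  The
    full-intersection region is the key with every name.
    """
    names = list(sets)
    if not 2 <= len(names) <= 5:
        raise ValidationError("venn_intersections supports 2-5 sets")
    counts: dict[tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            counts[combo] = 0
    for element in set().union(*sets.values()):
        pattern = tuple(n for n in names if element in sets[n])
        counts[pattern] += 1
    return counts


# ---------------------------------------------------------------------------
# K-means archetypes
# ---------------------------------------------------------------------------


@dataclass
class ClusterAssignment:
    """K-means result: integer labels, centroids, and K1-K4 archetype names."""

    labels: pd.Series                   # feature id -> cluster index
    centroids: pd.DataFrame             # cluster index x stages
    inertia: float
    archetypes: dict[int, str] | None = None  # cluster index -> K1..K4

    @property
    def sizes(self) -> dict[int, int]:
        return self.labels.value_counts().sort_index().to_dict()

    def archetype_labels(self) -> pd.Series:
        if self.archetypes is None:
            raise ValidationError("archetypes not assigned (k != 4?)")
        return self.labels.map(self.archetypes)


def zscore_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Standardise each feature's stage profile (flat rows map to all zeros)."""
    arr = profiles.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mean) / sd, index=profiles.index,
                        columns=profiles.columns)


def kmeans_cluster(
    deg_profiles: pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    n_init: int = 10,
    zscore: bool = True,
) -> ClusterAssignment:
    """Lloyd's K-means with Euclidean metric on (optionally standardised)
    stage-mean profiles; the best of *n_init* restarts is kept."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if len(deg_profiles) < k:
        raise ValidationError(f"k={k} exceeds number of features {len(deg_profiles)}")
    X = zscore_profiles(deg_profiles) if zscore else deg_profiles
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X.to_numpy(dtype=float))
    assignment = ClusterAssignment(
        labels=pd.Series(labels, index=deg_profiles.index, name="cluster"),
        centroids=pd.DataFrame(km.cluster_centers_, columns=deg_profiles.columns),
        inertia=float(km.inertia_),
    )
    if k == 4:
        assignment.archetypes = archetype_label(assignment.centroids)
    return assignment


def _rise_center(c: np.ndarray) -> float:
    """Weighted mean position of positive increments; larger = later rise."""
    inc = np.clip(np.diff(c), 0, None)
    if inc.sum() == 0:
        return 0.0
    return float((np.arange(1, len(c)) * inc).sum() / inc.sum())


def archetype_label(centroids: pd.DataFrame) -> dict[int, str]:
    """Map four centroids (rows) over ordered stages to K1-K4 semantics.

    K1: most negative Spearman trend against stage order.  K4: of the rest,
    the centroid peaking at the second stage (largest second-stage excess
    over all other stages).  The remaining two are K2 (later rise) and K3
    (earlier rise).  Ambiguities resolve to the lower cluster index with a
    warning.
    """
    if len(centroids) != 4:
        raise ValidationError("archetype_label expects exactly 4 centroids")
    order = np.arange(centroids.shape[1])
    idx = list(centroids.index)

    rhos = {}
    for i in idx:
        c = centroids.loc[i].to_numpy(dtype=float)
        if np.ptp(c) == 0:
            warnings.warn(f"centroid {i} is flat; archetype labels degenerate")
            rhos[i] = 0.0
        else:
            rhos[i] = float(stats.spearmanr(c, order).statistic)
    k1 = min(idx, key=lambda i: (rhos[i], i))

    rest = [i for i in idx if i != k1]
    peak = {i: float(centroids.loc[i].iloc[1]
                     - centroids.loc[i].drop(centroids.columns[1]).max())
            for i in rest}
    k4 = max(rest, key=lambda i: (peak[i], -i))

    k2k3 = [i for i in rest if i != k4]
    centers = {i: _rise_center(centroids.loc[i].to_numpy(dtype=float)) for i in k2k3}
    if centers[k2k3[0]] == centers[k2k3[1]]:
        warnings.warn("tied rise centers; K2/K3 broken by cluster index")
    k2 = max(k2k3, key=lambda i: (centers[i], -i))
    k3 = k2k3[0] if k2 == k2k3[1] else k2k3[1]
    return {k1: "K1", k2: "K2", k3: "K3", k4: "K4"}


def cluster_degs(
    expr: ExpressionMatrix,
    deg_ids: Iterable[str],
    k: int = 4,
    seed: int = 0,
    n_init: int = 10,
    zscore: bool = True,
) -> ClusterAssignment:
    """Convenience: stage-mean profiles of the DEG set, then K-means."""
    ids = sorted(deg_ids)
    profiles = expr.stage_means().loc[ids]
    return kmeans_cluster(profiles, k=k, seed=seed, n_init=n_init, zscore=zscore)
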