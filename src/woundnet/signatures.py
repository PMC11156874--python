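"""Gene signatures of the wound program and the three temporal stages.

Covers the expression filters (highly expressed iDEGs, wound-induced
genes), the fold-change trajectory matrix, k-means trajectory clustering
with elbow-based k selection, the timepoint-correlation view of the three
stages (Response 0.25 h, Repair 0.5-4 h, Remodeling 6-24 h), and generic
hypergeometric gene-set enrichment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .pointwise import bh_adjust, normalized_counts

STAGE_TIMEPOINTS: dict[str, tuple[float, ...]] = {
    "S1": (0.25,),
    "S2": (0.5, 1.0, 2.0, 4.0),
    "S3": (6.0, 10.0, 12.0, 14.0, 16.0, 18.0, 24.0),
}
STAGE_LABELS = {"S1": "Response", "S2": "Repair", "S3": "Remodeling"}


def stage_of_timepoint(t: float,
                       stages: dict[str, tuple[float, ...]] | None = None) -> str:
    stages = stages or STAGE_TIMEPOINTS
    for stage, tps in stages.items():
        if t in tps:
            return stage
    raise KeyError(f"timepoint {t} not in any stage")


# ---------------------------------------------------------------------------
# trajectory matrix


def median_expression(counts: pd.DataFrame, design: pd.DataFrame,
                      size_factors: pd.Series) -> dict[str, pd.DataFrame]:
    """Per-condition gene x timepoint medians of normalized counts."""
    norm = normalized_counts(counts, size_factors)
    out = {}
    for cond in ("UW", "W"):
        cols = {}
        sub = design[design["condition"] == cond]
        for t, grp in sub.groupby("timepoint_h"):
            cols[t] = norm[list(grp["sample_id"])].median(axis=1)
        out[cond] = pd.DataFrame(cols).sort_index(axis=1)
    return out


def trajectory_matrix(counts: pd.DataFrame, design: pd.DataFrame,
                      size_factors: pd.Series, pseudocount: float = 1.0,
                      include_pseudo_zero: bool = True) -> pd.DataFrame:
    """log2 fold-change trajectory matrix of median normalized counts.

    Entry (g, t) = log2((median_W + c) / (median_UW + c)); a pseudo-0 column
    of zeros is prepended so trajectories start from a shared baseline.
    """
    med = median_expression(counts, design, size_factors)
    common = [t for t in med["W"].columns if t in med["UW"].columns]
    mat = np.log2((med["W"][common] + pseudocount)
                  / (med["UW"][common] + pseudocount))
    if include_pseudo_zero:
        mat.insert(0, 0.0, 0.0)
    return mat


# ---------------------------------------------------------------------------
# signature filters


def select_hidegs(ideg_ids, counts: pd.DataFrame, design: pd.DataFrame,
                  size_factors: pd.Series, top_fraction: float = 0.75,
                  fc_cut: float = 2.0, pseudocount: float = 1.0) -> list[str]:
    """Highly expressed iDEGs.

    Keep genes that (1) fall in the top ``top_fraction`` of iDEGs sorted by
    overall median expression (median_W + median_UW, descending; ties broken
    by gene id) and (2) show a median fold change beyond ``fc_cut`` in either
    direction at >= 1 timepoint (strict, on pseudocounted medians).
    """
    ideg_ids = sorted(set(ideg_ids))
    if not ideg_ids:
        raise ValueError("iDEG set is empty")
    med = median_expression(counts, design, size_factors)
    overall = (med["W"].loc[ideg_ids].median(axis=1)
               + med["UW"].loc[ideg_ids].median(axis=1))
    order = sorted(ideg_ids, key=lambda g: (-overall[g], g))
    n_keep = int(np.ceil(top_fraction * len(order)))
    top = set(order[:n_keep])
    common = [t for t in med["W"].columns if t in med["UW"].columns]
    ratio = (med["W"].loc[ideg_ids, common] + pseudocount) \
        / (med["UW"].loc[ideg_ids, common] + pseudocount)
    passes_fc = ((ratio > fc_cut) | (ratio < 1.0 / fc_cut)).any(axis=1)
    return sorted(g for g in ideg_ids if g in top and passes_fc[g])


def define_wound_induced(hideg_ids, pointwise_results: pd.DataFrame,
                         q_cut: float = 0.05, log2fc_cut: float = 1.0) -> list[str]:
    """hiDEGs with significant >2-fold up-regulation at >= 1 timepoint."""
    hidegs = set(hideg_ids)
    hit = pointwise_results[
        (pointwise_results["q"] < q_cut)
        & (pointwise_results["log2fc"] > log2fc_cut)
        & pointwise_results["gene_id"].isin(hidegs)]
    return sorted(set(hit["gene_id"]))


# ---------------------------------------------------------------------------
# clustering


def choose_k_elbow(matrix: pd.DataFrame, k_max: int = 12, seed: int = 0,
                   n_restarts: int = 10) -> tuple[int, np.ndarray]:
    """Elbow choice of k: argmax of the second forward difference of the
    within-cluster SS curve over k = 1..k_max."""
    X = matrix.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        return 1, np.zeros(k_max)
    ss = np.empty(k_max)
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        km.fit(X)
        ss[k - 1] = km.inertia_
    # second forward difference at k: ss[k-1] - 2 ss[k] + ss[k+1]
    curvature = ss[:-2] - 2.0 * ss[1:-1] + ss[2:]
    k = int(np.argmax(curvature)) + 2
    return k, ss


def cluster_trajectories(matrix: pd.DataFrame, k: int, seed: int = 0,
                         n_restarts: int = 25) -> tuple[pd.Series, pd.DataFrame]:
    """Best-of-restarts k-means on log2FC rows, labels C1..Ck.

    Clusters are renumbered by the time of their composite (mean trajectory)
    peak, earliest first, so labels are stable under row permutation.
    Returns (gene -> cluster label, cluster x timepoint composite).
    """
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds {len(matrix)} rows")
    X = matrix.to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)
    composites = {}
    for c in range(k):
        composites[c] = X[raw == c].mean(axis=0)
    # canonical order: peak time, then descending peak height, largest first
    def key(c):
        comp = composites[c]
        peak = int(np.argmax(comp))
        return (matrix.columns[peak], -comp[peak])
    order = sorted(range(k), key=key)
    relabel = {c: f"C{i + 1}" for i, c in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=matrix.index,
                       name="cluster")
    composite = pd.DataFrame(
        {relabel[c]: composites[c] for c in range(k)},
        index=matrix.columns).T.sort_index()
    return labels, composite


def timepoint_correlation_stages(matrix: pd.DataFrame, n_groups: int = 3
                                 ) -> tuple[pd.DataFrame, dict[int, list[float]]]:
    """Pearson correlation between timepoint columns and its 3-block cut.

    Average-linkage hierarchical clustering on distance 1 - r; warns when the
    groups are not contiguous in time (the wound data yields contiguous
    early/middle/late blocks).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 timepoints")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [matrix.columns[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance timepoint column(s): {bad}")
    corr = np.corrcoef(X.T)
    corr_df = pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)
    if matrix.shape[1] < n_groups:
        raise ValueError(f"cannot form {n_groups} groups from "
                         f"{matrix.shape[1]} timepoints")
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    if dist.max() < 1e-10:
        warnings.warn("all timepoints perfectly correlated: a single "
                      "effective block")
        return corr_df, {1: list(matrix.columns)}
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    grp = hierarchy.fcluster(link, t=n_groups, criterion="maxclust")
    if len(set(grp)) < n_groups:
        warnings.warn("fewer effective timepoint blocks than requested "
                      "(near-identical columns)")
    groups: dict[int, list[float]] = {}
    for t, g in zip(matrix.columns, grp):
        groups.setdefault(int(g), []).append(t)
    for g, tps in groups.items():
        idx = [list(matrix.columns).index(t) for t in tps]
        if max(idx) - min(idx) + 1 != len(idx):
            warnings.warn(f"timepoint group {tps} is not contiguous in time")
    return corr_df, groups


def assign_stages(matrix: pd.DataFrame, seed: int = 0, k: int = 3,
                  onset_cut: float = 1.0,
                  stages: dict[str, tuple[float, ...]] | None = None
                  ) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster wound-induced trajectories into k=3 groups and label stages.

    Each cluster's onset is the earliest timepoint where its composite
    log2FC reaches ``onset_cut``; the cluster maps to the stage whose
    timepoint set contains that onset. A cluster whose composite never
    reaches the cut maps to the stage of its composite peak, with a warning.
    """
    if k != 3:
        raise ValueError("stage assignment is defined for k=3")
    stages = stages or STAGE_TIMEPOINTS
    labels, composite = cluster_trajectories(matrix, k=k, seed=seed)
    stage_of_cluster = {}
    for c in composite.index:
        comp = composite.loc[c]
        onset_tps = [t for t in comp.index if t > 0 and comp[t] >= onset_cut]
        if onset_tps:
            onset = min(onset_tps)
        else:
            post = [t for t in comp.index if t > 0]
            onset = max(post, key=lambda t: abs(comp[t]))
            warnings.warn(
                f"cluster {c}: composite never reaches {onset_cut}; "
                f"mapped via its absolute peak at {onset} h")
        stage_of_cluster[c] = stage_of_timepoint(onset, stages)
    if len(set(stage_of_cluster.values())) < k:
        warnings.warn("multiple clusters map to the same stage")
    stage = labels.map(stage_of_cluster).rename("stage")
    out = pd.DataFrame({"cluster": labels, "stage": stage})
    out["stage_label"] = out["stage"].map(STAGE_LABELS)
    return out, composite


# ---------------------------------------------------------------------------
# gene-set enrichment


def gene_set_enrichment(query, collection, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each gene set.

    p = P(X >= k) with population N = |universe|, K = |set & universe|,
    n = |query| draws; BH adjustment across sets.
    """
    query = set(query)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for set_id, (desc, members) in collection.sets.items():
        K = len(members & universe)
        k = len(members & query)
        expected = n * K / N if N else 0.0
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set_id": set_id, "description": desc, "overlap": k,
                     "set_size": K, "expected": expected, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
    return table
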