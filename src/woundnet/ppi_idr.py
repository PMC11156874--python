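"""Protein-interaction and disorder statistics for TF modules.

Topic TF sets are tested for excess within-set PPI edges against uniform
same-size draws from the TF universe; intrinsically disordered region
(IDR) presence and length fractions are compared between TF groups; and
chromatin-factor overlap is scored hypergeometrically.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def ppi_adjacency(ppi_edges: pd.DataFrame, proteins: list[str]) -> np.ndarray:
    """Symmetric boolean adjacency over ``proteins`` from an edge list."""
    index = {p: i for i, p in enumerate(proteins)}
    adj = np.zeros((len(proteins), len(proteins)), dtype=bool)
    for a, b in ppi_edges[["protein_a", "protein_b"]].itertuples(index=False):
        if a in index and b in index and a != b:
            adj[index[a], index[b]] = adj[index[b], index[a]] = True
    return adj


def ppi_degrees(ppi_edges: pd.DataFrame, proteins: list[str]) -> pd.Series:
    adj = ppi_adjacency(ppi_edges, proteins)
    return pd.Series(adj.sum(axis=1), index=proteins, name="ppi_degree")


def topic_ppi_enrichment(topic_tf_sets: dict[str, set[str]],
                         ppi_edges: pd.DataFrame, universe: list[str],
                         n_perm: int = 1000, seed: int = 0,
                         degree_preserving: bool = False) -> pd.DataFrame:
    """Within-topic PPI edge counts versus random same-size TF draws.

    p = (1 + #{null >= observed}) / (n_perm + 1). With
    ``degree_preserving`` the null shuffles edge stubs instead of drawing
    uniform sets (kept as an option; uniform draws are the default null).
    Topic sets of size < 2 are reported NA.
    """
    universe = sorted(set(universe))
    adj = ppi_adjacency(ppi_edges, universe)
    index = {p: i for i, p in enumerate(universe)}
    rng = np.random.default_rng(seed)
    rows = []
    for topic in sorted(topic_tf_sets):
        members = sorted(set(topic_tf_sets[topic]) & set(universe))
        m = len(members)
        if m < 2:
            rows.append({"topic": topic, "n_tfs": m, "observed": np.nan,
                         "expected": np.nan, "p": np.nan})
            continue
        idx = np.array([index[p] for p in members])
        observed = int(adj[np.ix_(idx, idx)].sum() // 2)
        null = np.empty(n_perm, dtype=np.int64)
        for i in range(n_perm):
            if degree_preserving:
                draw = _degree_matched_draw(adj, idx, rng)
            else:
                draw = rng.choice(len(universe), size=m, replace=False)
            null[i] = adj[np.ix_(draw, draw)].sum() // 2
        p = (1.0 + float((null >= observed).sum())) / (n_perm + 1.0)
        rows.append({"topic": topic, "n_tfs": m, "observed": observed,
                     "expected": float(null.mean()), "p": p})
    return pd.DataFrame(rows)


def _degree_matched_draw(adj: np.ndarray, idx: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw a same-size set matching the observed set's degree ranks."""
    degrees = adj.sum(axis=1)
    order = np.argsort(degrees, kind="stable")
    ranks = np.empty(len(degrees), dtype=np.int64)
    ranks[order] = np.arange(len(degrees))
    picked = []
    taken = np.zeros(len(degrees), dtype=bool)
    for i in idx:
        # candidates within +-10% degree rank
        window = max(1, len(degrees) // 10)
        cands = order[max(ranks[i] - window, 0): ranks[i] + window + 1]
        cands = cands[~taken[cands]]
        choice = int(rng.choice(cands)) if len(cands) else int(i)
        picked.append(choice)
        taken[choice] = True
    return np.asarray(picked)


def idr_presence_test(group_a: set[str], group_b: set[str],
                      idr: pd.DataFrame) -> dict:
    """One-sided Fisher exact test: IDR presence enriched in group A."""
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if group_a & group_b:
        raise ValueError("groups must be disjoint")
    with_idr = set(idr["protein_id"])
    a_with = len(group_a & with_idr)
    b_with = len(group_b & with_idr)
    table = [[a_with, len(group_a) - a_with],
             [b_with, len(group_b) - b_with]]
    _, p = stats.fisher_exact(table, alternative="greater")
    return {"table": table, "p": float(p),
            "prop_a": a_with / len(group_a), "prop_b": b_with / len(group_b)}


def idr_fraction_test(fractions_a, fractions_b) -> dict:
    """One-sided Wilcoxon rank-sum test that group A has larger IDR
    fractions; exact for small untied samples, normal with tie correction
    otherwise."""
    a = np.asarray(list(fractions_a), dtype=float)
    b = np.asarray(list(fractions_b), dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 annotated proteins per group")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        warnings.warn("all IDR fractions tied; test uninformative")
        return {"p": 1.0, "median_a": float(np.median(a)),
                "median_b": float(np.median(b))}
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 25 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    return {"p": float(res.pvalue), "median_a": float(np.median(a)),
            "median_b": float(np.median(b)), "method": method}


def idr_ppi_correlation(idr_values: pd.Series, degrees: pd.Series) -> dict:
    """Spearman correlation between IDR extent and PPI degree."""
    common = sorted(set(idr_values.index) & set(degrees.index))
    if len(common) < 4:
        raise ValueError("need >= 4 paired observations")
    x = idr_values.reindex(common).to_numpy(dtype=float)
    y = degrees.reindex(common).to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"r": np.nan, "p": np.nan, "n": len(common),
                "reason": "constant vector"}
    r, p = stats.spearmanr(x, y)
    return {"r": float(r), "p": float(p), "n": len(common)}


def chromatin_factor_overlap(network_tfs: set[str],
                             chromatin_factors: set[str],
                             tf_universe: set[str]) -> dict:
    """Overlap of network TFs with annotated chromatin factors plus an
    upper-tail hypergeometric enrichment p against the TF universe."""
    if not network_tfs or not chromatin_factors:
        raise ValueError("inputs must be non-empty")
    universe = set(tf_universe)
    query = set(network_tfs) & universe
    cf = set(chromatin_factors) & universe
    overlap = query & cf
    N, K, n, k = len(universe), len(cf), len(query), len(overlap)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
    return {"overlap": sorted(overlap), "k": k, "p": p}
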