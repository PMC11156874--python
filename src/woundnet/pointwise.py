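"""Per-timepoint wounded-vs-unwounded differential expression.

A transparent negative-binomial Wald test: median-of-ratios size factors,
method-of-moments gene dispersions pooled across replicate groups, and a
per-gene NB log-link fit of the condition contrast at each timepoint.
DEGs are called at BH-adjusted p < 0.05 and fold change > 1.5 (strict), the
cutoffs used for the wound time course.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA_FLOOR = 0.01


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios sequencing-depth factors, geometric mean rescaled to 1.

    Only genes with nonzero counts in every sample enter the geometric-mean
    reference, matching the standard median-of-ratios estimator.
    """
    arr = counts.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; median-of-ratios "
            "undefined (consider a pseudocount)")
    ref = arr[allpos]
    geomean = np.exp(np.log(ref).mean(axis=1))
    s = np.median(ref / geomean[:, None], axis=0)
    s = s / np.exp(np.log(s).mean())  # geometric mean 1
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    return counts / size_factors.reindex(counts.columns)


def compute_fpkm(counts: pd.DataFrame, size_factors: pd.Series,
                 annotation: pd.DataFrame) -> pd.DataFrame:
    """FPKM_gj = count_gj * 1e9 / (s_j * total_j * length_g)."""
    lengths = annotation["length_nt"].reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:3]
        raise ValueError(f"genes missing from annotation: {missing}")
    totals = counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise ValueError("zero library size")
    denom = size_factors.reindex(counts.columns) * totals
    return counts * 1e9 / denom / lengths.to_numpy()[:, None]


def _group_keys(design: pd.DataFrame) -> pd.Series:
    return design["condition"].astype(str) + "@" + design["timepoint_h"].astype(str)


def estimate_dispersion(counts: pd.DataFrame, size_factors: pd.Series,
                        design: pd.DataFrame) -> pd.Series:
    """Per-gene NB dispersion alpha (Var = mu + alpha*mu^2), floored at 0.01.

    Method of moments on normalized counts within each (condition, timepoint)
    replicate group, clipped at zero per group and averaged across groups.
    The denominator uses the standard plug-in-mean correction m^2 - s^2/n
    (E[m_hat^2] = mu^2 + Var/n), which removes the small-sample downward
    bias that would otherwise make downstream Wald tests anticonservative.
    """
    norm = normalized_counts(counts, size_factors).to_numpy()
    keys = _group_keys(design)
    estimates = []
    for _, idx in design.groupby(keys, sort=False).groups.items():
        cols = design.index.get_indexer(idx)
        sub = norm[:, cols]
        n = sub.shape[1]
        if n < 2:
            raise ValueError("each (condition, timepoint) group needs >=2 replicates")
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        den = m**2 - v / n
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / den
        a[~np.isfinite(a) | (den <= 0)] = 0.0
        estimates.append(np.clip(a, 0.0, None))
    alpha = np.mean(estimates, axis=0)
    alpha = np.maximum(alpha, ALPHA_FLOOR)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _nb_group_mle(y: np.ndarray, s: np.ndarray, alpha: np.ndarray,
                  n_iter: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Newton solve of the NB log-mean per gene for one group.

    y: genes x reps counts; s: reps size factors; alpha: genes dispersions.
    Returns (eta = log mu, fisher info of eta).
    """
    mean0 = (y / s[None, :]).mean(axis=1)
    eta = np.log(np.maximum(mean0, 1e-8))
    lo, hi = np.log(1e-8), np.log(1e12)
    for _ in range(n_iter):
        mu = s[None, :] * np.exp(eta)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        eta = np.clip(eta + np.clip(step, -5, 5), lo, hi)
    mu = s[None, :] * np.exp(eta)[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return eta, info


def wald_test_timepoint(counts: pd.DataFrame, design: pd.DataFrame,
                        timepoint_h: float, dispersion: pd.Series,
                        size_factors: pd.Series | None = None) -> pd.DataFrame:
    """NB Wald test of W vs UW at one timepoint.

    The log-link GLM with a condition indicator reduces to separate
    group-mean fits; log2fc is the W/UW log-mean contrast, its standard
    error comes from the per-group Fisher information, and the two-sided
    p-value from the normal reference. All-zero genes are reported as ns
    with p = 1.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    sel = design["timepoint_h"] == timepoint_h
    sub = design[sel]
    conds = set(sub["condition"])
    if conds != {"UW", "W"}:
        raise ValueError(f"both conditions required at t={timepoint_h}, got {conds}")
    alpha = dispersion.reindex(counts.index).to_numpy()
    etas, infos = {}, {}
    for cond in ("UW", "W"):
        samples = sub.loc[sub["condition"] == cond, "sample_id"]
        y = counts[list(samples)].to_numpy(dtype=float)
        s = size_factors.reindex(samples).to_numpy()
        etas[cond], infos[cond] = _nb_group_mle(y, s, alpha)
    delta = etas["W"] - etas["UW"]
    se = np.sqrt(1.0 / np.maximum(infos["W"], 1e-12)
                 + 1.0 / np.maximum(infos["UW"], 1e-12))
    z = delta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    allzero = (counts[list(sub["sample_id"])].to_numpy() == 0).all(axis=1)
    z[allzero] = 0.0
    p[allzero] = 1.0
    delta[allzero] = 0.0
    res = pd.DataFrame({
        "gene_id": counts.index,
        "timepoint_h": timepoint_h,
        "log2fc": delta / np.log(2.0),
        "se": se / np.log(2.0),
        "wald_z": z,
        "p": p,
    })
    res["q"] = bh_adjust(res["p"].to_numpy())
    return res


def run_pointwise(counts: pd.DataFrame, design: pd.DataFrame,
                  size_factors: pd.Series | None = None,
                  dispersion: pd.Series | None = None) -> pd.DataFrame:
    """Wald tests at every timepoint with both conditions present."""
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if dispersion is None:
        dispersion = estimate_dispersion(counts, size_factors, design)
    tables = []
    for t in sorted(design["timepoint_h"].unique()):
        sub = design[design["timepoint_h"] == t]
        if set(sub["condition"]) != {"UW", "W"}:
            continue
        tables.append(wald_test_timepoint(counts, design, t, dispersion,
                                          size_factors))
    return pd.concat(tables, ignore_index=True)


def call_degs(results: pd.DataFrame, fc_cut: float = 1.5,
              q_cut: float = 0.05) -> dict:
    """Call per-timepoint up/down DEG sets and their union.

    up requires q < q_cut and 2**log2fc > fc_cut (both strict); down is the
    mirror image. Genes up at one timepoint and down at another are flagged
    bidirectional.
    """
    fc = 2.0 ** results["log2fc"]
    up = (results["q"] < q_cut) & (fc > fc_cut)
    down = (results["q"] < q_cut) & (fc < 1.0 / fc_cut)
    call = np.where(up, "up", np.where(down, "down", "ns"))
    results = results.assign(call=call)
    per_tp = {}
    for t, grp in results.groupby("timepoint_h"):
        per_tp[t] = {
            "up": set(grp.loc[grp["call"] == "up", "gene_id"]),
            "down": set(grp.loc[grp["call"] == "down", "gene_id"]),
        }
    union: set[str] = set()
    ever_up: set[str] = set()
    ever_down: set[str] = set()
    for t, d in per_tp.items():
        union |= d["up"] | d["down"]
        ever_up |= d["up"]
        ever_down |= d["down"]
    return {
        "table": results,
        "per_timepoint": per_tp,
        "union": union,
        "bidirectional": ever_up & ever_down,
    }
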