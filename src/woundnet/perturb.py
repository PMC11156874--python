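"""Validation statistics for TF loss-of-function experiments.

Knockdown contrasts (mutant-W vs control-W at one timepoint) are reduced
to per-gene log2 fold changes; a TF's network targets are then compared
with non-targets by a one-sided rank-sum shift test, and double-loss
contrasts are tested for stronger repression of common targets than
either single loss (one-sided Welch t).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .pointwise import _nb_group_mle, bh_adjust, estimate_size_factors


def knockdown_de(counts: pd.DataFrame, design: pd.DataFrame,
                 dispersion: pd.Series | float = 0.2) -> pd.DataFrame:
    """Mutant vs control NB Wald contrast for a knockdown dataset.

    ``design`` needs columns sample_id and group in {control, mutant}.
    Returns gene_id, log2fc, p, q.
    """
    if isinstance(dispersion, (int, float)):
        alpha = np.full(len(counts), float(dispersion))
    else:
        alpha = dispersion.reindex(counts.index).to_numpy()
    sf = estimate_size_factors(counts)
    etas, infos = {}, {}
    for grp in ("control", "mutant"):
        samples = design.loc[design["group"] == grp, "sample_id"]
        if len(samples) < 2:
            raise ValueError(f"need >= 2 replicates in group {grp}")
        y = counts[list(samples)].to_numpy(dtype=float)
        s = sf.reindex(samples).to_numpy()
        etas[grp], infos[grp] = _nb_group_mle(y, s, alpha)
    delta = etas["mutant"] - etas["control"]
    se = np.sqrt(1.0 / np.maximum(infos["mutant"], 1e-12)
                 + 1.0 / np.maximum(infos["control"], 1e-12))
    z = delta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame({"gene_id": counts.index,
                        "log2fc": delta / np.log(2.0), "p": p})
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def target_vs_nontarget_test(kd: pd.DataFrame, edges: pd.DataFrame,
                             tf_id: str, direction: str = "down") -> dict:
    """Do the TF's targets shift relative to non-targets after its loss?

    Targets are the TF's network targets among tested genes; non-targets
    the remaining tested genes. One-sided Wilcoxon rank-sum with
    alternative "less" for ``direction='down'`` (activator loss represses
    targets) or "greater" for ``direction='up'``. Returns the p-value and
    the two empirical CDFs.
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    tested = kd.set_index("gene_id")["log2fc"]
    target_ids = set(edges.loc[edges["tf_id"] == tf_id, "target_id"])
    targets = sorted(target_ids & set(tested.index))
    if len(targets) < 5:
        raise ValueError(f"{tf_id}: fewer than 5 targets in the contrast")
    nontargets = sorted(set(tested.index) - target_ids)
    x = tested.reindex(targets).to_numpy()
    y = tested.reindex(nontargets).to_numpy()
    alt = "less" if direction == "down" else "greater"
    res = stats.mannwhitneyu(x, y, alternative=alt)
    def ecdf(vals):
        v = np.sort(vals)
        return pd.DataFrame({"log2fc": v,
                             "ecdf": np.arange(1, len(v) + 1) / len(v)})
    return {"p": float(res.pvalue), "n_targets": len(targets),
            "n_nontargets": len(nontargets),
            "ecdf_targets": ecdf(x), "ecdf_nontargets": ecdf(y),
            "median_targets": float(np.median(x)),
            "median_nontargets": float(np.median(y))}


def common_target_sets(edges: pd.DataFrame, tf_a: str, tf_b: str,
                       universe) -> dict[str, set[str]]:
    """Partition the tested-gene universe by regulation from two TFs."""
    tfs = set(edges["tf_id"])
    for tf in (tf_a, tf_b):
        if tf not in tfs:
            raise ValueError(f"TF {tf!r} not in the network")
    universe = set(universe)
    ta = set(edges.loc[edges["tf_id"] == tf_a, "target_id"]) & universe
    tb = set(edges.loc[edges["tf_id"] == tf_b, "target_id"]) & universe
    return {
        "common": ta & tb,
        "a_specific": ta - tb,
        "b_specific": tb - ta,
        "non_target": universe - ta - tb,
    }


def additive_effect_test(common_targets, kd_a: pd.DataFrame,
                         kd_b: pd.DataFrame, kd_double: pd.DataFrame) -> dict:
    """Is double loss stronger than each single loss on common targets?

    One-sided Welch two-sample t-tests of the common targets' log2FC under
    double loss vs under each single loss (alternative: double smaller,
    i.e. stronger repression). Identical constant vectors yield p = NA
    with a warning.
    """
    common = sorted(set(common_targets))
    vals = {}
    for name, kd in (("a", kd_a), ("b", kd_b), ("double", kd_double)):
        s = kd.set_index("gene_id")["log2fc"].reindex(common).dropna()
        vals[name] = s
    present = set(vals["a"].index) & set(vals["b"].index) \
        & set(vals["double"].index)
    if len(present) < 5:
        raise ValueError("fewer than 5 common targets present in all "
                         "three contrasts")
    present = sorted(present)
    dd = vals["double"].reindex(present).to_numpy()
    out = {"n_common": len(present),
           "mean_double": float(np.mean(dd))}
    for name in ("a", "b"):
        single = vals[name].reindex(present).to_numpy()
        out[f"mean_single_{name}"] = float(np.mean(single))
        if np.var(dd) == 0 and np.var(single) == 0:
            warnings.warn("zero variance in both samples; t-test undefined")
            out[f"p_vs_{name}"] = np.nan
            continue
        res = stats.ttest_ind(dd, single, equal_var=False,
                              alternative="less")
        out[f"p_vs_{name}"] = float(res.pvalue)
    return out
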