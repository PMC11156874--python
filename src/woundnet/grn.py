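"""TF-target regulatory network from promoter binding evidence.

Targets of a TF are genes with a ChIP peak or a motif hit inside the
promoter window (2 kb upstream to 1 kb downstream of the TSS, strand
aware). Motif scanning uses log-odds PWM scores with exact p-values from a
dynamic-programming null over integer-discretized scores. On top of the
static network sit the dynamic layers: expression-path split detection,
edge classification (TF->non-TF / other-TF / self-TF), autoregulator
calls, activator/repressor inference from unique-target correlation, and
stage subnetwork hub degrees.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .io import PWM
from .pointwise import bh_adjust
from .signatures import STAGE_TIMEPOINTS, stage_of_timepoint

SCORE_GRANULARITY_BITS = 1e-3
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_N_SENTINEL = -(10 ** 12)  # poisons windows containing N


# ---------------------------------------------------------------------------
# promoter windows


def promoter_windows(annotation: pd.DataFrame, up: int = 2000,
                     down: int = 1000,
                     chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Strand-aware promoter windows around each TSS, 0-based half-open.

    + strand: [tss - up, tss + down); - strand: [tss - down, tss + up);
    clipped to [0, chrom length) when lengths are known.
    """
    rows = []
    for gene, row in annotation.iterrows():
        tss = int(row["tss"])
        if row["strand"] == "+":
            start, end = tss - up, tss + down
        else:
            start, end = tss - down, tss + up
        start = max(start, 0)
        if chrom_lengths is not None:
            if row["chrom"] in chrom_lengths:
                end = min(end, chrom_lengths[row["chrom"]])
            else:
                import warnings
                warnings.warn(f"unknown chromosome length for {row['chrom']}; "
                              "window not clipped")
        rows.append((gene, row["chrom"], start, end, row["strand"]))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand"])


# ---------------------------------------------------------------------------
# PWM scanning with exact DP p-values


def encode_sequence(seq: str) -> np.ndarray:
    out = np.full(len(seq), 4, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8)
            == ord(base)] = idx
    return out


def _int_logodds(probs: np.ndarray, background: np.ndarray) -> np.ndarray:
    """L x 5 integer log-odds (units of 1e-3 bits); column 4 poisons N."""
    lod = np.log2(np.maximum(probs, 1e-300) / background[None, :])
    ints = np.rint(lod / SCORE_GRANULARITY_BITS).astype(np.int64)
    return np.hstack([ints, np.full((ints.shape[0], 1), _N_SENTINEL,
                                    dtype=np.int64)])


def _revcomp_pwm(pwm: PWM) -> PWM:
    return PWM(pwm.motif_id + "_rc", pwm.tf_id, pwm.probs[::-1, ::-1].copy(),
               pwm.background[::-1].copy())


def _score_tail(ints: np.ndarray, background: np.ndarray):
    """Exact null distribution of the integer window score under background.

    Returns (offset, tail) where tail[s - offset] = P(S >= s).
    """
    ints4 = ints[:, :4]
    # iterative convolution over positions
    cur = np.array([1.0])
    cur_lo = 0
    for pos in range(ints4.shape[0]):
        vals = ints4[pos]
        new_lo = cur_lo + int(vals.min())
        new_hi = cur_lo + len(cur) - 1 + int(vals.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            off = cur_lo + int(vals[b]) - new_lo
            new[off:off + len(cur)] += background[b] * cur
        cur, cur_lo = new, new_lo
    tail = np.cumsum(cur[::-1])[::-1]
    return cur_lo, tail


class PWMScanner:
    """Caches per-PWM integer score matrices, null tails and thresholds."""

    def __init__(self, pwms: list[PWM], p_cut: float = 1e-4):
        self.p_cut = p_cut
        self._entries = []
        for pwm in pwms:
            for strand, mat in (("+", pwm), ("-", _revcomp_pwm(pwm))):
                ints = _int_logodds(mat.probs, mat.background)
                offset, tail = _score_tail(ints, mat.background)
                # minimal integer score whose tail p is below the cutoff
                passing = np.flatnonzero(tail < p_cut)
                threshold = (offset + int(passing[0])) if len(passing) \
                    else None
                self._entries.append(
                    (pwm, strand, ints, offset, tail, threshold))

    def scan(self, gene_id: str, seq: str) -> pd.DataFrame:
        code = encode_sequence(seq)
        rows = []
        for pwm, strand, ints, offset, tail, threshold in self._entries:
            L = pwm.probs.shape[0]
            if threshold is None or L > len(code):
                continue
            win = np.lib.stride_tricks.sliding_window_view(code, L)
            scores = ints[np.arange(L)[None, :], win].sum(axis=1)
            hit_pos = np.flatnonzero(scores >= threshold)
            for pos in hit_pos:
                sc = int(scores[pos])
                idx = min(max(sc - offset, 0), len(tail) - 1)
                rows.append((gene_id, pwm.motif_id, pwm.tf_id, int(pos),
                             strand, sc * SCORE_GRANULARITY_BITS,
                             float(tail[idx])))
        return pd.DataFrame(rows, columns=["gene_id", "motif_id", "tf_id",
                                           "offset", "strand", "score_bits",
                                           "p"])


def scan_pwm(seq: str, pwm: PWM, p_cut: float = 1e-4,
             gene_id: str = "") -> pd.DataFrame:
    """Scan one sequence with one PWM on both strands.

    Hits are windows whose exact background p-value (DP over integer scores
    at 1e-3 bit granularity) is below ``p_cut``. Windows containing N are
    skipped.
    """
    return PWMScanner([pwm], p_cut=p_cut).scan(gene_id, seq)


def scan_promoters(promoters: dict[str, str], pwms: list[PWM],
                   p_cut: float = 1e-4) -> pd.DataFrame:
    """Scan every promoter with every PWM; returns the pooled hit table.

    Sequences are stacked (N-padded to a common length, which poisons the
    padded windows) so each PWM scans all promoters in one vectorised pass.
    """
    empty = pd.DataFrame(columns=["gene_id", "motif_id", "tf_id", "offset",
                                  "strand", "score_bits", "p"])
    if not promoters or not pwms:
        return empty
    scanner = PWMScanner(pwms, p_cut=p_cut)
    genes = list(promoters)
    lmax = max(len(s) for s in promoters.values())
    codes = np.full((len(genes), lmax), 4, dtype=np.int64)
    for gi, g in enumerate(genes):
        codes[gi, :len(promoters[g])] = encode_sequence(promoters[g])
    rows = []
    for pwm, strand, ints, offset, tail, threshold in scanner._entries:
        L = pwm.probs.shape[0]
        if threshold is None or L > lmax:
            continue
        width = lmax - L + 1
        scores = np.zeros((len(genes), width), dtype=np.int64)
        for l in range(L):
            scores += ints[l, codes[:, l:l + width]]
        gi, pos = np.nonzero(scores >= threshold)
        for a, b in zip(gi, pos):
            sc = int(scores[a, b])
            idx = min(max(sc - offset, 0), len(tail) - 1)
            rows.append((genes[a], pwm.motif_id, pwm.tf_id, int(b), strand,
                         sc * SCORE_GRANULARITY_BITS, float(tail[idx])))
    if not rows:
        return empty
    return pd.DataFrame(rows, columns=["gene_id", "motif_id", "tf_id",
                                       "offset", "strand", "score_bits",
                                       "p"])


# ---------------------------------------------------------------------------
# peak evidence


def map_peaks_to_promoters(peaks: pd.DataFrame,
                           windows: pd.DataFrame) -> pd.DataFrame:
    """Peak-in-promoter evidence: >= 1 bp half-open overlap."""
    rows = []
    for chrom, wsub in windows.groupby("chrom"):
        psub = peaks[peaks["chrom"] == chrom]
        if psub.empty:
            continue
        ws = wsub["start"].to_numpy()
        we = wsub["end"].to_numpy()
        ps = psub["start"].to_numpy()
        pe = psub["end"].to_numpy()
        overlap = (ps[:, None] < we[None, :]) & (pe[:, None] > ws[None, :])
        pi, wi = np.nonzero(overlap)
        for a, b in zip(pi, wi):
            rows.append((psub["tf_id"].iloc[a], wsub["gene_id"].iloc[b]))
    return (pd.DataFrame(rows, columns=["tf_id", "gene_id"])
            .drop_duplicates().reset_index(drop=True))


def build_tf_target_matrix(peak_evidence: pd.DataFrame,
                           motif_hits: pd.DataFrame
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine peak and motif evidence into the binary gene x TF matrix.

    Evidence is the OR of the two sources; the per-pair record notes
    "peak", "motif" or "both". A motif hit without a TF id is an error.
    """
    if len(motif_hits) and (motif_hits["tf_id"].isna()
                            | (motif_hits["tf_id"] == "")).any():
        raise ValueError("motif hit with unknown TF id")
    peak_pairs = set(zip(peak_evidence["tf_id"], peak_evidence["gene_id"])) \
        if len(peak_evidence) else set()
    motif_pairs = set(zip(motif_hits["tf_id"], motif_hits["gene_id"])) \
        if len(motif_hits) else set()
    rows = []
    for tf, gene in sorted(peak_pairs | motif_pairs):
        if (tf, gene) in peak_pairs and (tf, gene) in motif_pairs:
            ev = "both"
        elif (tf, gene) in peak_pairs:
            ev = "peak"
        else:
            ev = "motif"
        rows.append((tf, gene, ev))
    evidence = pd.DataFrame(rows, columns=["tf_id", "gene_id", "evidence"])
    if evidence.empty:
        return pd.DataFrame(dtype=bool), evidence
    matrix = pd.crosstab(evidence["gene_id"], evidence["tf_id"]).astype(bool)
    return matrix, evidence


# ---------------------------------------------------------------------------
# edge activity and classification


def tf_fpkm_by_timepoint(fpkm: pd.DataFrame, design: pd.DataFrame,
                         condition: str = "W") -> pd.DataFrame:
    """Mean FPKM per gene per timepoint in one condition."""
    sub = design[design["condition"] == condition]
    cols = {t: fpkm[list(grp["sample_id"])].mean(axis=1)
            for t, grp in sub.groupby("timepoint_h")}
    return pd.DataFrame(cols).sort_index(axis=1)


def annotate_edges(evidence: pd.DataFrame, trajectories: pd.DataFrame,
                   fpkm_tp: pd.DataFrame, annotation: pd.DataFrame,
                   fpkm_cut: float = 1.0, response_cut: float = 1.0
                   ) -> pd.DataFrame:
    """Attach active timepoints, stages and edge class to evidence pairs.

    An edge is active at timepoint t when the TF is expressed there
    (FPKM > ``fpkm_cut``) and the target is responding
    (|log2FC| > ``response_cut``). Stage sets follow the stage definition.
    """
    timepoints = [t for t in trajectories.columns if t > 0]
    rows = []
    for tf, gene, ev in evidence[["tf_id", "gene_id", "evidence"]].itertuples(
            index=False):
        active = []
        if gene in trajectories.index and tf in fpkm_tp.index:
            for t in timepoints:
                if t not in fpkm_tp.columns:
                    continue
                if (fpkm_tp.loc[tf, t] > fpkm_cut
                        and abs(trajectories.loc[gene, t]) > response_cut):
                    active.append(t)
        stages = sorted({stage_of_timepoint(t) for t in active})
        if tf == gene:
            klass = "TF-(self-TF)"
        elif gene in annotation.index and annotation.loc[gene, "is_tf"]:
            klass = "TF-(other-TF)"
        else:
            klass = "TF-(non-TF)"
        rows.append((tf, gene, ev, tuple(active), tuple(stages), klass))
    return pd.DataFrame(rows, columns=["tf_id", "target_id", "evidence",
                                       "active_timepoints", "stages",
                                       "edge_class"])


def classify_edges(edges: pd.DataFrame, annotation: pd.DataFrame
                   ) -> tuple[pd.DataFrame, set[str]]:
    """Per-stage counts of the three edge classes plus the autoregulators.

    Autoregulators are TFs with a self-edge (peak or motif evidence in
    their own promoter).
    """
    autoregulators = set(edges.loc[edges["tf_id"] == edges["target_id"],
                                   "tf_id"])
    counts: dict[tuple[str, str], int] = {}
    for row in edges.itertuples(index=False):
        stages = row.stages if row.stages else ("unassigned",)
        for st in stages:
            counts[(st, row.edge_class)] = counts.get((st, row.edge_class), 0) + 1
    table = pd.DataFrame(
        [(st, kl, n) for (st, kl), n in sorted(counts.items())],
        columns=["stage", "edge_class", "n_edges"])
    return table, autoregulators


def infer_tf_mode(tf_id: str, edges: pd.DataFrame,
                  trajectories: pd.DataFrame, max_regulators: int = 2,
                  r_cut: float = 0.5) -> dict:
    """Activator/repressor call from unique-target trajectory correlation.

    Unique targets are targets regulated by at most ``max_regulators`` TFs
    in the network (the TF itself included). The call is the Pearson
    correlation between the TF's own log2FC trajectory and the mean
    unique-target trajectory: activator if r >= r_cut, repressor if
    r <= -r_cut, otherwise indeterminate.
    """
    reg_counts = edges.groupby("target_id")["tf_id"].nunique()
    targets = edges.loc[edges["tf_id"] == tf_id, "target_id"]
    unique_targets = sorted(
        t for t in targets
        if reg_counts[t] <= max_regulators and t != tf_id
        and t in trajectories.index)
    result = {"tf_id": tf_id, "unique_targets": unique_targets,
              "r": np.nan, "mode": "indeterminate", "reason": ""}
    if len(unique_targets) < 3:
        result["reason"] = "fewer than 3 unique targets"
        return result
    if tf_id not in trajectories.index:
        result["reason"] = "TF has no trajectory"
        return result
    tf_traj = trajectories.loc[tf_id].to_numpy(dtype=float)
    target_traj = trajectories.loc[unique_targets].mean(axis=0).to_numpy()
    if np.std(tf_traj) == 0 or np.std(target_traj) == 0:
        result["reason"] = "zero-variance trajectory"
        return result
    r = float(np.corrcoef(tf_traj, target_traj)[0, 1])
    result["r"] = r
    if r >= r_cut:
        result["mode"] = "activator"
    elif r <= -r_cut:
        result["mode"] = "repressor"
    else:
        result["reason"] = f"|r|={abs(r):.2f} below {r_cut}"
    return result


def stage_subnetwork_degrees(edges: pd.DataFrame, stage: str) -> pd.DataFrame:
    """TF hub degrees in one stage's TF-TF subnetwork.

    Degree counts distinct TF partners (in + out, each unordered pair once)
    among TF-(other-TF) edges active in the stage.
    """
    if stage not in STAGE_TIMEPOINTS:
        raise ValueError(f"unknown stage {stage!r}")
    partners: dict[str, set[str]] = {}
    for row in edges.itertuples(index=False):
        if row.edge_class != "TF-(other-TF)" or stage not in row.stages:
            continue
        partners.setdefault(row.tf_id, set()).add(row.target_id)
        partners.setdefault(row.target_id, set()).add(row.tf_id)
    table = pd.DataFrame(
        [(tf, len(p)) for tf, p in partners.items()],
        columns=["tf_id", "degree"])
    return table.sort_values(["degree", "tf_id"],
                             ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# dynamic path / split detection


def detect_paths_and_splits(trajectories: pd.DataFrame,
                            tf_targets: pd.DataFrame,
                            tf_fpkm_tp: pd.DataFrame,
                            min_sd: float = 1.0, min_branch: int = 10,
                            fpkm_cut: float = 1.0, q_cut: float = 0.05,
                            use_before_h: float = 10.0,
                            seed: int = 0) -> dict:
    """Detect divergence points of co-expressed gene paths over time.

    All genes start on one path at the pseudo-0 baseline. At each later
    timepoint, within each active path, the per-gene change in log2FC since
    the previous timepoint is 2-means clustered; the path splits when the
    branch means differ by >= ``min_sd`` and both branches keep
    >= ``min_branch`` genes. TFs expressed at the split timepoint
    (FPKM > ``fpkm_cut``) are assigned to branches by hypergeometric
    enrichment of their targets (BH across TF x branch within the split,
    q < ``q_cut``). Splits strictly before ``use_before_h`` are flagged for
    downstream trajectory clustering.
    """
    if trajectories.empty:
        raise ValueError("empty trajectory matrix")
    cols = list(trajectories.columns)
    paths = [{"path_id": 0, "parent": None, "start_t": cols[0],
              "genes": list(trajectories.index), "active": True}]
    splits = []
    next_id = 1
    for i in range(1, len(cols)):
        t_prev, t = cols[i - 1], cols[i]
        for path in [p for p in paths if p["active"]]:
            members = path["genes"]
            if len(members) < 2 * min_branch:
                continue
            delta = (trajectories.loc[members, t]
                     - trajectories.loc[members, t_prev]).to_numpy()
            km = KMeans(n_clusters=2, n_init=5,
                        random_state=(seed + i) % (2**31 - 1))
            lab = km.fit_predict(delta.reshape(-1, 1))
            m0, m1 = delta[lab == 0].mean(), delta[lab == 1].mean()
            n0, n1 = int((lab == 0).sum()), int((lab == 1).sum())
            if abs(m0 - m1) < min_sd or min(n0, n1) < min_branch:
                continue
            # higher-moving branch listed first
            first = 0 if m0 >= m1 else 1
            branches = []
            for b in (first, 1 - first):
                genes_b = [g for g, l in zip(members, lab) if l == b]
                branches.append({"path_id": next_id, "parent": path["path_id"],
                                 "start_t": t, "genes": genes_b,
                                 "active": True})
                next_id += 1
            path["active"] = False
            tf_rows = _assign_split_tfs(
                members, branches, tf_targets, tf_fpkm_tp, t, fpkm_cut, q_cut)
            splits.append({
                "timepoint_h": t,
                "parent": path["path_id"],
                "branches": [{"path_id": b["path_id"],
                              "n_genes": len(b["genes"]),
                              "genes": b["genes"]} for b in branches],
                "tf_assignments": tf_rows,
                "used_for_clustering": t < use_before_h,
            })
            paths.extend(branches)
    return {"paths": paths, "splits": splits}


def _assign_split_tfs(parent_genes, branches, tf_targets, tf_fpkm_tp,
                      t, fpkm_cut, q_cut):
    parent = [g for g in parent_genes if g in tf_targets.index]
    if not parent:
        return []
    expressed = [tf for tf in tf_targets.columns
                 if tf in tf_fpkm_tp.index and t in tf_fpkm_tp.columns
                 and tf_fpkm_tp.loc[tf, t] > fpkm_cut]
    N = len(parent)
    recs = []
    for br in branches:
        bset = [g for g in br["genes"] if g in tf_targets.index]
        n = len(bset)
        for tf in expressed:
            col = tf_targets[tf]
            K = int(col.loc[parent].sum())
            if K == 0:
                continue
            k = int(col.loc[bset].sum())
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            recs.append({"tf_id": tf, "branch": br["path_id"], "overlap": k,
                         "targets_in_parent": K, "p": p})
    if not recs:
        return []
    table = pd.DataFrame(recs)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table = table[table["q"] < q_cut].sort_values(["branch", "q", "tf_id"])
    out = []
    for branch, grp in table.groupby("branch"):
        grp = grp.copy()
        grp["top3"] = False
        grp.iloc[:3, grp.columns.get_loc("top3")] = True
        out.extend(grp.to_dict("records"))
    return out
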