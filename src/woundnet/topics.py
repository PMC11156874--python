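"""Combinatorial TF modules by latent topic modelling.

Each regulated gene is a document; its regulating TFs, tagged with the
timepoint of regulation (the same TF at two timepoints is two distinct
words), are the words. A collapsed Gibbs LDA finds topics = combinations
of TFs that co-regulate gene sets; membership is by z-score across topics
(TF words at z > 2, genes at z > 1, both strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from scipy.spatial.distance import jensenshannon

DEFAULT_TOPIC_TIMEPOINTS = (0.25, 0.5, 6.0, 14.0, 24.0)


def word_label(tf_id: str, timepoint: float) -> str:
    return f"{tf_id}@{timepoint:g}"


@dataclass
class TimeTaggedMatrix:
    """Binary gene x (TF, timepoint) occurrence matrix as token lists."""

    documents: list[str]
    vocabulary: list[str]          # "tf@time" labels
    word_tf: list[str]             # tf id per vocabulary entry
    word_time: list[float]
    doc_tokens: np.ndarray         # token -> document index
    word_tokens: np.ndarray        # token -> vocabulary index

    @property
    def n_tokens(self) -> int:
        return len(self.doc_tokens)

    def to_dense(self) -> pd.DataFrame:
        mat = np.zeros((len(self.documents), len(self.vocabulary)), dtype=int)
        mat[self.doc_tokens, self.word_tokens] = 1
        return pd.DataFrame(mat, index=self.documents, columns=self.vocabulary)


def build_time_tagged_matrix(edges: pd.DataFrame,
                             timepoints=DEFAULT_TOPIC_TIMEPOINTS
                             ) -> TimeTaggedMatrix:
    """Concatenate the per-timepoint gene-TF networks with time tags.

    ``edges`` must carry active_timepoints; a gene becomes a document when
    it has at least one regulator at one of the selected timepoints.
    """
    tps = set(float(t) for t in timepoints)
    pairs = set()
    for row in edges.itertuples(index=False):
        for t in row.active_timepoints:
            if float(t) in tps:
                pairs.add((row.target_id, row.tf_id, float(t)))
    if not pairs:
        raise ValueError("no documents: no edges active at the selected "
                         "timepoints")
    documents = sorted({g for g, _, _ in pairs})
    vocab_keys = sorted({(tf, t) for _, tf, t in pairs})
    vocabulary = [word_label(tf, t) for tf, t in vocab_keys]
    word_index = {k: i for i, k in enumerate(vocab_keys)}
    doc_index = {d: i for i, d in enumerate(documents)}
    doc_tokens, word_tokens = [], []
    for g, tf, t in sorted(pairs):
        doc_tokens.append(doc_index[g])
        word_tokens.append(word_index[(tf, t)])
    return TimeTaggedMatrix(
        documents=documents, vocabulary=vocabulary,
        word_tf=[tf for tf, _ in vocab_keys],
        word_time=[t for _, t in vocab_keys],
        doc_tokens=np.asarray(doc_tokens, dtype=np.int64),
        word_tokens=np.asarray(word_tokens, dtype=np.int64))


@njit(cache=True)
def _gibbs(doc_tokens, word_tokens, K, D, V, alpha, eta, n_iter, burn_in,
           thin, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_tok = doc_tokens.shape[0]
    z = np.empty(n_tok, dtype=np.int64)
    ndk = np.zeros((D, K), dtype=np.float64)
    nkv = np.zeros((K, V), dtype=np.float64)
    nk = np.zeros(K, dtype=np.float64)
    for i in range(n_tok):
        k = np.random.randint(0, K)
        z[i] = k
        ndk[doc_tokens[i], k] += 1.0
        nkv[k, word_tokens[i]] += 1.0
        nk[k] += 1.0
    ndk_sum = np.zeros((D, K), dtype=np.float64)
    nkv_sum = np.zeros((K, V), dtype=np.float64)
    n_samples = 0
    trace = np.zeros(n_iter)
    probs = np.empty(K)
    for it in range(n_iter):
        for i in range(n_tok):
            d = doc_tokens[i]
            w = word_tokens[i]
            k = z[i]
            ndk[d, k] -= 1.0
            nkv[k, w] -= 1.0
            nk[k] -= 1.0
            total = 0.0
            for kk in range(K):
                p = (ndk[d, kk] + alpha) * (nkv[kk, w] + eta) / (nk[kk] + V * eta)
                total += p
                probs[kk] = total
            u = np.random.random() * total
            k = 0
            while probs[k] < u:
                k += 1
            z[i] = k
            ndk[d, k] += 1.0
            nkv[k, w] += 1.0
            nk[k] += 1.0
        # complete-data log posterior (up to a constant)
        lp = 0.0
        for kk in range(K):
            for v in range(V):
                if nkv[kk, v] > 0:
                    lp += nkv[kk, v] * np.log((nkv[kk, v] + eta)
                                              / (nk[kk] + V * eta))
        for d in range(D):
            tot_d = 0.0
            for kk in range(K):
                tot_d += ndk[d, kk]
            for kk in range(K):
                if ndk[d, kk] > 0:
                    lp += ndk[d, kk] * np.log((ndk[d, kk] + alpha)
                                              / (tot_d + K * alpha))
        trace[it] = lp
        if it >= burn_in and (it - burn_in) % thin == 0:
            ndk_sum += ndk
            nkv_sum += nkv
            n_samples += 1
    return z, ndk_sum, nkv_sum, n_samples, trace


@dataclass
class TopicModel:
    K: int
    phi: pd.DataFrame              # K x V, rows sum to 1
    theta: pd.DataFrame            # D x K, rows sum to 1
    assignments: np.ndarray
    alpha: float
    eta: float
    seed: int
    n_iter: int
    log_posterior_trace: np.ndarray = field(repr=False, default=None)


def fit_lda_gibbs(matrix: TimeTaggedMatrix, K: int, alpha: float | None = None,
                  eta: float = 0.1, n_iter: int = 1000, burn_in: int = 500,
                  thin: int = 10, seed: int = 0) -> TopicModel:
    """Collapsed Gibbs LDA; phi/theta from post-burn-in averaged counts.

    Deterministic given ``seed``. ``alpha`` defaults to 1/K: the documents
    here are genes with only a handful of regulator words, so a weak
    document-topic prior is needed for topics to concentrate (a
    text-corpus-scale prior like 50/K flattens theta and destroys module
    structure at this document length).
    """
    V, D = len(matrix.vocabulary), len(matrix.documents)
    if V == 0:
        raise ValueError("empty vocabulary")
    if K < 1 or (K > 1 and V < K):
        raise ValueError(f"need vocabulary >= K topics, got V={V}, K={K}")
    if alpha is None:
        alpha = 1.0 / K
    z, ndk_sum, nkv_sum, n_samples, trace = _gibbs(
        matrix.doc_tokens, matrix.word_tokens, K, D, V, float(alpha),
        float(eta), int(n_iter), int(burn_in), int(thin), int(seed) % (2**31))
    n_samples = max(n_samples, 1)
    phi = (nkv_sum / n_samples + eta)
    phi = phi / phi.sum(axis=1, keepdims=True)
    theta = (ndk_sum / n_samples + alpha)
    theta = theta / theta.sum(axis=1, keepdims=True)
    return TopicModel(
        K=K,
        phi=pd.DataFrame(phi, index=[f"topic{k+1}" for k in range(K)],
                         columns=matrix.vocabulary),
        theta=pd.DataFrame(theta, index=matrix.documents,
                           columns=[f"topic{k+1}" for k in range(K)]),
        assignments=z, alpha=alpha, eta=eta, seed=seed, n_iter=n_iter,
        log_posterior_trace=trace)


# ---------------------------------------------------------------------------
# model selection


def _heldout_perplexity(model: TopicModel, matrix: TimeTaggedMatrix,
                        heldout_docs: np.ndarray, n_fold_iter: int = 50
                        ) -> float:
    """Document-completion perplexity: fold in half of each heldout
    document's tokens to estimate theta, score the other half."""
    phi = model.phi.to_numpy()
    K = model.K
    loglik, n_eval = 0.0, 0
    for d in heldout_docs:
        words = matrix.word_tokens[matrix.doc_tokens == d]
        if len(words) < 2:
            continue
        est, ev = words[::2], words[1::2]
        theta = np.full(K, 1.0 / K)
        for _ in range(n_fold_iter):
            q = theta[:, None] * phi[:, est]
            q = q / np.maximum(q.sum(axis=0, keepdims=True), 1e-300)
            theta = (model.alpha + q.sum(axis=1))
            theta = theta / theta.sum()
        probs = theta @ phi[:, ev]
        loglik += float(np.log(np.maximum(probs, 1e-300)).sum())
        n_eval += len(ev)
    if n_eval == 0:
        return np.inf
    return float(np.exp(-loglik / n_eval))


def mean_topic_divergence(model: TopicModel) -> float:
    """Mean pairwise Jensen-Shannon divergence between topic-word rows."""
    phi = model.phi.to_numpy()
    K = phi.shape[0]
    if K < 2:
        return 0.0
    vals = [jensenshannon(phi[a], phi[b], base=2) ** 2
            for a in range(K) for b in range(a + 1, K)]
    return float(np.mean(vals))


def select_topic_number(matrix: TimeTaggedMatrix, k_range=range(2, 15),
                        seed: int = 0, n_iter: int = 400, burn_in: int = 200
                        ) -> tuple[int, pd.DataFrame]:
    """Pick K by rank-sum over held-out perplexity and topic separation.

    Documents are split 80/20; perplexity (lower better) is computed by
    document completion on the held-out fifth, topic separation (higher
    better) as mean pairwise Jensen-Shannon divergence. Ties go to the
    smaller K.
    """
    ks = [k for k in k_range]
    if not ks:
        raise ValueError("empty K range")
    D = len(matrix.documents)
    ks = [k for k in ks if k <= max(D - 1, 2)]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(D)
    n_train = max(int(0.8 * D), 1)
    heldout = perm[n_train:]
    rows = []
    for k in ks:
        model = fit_lda_gibbs(matrix, K=k, n_iter=n_iter, burn_in=burn_in,
                              seed=seed + k)
        rows.append({
            "K": k,
            "heldout_perplexity": _heldout_perplexity(model, matrix, heldout),
            "topic_divergence": mean_topic_divergence(model),
        })
    table = pd.DataFrame(rows)
    rank_p = table["heldout_perplexity"].rank(method="min")
    rank_d = table["topic_divergence"].rank(method="min", ascending=False)
    table["rank_sum"] = rank_p + rank_d
    best = table.sort_values(["rank_sum", "K"]).iloc[0]
    return int(best["K"]), table


# ---------------------------------------------------------------------------
# membership


def topic_membership_zscores(model: TopicModel, matrix: TimeTaggedMatrix,
                             tf_z_cut: float = 2.0, gene_z_cut: float = 1.0
                             ) -> dict[str, pd.DataFrame]:
    """Topic membership by z-score across topics.

    For a word w, z(w, k) = (phi[k, w] - mean over topics) / population sd
    over topics; analogously for genes on theta rows. A word or gene joins
    a topic when z exceeds the (strict) threshold; zero-spread entries are
    reported as non-members with a reason.
    """
    if model.K < 3:
        raise ValueError("z-score membership needs K >= 3 topics")
    out = {}
    recs = []
    phi = model.phi.to_numpy()
    mean = phi.mean(axis=0)
    sd = phi.std(axis=0)  # population sd over the K topics
    for vi, word in enumerate(model.phi.columns):
        if sd[vi] == 0:
            continue
        z = (phi[:, vi] - mean[vi]) / sd[vi]
        for k in range(model.K):
            if z[k] > tf_z_cut:
                recs.append({"word": word, "tf_id": matrix.word_tf[vi],
                             "timepoint_h": matrix.word_time[vi],
                             "topic": model.phi.index[k], "z": float(z[k])})
    out["tf"] = pd.DataFrame(recs, columns=["word", "tf_id", "timepoint_h",
                                            "topic", "z"])
    recs = []
    theta = model.theta.to_numpy()
    gmean = theta.mean(axis=1)
    gsd = theta.std(axis=1)
    for di, gene in enumerate(model.theta.index):
        if gsd[di] == 0:
            continue
        z = (theta[di] - gmean[di]) / gsd[di]
        for k in range(model.K):
            if z[k] > gene_z_cut:
                recs.append({"gene_id": gene, "topic": model.theta.columns[k],
                             "z": float(z[k])})
    out["gene"] = pd.DataFrame(recs, columns=["gene_id", "topic", "z"])
    return out


def tf_topic_occurrence(membership: pd.DataFrame) -> pd.DataFrame:
    """Per-TF counts of distinct topics and timepoints after stripping tags."""
    if membership.empty:
        return pd.DataFrame(columns=["tf_id", "n_topics", "n_timepoints"])
    g = membership.groupby("tf_id").agg(
        n_topics=("topic", "nunique"),
        n_timepoints=("timepoint_h", "nunique")).reset_index()
    return g.sort_values(["n_topics", "n_timepoints", "tf_id"],
                         ascending=[False, False, True]).reset_index(drop=True)


def dominant_topic_per_tf(membership: pd.DataFrame) -> pd.Series:
    """Each TF's strongest topic (max z across its time-tagged words)."""
    if membership.empty:
        return pd.Series(dtype=object)
    idx = membership.groupby("tf_id")["z"].idxmax()
    return membership.loc[idx].set_index("tf_id")["topic"]


def tf_topic_partition(model: TopicModel, matrix: TimeTaggedMatrix
                       ) -> pd.Series:
    """Hard TF -> topic assignment by aggregate topic-word mass.

    Sums phi over a TF's time-tagged words and takes the argmax topic.
    Unlike z-score membership this is defined for any K (the z > 2
    threshold is unreachable below K = 6, since max z = sqrt(K - 1)), so
    it is the right view for comparing a fit against a known module
    partition.
    """
    phi = model.phi.to_numpy()
    tf_ids = sorted(set(matrix.word_tf))
    out = {}
    for tf in tf_ids:
        cols = [i for i, t in enumerate(matrix.word_tf) if t == tf]
        mass = phi[:, cols].sum(axis=1)
        out[tf] = model.phi.index[int(np.argmax(mass))]
    return pd.Series(out, name="topic")
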