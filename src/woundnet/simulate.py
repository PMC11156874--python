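"""Seeded synthetic wound-response experiment with planted ground truth.

Emulates the study design end to end: two conditions (unwounded UW,
wounded W) x 12 timepoints (0.25-24 h) x 3 single-worm NB replicates;
wound-induced genes follow impulse trajectories whose onsets define the
three stages (Response 0.25 h, Repair 0.5-4 h, Remodeling 6-24 h);
TF-target edges are planted as exact motif consensus occurrences in
promoters, half the TFs additionally receive ChIP-like peaks; TFs carry
module structure that drives correlated PPI edges and IDR fractions; and
knockdown datasets follow log2-additive direct-target effects.

Promoter background is i.i.d. uniform ACGT, with one refinement: chance
occurrences of any simulated TF consensus (either strand) are resampled
away before true sites are planted, so that every motif-level edge in the
emitted data is a planted one and network recovery is evaluated against
an exactly known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .impulse import ImpulseParams, impulse_value
from .io import PWM

STUDY_TIMEPOINTS = (0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 10.0, 12.0, 14.0, 16.0,
                    18.0, 24.0)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    n_genes: int = 3000
    n_tfs: int = 60
    timepoints: tuple = STUDY_TIMEPOINTS
    n_reps: int = 3
    library_size_mean: float = 3e5
    nb_dispersion: float = 0.2
    promoter_len: int = 3000
    motif_len: int = 8
    n_modules: int = 4
    frac_wound_induced: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genes, self.n_tfs, self.n_reps, self.promoter_len,
               self.motif_len, self.n_modules) <= 0:
            raise ValueError("all sizes must be positive")
        if not 0 <= self.frac_wound_induced < 1:
            raise ValueError("frac_wound_induced must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_tfs >= self.n_genes:
            raise ValueError("n_tfs must be smaller than n_genes")


@dataclass
class SyntheticTruth:
    planted_edges: pd.DataFrame          # tf_id, target_id, sign, weight
    gene_params: dict                    # gene -> ImpulseParams (W) or None
    baseline: pd.Series                  # gene -> UW mean
    stage_label: dict                    # gene -> S1/S2/S3/none
    tf_modules: dict                     # tf -> module int
    module_stage: dict                   # module -> stage
    tf_signs: dict                       # tf -> +1/-1
    autoregulators: set
    planted_sites: pd.DataFrame          # gene_id, tf_id, offset, strand
    motif_consensus: dict                # tf -> consensus string
    knockdown_effects: pd.DataFrame      # tf_id, target_id, effect (log2)
    ppi_edges: pd.DataFrame | None = None
    idr_fractions: dict = field(default_factory=dict)


@dataclass
class SimulationBundle:
    counts: pd.DataFrame
    design: pd.DataFrame
    annotation: pd.DataFrame
    promoters: dict
    peaks: pd.DataFrame
    pwms: list
    truth: SyntheticTruth
    config: SimulationConfig


_STAGE_ONSETS = {"S1": (0.15,), "S2": (0.5, 1.0, 2.0), "S3": (6.0, 10.0, 12.0)}
_STAGE_DURATION = {"S1": 2.5, "S2": 6.0, "S3": 30.0}


def _draw_impulse(rng, stage: str, baseline: float, sign: int,
                  amp_range=(2.0, 4.0)) -> ImpulseParams:
    amp = rng.uniform(*amp_range)
    t1 = float(rng.choice(_STAGE_ONSETS[stage]))
    beta = rng.uniform(4.0, 16.0)
    h0 = baseline
    h1 = baseline * 2.0 ** (sign * amp)
    h2 = baseline * 2.0 ** (sign * amp * (0.9 if stage == "S3" else 0.2))
    return ImpulseParams(beta=beta, h0=h0, h1=h1, h2=h2, t1=t1,
                         t2=t1 + _STAGE_DURATION[stage])


def _random_consensi(rng, n: int, length: int) -> list[str]:
    bases = "ACGT"
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        cand = "".join(bases[i] for i in rng.integers(0, 4, size=length))
        rc = revcomp(cand)
        if cand in seen or rc in seen or cand == rc:
            continue
        seen.add(cand)
        seen.add(rc)
        out.append(cand)
    return out


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def _scrub_sequence(seq: list[str], patterns: list[str], frozen: np.ndarray,
                    allowed: set[tuple[int, int]], rng,
                    max_rounds: int = 50) -> None:
    """Resample non-frozen bases of any unplanned pattern occurrence."""
    bases = "ACGT"
    for _ in range(max_rounds):
        text = "".join(seq)
        dirty = False
        for pi, pat in enumerate(patterns):
            for off in _find_all(text, pat):
                if (pi, off) in allowed:
                    continue
                free = [j for j in range(off, off + len(pat)) if not frozen[j]]
                if not free:
                    continue
                for j in free:
                    seq[j] = bases[rng.integers(0, 4)]
                dirty = True
        if not dirty:
            return


def simulate_experiment(config: SimulationConfig | None = None
                        ) -> SimulationBundle:
    """Generate the full synthetic experiment with planted ground truth.

    Deterministic given ``config.seed``: identical seeds give bit-identical
    outputs.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n, ntf = config.n_genes, config.n_tfs
    tf_ids = [f"TF{i + 1:03d}" for i in range(ntf)]
    gene_ids = tf_ids + [f"G{i + 1:05d}" for i in range(n - ntf)]

    # --- annotation: genes laid along one chromosome, random strand
    spacing = max(config.promoter_len + 1000, 4000)
    tss = 2000 + spacing * np.arange(n)
    strand = rng.choice(["+", "-"], size=n)
    lengths = rng.integers(800, 3000, size=n)
    cf = set(rng.choice(tf_ids, size=max(2, ntf // 20), replace=False))
    annotation = pd.DataFrame({
        "chrom": "chrI", "strand": strand, "tss": tss,
        "length_nt": lengths,
        "is_tf": [g in set(tf_ids) for g in gene_ids],
        "is_chromatin_factor": [g in cf for g in gene_ids],
    }, index=pd.Index(gene_ids, name="gene_id"))

    # --- modules, stages, signs
    stage_cycle = ("S1", "S2", "S3")
    tf_modules = {tf: i % config.n_modules for i, tf in enumerate(tf_ids)}
    module_stage = {m: stage_cycle[m % 3] for m in range(config.n_modules)}
    # regulatory sign is a module property (a module of co-acting
    # activators or of co-acting repressors); one module in five is
    # repressive, giving ~80% activator TFs overall
    n_neg = max(1, round(0.2 * config.n_modules))
    neg_modules = set(rng.choice(config.n_modules, size=n_neg, replace=False))
    module_sign = {m: (-1 if m in neg_modules else 1)
                   for m in range(config.n_modules)}
    tf_signs = {tf: module_sign[tf_modules[tf]] for tf in tf_ids}
    module_tfs: dict[int, list[str]] = {}
    for tf in tf_ids:
        module_tfs.setdefault(tf_modules[tf], []).append(tf)

    # --- baselines
    base = np.exp(rng.normal(np.log(30.0), 1.0, size=n))
    base[:ntf] = np.maximum(base[:ntf], 50.0)
    base *= config.library_size_mean / base.sum()
    baseline = pd.Series(base, index=gene_ids, name="baseline")

    # --- planted regulation and trajectories
    stage_label = {g: "none" for g in gene_ids}
    gene_params: dict[str, ImpulseParams | None] = {g: None for g in gene_ids}
    edges = []
    for tf in tf_ids:
        st = module_stage[tf_modules[tf]]
        stage_label[tf] = st
        gene_params[tf] = _draw_impulse(rng, st, baseline[tf], +1,
                                        amp_range=(1.5, 3.0))
    for g in gene_ids[ntf:]:
        if rng.random() >= config.frac_wound_induced:
            continue
        module = int(rng.integers(0, config.n_modules))
        st = module_stage[module]
        pool = module_tfs.get(module, [])
        if not pool:
            continue
        sign = module_sign[module]
        k = int(rng.integers(1, min(3, len(pool)) + 1))
        regulators = list(rng.choice(pool, size=k, replace=False))
        stage_label[g] = st
        gene_params[g] = _draw_impulse(rng, st, baseline[g], sign)
        for tf in regulators:
            edges.append((tf, g, sign, float(rng.uniform(0.5, 1.5))))

    # --- autoregulators (self-edges, zero knockdown weight)
    autoregs = set(rng.choice(tf_ids, size=max(3, ntf // 10), replace=False))
    for tf in sorted(autoregs):
        edges.append((tf, tf, +1, 0.0))
    planted_edges = pd.DataFrame(
        edges, columns=["tf_id", "target_id", "sign", "weight"])

    # --- design and counts
    design_rows, lib = [], []
    for cond in ("UW", "W"):
        for t in config.timepoints:
            for rep in range(1, config.n_reps + 1):
                design_rows.append({
                    "sample_id": f"{cond}_t{t:g}_r{rep}", "condition": cond,
                    "timepoint_h": float(t), "replicate": rep})
                lib.append(np.exp(rng.normal(0.0, 0.25)))
    design = pd.DataFrame(design_rows)
    lib = np.asarray(lib)

    tps = np.asarray(config.timepoints, dtype=float)
    w_means = np.tile(base[:, None], (1, len(tps)))
    for gi, g in enumerate(gene_ids):
        if gene_params[g] is not None:
            w_means[gi] = impulse_value(gene_params[g], tps)
    mu = np.empty((n, len(design)))
    for j, row in enumerate(design_rows):
        ti = int(np.flatnonzero(tps == row["timepoint_h"])[0])
        mu[:, j] = lib[j] * (base if row["condition"] == "UW"
                             else w_means[:, ti])
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(counts, index=gene_ids,
                          columns=[d["sample_id"] for d in design_rows])

    # --- motifs, promoters, planted sites
    consensi = _random_consensi(rng, ntf, config.motif_len)
    motif_consensus = dict(zip(tf_ids, consensi))
    pwms = []
    for tf, cons in motif_consensus.items():
        probs = np.full((len(cons), 4), 0.05)
        for i, b in enumerate(cons):
            probs[i, "ACGT".index(b)] = 0.85
        pwms.append(PWM(f"M_{tf}", tf, probs))

    L = config.promoter_len
    site_rows = []
    promoters: dict[str, str] = {}
    patterns = [c for cons in consensi for c in (cons, revcomp(cons))]
    pattern_tf = [tf for tf in tf_ids for _ in range(2)]
    edges_by_gene: dict[str, list[str]] = {}
    for tf, g in planted_edges[["tf_id", "target_id"]].itertuples(index=False):
        edges_by_gene.setdefault(g, []).append(tf)
    bases = "ACGT"
    for g in gene_ids:
        seq = [bases[i] for i in rng.integers(0, 4, size=L)]
        frozen = np.zeros(L, dtype=bool)
        allowed: set[tuple[int, int]] = set()
        _scrub_sequence(seq, patterns, frozen, allowed, rng)
        for tf in edges_by_gene.get(g, []):
            n_occ = int(rng.integers(1, 4))
            cons = motif_consensus[tf]
            for _ in range(n_occ):
                for _attempt in range(100):
                    off = int(rng.integers(0, L - len(cons) + 1))
                    if not frozen[off:off + len(cons)].any():
                        break
                else:
                    continue
                minus = bool(rng.random() < 0.5)
                written = revcomp(cons) if minus else cons
                for i, b in enumerate(written):
                    seq[off + i] = b
                frozen[off:off + len(cons)] = True
                pi = patterns.index(cons)
                allowed.add((pi if not minus else pi + 1, off))
                # the opposite-strand pattern matches at the same offset
                allowed.add((pi + 1 if not minus else pi, off))
                site_rows.append((g, tf, off, "-" if minus else "+"))
        _scrub_sequence(seq, patterns, frozen, allowed, rng)
        promoters[g] = "".join(seq)
    planted_sites = pd.DataFrame(
        site_rows, columns=["gene_id", "tf_id", "offset", "strand"])

    # --- peaks for half of the TFs, spanning planted sites
    peaked_tfs = set(rng.choice(tf_ids, size=ntf // 2, replace=False))
    peak_rows = []
    windows = {}
    for gi, g in enumerate(gene_ids):
        if strand[gi] == "+":
            windows[g] = int(tss[gi] - 2000)
        else:
            windows[g] = int(tss[gi] - 1000)
    for g, tf, off, _ in site_rows:
        if tf not in peaked_tfs:
            continue
        w0 = windows[g]
        start = max(w0 + off - 150, 0)
        end = w0 + off + config.motif_len + 150
        peak_rows.append(("chrI", start, end, tf,
                          float(rng.uniform(100, 1000))))
    peaks = pd.DataFrame(peak_rows,
                         columns=["chrom", "start", "end", "tf_id", "score"])

    nonself = planted_edges["tf_id"] != planted_edges["target_id"]
    knockdown_effects = planted_edges[nonself].assign(
        effect=lambda d: d["sign"] * d["weight"])[
        ["tf_id", "target_id", "effect"]].reset_index(drop=True)

    truth = SyntheticTruth(
        planted_edges=planted_edges, gene_params=gene_params,
        baseline=baseline, stage_label=stage_label, tf_modules=tf_modules,
        module_stage=module_stage, tf_signs=tf_signs,
        autoregulators=autoregs, planted_sites=planted_sites,
        motif_consensus=motif_consensus, knockdown_effects=knockdown_effects)
    return SimulationBundle(counts=counts, design=design,
                            annotation=annotation, promoters=promoters,
                            peaks=peaks, pwms=pwms, truth=truth,
                            config=config)


# ---------------------------------------------------------------------------
# knockdown simulation


def knockdown_means(truth: SyntheticTruth, lost_tfs, timepoint_h: float
                    ) -> tuple[pd.Series, pd.Series]:
    """Expected W-condition means under control and TF loss.

    Direct-target means are multiplied by 2^(-sum of effects over lost
    regulators); effects combine additively in log2 space.
    """
    lost = set(lost_tfs)
    known = set(truth.tf_modules)
    unknown = lost - known
    if unknown:
        raise ValueError(f"unknown TF(s): {sorted(unknown)}")
    genes = list(truth.baseline.index)
    control = np.empty(len(genes))
    for gi, g in enumerate(genes):
        params = truth.gene_params[g]
        control[gi] = (truth.baseline[g] if params is None
                       else float(impulse_value(params, timepoint_h)))
    shift = pd.Series(0.0, index=genes)
    eff = truth.knockdown_effects
    hit = eff[eff["tf_id"].isin(lost)]
    for tgt, grp in hit.groupby("target_id"):
        shift[tgt] = grp["effect"].sum()
    mutant = control * 2.0 ** (-shift.to_numpy())
    return (pd.Series(control, index=genes, name="control"),
            pd.Series(mutant, index=genes, name="mutant"))


def simulate_knockdown(truth: SyntheticTruth, lost_tfs, timepoint_h: float,
                       config: SimulationConfig, n_reps: int | None = None,
                       seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mutant-W vs control-W count matrix at one timepoint."""
    n_reps = n_reps or config.n_reps
    control, mutant = knockdown_means(truth, lost_tfs, timepoint_h)
    rng = np.random.default_rng(seed)
    cols, rows, mus = [], [], []
    for group, means in (("control", control), ("mutant", mutant)):
        for rep in range(1, n_reps + 1):
            sid = f"{group}_r{rep}"
            cols.append(sid)
            rows.append({"sample_id": sid, "group": group,
                         "timepoint_h": timepoint_h, "replicate": rep})
            mus.append(np.exp(rng.normal(0.0, 0.25)) * means.to_numpy())
    mu = np.column_stack(mus)
    r = 1.0 / config.nb_dispersion
    counts = pd.DataFrame(rng.negative_binomial(r, r / (r + mu)),
                          index=control.index, columns=cols)
    return counts, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PPI / IDR simulation


def simulate_ppi_idr(truth: SyntheticTruth, within_module_p: float = 0.5,
                     between_p: float = 0.02, seed: int = 0,
                     n_background: int = 60,
                     presence_p_tf: float = 0.85,
                     presence_p_background: float = 0.5
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Module-correlated PPI edges and Beta-distributed IDR annotations.

    TF pairs in the same module interact with probability
    ``within_module_p``, others with ``between_p``. Wound TFs draw IDR
    fractions from Beta(4, 2), background proteins from Beta(2, 4); a
    protein appears in the IDR table (one interval) with the group's
    presence probability. Updates ``truth.ppi_edges`` and
    ``truth.idr_fractions`` in place and returns the two tables.
    """
    for p in (within_module_p, between_p):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tfs = sorted(truth.tf_modules)
    edge_rows = []
    for i, a in enumerate(tfs):
        for b in tfs[i + 1:]:
            p = within_module_p if truth.tf_modules[a] == truth.tf_modules[b] \
                else between_p
            if rng.random() < p:
                edge_rows.append((a, b))
    ppi = pd.DataFrame(edge_rows, columns=["protein_a", "protein_b"])

    idr_rows = []
    fractions: dict[str, float] = {}
    proteins = [(tf, True) for tf in tfs] + \
        [(f"BG{i + 1:03d}", False) for i in range(n_background)]
    for pid, is_tf in proteins:
        frac = float(rng.beta(4, 2) if is_tf else rng.beta(2, 4))
        fractions[pid] = frac
        present_p = presence_p_tf if is_tf else presence_p_background
        if rng.random() >= present_p:
            continue
        length = int(rng.integers(300, 800))
        span = max(int(round(frac * length)), 1)
        start = int(rng.integers(0, length - span + 1))
        idr_rows.append((pid, start, start + span, length))
    idr = pd.DataFrame(idr_rows, columns=["protein_id", "idr_start",
                                          "idr_end", "protein_length"])
    truth.ppi_edges = ppi
    truth.idr_fractions = fractions
    return ppi, idr
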