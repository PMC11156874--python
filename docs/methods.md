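# Methods

This note documents the models implemented in `woundnet`, the reasoning
behind the defaults, and what the synthetic benchmark does and does not
establish about real data.

## Count model and normalization

Counts are modelled negative-binomial with `Var = μ + α μ²` throughout.
Sequencing depth is removed by median-of-ratios size factors computed
over genes with nonzero counts in every sample, rescaled to geometric
mean 1. Gene dispersions are method-of-moments estimates on normalized
counts within each (condition, timepoint) replicate group, averaged
across groups and floored at `α = 0.01`. The moment ratio uses the
plug-in-mean-corrected denominator `m² − s²/n` (since
`E[m̂²] = μ² + Var/n`); without it the estimator is biased several
percent low at n = 3 and the downstream Wald tests become
anticonservative. Single-worm libraries are noisy, hence the relatively
high default simulated dispersion (α = 0.2) and the pseudocount of 1 used
whenever medians are ratioed.

## Per-timepoint test

The NB log-link GLM with a condition indicator decomposes into
independent per-group mean fits, solved by Newton iteration on
`η = log μ` with score `Σ (y − μ)/(1 + αμ)` and Fisher information
`Σ μ/(1 + αμ)`. The Wald statistic uses the normal reference. With three
replicates per group this is mildly anticonservative by construction
(measured null type-I ≈ 0.05–0.06 at p < 0.05); no dispersion or LFC
shrinkage and no independent filtering are applied — the aim is a
transparent test whose behaviour is fully characterized, not a clone of
a specific tool, and results on real data will differ in the tails.
DEG calls use strict inequalities: BH q < 0.05 and fold change > 1.5.

## Impulse model and case-control screen

The wounded trajectory model is the six-parameter product of sigmoids
with slope β, levels h₀/h₁/h₂ and onset/offset t₁ < t₂. Fitting
maximizes the NB likelihood (dispersion taken from the pointwise stage)
by bounded L-BFGS-B with an analytic gradient, from eight data-driven
starts (transient peak, trough, monotone, constant, and jittered
variants); each start is polished briefly and the best refined to
convergence. Bounds: β ∈ [0.1, 50], t₁ ∈ [−1, 25] h, t₂ − t₁ ∈
[0.01, 30] h, levels positive. The optimization is parameterized in
(log β, log h, t₁, log Δt) so the t₁ < t₂ invariant is structural.

The case-control test fits one impulse to all samples (null, 6 df) and
one per condition (alternative, 12 df); the alternative fits are
additionally seeded with the null optimum, which guarantees the nesting
inequality `ℓ_alt ≥ ℓ_null − ε` at the optimizer level. p-values come
from the asymptotic χ²₆; measured null behaviour is slightly
conservative to nominal (fraction p < 0.05 around 0.05–0.09, zero
FDR-0.01 discoveries on 500-gene null runs). Unwounded 0.25 h replicates
are duplicated into both conditions at t = 0 as a shared pre-wound
baseline — assigning them to both conditions (rather than UW only) is an
interpretive choice; it anchors both fits at the same level and makes
the null well-specified. Genes below mean normalized count 1 in both
conditions are reported `untested` rather than fitted.

## Signature filters, clustering, stages

The hiDEG filter sorts iDEGs by overall median expression
(median_W + median_UW), keeps the top ⌈0.75·n⌉ (ties broken by gene id,
documented), and requires a pseudocounted median ratio beyond 2× in
either direction at ≥1 timepoint — down-regulation is accepted here
because one trajectory cluster in this system is a down cluster, while
wound-*induced* genes additionally require significant up-regulation
(q < 0.05 and log2FC > 1) at ≥1 timepoint. All boundary comparisons are
strict.

Trajectory clustering is Euclidean k-means (k-means++, 25 restarts,
fixed seed) on log2FC rows; cluster labels are canonicalized by
composite peak time so they are invariant to input row order. The elbow
choice of k is the argmax of the second forward difference of the
within-SS curve. Timepoint correlation uses Pearson r with
average-linkage clustering on 1 − r cut into three groups, warning when
groups are not contiguous in time. Stage assignment clusters
wound-induced trajectories at k = 3 and maps each cluster to the stage
containing its onset (first timepoint with composite log2FC ≥ 1);
clusters that never reach the threshold map via their absolute peak with
a warning. For the Fig-2-style correlation view the matrix of W/UW
log2 ratios is used; computing it on W expression alone is a documented
alternative the data do not disambiguate.

## Promoter scanning and network construction

Promoter windows are strand-aware `[TSS−2000, TSS+1000)` intervals
(0-based half-open everywhere), clipped at chromosome bounds. PWM
scanning discretizes log-odds scores to 10⁻³ bits and computes the exact
null score distribution by dynamic programming under the background
model, so hit p-values agree with brute-force enumeration up to the
discretization; both strands are scanned and windows containing N are
skipped. The default hit threshold is p < 10⁻⁴ per window, the
conventional scanner default. A TF's targets are genes with a peak
overlap (≥1 bp, half-open) or a motif hit in the promoter window — the
OR rule; evidence is recorded as peak/motif/both.

Edge dynamics: an edge is active at timepoint t when the TF is expressed
there (FPKM > 1 in wounded samples) and the target is responding
(|log2FC| > 1); stages follow from active timepoints. Activator versus
repressor is decided by the Pearson correlation between the TF's own
trajectory and the mean trajectory of its *unique* targets (genes with
at most two regulators), threshold |r| ≥ 0.5 — a numeric stand-in for a
judgement the original analysis made visually. Hub degree counts
distinct TF partners (undirected, deduplicated) in the stage's TF–TF
subnetwork.

Path-split detection is a transparent stand-in for an external
IOHMM-based tool whose internals are out of scope here: genes start on
one path at the pseudo-0 baseline; at each timepoint each path's
per-gene Δlog2FC is 2-means clustered and the path splits when branch
means differ by ≥ 1.0 (mirroring the published minimum-standard-deviation
knob) with both branches ≥ 10 genes; TFs expressed at the split are
assigned to branches by hypergeometric target enrichment (BH across
TF × branch, q < 0.05, top 3 reported); splits before 10 h are flagged
for downstream clustering. Real-data path topology from the original
tool will differ; recovery is validated on planted bifurcations.

## Topic model

Genes are documents, time-tagged TFs are words (the same TF at two
timepoints is two words; the matrices at 0.25/0.5/6/14/24 h are
concatenated). A collapsed Gibbs sampler (1000 sweeps, 500 burn-in,
samples every 10) estimates φ and θ from averaged counts plus priors.
The document prior defaults to α = 1/K: documents here have only a
handful of regulator tokens, and a text-corpus-scale prior such as 50/K
flattens θ and erases module structure at this document length (measured
module ARI collapses from 1.0 to < 0.4). η = 0.1. K selection reports
held-out document-completion perplexity (80/20 split) and mean pairwise
topic Jensen–Shannon divergence, combined by rank-sum; K can always be
pinned (the study's value is 8).

Membership z-scores are computed across topics for a fixed word
(z(w,k) = (φ[k,w] − mean_k φ)/sd_k φ, population sd) and analogously for
genes on θ rows, with strict thresholds 2 and 1. Note max z = √(K−1), so
the TF threshold is only reachable for K ≥ 6; for comparing a small-K
fit against a known partition use the dominant-topic view
(`tf_topic_partition`, aggregate φ mass).

## Enrichment and perturbation statistics

Within-topic PPI enrichment uses uniform same-size draws from the TF
universe as the null (1000 permutations, `p = (1 + #{null ≥ obs})/(N+1)`);
a degree-matched null is available as a flag. IDR presence uses a
one-sided Fisher exact test, IDR length fractions a one-sided Wilcoxon
rank-sum (exact for ≤25 untied observations), IDR–degree association a
Spearman correlation. Knockdown contrasts reduce to per-gene log2FC by
the same NB machinery; target-vs-non-target shifts use a one-sided
rank-sum over the tested-gene universe, and double-loss additivity a
one-sided Welch t-test of common targets under double versus each single
loss. Note that with a broad knockdown, median-of-ratios normalization
absorbs part of the global shift, so absolute log2FCs are
composition-biased toward zero; all the tests used are contrasts between
gene groups and are unaffected.

## Synthetic generator

Defaults emulate the study design: 3000 genes (60 TFs), 2 conditions ×
12 timepoints (0.25–24 h) × 3 replicates, NB counts with α = 0.2 and
lognormal library factors (σ = 0.25), mean library 3×10⁵ reads.
A quarter of non-TF genes are wound-induced, with impulse trajectories
whose onsets are drawn inside their stage (S1 ≈ 0.25 h, S2 ∈ {0.5, 1, 2} h,
S3 ∈ {6, 10, 12} h), amplitudes 2–4 log2 units, and stage-scaled
durations; TFs are constitutively expressed and respond with their
module's stage. TFs carry one of four modules; regulatory sign is a
module property (one module in five is repressive, giving ~80 % activator
TFs) so that modules remain coherent co-occurrence blocks. Planted edges
place 1–3 exact motif consensus occurrences (8-mers, 0.85/0.05 PWMs) in
the target promoter on either strand; half the TFs also get ChIP-like
peaks spanning their sites ± 150 nt; autoregulators get a site in their
own promoter.

Promoters are i.i.d. uniform ACGT with one refinement: chance
occurrences of any simulated consensus are resampled away before
planting, so motif-level decoy edges are absent by construction. The
expected decoy rate would otherwise be ≈ 6000/4⁸ ≈ 0.09 per (TF, gene)
pair — ~16 000 spurious edges against ~2 000 planted at default scale —
which would make recovery metrics measure background collision
statistics rather than the pipeline. Consequently the benchmark
demonstrates correct evidence plumbing and sharp recovery, not
robustness to motif false positives in real genomes; peaks overlapping
an adjacent gene's abutting promoter window remain as a small realistic
false-positive source (edge precision ≈ 0.98, not 1.0).

PPI edges are Erdős–Rényi with module-dependent probability (0.5 within,
0.02 between); IDR fractions are Beta(4,2) for TFs and Beta(2,4) for
background proteins, with presence probabilities 0.85/0.5. Knockdowns
multiply direct-target means by `2^(−Σ effects)`, additive in log2.

What the generator does not emulate: realistic promoter composition (GC
structure, repeats), read-level artifacts, isoforms, indirect regulatory
effects, or motif decoys (above). Passing recovery tests therefore shows
the inference chain is correct and calibrated under its own model, not
that it matches the original study's counts on deposited data.

## Problem sizes and determinism

The test suite runs the generator at its study-scale default (3000
genes, 60 TFs) for the recovery checks and at reduced sizes elsewhere;
the end-to-end determinism check runs a structurally complete 150-gene
pipeline twice and compares manifest hashes. `scripts/acceptance.py`
uses a 1200-gene, 40-TF configuration (a few minutes on one CPU; the
full default pipeline completes in well under 15 minutes). All
randomness flows from a single master seed; identical config + seed
yields bit-identical run directories, verified via sha256 manifests.

## Known limitations

- The Wald normal reference is anticonservative in the extreme tails at
  n = 3; a permutation option is not implemented.
- The split-detection stand-in shares only the published knobs (minimum
  separation 1.0, FPKM > 1 TF filter, <10 h usage) with the original
  IOHMM tool; topologies are not comparable node-for-node.
- χ²₆ for the impulse LRT is asymptotic; at very low counts the screen
  relies on the expression prefilter.
- Accessibility (ATAC) masking of promoter evidence is not implemented.
- Exact numerical agreement with the Bioconductor impulse implementation
  is out of scope; the functional form and test structure match.
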