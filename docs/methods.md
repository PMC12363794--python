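# Methods

This note documents the models, parameter choices and numerical
conventions behind each stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Chromatin-state classification

A promoter's state in a condition is a deterministic function of two
booleans — presence of an H3K4me3 peak and of an H3K27me3 peak in the
window `[tss − w, tss + w)` (0-based half-open, clipped at 0, strand
ignored): Active (K4 only), Repressed (K27 only), Bivalent (both),
Unmarked (neither). The window half-width `w` defaults to 2,000 bp, a
conventional promoter-proximal span for these broad marks; it is
overridable everywhere because peak-overlap state calling is a choice, not
a canon — signal-threshold or HMM-segmentation definitions would draw the
boundaries differently, and nothing downstream depends on which is used as
long as presence calls are consistent between conditions.

Replicated peak files are combined by majority rule (peak in
≥ ⌈r/2⌉ replicates); the default path is a single pooled file per
mark/condition. A gene with several annotated TSSs is scored on the union
of its windows — conservative for presence. Genes called in only one
condition are reported separately and excluded from the 4×4 transition
matrix, whose total therefore equals the number of jointly-called genes.

**Transition-class enrichment.** For each condition-2 state, and each of
the 16 (state₁ → state₂) classes, the number of differentially expressed
genes (chosen direction, q ≤ q_max, default 0.05) is tested against the
background of all jointly-called genes with a one-sided hypergeometric
P(X ≥ k). BH adjustment is applied within the 4-class table and within
the 16-class table separately, since the two granularities answer the same
question at different resolution and should not dilute each other. Genes
missing from the DE table count as not differentially expressed. Both the
enrichment ranking and the raw per-class counts are emitted, since a
count ranking and a test ranking can disagree on small classes.

## Single-cell program scoring

Counts are depth-scaled to the median cell total and log1p-transformed;
cells with zero totals are dropped with a warning. A signature score is
the mean over member genes of per-gene z-scores (population SD across
cells). This "average Z-score" is deliberately the simplest defensible
scheme: it is invariant to gene order and per-cell depth, and exactly
verifiable. It does not use binned control genes (à la Seurat/scanpy
`score_genes`), so scores of sets with very different expression levels
are less comparable than control-matched scores would be; for argmax-type
subtype calls over sets of similar size this does not matter. Genes whose
normalized expression is numerically constant (SD below 1e−12 relative)
are excluded with a warning; an all-constant set is an error, not a NaN.

Subtype assignment takes the argmax over marker-set scores at cluster
level by default (labels attach to clusters, cells inherit them); the
margin (top minus runner-up) is reported, and a tie at machine precision
yields "ambiguous". Master-regulator TF modules map the argmax over the
three TF group scores to modules 0/1/2 (NEPC, transition, adenocarcinoma);
exact ties break deterministically in that fixed order and carry a `tied`
flag, so module assignment is always a partition. The module summary
(mean pseudotime, treatment/subtype composition) is descriptive output for
interpretation, not part of the assignment rule.

**Pseudotime smoothing.** Program-vs-pseudotime profiles use a degree-3
B-spline regression with `df + 1` coefficients and interior knots at
pseudotime quantiles, fit by least squares and evaluated on a 100-point
grid. `df = 3` is a plain cubic polynomial, so any cubic trend (including
a linear one) is reproduced exactly; default `df = 5` allows one
inflection without chasing noise at typical cell counts. `df` must be
below the number of distinct pseudotime values. Pseudotime is consumed,
never computed here — trajectory inference is a separate concern.

**DE ranking.** Genes are ranked by sign(log2 fold change of group means,
pseudocount 1) × (−log10 Wilcoxon rank-sum p), ties broken by gene id.
p-values are clipped at 1e−300 before the log. The Wilcoxon test is a
robust default for log-normalized single-cell data; genes constant in
both groups get p = 1 and effect 0.

**Pre-ranked GSEA.** The enrichment score is the classic weighted
running-sum statistic: walking the ranked list, member genes add
|statistic|^p (p = 1, normalized to sum 1), non-members subtract
1/(N − n_set); ES is the maximum signed deviation, computed in O(n_set)
from the hit positions. A near-exact tie between the positive and negative
extremes (within 1e−9) resolves to the positive deviation, a convention
fixed so that the O(n_set) path and the O(N) brute-force check agree to
rounding. Null distributions come from gene-label permutations (random
sets of the same size against the fixed ranking) under a dedicated child
seed; NES divides ES by the mean |permuted ES| of the matching sign, the
nominal p is the same-sign permutation tail with a +1 correction, and FDR
q is the standard NES-ratio estimator (pooled permutation NES tail over
observed NES tail, clipped to [0, 1], monotone in |NES| within each sign).
This estimator is known to be anti-conservative near its nominal level
under a complete null: in our calibration study (random sets, null
rankings, 200 simulations of 50 sets) the q < 0.25 discovery fraction
measures ≈ 0.33 — a property of the estimator itself, reported rather
than patched, and the reason significance defaults are conservative
(FDR < 0.01 with |NES| > 1 for single-cell contrasts; q < 0.25 for bulk
contrasts).

## Bliss synergy

Relative viability is raw luminescence over the mean of the plate's
control wells (dose (0, 0)); inhibition is 1 − viability clamped to
[0, 1], with the clamp count logged — negative inhibition (apparent
growth stimulation) is clamped rather than propagated because the Bliss
formula is undefined outside the unit square. Monotherapy effects E_a and
E_b are taken directly from the same plate's dose margins, with no curve
fitting: the landscape summary is a plain average, and model-fitting the
margins would trade transparency for smoothness. δ is computed per
replicate and then averaged; the summary is the mean δ over combination
wells only (margins are identically 0 by construction), with the
replicate SD reported. The summary is invariant to plate-wide rescaling
and to swapping the two drugs.

## RIME interactor nomination

The two filtering procedures are deliberately kept as distinct modes
rather than reconciled, because they encode different philosophies:
`venn` is a hard count threshold (≥ 5 in every bait replicate, absent
from the IgG-passing set, where any IgG replicate at ≥ 5 disqualifies);
`fdr` is a statistical comparison (summed bait vs summed IgG counts,
one-sided exact conditional binomial with success probability equal to
the bait arm's share of total counts — the conditional form of a Poisson
rate-ratio test with arm-total offsets — BH-adjusted, with q ≤ 0.1,
detection meaning count > 0 in ≥ 2 of the bait samples, and bait rate
above IgG rate). "Detection" is count > 0, not ≥ 5, because detection and
enrichment are separate requirements in the fdr rule. The arm-total
offset means strong enrichment in a small table inflates the bait
baseline and costs power — acceptable for realistic tables with hundreds
of background proteins, and visible in the fixture tests. Both modes are
monotone: raising a bait count never removes a hit, raising an IgG count
never creates one.

## Synthetic data: what is emulated, what is not

One global seed fans out to a fixed child stream per generator
(`SeedSequence(seed, spawn_key=(stream,))`), so outputs are byte-identical
under a fixed seed and adding a generator never perturbs the others.

* **Promoters/peaks** — condition-1 states drawn from a 4-state mixture
  (default uniform), condition-2 states evolved by a row-stochastic
  kernel whose default gains bivalency (each state 70% stable, 20%
  flowing to Bivalent), emulating Polycomb redistribution between
  genotypes. TSSs sit on a 50 kb grid so promoter windows can never
  collide — which is also why the noise-free round trip is exact. Peaks
  are fixed-width TSS ± 1 kb intervals; real peak calls have variable
  width, scores and noise, none of which the state-calling logic reads.
* **Single-cell counts** — negative binomial with variance
  μ + μ²·dispersion (dispersion 0.3, a typical droplet-data value), gene
  means lognormal around 0.5 counts/cell, cells split evenly over
  clusters, one 50-gene program per designated cluster up-shifted by 1
  log2 by default, treatment labels tied to cluster blocks, pseudotime =
  cluster ordinal + uniform jitter. No ambient RNA, doublets, batch
  effects, or mean–dispersion trend: passing recovery tests shows the
  scoring machinery works, not that it is robust to those artifacts.
* **Viability plates** — monotherapy inhibition from a 4-parameter
  logistic (EC50 1.0, slope 1, E_max 0.6 on a 0–2 dose range, chosen so
  the planted interaction never saturates the unit interval), combination
  wells at Bliss + δ (default 10 points), mean-one lognormal noise with
  5% CV, three replicate plates, and six control wells per replicate
  whose average fills the (0, 0) cell — as on a real CellTiter-Glo
  layout; with a single control well the shared normalization noise both
  biases and inflates the recovered summary.
* **Spectral counts** — Poisson, background rate 5 per replicate, planted
  enriched proteins at 20× in the bait arm only, 4 bait / 2 IgG
  replicates. Real spectral counts are overdispersed and share peptides
  across proteins; the Poisson null matches the fdr-mode test's
  assumption, so the null-calibration study checks the procedure, not
  spectral-count realism.

## Pipeline

Stages communicate only through files and run in dependency order
(simulate → programs → chromstate, with synergy and rime independent);
programs runs before chromstate so its DE table can feed the
transition-class enrichment. A failed stage skips its dependents, never
its independents. The run report echoes every parameter used and lists
every output with a SHA-256 checksum; re-running a config reproduces the
manifest byte for byte. All tabular outputs carry a one-line `#` header
with tool version and parameters.

## Validation studies and their problem sizes

The studies in `plastichrom.validation` (driven by the test suite and
`scripts/acceptance.py`) use: 10,000 promoters for round-trip and
kernel-recovery checks; 10,000 genes × 300 cells for the planted-bivalency
enrichment; all 21,699 gene sets of size ≤ 5 over a 20-gene ranking for
the GSEA oracle; 200 simulations of 50 null sets (500 genes, 200
permutations) for GSEA calibration; 200 plates for Bliss recovery; 200
null tables and 20 enriched tables for RIME error rates; and 20 seeded
runs of 2,000 cells for signature/subtype recovery. These sizes give
stable estimates (binomial/multinomial standard errors small relative to
every tolerance) while keeping a full run in tens of seconds.

## Known limitations

* State calling is binary peak overlap; partial-window or signal-strength
  information is discarded.
* The signature score has no control-gene matching, and module assignment
  is pure argmax — the upstream work that motivated this pipeline layered
  manual curation over pseudotime, subtype and TF expression, which an
  argmax cannot fully reproduce; the module summary table exists to make
  such curation possible.
* Scores are computed on normalized, non-imputed expression; imputed
  (smoothed) expression would shift absolute score ranges.
* The Bliss summary averages the whole landscape; tools that report a
  maximal-synergy window will read higher on the same plate.
* fdr-mode RIME assumes Poisson counts; overdispersed real data would
  need a negative-binomial test for honest error control.
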