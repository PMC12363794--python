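# plastichrom

Analysis pipeline for studying how the Polycomb methyltransferase **EZH2**
maintains phenotypic plasticity in prostate cancer models — linking
chromatin-state dynamics at promoters to single-cell lineage programs,
drug-combination synergy, and the EZH2 protein interactome. It is built for
computational biologists integrating H3K4me3/H3K27me3 ChIP-seq, snRNA-seq,
viability plate assays, and RIME spectral-count proteomics around a common
question: which genes and cell states does EZH2 inhibition remodel, and
what does that imply therapeutically?

Every stage ships with a synthetic-data generator that plants a known
ground truth, so the whole pipeline is testable end to end without any
external data.

## What it computes

**Chromatin states and transitions** (`plastichrom.chromstate`).
A promoter is classified from peak overlap in a ±2 kb TSS window into one
of four states: Active (H3K4me3 only), Repressed (H3K27me3 only),
Bivalent (both marks — the "poised" developmental configuration), or
Unmarked (neither). Between two conditions (e.g. *Pten*-null vs
*Pten:Rb1*-null tumors) the per-gene labels form a 4×4 transition matrix.
Transition classes are then ranked for enrichment of differentially
expressed genes by a hypergeometric test (BH-adjusted):

> P(X ≥ k), X ~ Hypergeom(N genes, K DE genes, n genes in class)

**Gene programs per cell** (`plastichrom.programs`). Signature scores are
mean per-gene z-scores over depth-normalized log1p expression ("average
Z-score" units). Epithelial subtypes and master-regulator TF modules
(NEPC → 0, transition → 1, adenocarcinoma → 2) are argmax assignments over
marker-set scores; program trajectories are smoothed along pseudotime by a
cubic regression spline. Pre-ranked GSEA uses the weighted running-sum
enrichment score with gene-label permutations, NES = ES / mean(|permuted
ES| of matching sign), and the standard NES-ratio FDR.

**Bliss synergy landscapes** (`plastichrom.synergy`). Plates are
normalized to the mean of their control wells; for each combination well

> δ = 100 · (E_obs − (E_a + E_b − E_a·E_b))

with monotherapy inhibitions E_a, E_b read off the plate's own dose
margins. The landscape summary score is the mean δ over combination wells
(+: synergy, −: antagonism, in percentage points).

**RIME interactor nomination** (`plastichrom.rime`). Two modes against the
IgG control: `venn` (spectral count ≥ 5 in every bait replicate, absent
from the IgG-passing set) and `fdr` (one-sided Poisson rate-ratio test on
summed counts with arm-total offsets, BH q ≤ 0.1, detection in ≥ 2 of 4
bait samples, bait rate > IgG rate).

## Worked example

Simulate a full input bundle (2,000 promoters, 400 cells, one drug pair,
one spectral-count table) and run three stages:

```sh
$ plastichrom simulate --config sim.yaml --outdir demo_sim --seed 11
wrote 11 outputs to demo_sim

$ plastichrom chromstate \
    --k4-cond1 demo_sim/peaks_H3K4me3_cond1.bed --k27-cond1 demo_sim/peaks_H3K27me3_cond1.bed \
    --k4-cond2 demo_sim/peaks_H3K4me3_cond2.bed --k27-cond2 demo_sim/peaks_H3K27me3_cond2.bed \
    --promoters demo_sim/promoters.tsv --out chromstate_out
called 2000 genes in both conditions -> chromstate_out

$ head -6 chromstate_out/transitions.tsv
# {"tool": "plastichrom 0.1.0", "window": 2000}
state_cond1	state_cond2	n_genes
Active	Active	382
Active	Repressed	24
Active	Bivalent	107
Active	Unmarked	27

$ plastichrom synergy --plate demo_sim/plate_drugA_drugB.csv --out synergy.tsv
plate_drugA_drugB.csv: Bliss summary +8.23 (SD 1.43, 16 wells)

$ plastichrom rime --counts demo_sim/spectral_counts.tsv --mode fdr --out hits.tsv
30 hit(s) in fdr mode -> hits.tsv
```

Reading the output: of 540 promoters Active in condition 1, 107 became
Bivalent in condition 2 — gain of poised chromatin, the signature this
pipeline is built to track. The synergy summary of +8.2 points estimates
the planted 10-point interaction from a single noisy 3-replicate plate
(the plate-to-plate SD is ≈1.3 points); the 30 fdr-mode hits are exactly
the 30 planted bait-enriched proteins, with no false positives. `plastichrom run --config examples/demo_config.yaml` chains all
stages from one file and writes a checksum-manifested `report.json`.

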