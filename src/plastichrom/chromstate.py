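"""Four-state promoter classification and condition-to-condition transitions.

Promoters are labelled Active / Repressed / Bivalent / Unmarked from the
presence of H3K4me3 and H3K27me3 peaks in a window around the TSS, the 4x4
transition matrix between two conditions is tabulated, and transition
classes are ranked for enrichment of differentially expressed genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from plastichrom.config import ConfigError
from plastichrom.states import STATES, classify
from plastichrom.synthio import CONDITIONS, MARKS

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 2_000


class InputError(ValueError):
    """Inconsistent or malformed analysis input."""


def _build_trees(beds: list[pd.DataFrame]) -> tuple[dict[str, IntervalTree], list[int]]:
    """One interval tree per chromosome; interval data = replicate index."""
    trees: dict[str, IntervalTree] = {}
    for rep, bed in enumerate(beds):
        for chrom, start, end in zip(bed["chrom"], bed["start"], bed["end"]):
            if end > start:
                trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end), rep)
    return trees, list(range(len(beds)))


def _has_overlap(trees: dict[str, IntervalTree], chrom: str, lo: int, hi: int,
                 n_reps: int) -> bool:
    """Peak presence: overlap in >= ceil(n_reps / 2) replicates (majority)."""
    tree = trees.get(chrom)
    if tree is None:
        return False
    reps = {iv.data for iv in tree.overlap(lo, hi)}
    return len(reps) >= math.ceil(n_reps / 2)


def assign_mark_presence(
    peaks: dict[tuple[str, str], pd.DataFrame | list[pd.DataFrame]],
    promoters: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Call per-promoter H3K4me3 / H3K27me3 presence in each condition.

    Parameters
    ----------
    peaks
        Mapping ``(mark, condition) -> BED frame`` (or list of replicate
        frames; presence then requires a peak in a majority of replicates).
        Marks are ``H3K4me3`` / ``H3K27me3``; conditions ``cond1`` / ``cond2``.
    promoters
        Annotation with gene_id, chrom, tss (0-based), strand.
    window
        Half-width of the promoter window ``[tss - window, tss + window)``,
        clipped at 0. Strand is ignored (the window is symmetric).

    Returns
    -------
    DataFrame with one row per (gene, condition): gene_id, condition,
    has_k4, has_k27.
    """
    if window <= 0:
        raise ConfigError("window must be > 0")
    missing = [key for cond in CONDITIONS for mark in MARKS if (key := (mark, cond)) not in peaks]
    if missing:
        raise InputError(f"missing peak sets for {missing}")
    if promoters["gene_id"].duplicated().any():
        # multiple annotated TSSs per gene: presence over the union of windows
        logger.info("promoter table has repeated gene_ids; using union of TSS windows")

    trees = {}
    n_reps = {}
    for key, bed in peaks.items():
        beds = bed if isinstance(bed, list) else [bed]
        trees[key], _ = _build_trees(beds)
        n_reps[key] = len(beds)

    promoter_chroms = set(promoters["chrom"])
    for key in trees:
        absent = promoter_chroms - set(trees[key]) if trees[key] else promoter_chroms
        if absent and any(len(t) for t in trees[key].values()):
            logger.info("%s: %d promoter chromosome(s) absent from peaks (treated as no overlap)",
                        key, len(absent))

    rows = []
    grouped = promoters.groupby("gene_id", sort=False)
    for gene_id, grp in grouped:
        windows = [
            (chrom, max(int(tss) - window, 0), int(tss) + window)
            for chrom, tss in zip(grp["chrom"], grp["tss"])
        ]
        for cond in CONDITIONS:
            presence = {}
            for mark in MARKS:
                key = (mark, cond)
                presence[mark] = any(
                    _has_overlap(trees[key], c, lo, hi, n_reps[key]) for c, lo, hi in windows
                )
            rows.append(
                {
                    "gene_id": gene_id,
                    "condition": cond,
                    "has_k4": presence["H3K4me3"],
                    "has_k27": presence["H3K27me3"],
                }
            )
    return pd.DataFrame(rows)


def call_states(presence: pd.DataFrame) -> pd.DataFrame:
    """Map mark presence to the four chromatin states.

    (k4, not k27) -> Active; (not k4, k27) -> Repressed; (k4, k27) ->
    Bivalent; (neither) -> Unmarked. One record per (gene, condition).
    """
    if presence.duplicated(subset=["gene_id", "condition"]).any():
        dups = presence[presence.duplicated(subset=["gene_id", "condition"])]
        raise InputError(
            f"duplicate (gene, condition) presence records, e.g. {dups.iloc[0].tolist()[:2]}"
        )
    out = presence[["gene_id", "condition"]].copy()
    out["state"] = [
        classify(bool(k4), bool(k27)) for k4, k27 in zip(presence["has_k4"], presence["has_k27"])
    ]
    return out


@dataclass
class TransitionTable:
    """4x4 condition-1 -> condition-2 state transition counts."""

    counts: pd.DataFrame  # rows: cond1 state, cols: cond2 state
    per_gene: pd.DataFrame  # gene_id, state_cond1, state_cond2
    only_cond1: list[str]
    only_cond2: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def row_normalized(self) -> pd.DataFrame:
        mat = self.counts.to_numpy(dtype=float)
        sums = mat.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(sums > 0, mat / sums, np.nan)
        return pd.DataFrame(norm, index=self.counts.index, columns=self.counts.columns)

    def to_long(self) -> pd.DataFrame:
        long = self.counts.rename_axis(index="state_cond1", columns="state_cond2").stack()
        return long.rename("n_genes").reset_index()


def transition_matrix(states_cond1: pd.DataFrame, states_cond2: pd.DataFrame) -> TransitionTable:
    """Tabulate per-gene state transitions between two conditions.

    Both inputs are state-call frames (gene_id, state). Genes present in
    only one condition are reported separately, not counted.
    """
    s1 = states_cond1.set_index("gene_id")["state"]
    s2 = states_cond2.set_index("gene_id")["state"]
    shared = s1.index.intersection(s2.index)
    if len(shared) == 0:
        raise InputError("no genes called in both conditions")
    per_gene = pd.DataFrame(
        {"gene_id": shared, "state_cond1": s1[shared].to_numpy(), "state_cond2": s2[shared].to_numpy()}
    )
    counts = pd.crosstab(per_gene["state_cond1"], per_gene["state_cond2"])
    counts = counts.reindex(index=STATES, columns=STATES, fill_value=0)
    counts.index.name, counts.columns.name = "state_cond1", "state_cond2"
    return TransitionTable(
        counts=counts,
        per_gene=per_gene,
        only_cond1=sorted(s1.index.difference(s2.index)),
        only_cond2=sorted(s2.index.difference(s1.index)),
    )


def integrate_with_de(
    transitions: TransitionTable,
    de: pd.DataFrame,
    direction: str = "up",
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Rank chromatin-state classes by enrichment of DE genes.

    For each condition-2 state (``class_type == "cond2_state"``) and each
    (state1 -> state2) pair (``class_type == "transition"``), counts the
    genes differentially expressed in ``direction`` at ``q <= q_max`` and
    computes a hypergeometric enrichment p-value against the background of
    all jointly-called genes, BH-adjusted within each class_type. Sorted by
    adjusted p within class_type.

    ``de`` needs columns gene_id, effect (signed log2 fold change), p, q.
    Jointly-called genes missing from ``de`` count as not differentially
    expressed.
    """
    if direction not in ("up", "down"):
        raise ConfigError("direction must be 'up' or 'down'")
    if not 0 < q_max <= 1:
        raise ConfigError("q_max must be in (0, 1]")
    universe = transitions.per_gene["gene_id"]
    de_idx = de.set_index("gene_id")
    de_u = de_idx.reindex(universe)
    sig = (de_u["q"] <= q_max) & (de_u["effect"] > 0 if direction == "up" else de_u["effect"] < 0)
    sig = sig.fillna(False).to_numpy()

    n_total = len(universe)
    n_sig = int(sig.sum())
    pg = transitions.per_gene

    rows = []
    for state2 in STATES:
        mask = (pg["state_cond2"] == state2).to_numpy()
        rows.append(("cond2_state", state2, mask))
    for state1 in STATES:
        for state2 in STATES:
            mask = ((pg["state_cond1"] == state1) & (pg["state_cond2"] == state2)).to_numpy()
            rows.append(("transition", f"{state1}->{state2}", mask))

    records = []
    for class_type, label, mask in rows:
        n_class = int(mask.sum())
        k = int((mask & sig).sum())
        # P(X >= k) for X ~ Hypergeom(N=n_total, K=n_sig, n=n_class)
        p = float(hypergeom.sf(k - 1, n_total, n_sig, n_class)) if n_class else 1.0
        records.append(
            {
                "class_type": class_type,
                "class": label,
                "n_genes": n_class,
                "n_de": k,
                "de_fraction": k / n_class if n_class else np.nan,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(records)
    out["q"] = np.nan
    for class_type in ("cond2_state", "transition"):
        m = out["class_type"] == class_type
        out.loc[m, "q"] = multipletests(out.loc[m, "p"], method="fdr_bh")[1]
    out = (
        out.sort_values(["class_type", "q", "p", "class"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out
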