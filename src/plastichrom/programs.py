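"""Per-cell gene-program scoring, subtype/module assignment, pseudotime
smoothing and pre-ranked permutation GSEA.

Scores are mean per-gene z-scores ("average Z-score" units): every gene is
standardized across cells on depth-normalized log1p expression, then
averaged over the member genes of a signature. Epithelial subtypes and
master-regulator TF modules are argmax assignments over marker-set scores.
GSEA follows the weighted running-sum statistic with gene-label
permutations and the standard NES-based FDR estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import mannwhitneyu

from plastichrom.config import ConfigError

logger = logging.getLogger(__name__)


class GeneSetError(ValueError):
    """A gene set unusable with the given expression matrix."""


class InputError(ValueError):
    pass


#: Fixed MR-TF group -> module mapping (and tie-break precedence).
MRTF_MODULE_ORDER = ("NEPC_TFs", "transition_TFs", "adeno_TFs")


# ---------------------------------------------------------------------------
# normalization and signature scoring

def normalize_log(counts: pd.DataFrame) -> pd.DataFrame:
    """Depth-normalize to the median cell total, then log1p.

    ``counts`` is cells x genes (non-negative). Cells with zero total counts
    are dropped with a warning. The per-cell scaling makes the score
    invariant to multiplying any one cell's counts by a constant.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise InputError("counts must be non-negative")
    totals = mat.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        logger.warning("dropping %d cell(s) with zero total counts", int((~keep).sum()))
        counts, mat, totals = counts.loc[keep], mat[keep], totals[keep]
    if len(totals) == 0:
        raise InputError("no cells with nonzero counts")
    target = float(np.median(totals))
    scaled = mat * (target / totals)[:, None]
    return pd.DataFrame(np.log1p(scaled), index=counts.index, columns=counts.columns)


def score_signature(norm_expr: pd.DataFrame, geneset: list[str], name: str = "signature") -> pd.Series:
    """Per-cell signature score: mean over member genes of per-gene z-scores.

    Genes absent from the matrix are ignored; constant (zero-variance) genes
    are excluded with a warning. An empty usable overlap raises
    :class:`GeneSetError` naming the set.
    """
    members = [g for g in dict.fromkeys(geneset) if g in norm_expr.columns]
    if not members:
        raise GeneSetError(f"gene set {name!r} has no overlap with the expression matrix")
    sub = norm_expr[members].to_numpy()
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    # relative tolerance: a numerically-constant gene has sd at rounding level
    usable = sd > 1e-12 * np.maximum(1.0, np.abs(mean))
    if not usable.any():
        raise GeneSetError(f"gene set {name!r}: all member genes are constant across cells")
    if not usable.all():
        logger.warning(
            "gene set %r: excluding %d constant gene(s) from the score", name, int((~usable).sum())
        )
    z = (sub[:, usable] - mean[usable]) / sd[usable]
    return pd.Series(z.mean(axis=1), index=norm_expr.index, name=name)


def score_signatures(norm_expr: pd.DataFrame, gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Score several signatures; returns a cells x sets score frame."""
    return pd.DataFrame(
        {name: score_signature(norm_expr, genes, name) for name, genes in gene_sets.items()}
    )


# ---------------------------------------------------------------------------
# subtype and module assignment

def assign_subtype(
    scores: pd.DataFrame,
    level: str = "cluster",
    clusters: pd.Series | None = None,
) -> pd.DataFrame:
    """Assign each cell (or cluster) the subtype with the highest score.

    ``scores`` is cells x marker-sets. At ``level="cluster"`` the argmax is
    taken over cluster-mean scores and broadcast back to cells. The margin
    (top minus runner-up score) is reported; a tie at machine precision
    yields label ``"ambiguous"`` with both candidates listed.
    """
    if scores.shape[1] < 2:
        raise ConfigError("subtype assignment needs >= 2 marker sets")
    if level not in ("cell", "cluster"):
        raise ConfigError("level must be 'cell' or 'cluster'")
    if level == "cluster":
        if clusters is None:
            raise ConfigError("cluster-level assignment needs cluster labels")
        cl = clusters.reindex(scores.index)
        unit_scores = scores.groupby(cl).mean()
    else:
        unit_scores = scores

    labels, margins, runners = [], [], []
    cols = unit_scores.columns.to_numpy()
    for _, row in unit_scores.iterrows():
        vals = row.to_numpy(dtype=float)
        order = np.argsort(-vals, kind="stable")
        top, second = vals[order[0]], vals[order[1]]
        margin = top - second
        if np.isclose(top, second, rtol=0.0, atol=np.finfo(float).eps * max(1.0, abs(top))):
            labels.append("ambiguous")
            runners.append(f"{cols[order[0]]}|{cols[order[1]]}")
        else:
            labels.append(cols[order[0]])
            runners.append(cols[order[1]])
        margins.append(margin)
    assigned = pd.DataFrame(
        {"subtype": labels, "margin": margins, "runner_up": runners}, index=unit_scores.index
    )
    if level == "cluster":
        per_cell = assigned.loc[cl].set_axis(scores.index)
        per_cell.insert(0, "cluster", cl.to_numpy())
        return per_cell
    return assigned


def mrtf_modules(
    scores: pd.DataFrame,
    meta: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each cell a master-regulator TF module in {0, 1, 2}.

    ``scores`` must contain the three TF group columns NEPC_TFs,
    transition_TFs and adeno_TFs; the module is the argmax group
    (NEPC_TFs -> 0, transition_TFs -> 1, adeno_TFs -> 2). Exact ties break
    deterministically in that fixed group order and are flagged ``tied``.

    Returns ``(per_cell, summary)``; the summary reports per-module cell
    counts and, when ``meta`` carries them, mean pseudotime and
    treatment/subtype composition for interpretation.
    """
    missing = [g for g in MRTF_MODULE_ORDER if g not in scores.columns]
    if missing:
        raise ConfigError(f"missing TF group score column(s): {missing}")
    mat = scores[list(MRTF_MODULE_ORDER)].to_numpy(dtype=float)
    module = np.argmax(mat, axis=1)  # first max wins = fixed group order
    top = mat[np.arange(len(mat)), module]
    tied = (np.isclose(mat, top[:, None]).sum(axis=1)) > 1
    per_cell = pd.DataFrame(
        {
            "module": module,
            "module_group": [MRTF_MODULE_ORDER[m] for m in module],
            "tied": tied,
        },
        index=scores.index,
    )

    summary_cols: dict[str, pd.Series] = {"n_cells": per_cell.groupby("module").size()}
    if meta is not None:
        meta = meta.reindex(per_cell.index)
        if "pseudotime" in meta:
            summary_cols["mean_pseudotime"] = meta.groupby(per_cell["module"])["pseudotime"].mean()
        for col in ("treatment", "subtype", "cluster"):
            if col in meta:
                comp = (
                    meta.groupby(per_cell["module"])[col]
                    .value_counts(normalize=True)
                    .unstack(fill_value=0.0)
                )
                for value in comp.columns:
                    summary_cols[f"frac_{col}_{value}"] = comp[value]
    summary = pd.DataFrame(summary_cols).rename_axis("module")
    return per_cell, summary


# ---------------------------------------------------------------------------
# pseudotime smoothing

def pseudotime_profile(
    score: pd.Series,
    pseudotime: pd.Series,
    df: int = 5,
    n_grid: int = 100,
) -> pd.DataFrame:
    """Cubic regression-spline fit of a program score along pseudotime.

    The basis is a degree-3 B-spline with ``df + 1`` coefficients (interior
    knots at pseudotime quantiles; ``df = 3`` reduces to a cubic
    polynomial), fit by least squares and evaluated on ``n_grid`` evenly
    spaced points across the observed pseudotime range.

    Returns a frame with columns pseudotime, fitted, resid_sd (the residual
    SD, constant down the column).
    """
    joined = pd.DataFrame({"score": score, "pt": pseudotime}).dropna()
    if len(joined) < 10:
        raise ConfigError("pseudotime smoothing needs >= 10 cells with pseudotime")
    if df < 3:
        raise ConfigError("df must be >= 3")
    x = joined["pt"].to_numpy(dtype=float)
    y = joined["score"].to_numpy(dtype=float)
    n_distinct = len(np.unique(x))
    if df >= n_distinct:
        raise ConfigError(f"df={df} must be < number of distinct pseudotime values ({n_distinct})")

    k = 3
    n_coef = df + 1
    n_interior = n_coef - (k + 1)
    lo, hi = float(x.min()), float(x.max())
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
    else:
        interior = np.array([])
    t = np.concatenate([[lo] * (k + 1), interior, [hi] * (k + 1)])

    design = BSpline.design_matrix(x, t, k, extrapolate=False).toarray()
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    resid_sd = float(np.sqrt(np.mean(resid ** 2)))

    grid = np.linspace(lo, hi, n_grid)
    fitted = BSpline.design_matrix(grid, t, k, extrapolate=False).toarray() @ coef
    return pd.DataFrame({"pseudotime": grid, "fitted": fitted, "resid_sd": resid_sd})


# ---------------------------------------------------------------------------
# differential expression ranking

def de_rank(
    norm_expr: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Rank genes by signed evidence of differential expression (A vs B).

    Effect is the log2 ratio of group means (pseudocount 1) on normalized
    expression; the p-value is a two-sided Wilcoxon rank-sum. The ranking
    key is ``sign(effect) * -log10(p)``; exact ties break by gene id.
    Returns a frame sorted by descending rank key with columns gene_id,
    effect, p, q, rank_key.
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise InputError(f"groups overlap on {len(set_a & set_b)} cell(s)")
    if len(set_a) < 3 or len(set_b) < 3:
        raise InputError("both groups need >= 3 cells")
    a = norm_expr.loc[list(group_a)].to_numpy()
    b = norm_expr.loc[list(group_b)].to_numpy()
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    effect = np.log2(mean_a + 1.0) - np.log2(mean_b + 1.0)

    p = np.ones(norm_expr.shape[1])
    # rank-sum is undefined for all-constant genes; leave p = 1 there
    varies = (a.max(axis=0) > a.min(axis=0)) | (b.max(axis=0) > b.min(axis=0)) | (
        mean_a != mean_b
    )
    if varies.any():
        res = mannwhitneyu(a[:, varies], b[:, varies], alternative="two-sided",
                           method="asymptotic", axis=0)
        p[varies] = res.pvalue
    p = np.clip(np.nan_to_num(p, nan=1.0), 1e-300, 1.0)

    from statsmodels.stats.multitest import multipletests

    q = multipletests(p, method="fdr_bh")[1]
    rank_key = np.sign(effect) * (-np.log10(p))
    out = pd.DataFrame(
        {
            "gene_id": norm_expr.columns,
            "effect": effect,
            "p": p,
            "q": q,
            "rank_key": rank_key,
        }
    )
    return out.sort_values(["rank_key", "gene_id"], ascending=[False, True],
                           kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# pre-ranked GSEA

@dataclass
class GseaResult:
    """Per-set enrichment statistics from pre-ranked permutation GSEA."""

    table: pd.DataFrame  # set, size, es, nes, p, q, leading_edge
    n_permutations: int
    seed: int


def _es_from_positions(positions: np.ndarray, weights: np.ndarray, n_total: int):
    """Enrichment score of one gene set given hit positions in the ranking.

    ``positions`` are 0-based ranks of the member genes (any order);
    ``weights`` the matching |statistic|^p values. Returns (es, peak_index).
    The running sum rises by normalized weight at each hit and falls by
    1/(N - n_set) per miss; the ES is the maximum signed deviation. O(k).
    """
    order = np.argsort(positions, kind="stable")
    pos = positions[order]
    w = weights[order].astype(float)
    total = w.sum()
    w = w / total if total > 0 else np.full(len(w), 1.0 / len(w))
    k, miss_step = len(pos), 1.0 / (n_total - len(pos))
    cum_w = np.cumsum(w)
    idx = np.arange(k)
    # running-sum value just after each hit, and just before each hit
    after = cum_w - (pos + 1 - (idx + 1)) * miss_step
    before = np.concatenate([[0.0], cum_w[:-1]]) - (pos - idx) * miss_step
    max_dev = float(after.max())
    min_dev = float(min(before.min(), 0.0))
    # near-exact magnitude ties resolve to the positive deviation
    if max_dev >= -min_dev - 1e-9:
        return max_dev, int(pos[int(np.argmax(after))])
    return min_dev, int(pos[int(np.argmin(before))])


def _perm_es(n_total: int, set_size: int, weights_all: np.ndarray, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """ES of ``n_perm`` random gene sets of the given size (label permutation)."""
    out = np.empty(n_perm)
    # vectorized sampling of positions without replacement
    keys = rng.random((n_perm, n_total))
    pos_all = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    for i in range(n_perm):
        pos = pos_all[i]
        out[i], _ = _es_from_positions(pos, weights_all[pos], n_total)
    return out


def gsea_preranked(
    ranking: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 10_000,
    seed: int = 0,
    weight: float = 1.0,
) -> GseaResult:
    """Pre-ranked GSEA with gene-label permutations.

    Parameters
    ----------
    ranking
        Signed ranking statistic indexed by gene, sorted descending (it is
        re-sorted defensively; exact ties keep their given order). Duplicate
        genes are an error.
    gene_sets
        Name -> member genes; members absent from the ranking are dropped,
        and a set larger than the ranking (or empty after intersection) is
        an error.
    n_perm
        Gene-label permutations per set size (>= 100).
    weight
        Exponent on |statistic| for hit increments (1.0 = classic weighted).

    Notes
    -----
    NES = ES / mean(|permutation ES| of the matching sign); the nominal p is
    the same-sign permutation tail with a +1 correction; FDR q follows the
    standard NES-ratio estimator over the pooled permutation NES
    distribution, clipped to [0, 1] and made monotone.
    """
    if ranking.index.duplicated().any():
        raise InputError("ranking contains duplicate genes")
    if n_perm < 100:
        raise ConfigError("n_perm must be >= 100")
    ranking = ranking.sort_values(ascending=False, kind="mergesort")
    genes = ranking.index.to_numpy()
    stats = ranking.to_numpy(dtype=float)
    n_total = len(genes)
    weights_all = np.abs(stats) ** weight
    gene_pos = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(0,)))
    perm_cache: dict[int, np.ndarray] = {}

    records = []
    perm_nes_pool: list[np.ndarray] = []
    for name, members in gene_sets.items():
        members = list(dict.fromkeys(members))
        if len(members) > n_total:
            raise GeneSetError(f"gene set {name!r} is larger than the ranked list")
        pos = np.array([gene_pos[g] for g in members if g in gene_pos], dtype=int)
        if len(pos) == 0:
            raise GeneSetError(f"gene set {name!r} has no overlap with the ranking")
        if len(pos) == n_total:
            raise GeneSetError(f"gene set {name!r} covers the entire ranked list")
        es, peak = _es_from_positions(pos, weights_all[pos], n_total)
        if len(pos) not in perm_cache:
            perm_cache[len(pos)] = _perm_es(n_total, len(pos), weights_all, n_perm, rng)
        perm = perm_cache[len(pos)]

        pos_perm = perm[perm > 0]
        neg_perm = perm[perm < 0]
        mean_pos = pos_perm.mean() if len(pos_perm) else np.nan
        mean_neg = np.abs(neg_perm).mean() if len(neg_perm) else np.nan
        if es > 0:
            nes = es / mean_pos if np.isfinite(mean_pos) else np.nan
            p = (1 + int((pos_perm >= es).sum())) / (1 + len(pos_perm))
            perm_nes = perm / mean_pos if np.isfinite(mean_pos) else np.full_like(perm, np.nan)
        elif es < 0:
            nes = es / mean_neg if np.isfinite(mean_neg) else np.nan
            p = (1 + int((neg_perm <= es).sum())) / (1 + len(neg_perm))
            perm_nes = perm / mean_neg if np.isfinite(mean_neg) else np.full_like(perm, np.nan)
        else:
            nes, p = 0.0, 1.0
            perm_nes = np.full_like(perm, np.nan)

        order = np.argsort(pos)
        sorted_pos = pos[order]
        if es >= 0:
            lead = [genes[p_] for p_ in sorted_pos if p_ <= peak]
        else:
            lead = [genes[p_] for p_ in sorted_pos if p_ >= peak]
        records.append(
            {"set": name, "size": len(pos), "es": es, "nes": nes, "p": p,
             "leading_edge": ",".join(map(str, lead))}
        )
        perm_nes_pool.append(perm_nes[np.isfinite(perm_nes)])

    table = pd.DataFrame(records)
    table["q"] = _gsea_fdr(table["nes"].to_numpy(), np.concatenate(perm_nes_pool)
                           if perm_nes_pool else np.array([]))
    table = table[["set", "size", "es", "nes", "p", "q", "leading_edge"]]
    table = table.sort_values("q", kind="mergesort").reset_index(drop=True)
    return GseaResult(table=table, n_permutations=n_perm, seed=seed)


def _gsea_fdr(obs_nes: np.ndarray, perm_nes: np.ndarray) -> np.ndarray:
    """Standard NES-ratio FDR: tail fraction in the pooled permutation NES
    over the tail fraction in the observed NES, same sign, clipped to 1."""
    q = np.ones(len(obs_nes))
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes) or nes == 0:
            q[i] = 1.0
            continue
        if nes > 0:
            num_pool = perm_nes[perm_nes > 0]
            num = (num_pool >= nes).mean() if len(num_pool) else 1.0
            obs_pool = obs_nes[obs_nes > 0]
            den = (obs_pool >= nes).mean() if len(obs_pool) else 1.0
        else:
            num_pool = perm_nes[perm_nes < 0]
            num = (num_pool <= nes).mean() if len(num_pool) else 1.0
            obs_pool = obs_nes[obs_nes < 0]
            den = (obs_pool <= nes).mean() if len(obs_pool) else 1.0
        q[i] = min(num / den, 1.0) if den > 0 else 1.0
    # enforce monotonicity in |NES| within each sign
    for sign in (1, -1):
        idx = np.where(np.sign(obs_nes) == sign)[0]
        if len(idx) > 1:
            order = idx[np.argsort(-np.abs(obs_nes[idx]), kind="stable")]
            q[order] = np.minimum.accumulate(q[order])
    return q
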