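"""Interactor nomination from RIME spectral-count tables.

Two filtering procedures against the IgG control are provided as explicit
modes:

* ``venn`` — threshold filtering: a protein is a hit when its spectral
  count reaches ``min_count`` (default 5) in **every** bait replicate and
  it is absent from the analogous IgG-passing set (an IgG count >=
  ``min_count`` in any IgG replicate disqualifies it).
* ``fdr`` — statistical filtering: summed bait vs summed IgG counts are
  compared by a one-sided Poisson rate-ratio test (exact conditional
  binomial with arm-total offsets), BH-adjusted; a hit needs q <= ``q_max``
  (default 0.1), detection (count > 0) in at least ``min_detected`` of the
  bait samples (default 2 of 4) and a bait rate above the IgG rate.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from plastichrom.config import ConfigError


class RimeInputError(ValueError):
    pass


def _split_arms(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    bait = table[[c for c in table.columns if c.split(":")[0] == "bait"]]
    igg = table[[c for c in table.columns if c.split(":")[0] == "IgG"]]
    return bait, igg


def nominate_venn(table: pd.DataFrame, min_count: int = 5) -> pd.DataFrame:
    """Nominate interactors by per-replicate count thresholding vs IgG.

    ``table`` is protein x replicate counts with columns prefixed
    ``bait:`` / ``IgG:``. Returns the hit table with per-protein bait
    minima and replicate detection counts, indexed by protein.
    """
    bait, igg = _split_arms(table)
    if bait.shape[1] < 2:
        raise ConfigError("venn mode needs >= 2 bait replicates")
    if igg.shape[1] < 1:
        raise ConfigError("venn mode needs an IgG control arm")
    passes_bait = (bait >= min_count).all(axis=1)
    igg_passing = (igg >= min_count).any(axis=1)
    hits = table.index[passes_bait & ~igg_passing]
    out = pd.DataFrame(
        {
            "mode": "venn",
            "n_bait_replicates_detected": (bait.loc[hits] > 0).sum(axis=1),
            "min_bait_count": bait.loc[hits].min(axis=1),
            "max_igg_count": igg.loc[hits].max(axis=1),
        },
        index=hits,
    )
    return out.sort_index()


def nominate_fdr(
    table: pd.DataFrame,
    q_max: float = 0.1,
    min_detected: int = 2,
    n_samples: int | None = None,
) -> pd.DataFrame:
    """Nominate interactors by FDR-controlled enrichment over IgG.

    Per protein, the summed bait count is tested against the summed IgG
    count with a one-sided exact conditional binomial (success probability
    = bait-arm total / grand total), i.e. a Poisson rate-ratio test with
    arm-total offsets. p-values are BH-adjusted across the tested proteins.
    A hit requires q <= ``q_max``, detection (count > 0) in >=
    ``min_detected`` of ``n_samples`` bait samples (default: all bait
    columns) and bait rate > IgG rate.
    """
    if not 0 < q_max <= 1:
        raise ConfigError("q_max must be in (0, 1]")
    bait, igg = _split_arms(table)
    if igg.shape[1] < 1:
        raise ConfigError("fdr mode needs an IgG control arm")
    n_samples = bait.shape[1] if n_samples is None else n_samples
    if bait.shape[1] < n_samples:
        raise ConfigError(f"fdr mode expects >= {n_samples} bait samples, got {bait.shape[1]}")
    if int(table.to_numpy().sum()) == 0:
        raise RimeInputError("spectral-count table is all zero")

    bait_sum = bait.sum(axis=1)
    igg_sum = igg.sum(axis=1)
    bait_total = float(bait_sum.sum())
    igg_total = float(igg_sum.sum())
    p0 = bait_total / (bait_total + igg_total)

    total = bait_sum + igg_sum
    tested = total > 0
    # P(X >= bait_sum | X ~ Binom(total, p0)): one-sided, larger bait rate
    pvals = pd.Series(1.0, index=table.index)
    pvals[tested] = binom.sf(bait_sum[tested] - 1, total[tested], p0)
    qvals = pd.Series(1.0, index=table.index)
    qvals[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    n_detected = (bait > 0).sum(axis=1)
    bait_rate = bait_sum / bait_total if bait_total > 0 else bait_sum * 0.0
    igg_rate = igg_sum / igg_total if igg_total > 0 else igg_sum * 0.0
    is_hit = tested & (qvals <= q_max) & (n_detected >= min_detected) & (bait_rate > igg_rate)

    out = pd.DataFrame(
        {
            "mode": "fdr",
            "n_bait_replicates_detected": n_detected[is_hit],
            "bait_sum": bait_sum[is_hit],
            "igg_sum": igg_sum[is_hit],
            "rate_ratio": (bait_rate[is_hit] / igg_rate[is_hit].where(igg_rate[is_hit] > 0)),
            "p": pvals[is_hit],
            "q": qvals[is_hit],
        },
        index=table.index[is_hit],
    )
    return out.sort_values(["q", "p"]).rename_axis("protein_id")


def compare_conditions(hits_cond1: pd.DataFrame, hits_cond2: pd.DataFrame) -> dict[str, list[str]]:
    """Split two hit lists into condition-specific and shared interactors.

    Both lists must come from the same nomination mode. Returns a dict with
    keys ``cond1_only``, ``cond2_only`` and ``shared`` (sorted lists whose
    union is the union of the two hit sets).
    """
    modes = set()
    for hits in (hits_cond1, hits_cond2):
        if len(hits) and "mode" in hits.columns:
            modes.update(hits["mode"].unique())
    if len(modes) > 1:
        raise RimeInputError(f"hit lists mix nomination modes: {sorted(modes)}")
    s1, s2 = set(hits_cond1.index), set(hits_cond2.index)
    return {
        "cond1_only": sorted(s1 - s2),
        "cond2_only": sorted(s2 - s1),
        "shared": sorted(s1 & s2),
    }
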