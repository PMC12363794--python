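"""Planted-truth recovery studies for self-validation.

Each study simulates data with :mod:`plastichrom.synthio` under a known
ground truth, runs the corresponding analysis stage, and measures how well
the planted signal is recovered (or, under a null, how well error rates are
controlled). They are the package's built-in calibration experiments; the
test suite and the reproduction script both drive them.

All studies are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from plastichrom import chromstate, programs, rime, synthio
from plastichrom.config import SimConfig
from plastichrom.states import BIVALENT
from plastichrom.synergy import score_plate


def _spawn(seed: int, tag: int, rep: int = 0) -> int:
    """Derive a reproducible sub-seed < 2**31 for replicate ``rep``."""
    return int(np.random.SeedSequence(entropy=int(seed), spawn_key=(tag, rep))
               .generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def round_trip_state_recovery(seed: int, n_promoters: int = 10_000,
                              gen_window: int = 1_000, call_window: int = 2_000) -> float:
    """Fraction of planted states recovered by peaks -> presence -> states."""
    cfg = SimConfig(seed=seed, n_promoters=n_promoters)
    promoters, truth = synthio.make_promoters(cfg)
    peaks = synthio.make_peaks(promoters, truth.promoter_states, window=gen_window)
    presence = chromstate.assign_mark_presence(peaks, promoters, window=call_window)
    states = chromstate.call_states(presence)
    wide = states.pivot(index="gene_id", columns="condition", values="state")
    planted = truth.promoter_states.set_index("gene_id")
    ok = (wide["cond1"] == planted["state_cond1"]) & (wide["cond2"] == planted["state_cond2"])
    return float(ok.mean())


def transition_kernel_recovery(seed: int, n_promoters: int = 10_000) -> dict:
    """Empirical row-normalized transition matrix vs the planted kernel.

    Returns the maximum absolute z-score over the 16 cells, where the
    standard error of each cell is the binomial SE at the kernel probability
    given the realized row count.
    """
    cfg = SimConfig(seed=seed, n_promoters=n_promoters)
    _, truth = synthio.make_promoters(cfg)
    st = truth.promoter_states
    table = chromstate.transition_matrix(
        st[["gene_id", "state_cond1"]].rename(columns={"state_cond1": "state"}),
        st[["gene_id", "state_cond2"]].rename(columns={"state_cond2": "state"}),
    )
    emp = table.row_normalized().to_numpy()
    kernel = cfg.kernel
    rows = table.counts.sum(axis=1).to_numpy()
    se = np.sqrt(kernel * (1 - kernel) / rows[:, None])
    z = np.abs(emp - kernel) / se
    return {"max_abs_z": float(z.max()), "n": int(table.total)}


def bivalent_de_study(seed: int, n_promoters: int = 10_000,
                      n_cells_per_group: int = 150, effect: float = 1.0,
                      dispersion: float = 0.3) -> pd.DataFrame:
    """Plant an expression up-shift exclusively in Bivalent-state genes.

    Genes bivalent in condition 2 are up-shifted by ``effect`` log2 units in
    a simulated treated group; differential expression is ranked and fed to
    the transition-class enrichment. Returns the enrichment table (the
    Bivalent condition-2 class should rank first).
    """
    cfg = SimConfig(seed=seed, n_promoters=n_promoters)
    _, truth = synthio.make_promoters(cfg)
    st = truth.promoter_states
    gene_ids = st["gene_id"].tolist()
    bivalent = (st["state_cond2"] == BIVALENT).to_numpy()

    rng = np.random.default_rng(_spawn(seed, 10))
    base_mu = rng.lognormal(mean=np.log(0.5), sigma=1.0, size=len(gene_ids))
    r = 1.0 / dispersion

    def draw(mu, n):
        return rng.negative_binomial(r, r / (r + np.tile(mu, (n, 1))))

    mu_treated = np.where(bivalent, base_mu * 2.0 ** effect, base_mu)
    treated = draw(mu_treated, n_cells_per_group)
    control = draw(base_mu, n_cells_per_group)
    counts = pd.DataFrame(
        np.vstack([treated, control]),
        index=[f"t{i}" for i in range(n_cells_per_group)]
        + [f"v{i}" for i in range(n_cells_per_group)],
        columns=gene_ids,
    )
    norm = programs.normalize_log(counts)
    de = programs.de_rank(norm,
                          [f"t{i}" for i in range(n_cells_per_group)],
                          [f"v{i}" for i in range(n_cells_per_group)])
    transitions = chromstate.transition_matrix(
        st[["gene_id", "state_cond1"]].rename(columns={"state_cond1": "state"}),
        st[["gene_id", "state_cond2"]].rename(columns={"state_cond2": "state"}),
    )
    return chromstate.integrate_with_de(transitions, de, direction="up", q_max=0.05)


def gsea_null_calibration(seed: int, n_sims: int = 200, n_sets: int = 50,
                          n_genes: int = 500, set_size: int = 20,
                          n_perm: int = 200, q_threshold: float = 0.25) -> float:
    """Mean fraction of random sets called at q < threshold on null rankings."""
    fractions = []
    for rep in range(n_sims):
        rng = np.random.default_rng(_spawn(seed, 20, rep))
        stats = np.sort(rng.normal(size=n_genes))[::-1]
        ranking = pd.Series(stats, index=[f"g{i:04d}" for i in range(n_genes)])
        sets = {
            f"s{j}": list(rng.choice(ranking.index, size=set_size, replace=False))
            for j in range(n_sets)
        }
        result = programs.gsea_preranked(ranking, sets, n_perm=n_perm,
                                         seed=_spawn(seed, 21, rep))
        fractions.append(float((result.table["q"] < q_threshold).mean()))
    return float(np.mean(fractions))


def bliss_recovery_study(seed: int, n_plates: int = 200, delta: float = 10.0,
                         noise_cv: float = 0.05) -> float:
    """Mean recovered synergy summary over noisy plates with planted delta."""
    summaries = []
    for rep in range(n_plates):
        cfg = SimConfig(seed=_spawn(seed, 30, rep), bliss_delta=delta, noise_cv=noise_cv)
        doses_a, doses_b, raw, _ = synthio.make_dose_response(cfg)
        summaries.append(score_plate(doses_a, doses_b, raw).summary)
    return float(np.mean(summaries))


def bliss_null_exact(seed: int) -> float:
    """Summary score of a noise-free Bliss-consistent plate (must be 0)."""
    cfg = SimConfig(seed=seed, bliss_delta=0.0, noise_cv=0.0)
    doses_a, doses_b, raw, _ = synthio.make_dose_response(cfg, n_replicates=1)
    return float(score_plate(doses_a, doses_b, raw).summary)


def rime_null_fdr(seed: int, n_sims: int = 200, n_proteins: int = 300) -> float:
    """Mean false-discovery proportion of fdr-mode under a flat null.

    Every protein sits at the background rate in both arms; any hit is a
    false discovery. FDP is 0 when nothing is nominated.
    """
    fdps = []
    for rep in range(n_sims):
        cfg = SimConfig(seed=_spawn(seed, 40, rep), bait_rate_ratio=1.0, n_bait_enriched=0)
        table, _ = synthio.make_spectral_counts(cfg, n_proteins=n_proteins)
        hits = rime.nominate_fdr(table, q_max=0.1)
        fdps.append(0.0 if len(hits) == 0 else 1.0)
    return float(np.mean(fdps))


def rime_sensitivity(seed: int, n_sims: int = 20, n_proteins: int = 400) -> float:
    """Mean fraction of planted 20x-enriched proteins recovered by fdr-mode."""
    hits_frac = []
    for rep in range(n_sims):
        cfg = SimConfig(seed=_spawn(seed, 41, rep), bait_rate_ratio=20.0,
                        n_bait_enriched=30, background_rate=5.0)
        table, truth = synthio.make_spectral_counts(cfg, n_proteins=n_proteins)
        hits = rime.nominate_fdr(table, q_max=0.1)
        planted = set(truth.enriched_proteins)
        hits_frac.append(len(set(hits.index) & planted) / len(planted))
    return float(np.mean(hits_frac))


def signature_recovery_study(seed: int, n_runs: int = 20, n_cells: int = 2_000,
                             n_genes: int = 600, n_clusters: int = 3,
                             effect: float = 1.0) -> dict:
    """Score AUROC and cluster-level subtype accuracy over seeded runs.

    Each run simulates counts with one planted marker program per cluster,
    scores all programs, and checks (i) the AUROC of the cluster-0 program
    score for separating cluster-0 cells and (ii) whether every cluster is
    assigned its own marker program at the cluster level.
    """
    aurocs, accuracies = [], []
    for rep in range(n_runs):
        cfg = SimConfig(seed=_spawn(seed, 50, rep), n_cells=n_cells, n_genes=n_genes,
                        n_clusters=n_clusters, program_size=50, program_effect=effect)
        counts, meta, truth = synthio.make_sc_counts(cfg)
        norm = programs.normalize_log(counts)
        scores = programs.score_signatures(norm, truth.program_genes)
        clusters = meta.set_index("cell_id")["cluster"].reindex(norm.index)

        score0 = scores["program_cluster0"]
        in_cl = (clusters == 0).to_numpy()
        from scipy.stats import mannwhitneyu

        u = mannwhitneyu(score0[in_cl], score0[~in_cl]).statistic
        aurocs.append(u / (in_cl.sum() * (~in_cl).sum()))

        assigned = programs.assign_subtype(scores, level="cluster", clusters=clusters)
        per_cluster = assigned.drop_duplicates("cluster").set_index("cluster")["subtype"]
        accuracies.append(
            float(all(per_cluster[cl] == f"program_cluster{cl}" for cl in range(n_clusters)))
        )
    return {
        "min_auroc": float(np.min(aurocs)),
        "mean_auroc": float(np.mean(aurocs)),
        "accuracy": float(np.mean(accuracies)),
        "n_runs": n_runs,
    }
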