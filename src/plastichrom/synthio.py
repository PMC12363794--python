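"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator draws from its own child random stream of the global seed
(see :mod:`plastichrom.config`), so outputs are byte-identical under a fixed
seed and independent across generators.

The generators emulate the statistical structure of the real assays:

* promoters with a planted four-state chromatin composition evolved between
  two conditions by a row-stochastic transition kernel, rendered as
  H3K4me3 / H3K27me3 BED peak files;
* negative-binomial single-cell counts with cluster-specific planted gene
  programs and a cluster-ordinal pseudotime;
* two-drug viability plates built from 4-parameter-logistic monotherapy
  curves under Bliss independence plus a planted interaction term and
  multiplicative lognormal noise;
* Poisson spectral-count tables with a planted set of bait-enriched
  proteins over an IgG-level background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from plastichrom import io as pio
from plastichrom.config import ConfigError, SimConfig, child_rng
from plastichrom.states import STATES, marks_for_state

CONDITIONS = ("cond1", "cond2")
MARKS = ("H3K4me3", "H3K27me3")

#: Distance between consecutive simulated TSSs on a chromosome. Large enough
#: that a promoter window can never overlap a neighbouring promoter's peaks.
TSS_SPACING = 50_000
_N_CHROMS = 19  # mouse autosomes


@dataclass
class GroundTruth:
    """Planted truth recorded alongside the generated inputs."""

    promoter_states: pd.DataFrame | None = None  # gene_id, state_cond1, state_cond2
    program_genes: dict[str, list[str]] = field(default_factory=dict)
    program_clusters: dict[str, int] = field(default_factory=dict)
    true_synergy: dict[str, float] = field(default_factory=dict)
    enriched_proteins: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "promoter_states": (
                None
                if self.promoter_states is None
                else self.promoter_states.to_dict(orient="list")
            ),
            "program_genes": self.program_genes,
            "program_clusters": self.program_clusters,
            "true_synergy": self.true_synergy,
            "enriched_proteins": self.enriched_proteins,
        }


# ---------------------------------------------------------------------------
# promoters and peaks

def make_promoters(cfg: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a promoter annotation with planted per-condition states.

    Condition-1 states are drawn from ``cfg.state_mix``; condition-2 states
    evolve each promoter through ``cfg.transition_kernel``. TSSs are laid out
    on a deterministic grid (one TSS per ``TSS_SPACING`` bp) so windows of
    neighbouring promoters never collide.
    """
    cfg.validate()
    rng = child_rng(cfg.seed, "promoters")
    n = cfg.n_promoters
    gene_ids = [f"gene{i:05d}" for i in range(n)]
    chrom_idx = np.arange(n) % _N_CHROMS
    pos_on_chrom = np.arange(n) // _N_CHROMS
    promoters = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": [f"chr{c + 1}" for c in chrom_idx],
            "tss": TSS_SPACING * (pos_on_chrom + 1),
            "strand": rng.choice(["+", "-"], size=n),
        }
    )
    s1 = rng.choice(len(STATES), size=n, p=cfg.mix)
    # evolve each promoter through the kernel row of its condition-1 state
    u = rng.random(n)
    cum = np.cumsum(cfg.kernel, axis=1)
    s2 = (u[:, None] > cum[s1]).sum(axis=1)
    truth = GroundTruth(
        promoter_states=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "state_cond1": [STATES[i] for i in s1],
                "state_cond2": [STATES[i] for i in s2],
            }
        )
    )
    return promoters, truth


def make_peaks(
    promoters: pd.DataFrame,
    promoter_states: pd.DataFrame,
    window: int = 1_000,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Render planted states as per-mark, per-condition BED peak sets.

    A peak covering TSS +/- ``window`` (0-based half-open, clipped at 0) is
    emitted for H3K4me3 iff the state is Active or Bivalent, and for
    H3K27me3 iff Repressed or Bivalent. Returns a dict keyed by
    ``(mark, condition)`` with sorted BED frames.
    """
    if window <= 0:
        raise ConfigError("peak window must be > 0")
    merged = promoters.merge(promoter_states, on="gene_id", validate="one_to_one")
    peaks: dict[tuple[str, str], pd.DataFrame] = {}
    for cond_i, cond in enumerate(CONDITIONS):
        states = merged[f"state_cond{cond_i + 1}"]
        has = np.array([marks_for_state(s) for s in states])  # (n, 2) = (k4, k27)
        for mark_i, mark in enumerate(MARKS):
            sel = merged[has[:, mark_i]]
            bed = pd.DataFrame(
                {
                    "chrom": sel["chrom"],
                    "start": np.maximum(sel["tss"] - window, 0),
                    "end": sel["tss"] + window,
                    "name": [f"{mark}_{cond}_{g}" for g in sel["gene_id"]],
                }
            )
            peaks[(mark, cond)] = bed.sort_values(
                ["chrom", "start", "end"], kind="mergesort"
            ).reset_index(drop=True)
    return peaks


# ---------------------------------------------------------------------------
# single-cell counts

def make_sc_counts(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a cells x genes negative-binomial count matrix.

    Cells are split evenly across ``n_clusters`` clusters; the first half of
    the clusters is labelled ``vehicle``, the rest ``EZH2i``. One gene
    program of ``program_size`` genes is planted per designated cluster and
    up-shifted there by ``program_effect`` log2 units. Pseudotime is the
    cluster ordinal plus uniform jitter, rescaled to [0, 1].

    Returns ``(counts, cellmeta, truth)`` with counts as a cells x genes
    integer DataFrame.
    """
    cfg.validate()
    rng = child_rng(cfg.seed, "sc_counts")
    n_cells, n_genes, k = cfg.n_cells, cfg.n_genes, cfg.n_clusters
    designated = (
        list(range(k)) if cfg.program_clusters is None else [int(c) for c in cfg.program_clusters]
    )
    if cfg.program_effect != 0 and not designated:
        raise ConfigError("program_effect != 0 requires at least one designated cluster")
    if len(designated) * cfg.program_size > n_genes:
        raise ConfigError("programs do not fit: n_clusters * program_size > n_genes")

    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    clusters = rng.integers(0, k, size=n_cells)
    treatment = np.where(clusters < (k + 1) // 2, "vehicle", "EZH2i")
    pseudotime = (clusters + rng.random(n_cells)) / k

    # baseline per-gene means: lognormal around 0.5 counts/cell
    base_mu = rng.lognormal(mean=np.log(0.5), sigma=1.0, size=n_genes)
    mu = np.tile(base_mu, (n_cells, 1))
    truth = GroundTruth()
    for j, cl in enumerate(designated):
        genes = slice(j * cfg.program_size, (j + 1) * cfg.program_size)
        mu[np.ix_(clusters == cl, range(*genes.indices(n_genes)))] *= 2.0 ** cfg.program_effect
        name = f"program_cluster{cl}"
        truth.program_genes[name] = gene_ids[genes]
        truth.program_clusters[name] = cl

    r = 1.0 / cfg.nb_dispersion  # variance = mu + mu^2 * dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(
        counts, index=pd.Index(cell_ids, name="cell_id"), columns=pd.Index(gene_ids, name="gene_id")
    )
    cellmeta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "cluster": clusters,
            "treatment": treatment,
            "pseudotime": pseudotime,
        }
    )
    return counts_df, cellmeta, truth


# ---------------------------------------------------------------------------
# dose-response plates

@dataclass
class HillParams:
    """4-parameter-logistic monotherapy inhibition curve.

    ``inhibition(d) = emax * d**slope / (d**slope + ec50**slope)`` with
    ``inhibition(0) = 0``; dose units are arbitrary but consistent.
    """

    ec50: float = 1.0
    slope: float = 1.0
    emax: float = 0.6

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.slope <= 0 or not 0 < self.emax <= 1:
            raise ConfigError("Hill parameters must satisfy ec50>0, slope>0, 0<emax<=1")

    def inhibition(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            frac = dose ** self.slope / (dose ** self.slope + self.ec50 ** self.slope)
        return np.where(dose > 0, self.emax * frac, 0.0)


DEFAULT_DOSES = (0.0, 0.25, 0.5, 1.0, 2.0)


def make_dose_response(
    cfg: SimConfig,
    doses_a=DEFAULT_DOSES,
    doses_b=DEFAULT_DOSES,
    hill_a: HillParams | None = None,
    hill_b: HillParams | None = None,
    n_replicates: int = 3,
    n_control_wells: int = 6,
    plate_scale: float = 1e5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Simulate raw luminescence plates for a two-drug dose grid.

    Monotherapy inhibition follows each drug's Hill curve; combination
    inhibition is Bliss-expected plus ``cfg.bliss_delta`` percentage points,
    clamped to [0, 1]. Luminescence is ``(1 - inhibition) * plate_scale``
    times mean-one lognormal noise with CV ``cfg.noise_cv``. Each replicate
    plate carries ``n_control_wells`` untreated wells whose average is
    reported in the grid's (0, 0) cell, as on a real viability plate.

    Returns ``(doses_a, doses_b, raw, truth)`` with raw shaped
    (n_replicates, len(doses_a), len(doses_b)).
    """
    cfg.validate()
    rng = child_rng(cfg.seed, "dose_response")
    doses_a = np.asarray(sorted(doses_a), dtype=float)
    doses_b = np.asarray(sorted(doses_b), dtype=float)
    for name, d in (("doses_a", doses_a), ("doses_b", doses_b)):
        if len(d) < 2 or d[0] != 0.0:
            raise ConfigError(f"{name} must contain dose 0 and at least one positive dose")
        if np.any(d < 0):
            raise ConfigError(f"{name} must be non-negative")
    hill_a = hill_a or HillParams()
    hill_b = hill_b or HillParams()

    e_a = hill_a.inhibition(doses_a)[:, None]
    e_b = hill_b.inhibition(doses_b)[None, :]
    bliss = e_a + e_b - e_a * e_b
    combo = (doses_a[:, None] > 0) & (doses_b[None, :] > 0)
    inhibition = np.where(combo, np.clip(bliss + cfg.bliss_delta / 100.0, 0.0, 1.0), bliss)

    if n_control_wells < 1:
        raise ConfigError("n_control_wells must be >= 1")
    if cfg.noise_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.noise_cv ** 2))
        noise = rng.lognormal(
            mean=-sigma ** 2 / 2, sigma=sigma, size=(n_replicates,) + inhibition.shape
        )
        ctrl = rng.lognormal(
            mean=-sigma ** 2 / 2, sigma=sigma, size=(n_replicates, n_control_wells)
        ).mean(axis=1)
    else:
        noise = np.ones((n_replicates,) + inhibition.shape)
        ctrl = np.ones(n_replicates)
    raw = (1.0 - inhibition)[None, :, :] * plate_scale * noise
    raw[:, 0, 0] = plate_scale * ctrl  # (0,0) = average of the control wells
    truth = GroundTruth(true_synergy={"plate": float(cfg.bliss_delta)})
    return doses_a, doses_b, raw, truth


# ---------------------------------------------------------------------------
# spectral counts

def make_spectral_counts(
    cfg: SimConfig,
    n_proteins: int = 400,
    n_bait_reps: int = 4,
    n_igg_reps: int = 2,
    sample_label: str = "DKO",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a protein x replicate Poisson spectral-count table.

    The first ``cfg.n_bait_enriched`` proteins are truly bait-enriched: their
    bait-arm Poisson rate is ``background_rate * bait_rate_ratio``; all other
    rates (including the whole IgG arm) sit at ``background_rate``.
    """
    cfg.validate()
    if n_proteins <= 0 or n_bait_reps <= 0 or n_igg_reps <= 0:
        raise ConfigError("n_proteins and replicate counts must be positive")
    if cfg.n_bait_enriched > n_proteins:
        raise ConfigError("n_bait_enriched exceeds n_proteins")
    rng = child_rng(cfg.seed, "spectral_counts")
    ids = [f"protein{i:04d}" for i in range(n_proteins)]
    bait_rate = np.full(n_proteins, cfg.background_rate)
    bait_rate[: cfg.n_bait_enriched] *= cfg.bait_rate_ratio
    cols = {}
    for r in range(n_bait_reps):
        cols[f"bait:{sample_label}:rep{r + 1}"] = rng.poisson(bait_rate)
    for r in range(n_igg_reps):
        cols[f"IgG:{sample_label}:rep{r + 1}"] = rng.poisson(
            np.full(n_proteins, cfg.background_rate)
        )
    table = pd.DataFrame(cols, index=pd.Index(ids, name="protein_id"))
    truth = GroundTruth(enriched_proteins=ids[: cfg.n_bait_enriched])
    return table, truth


# ---------------------------------------------------------------------------
# whole-simulation writer

def simulate_to_dir(cfg: SimConfig, outdir: str | Path, peak_window: int = 1_000) -> dict:
    """Run every generator and write the full input bundle plus truth.json.

    Writes promoters.tsv, peaks_{mark}_{cond}.bed, counts.mtx (+ genes.tsv,
    cells.tsv, cellmeta.tsv), plate_drugA_drugB.csv, spectral_counts.tsv and
    truth.json. Returns the manifest of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    promoters, chrom_truth = make_promoters(cfg)
    promoters.to_csv(outdir / "promoters.tsv", sep="\t", index=False)
    manifest["promoters"] = str(outdir / "promoters.tsv")
    for (mark, cond), bed in make_peaks(promoters, chrom_truth.promoter_states, peak_window).items():
        path = outdir / f"peaks_{mark}_{cond}.bed"
        pio.write_bed(bed, path)
        manifest[f"peaks_{mark}_{cond}"] = str(path)

    counts, cellmeta, sc_truth = make_sc_counts(cfg)
    pio.write_counts_mtx(counts.to_numpy(), counts.index, counts.columns, outdir)
    cellmeta.to_csv(outdir / "cellmeta.tsv", sep="\t", index=False)
    manifest["counts"] = str(outdir / "counts.mtx")
    manifest["cellmeta"] = str(outdir / "cellmeta.tsv")
    pio.write_gmt(
        {name: genes for name, genes in sc_truth.program_genes.items()},
        outdir / "programs.gmt",
    )
    manifest["gene_sets"] = str(outdir / "programs.gmt")

    doses_a, doses_b, raw, syn_truth = make_dose_response(cfg)
    plate_path = outdir / "plate_drugA_drugB.csv"
    pio.write_plate_csv(doses_a, doses_b, raw, plate_path)
    manifest["plate_drugA_drugB"] = str(plate_path)

    spectra, rime_truth = make_spectral_counts(cfg)
    pio.write_spectral_counts(spectra, outdir / "spectral_counts.tsv")
    manifest["spectral_counts"] = str(outdir / "spectral_counts.tsv")

    truth = GroundTruth(
        promoter_states=chrom_truth.promoter_states,
        program_genes=sc_truth.program_genes,
        program_clusters=sc_truth.program_clusters,
        true_synergy=syn_truth.true_synergy,
        enriched_proteins=rime_truth.enriched_proteins,
    )
    pio.write_json({"config": cfg.to_dict(), "truth": truth.to_dict()}, outdir / "truth.json")
    manifest["truth"] = str(outdir / "truth.json")
    return manifest
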