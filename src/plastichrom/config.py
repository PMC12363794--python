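"""Simulation configuration and deterministic seed fan-out.

A single :class:`SimConfig` seed is fanned out to one independent random
stream per generator through :func:`child_rng`, using
``numpy.random.SeedSequence(entropy=seed, spawn_key=(stream_index,))``.
Stream indices are fixed in :data:`STREAMS`, so adding a new generator
(with a new index) never perturbs the draws of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from plastichrom.states import STATES


class ConfigError(ValueError):
    """Invalid configuration value."""


#: Fixed stream index per generator; append-only.
STREAMS: dict[str, int] = {
    "promoters": 0,
    "peaks": 1,
    "sc_counts": 2,
    "dose_response": 3,
    "spectral_counts": 4,
    "gsea": 5,
    "pipeline": 6,
}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Return the dedicated random generator for one named stream."""
    if stream not in STREAMS:
        raise ConfigError(f"unknown random stream {stream!r}; known: {sorted(STREAMS)}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(STREAMS[stream],))
    return np.random.default_rng(ss)


def _default_kernel() -> list[list[float]]:
    # Condition-1 -> condition-2 state kernel emulating Polycomb redistribution:
    # each state mostly persists, with net gain of bivalency in condition 2.
    return [
        [0.70, 0.05, 0.20, 0.05],  # Active ->
        [0.05, 0.70, 0.20, 0.05],  # Repressed ->
        [0.10, 0.10, 0.70, 0.10],  # Bivalent ->
        [0.05, 0.05, 0.20, 0.70],  # Unmarked ->
    ]


@dataclass
class SimConfig:
    """Ground-truth parameters for every synthetic input.

    Parameters
    ----------
    seed
        Global seed; fans out deterministically per generator.
    n_promoters
        Number of simulated promoters (TSS records).
    state_mix
        Probability over (Active, Repressed, Bivalent, Unmarked) for the
        condition-1 state of each promoter. Must sum to 1.
    transition_kernel
        Row-stochastic 4x4 matrix; row ``i`` gives the condition-2 state
        distribution of a promoter in condition-1 state ``i``.
    n_cells, n_genes, n_clusters
        Shape of the simulated single-cell count matrix.
    program_effect
        log2 fold shift applied to each planted program's genes in its
        designated cluster.
    program_size
        Genes per planted program (one program per designated cluster).
    program_clusters
        Clusters carrying a planted program; ``None`` plants one program in
        every cluster.
    nb_dispersion
        Negative-binomial dispersion: ``var = mu + mu**2 * dispersion``.
    bliss_delta
        Planted drug-interaction term, in percentage points of inhibition,
        added on top of Bliss-expected inhibition at every combination well.
    noise_cv
        Coefficient of variation of multiplicative (lognormal) plate noise.
    n_bait_enriched
        Number of truly bait-enriched proteins in the spectral-count table.
    bait_rate_ratio
        Poisson rate multiplier of enriched proteins in the bait arm.
    background_rate
        Per-replicate Poisson background spectral-count rate.
    """

    seed: int = 0
    # chromatin
    n_promoters: int = 10_000
    state_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    transition_kernel: list[list[float]] = field(default_factory=_default_kernel)
    # single-cell
    n_cells: int = 2_000
    n_genes: int = 2_000
    n_clusters: int = 5
    program_effect: float = 1.0
    program_size: int = 50
    program_clusters: list[int] | None = None
    nb_dispersion: float = 0.3
    # drug plates
    bliss_delta: float = 10.0
    noise_cv: float = 0.05
    # spectral counts
    n_bait_enriched: int = 30
    bait_rate_ratio: float = 20.0
    background_rate: float = 5.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        mix = np.asarray(self.state_mix, dtype=float)
        if mix.shape != (len(STATES),):
            raise ConfigError(f"state_mix must have {len(STATES)} entries")
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigError("state_mix must be non-negative and sum to 1 (tol 1e-9)")
        kernel = np.asarray(self.transition_kernel, dtype=float)
        if kernel.shape != (len(STATES), len(STATES)):
            raise ConfigError("transition_kernel must be 4x4")
        if np.any(kernel < 0) or np.any(np.abs(kernel.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigError("transition_kernel rows must be non-negative and sum to 1")
        for name in ("n_promoters", "n_cells", "n_genes", "n_clusters", "program_size"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be a positive count")
        if self.n_clusters < 2:
            raise ConfigError("n_clusters must be >= 2")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.bait_rate_ratio < 1:
            raise ConfigError("bait_rate_ratio must be >= 1")
        if self.n_bait_enriched < 0:
            raise ConfigError("n_bait_enriched must be >= 0")
        if self.background_rate < 0:
            raise ConfigError("background_rate must be >= 0")
        if self.program_clusters is not None:
            bad = [c for c in self.program_clusters if not 0 <= int(c) < self.n_clusters]
            if bad:
                raise ConfigError(f"program_clusters out of range: {bad}")
            if self.program_effect != 0 and len(self.program_clusters) == 0:
                raise ConfigError("program_effect != 0 requires at least one designated cluster")

    @property
    def kernel(self) -> np.ndarray:
        return np.asarray(self.transition_kernel, dtype=float)

    @property
    def mix(self) -> np.ndarray:
        return np.asarray(self.state_mix, dtype=float)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_promoters": self.n_promoters,
            "state_mix": list(self.state_mix),
            "transition_kernel": [list(r) for r in self.transition_kernel],
            "n_cells": self.n_cells,
            "n_genes": self.n_genes,
            "n_clusters": self.n_clusters,
            "program_effect": self.program_effect,
            "program_size": self.program_size,
            "program_clusters": (
                None if self.program_clusters is None else list(self.program_clusters)
            ),
            "nb_dispersion": self.nb_dispersion,
            "bliss_delta": self.bliss_delta,
            "noise_cv": self.noise_cv,
            "n_bait_enriched": self.n_bait_enriched,
            "bait_rate_ratio": self.bait_rate_ratio,
            "background_rate": self.background_rate,
        }
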