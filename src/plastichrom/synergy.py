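"""Bliss-independence synergy landscapes for two-drug dose grids.

Raw luminescence plates are normalized to the mean of their (0, 0) control
wells to give relative viability; inhibition = 1 - viability, clamped to
[0, 1]. For each combination well the Bliss delta is

    delta = 100 * (observed inhibition - (E_a + E_b - E_a * E_b))

with monotherapy effects E_a, E_b read off the same plate's dose margins.
The landscape summary score is the arithmetic mean of delta over the
combination wells (doses a > 0 and b > 0): positive = synergy, negative =
antagonism, in percentage points of inhibition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class PlateError(ValueError):
    """Unusable plate input."""


@dataclass
class PlateGrid:
    """Raw luminescence over a dose grid; (0, 0) wells are the controls."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    raw: np.ndarray  # (n_replicates, n_doses_a, n_doses_b)

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim == 2:
            self.raw = self.raw[None, :, :]
        if self.raw.shape[1:] != (len(self.doses_a), len(self.doses_b)):
            raise PlateError("raw grid shape does not match dose vectors")
        for name, d in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            if np.any(d < 0) or np.any(np.diff(d) <= 0):
                raise PlateError(f"{name} must be non-negative and strictly increasing")
        if self.doses_a[0] != 0 or self.doses_b[0] != 0:
            raise PlateError("plate must include the (0, 0) control dose")


@dataclass
class ViabilityGrid:
    """Control-normalized relative viability, per replicate and averaged."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    viability_reps: np.ndarray  # (n_replicates, n_a, n_b)
    n_clamped: int

    @property
    def viability(self) -> np.ndarray:
        return self.viability_reps.mean(axis=0)

    @property
    def inhibition_reps(self) -> np.ndarray:
        return np.clip(1.0 - self.viability_reps, 0.0, 1.0)

    @property
    def inhibition(self) -> np.ndarray:
        return self.inhibition_reps.mean(axis=0)


@dataclass
class SynergySummary:
    """Per-well Bliss deltas (percentage points) and their landscape mean."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    delta: np.ndarray  # (n_a, n_b); NaN on the margins
    summary: float
    replicate_summaries: np.ndarray
    replicate_sd: float
    n_wells: int

    def surface_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.delta, index=pd.Index(self.doses_a, name="dose_a"),
                          columns=pd.Index(self.doses_b, name="dose_b"))
        return df.stack().rename("delta").reset_index()


def normalize_plate(plate: PlateGrid) -> ViabilityGrid:
    """Normalize each replicate plate to the mean of its control wells.

    viability(well) = raw(well) / mean(raw at dose (0, 0)); replicates are
    kept separate (downstream deltas are computed per replicate, then
    averaged). Inhibition values outside [0, 1] are clamped, with the clamp
    count logged.
    """
    ctrl = plate.raw[:, 0, 0]
    if np.any(ctrl <= 0):
        raise PlateError("control-well mean must be positive in every replicate")
    viab = plate.raw / ctrl[:, None, None]
    n_clamped = int((viab > 1.0).sum() + (viab < 0.0).sum())
    if n_clamped:
        logger.info("clamped %d well inhibition value(s) into [0, 1]", n_clamped)
    return ViabilityGrid(plate.doses_a, plate.doses_b, viab, n_clamped)


def bliss_expected(e_a, e_b):
    """Bliss-independence expected inhibition: ``e_a + e_b - e_a * e_b``.

    Both inputs must be inhibition fractions in [0, 1]; broadcasting applies.
    """
    e_a = np.asarray(e_a, dtype=float)
    e_b = np.asarray(e_b, dtype=float)
    if np.any((e_a < 0) | (e_a > 1)) or np.any((e_b < 0) | (e_b > 1)):
        raise ValueError("inhibition fractions must lie in [0, 1]")
    out = e_a + e_b - e_a * e_b
    return float(out) if out.ndim == 0 else out


def synergy_surface(viab: ViabilityGrid) -> SynergySummary:
    """Compute the Bliss delta landscape and its summary score.

    Monotherapy effects come from the plate's own margins (dose_b = 0 row
    for drug A, dose_a = 0 column for drug B). Deltas are computed per
    replicate and then averaged; the summary is the mean delta over
    combination wells only, reported with per-replicate summaries and SD.
    """
    if len(viab.doses_a) < 2 or len(viab.doses_b) < 2:
        raise PlateError("plate needs monotherapy margins for both drugs")
    inh = viab.inhibition_reps  # (r, a, b), already clamped
    e_a = inh[:, :, 0]  # drug A alone
    e_b = inh[:, 0, :]  # drug B alone
    expected = e_a[:, :, None] + e_b[:, None, :] - e_a[:, :, None] * e_b[:, None, :]
    delta_reps = 100.0 * (inh - expected)
    combo = (viab.doses_a[:, None] > 0) & (viab.doses_b[None, :] > 0)
    if not combo.any():
        raise PlateError("plate has no combination wells")
    rep_summaries = delta_reps[:, combo].mean(axis=1)
    delta = np.where(combo, delta_reps.mean(axis=0), np.nan)
    return SynergySummary(
        doses_a=viab.doses_a,
        doses_b=viab.doses_b,
        delta=delta,
        summary=float(rep_summaries.mean()),
        replicate_summaries=rep_summaries,
        replicate_sd=float(rep_summaries.std(ddof=1)) if len(rep_summaries) > 1 else 0.0,
        n_wells=int(combo.sum()),
    )


def score_plate(doses_a, doses_b, raw) -> SynergySummary:
    """Convenience: PlateGrid -> normalize -> synergy surface."""
    return synergy_surface(normalize_plate(PlateGrid(doses_a, doses_b, raw)))
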