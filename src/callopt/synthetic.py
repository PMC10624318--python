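"""Replicate-level data generation.

The screen reports only treatment means and standard errors, so replicate
vessels must be emulated for any record-level analysis.  Two generators are
provided:

``reconstruct_replicates``
    draws vessels statistically consistent with the printed summaries.
    CFR is the percentage of 4 explants forming callus, so a replicate is
    ``100 * Binomial(4, mean/100) / 4`` — the binomial granularity, not the
    printed SE, fixes its variance.  CFW is drawn from a normal with
    SD = SE * sqrt(n_reps) (the SE of a mean of ``n_reps`` vessels),
    truncated at zero, and forced to exactly zero for vessels in which no
    explant formed callus.

``simulate_surface``
    produces fully synthetic dose-response data from a Gaussian-bump
    surface with a known optimum, for parameter-recovery tests where the
    ground truth must be known by construction.

Each treatment draws from its own counter-based substream of the global
seed, so appending treatments never reshuffles earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _treatment_rng(seed: int, treatment_id: int) -> np.random.Generator:
    # independent substream per treatment; stable under dataset edits
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(treatment_id,)))


def _truncated_normal(rng, mean, sd, size):
    """Normal(mean, sd) truncated at zero (proper renormalised truncation)."""
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def reconstruct_replicates(
    table: pd.DataFrame,
    n_reps: int = 7,
    explants_per_vessel: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate replicate vessels for each treatment row of ``table``.

    Parameters
    ----------
    table
        Treatment table (columns ``bap, kin, naa, iba, cfr_mean, cfr_se,
        cfw_mean, cfw_se``).
    n_reps
        Vessels per treatment; the screen used 7.
    explants_per_vessel
        Explants cultured per vessel; the screen used 4, which makes
        per-vessel CFR live on the 0/25/50/75/100 lattice.
    seed
        Global seed; each treatment uses its own substream.

    Returns
    -------
    DataFrame with columns ``treatment_id, bap, kin, naa, iba, cfr, cfw``
    and ``len(table) * n_reps`` rows.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if explants_per_vessel < 1:
        raise ValueError(f"explants_per_vessel must be >= 1, got {explants_per_vessel}")
    out = []
    for tid, row in enumerate(table.itertuples(index=False)):
        rng = _treatment_rng(seed, tid)
        p = row.cfr_mean / 100.0
        formed = rng.binomial(explants_per_vessel, p, size=n_reps)
        cfr = 100.0 * formed / explants_per_vessel
        cfw = _truncated_normal(rng, row.cfw_mean, row.cfw_se * np.sqrt(n_reps), n_reps)
        cfw = np.where(cfr == 0.0, 0.0, cfw)
        for j in range(n_reps):
            out.append(
                {
                    "treatment_id": tid,
                    "bap": row.bap,
                    "kin": row.kin,
                    "naa": row.naa,
                    "iba": row.iba,
                    "cfr": cfr[j],
                    "cfw": cfw[j],
                }
            )
    return pd.DataFrame(out)


@dataclass
class SurfaceSpec:
    """Ground-truth Gaussian dose-response surface.

    The noiseless response at dose vector ``x`` is
    ``peak * exp(-sum_j (x_j - optimum_j)^2 / (2 * widths_j^2))``,
    optionally rescaled so the hormone-free origin responds exactly zero
    (mirroring the screen's control row).
    """

    optimum: tuple = (1.3, 1.0, 1.4, 1.7)
    peak_cfr: float = 95.0
    peak_cfw: float = 1.8
    widths: tuple = (1.0, 1.0, 1.0, 1.0)
    noise_sd_cfr: float = 10.0
    noise_sd_cfw: float = 0.1
    zero_at_origin: bool = True

    def __post_init__(self):
        if not 0 < self.peak_cfr <= 100:
            raise ValueError("peak_cfr must lie in (0, 100]")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be strictly positive")

    def _bump(self, X: np.ndarray) -> np.ndarray:
        opt = np.asarray(self.optimum, dtype=float)
        w = np.asarray(self.widths, dtype=float)
        g = np.exp(-np.sum((X - opt) ** 2 / (2 * w**2), axis=1))
        if self.zero_at_origin:
            g0 = np.exp(-np.sum(opt**2 / (2 * w**2)))
            g = (g - g0) / (1.0 - g0)
        return g

    def cfr(self, X: np.ndarray) -> np.ndarray:
        """Noiseless CFR surface at dose matrix ``X`` (n x 4)."""
        return self.peak_cfr * self._bump(np.atleast_2d(X))

    def cfw(self, X: np.ndarray) -> np.ndarray:
        """Noiseless CFW surface at dose matrix ``X`` (n x 4)."""
        return self.peak_cfw * self._bump(np.atleast_2d(X))


def simulate_surface(
    spec: SurfaceSpec,
    design: np.ndarray,
    n_reps: int = 7,
    seed: int = 0,
) -> tuple[pd.DataFrame, SurfaceSpec]:
    """Sample noisy replicates of a known surface at the given design points.

    ``design`` is an (n_points x 4) array of dose vectors in [0, 2]^4.
    Gaussian noise is added per replicate; CFR is clipped to [0, 100] and
    CFW to [0, inf).  Returns the replicate table together with the spec so
    callers always carry the ground truth alongside the data.
    """
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.shape[1] != 4:
        raise ValueError("design points must be 4-dimensional dose vectors")
    if design.min() < 0 or design.max() > 2:
        raise ValueError("design points must lie in [0, 2]^4")
    true_cfr = spec.cfr(design)
    true_cfw = spec.cfw(design)
    out = []
    for tid in range(len(design)):
        rng = _treatment_rng(seed, tid)
        cfr = true_cfr[tid] + rng.normal(0.0, spec.noise_sd_cfr, n_reps) if spec.noise_sd_cfr else np.full(n_reps, true_cfr[tid])
        cfw = true_cfw[tid] + rng.normal(0.0, spec.noise_sd_cfw, n_reps) if spec.noise_sd_cfw else np.full(n_reps, true_cfw[tid])
        cfr = np.clip(cfr, 0.0, 100.0)
        cfw = np.clip(cfw, 0.0, None)
        for j in range(n_reps):
            out.append(
                {
                    "treatment_id": tid,
                    "bap": design[tid, 0],
                    "kin": design[tid, 1],
                    "naa": design[tid, 2],
                    "iba": design[tid, 3],
                    "cfr": cfr[j],
                    "cfw": cfw[j],
                }
            )
    return pd.DataFrame(out), spec
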