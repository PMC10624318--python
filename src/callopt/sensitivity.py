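"""Hormone importance via the Variable Sensitivity Ratio (VSR).

Two schemes are provided:

``error_ratio`` (default)
    VSR_i = RMSE of the model with input i clamped to its dataset mean,
    divided by the RMSE of the intact model, both over the full dataset.
    A hormone the model does not use at all gives exactly 1.0; values near
    1.0-1.3 are typical when replicate noise dominates the error.

``mean_slope``
    the mean over dataset points and perturbation steps of
    |delta output| / |delta input|, with inputs perturbed on the normalised
    scale so hormones with different dose ranges are comparable.

Ranking is by descending VSR; ties fall back to input order
(BAP, KIN, NAA, IBA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import HORMONES
from .metrics import fit_minmax, rmse


@dataclass
class VSRResult:
    """Per-hormone VSR and ranks (1 = most important) for one output."""

    output: str
    model: str
    scheme: str
    vsr: dict  # hormone -> ratio
    rank: dict  # hormone -> 1..4

    def as_dict(self) -> dict:
        return {
            "output": self.output,
            "model": self.model,
            "scheme": self.scheme,
            "vsr": self.vsr,
            "rank": self.rank,
        }


def compute_vsr(model, X, y, input_index, scheme="error_ratio", n_steps=8,
                step=0.1) -> float:
    """Sensitivity of a trained model to one input over a dataset.

    Parameters
    ----------
    model
        Fitted surrogate with a ``predict`` method taking raw dose vectors.
    X, y
        Dose matrix (n x 4) and observed response used as the evaluation
        set.
    input_index
        Column of ``X`` to perturb/clamp (0=BAP, 1=KIN, 2=NAA, 3=IBA).
    scheme
        ``error_ratio`` or ``mean_slope`` (see module docstring).
    n_steps, step
        For ``mean_slope``: number of symmetric perturbation steps and the
        per-step size on the normalised input scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not 0 <= input_index < X.shape[1]:
        raise ValueError(f"input_index must be in [0, {X.shape[1]}), got {input_index}")
    if scheme == "error_ratio":
        base = rmse(y, model.predict(X))
        X_clamped = X.copy()
        X_clamped[:, input_index] = X[:, input_index].mean()
        clamped = rmse(y, model.predict(X_clamped))
        if clamped == base:  # input ignored (or clamping changed nothing)
            return 1.0
        if base == 0.0:  # exact fit: ratio degenerates, keep ordering finite
            base = 1e-12 * max(1.0, float(np.std(y)))
        return float(clamped / base)
    if scheme == "mean_slope":
        scaler = fit_minmax(X)
        Xn = scaler.apply(X)
        slopes = []
        for s in range(1, n_steps + 1):
            for sign in (+1.0, -1.0):
                delta = sign * s * step
                Xp = Xn.copy()
                Xp[:, input_index] = np.clip(Xn[:, input_index] + delta, 0.0, 1.0)
                actual = Xp[:, input_index] - Xn[:, input_index]
                moved = actual != 0
                if not moved.any():
                    continue
                dy = model.predict(scaler.invert(Xp[moved])) - model.predict(
                    scaler.invert(Xn[moved])
                )
                slopes.append(np.mean(np.abs(dy) / np.abs(actual[moved])))
        return float(np.mean(slopes))
    raise ValueError(f"unknown VSR scheme '{scheme}'")


def rank_variables(vsr_values, output="", model="", scheme="error_ratio") -> VSRResult:
    """Rank the four hormones by descending VSR (stable tie-break by order)."""
    vsr = np.asarray(vsr_values, dtype=float)
    if vsr.shape != (4,):
        raise ValueError("expected exactly 4 VSR values (BAP, KIN, NAA, IBA)")
    if not np.all(np.isfinite(vsr)):
        raise ValueError("VSR values must be finite")
    order = np.argsort(-vsr, kind="stable")  # descending, first-come tie-break
    rank = np.empty(4, dtype=int)
    rank[order] = np.arange(1, 5)
    return VSRResult(
        output=output,
        model=model,
        scheme=scheme,
        vsr=dict(zip(HORMONES, vsr.tolist())),
        rank=dict(zip(HORMONES, rank.tolist())),
    )


def analyze(model, X, y, output="", scheme="error_ratio", n_steps=8) -> VSRResult:
    """Compute and rank VSR for all four hormones with one trained model."""
    vsr = [
        compute_vsr(model, X, y, i, scheme=scheme, n_steps=n_steps) for i in range(4)
    ]
    return rank_variables(
        vsr, output=output, model=getattr(model, "name", type(model).__name__),
        scheme=scheme,
    )
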