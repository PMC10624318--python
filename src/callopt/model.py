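"""High-level modelling interface.

:class:`CallogenesisModel` wraps one response (CFR or CFW) of a
replicate-level dose-response dataset; ``fit()`` trains the chosen
surrogate on a treatment-level train/test split and returns a
:class:`CallogenesisResults` carrying the trained surrogate, its train and
test metrics, and methods for sensitivity analysis, dose optimisation and
a text ``summary()``.

Example
-------
>>> from callopt import dataset, synthetic
>>> from callopt.model import CallogenesisModel
>>> table = dataset.load_packaged_table()
>>> reps = synthetic.reconstruct_replicates(table, n_reps=7, seed=1)
>>> res = CallogenesisModel(reps, output="cfr", algorithm="grnn", seed=1).fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthetic
from .dataset import HORMONES
from .ga import GAConfig, GAResult, ga_optimize
from .metrics import score, split_by_group, split_train_test
from .models import make_model, treatment_aggregate
from .sensitivity import VSRResult, analyze


class CallogenesisModel:
    """One output of the callogenesis dose-response data, ready to fit.

    Parameters
    ----------
    replicates
        Replicate-level DataFrame (columns ``treatment_id, bap, kin, naa,
        iba`` and the response).
    output
        ``"cfr"`` (percent) or ``"cfw"`` (grams).
    algorithm
        ``"grnn"``, ``"rbf"`` or ``"mlp"``.
    seed
        Drives the train/test split and any stochastic training step.
    split_level
        ``"record"`` (default, the study's random 80:20 of all vessels) or
        ``"treatment"`` to hold out whole treatments.
    metric_level
        ``"treatment"`` (default) scores predictions against observed
        treatment means — the quantity the screen reports, free of the
        25-percent quantisation of single 4-explant vessels; ``"record"``
        scores raw vessels.
    """

    def __init__(self, replicates: pd.DataFrame, output: str = "cfr",
                 algorithm: str = "grnn", seed: int = 0, ratio: float = 0.8,
                 split_level: str = "record", metric_level: str = "treatment",
                 **model_kwargs):
        if output not in ("cfr", "cfw"):
            raise ValueError(f"output must be 'cfr' or 'cfw', got {output!r}")
        self.replicates = replicates.reset_index(drop=True)
        self.output = output
        self.algorithm = algorithm
        self.seed = seed
        self.ratio = ratio
        self.split_level = split_level
        self.metric_level = metric_level
        self.model_kwargs = model_kwargs
        self.X = self.replicates[HORMONES].to_numpy(dtype=float)
        self.y = self.replicates[output].to_numpy(dtype=float)

    @classmethod
    def from_treatment_table(cls, table: pd.DataFrame, output: str = "cfr",
                             algorithm: str = "grnn", n_reps: int = 7,
                             seed: int = 0, **kwargs) -> "CallogenesisModel":
        """Reconstruct replicate vessels from a treatment table, then build."""
        reps = synthetic.reconstruct_replicates(table, n_reps=n_reps, seed=seed)
        return cls(reps, output=output, algorithm=algorithm, seed=seed, **kwargs)

    def fit(self, holdout: bool = True) -> "CallogenesisResults":
        """Train the surrogate; with ``holdout=False`` fit on all records."""
        if holdout:
            if self.split_level == "treatment":
                split = split_by_group(
                    self.replicates["treatment_id"].to_numpy(),
                    ratio=self.ratio, seed=self.seed,
                )
            else:
                split = split_train_test(len(self.y), ratio=self.ratio, seed=self.seed)
            train_idx, test_idx = split.train, split.test
        else:
            train_idx, test_idx = np.arange(len(self.y)), None
        surrogate = make_model(self.algorithm, seed=self.seed, **self.model_kwargs)
        surrogate.fit(self.X[train_idx], self.y[train_idx])

        def _score(part, idx):
            if self.metric_level == "treatment":
                Xa, ya = treatment_aggregate(self.replicates, self.output, idx)
                return score(surrogate.name, self.output, part, ya, surrogate.predict(Xa))
            return score(surrogate.name, self.output, part,
                         self.y[idx], surrogate.predict(self.X[idx]))

        metrics = {"train": _score("train", train_idx)}
        if test_idx is not None and len(test_idx):
            metrics["test"] = _score("test", test_idx)
        return CallogenesisResults(self, surrogate, metrics, train_idx, test_idx)


class CallogenesisResults:
    """Fitted surrogate plus diagnostics, sensitivity and optimisation."""

    def __init__(self, model: CallogenesisModel, surrogate, metrics,
                 train_idx, test_idx):
        self.model = model
        self.surrogate = surrogate
        self.metrics = metrics
        self.train_idx = train_idx
        self.test_idx = test_idx

    @property
    def spread(self):
        """CV-selected GRNN spread, if the surrogate is a GRNN."""
        return getattr(self.surrogate, "spread", None)

    def predict(self, doses) -> np.ndarray:
        """Predict the response at raw dose vectors (mg/L)."""
        return self.surrogate.predict(np.atleast_2d(np.asarray(doses, dtype=float)))

    def sensitivity(self, scheme: str = "error_ratio") -> VSRResult:
        """Variable Sensitivity Ratio of each hormone over the full dataset."""
        return analyze(self.surrogate, self.model.X, self.model.y,
                       output=self.model.output, scheme=scheme)

    def optimize(self, config: GAConfig | None = None,
                 seed_with_data: bool = True) -> GAResult:
        """GA search for the dose vector maximising the fitted surrogate.

        By default the screened dose combinations seed part of the initial
        population, so the optimum can never fall below the best design
        point's prediction.
        """
        cfg = config or GAConfig(seed=self.model.seed)
        init = np.unique(self.model.X, axis=0) if seed_with_data else None
        return ga_optimize(lambda P: self.surrogate.predict(P), cfg,
                           initial_points=init)

    def summary(self) -> str:
        unit = "%" if self.model.output == "cfr" else "g"
        lines = [
            "Callogenesis surrogate model results",
            "=" * 44,
            f"Output:     {self.model.output.upper()} ({unit})",
            f"Algorithm:  {self.surrogate.name}",
            f"Records:    {len(self.model.y)} "
            f"(train {len(self.train_idx)}, "
            f"test {0 if self.test_idx is None else len(self.test_idx)})",
            f"Seed:       {self.model.seed}",
        ]
        if self.spread is not None:
            lines.append(f"Spread:     {self.spread:.4g} (CV-selected)")
        lines.append("-" * 44)
        lines.append(f"{'Partition':<10}{'R2':>8}{'RMSE':>10}{'MBE':>10}{'n':>6}")
        for part, rep in self.metrics.items():
            lines.append(
                f"{part:<10}{rep.r2:>8.3f}{rep.rmse:>10.3f}{rep.mbe:>10.3f}{rep.n:>6d}"
            )
        return "\n".join(lines)
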