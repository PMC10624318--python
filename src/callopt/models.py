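"""The three surrogate regressors: GRNN, RBF network and a one-hidden-layer MLP.

All three map a 4-vector of hormone doses (BAP, KIN, NAA, IBA; mg/L) to a
single response (CFR in percent or CFW in grams).  Inputs are min-max
normalised inside ``fit`` by default so Euclidean distances weight the four
hormones equally; pass ``normalize=False`` to work directly in an already
normalised space.

GRNN
    Nadaraya-Watson kernel regression: the prediction is the Gaussian
    kernel-weighted average of all stored training targets,

        yhat(x) = sum_i y_i exp(-d_i^2 / 2 sigma^2) / sum_i exp(-d_i^2 / 2 sigma^2),

    with d_i the Euclidean distance to stored pattern i.  The single free
    parameter sigma (the spread) is chosen by k-fold cross-validation.
    Weights are evaluated through a max-shifted exponential so distant
    queries never produce 0/0 and the sigma -> 0 limit returns the nearest
    pattern's target.

RBF network
    m Gaussian bumps centred on k-means prototypes of the training inputs;
    per-centre widths are set to the mean distance to the two nearest other
    centres, and the output weights plus bias are solved by ridge-regularised
    linear least squares (optionally refined by gradient descent).

MLP
    Fixed 4-128-1 architecture, sigmoid hidden layer, linear output, trained
    by minibatch stochastic gradient descent on the mean squared error with
    backpropagated analytic gradients.  Targets are standardised internally
    for conditioning and predictions returned on the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .metrics import MetricsReport, fit_minmax, kfold_indices, rmse, score, split_by_group

DEFAULT_SPREAD_GRID = tuple(np.geomspace(0.02, 1.0, 20))


def _as_2d(X):
    X = np.asarray(X, dtype=float)
    return X.reshape(1, -1) if X.ndim == 1 else X


class GRNN:
    """Generalized regression neural network (kernel-average regressor).

    Parameters
    ----------
    spread
        Gaussian kernel width sigma in normalised-input units.  ``None``
        selects it by k-fold cross-validation over ``spread_grid`` at fit
        time, preferring the larger (smoother) sigma on ties.
    normalize
        Min-max normalise inputs inside ``fit`` (default).  The scaler is
        stored on the model so ``predict`` accepts raw doses.
    """

    name = "GRNN"

    def __init__(self, spread=None, spread_grid=DEFAULT_SPREAD_GRID, cv_folds=5,
                 seed=0, normalize=True):
        self.spread = spread
        self.spread_grid = spread_grid
        self.cv_folds = cv_folds
        self.seed = seed
        self.normalize = normalize
        self.scaler = None
        self.patterns_ = None
        self.targets_ = None

    def fit(self, X, y):
        X, y = _as_2d(X), np.asarray(y, dtype=float).ravel()
        if len(X) == 0:
            raise ValueError("cannot fit GRNN on an empty pattern set")
        if self.normalize:
            self.scaler = fit_minmax(X)
            X = self.scaler.apply(X)
        self.patterns_ = X
        self.targets_ = y
        if self.spread is None:
            self.spread = select_spread(
                X, y, self.spread_grid, k=self.cv_folds, seed=self.seed
            )
        if self.spread <= 0:
            raise ValueError(f"spread must be positive, got {self.spread}")
        return self

    def predict(self, X):
        if self.patterns_ is None:
            raise ValueError("GRNN is not fitted")
        X = _as_2d(X)
        if self.scaler is not None:
            X = self.scaler.apply(X)
        # max-shifted kernel weights: at least one weight is exactly 1,
        # so the denominator never underflows to zero
        d2 = cdist(X, self.patterns_, "sqeuclidean")
        logw = -d2 / (2.0 * self.spread**2)
        w = np.exp(logw - logw.max(axis=1, keepdims=True))
        return w @ self.targets_ / w.sum(axis=1)


def select_spread(X_norm, y, spread_grid=DEFAULT_SPREAD_GRID, k=5, seed=0):
    """Pick the GRNN spread minimising mean k-fold CV RMSE.

    Duplicate grid values are collapsed; ties are broken toward the larger
    sigma, i.e. the smoother model.
    """
    grid = sorted(set(float(s) for s in spread_grid))
    if len(grid) < 2:
        raise ValueError("spread grid needs at least 2 distinct positive values")
    if grid[0] <= 0:
        raise ValueError("spread grid values must be positive")
    X_norm = _as_2d(X_norm)
    y = np.asarray(y, dtype=float).ravel()
    folds = kfold_indices(len(y), k=min(k, len(y)), seed=seed)
    best_sigma, best_err = None, np.inf
    for sigma in grid:  # ascending, so >= keeps the larger sigma on ties
        errs = []
        for f in folds:
            m = GRNN(spread=sigma, normalize=False).fit(X_norm[f.train], y[f.train])
            errs.append(rmse(y[f.test], m.predict(X_norm[f.test])))
        err = float(np.mean(errs))
        if err <= best_err:
            best_sigma, best_err = sigma, err
    return best_sigma


class RBFNetwork:
    """Gaussian radial basis function network with linearly solved weights."""

    name = "RBF"

    def __init__(self, n_centers=None, ridge=1e-8, refine_epochs=0,
                 refine_lr=1e-3, widths_neighbors=2, fixed_width=None,
                 seed=0, normalize=True):
        self.n_centers = n_centers
        self.fixed_width = fixed_width
        self.ridge = ridge
        self.refine_epochs = refine_epochs
        self.refine_lr = refine_lr
        self.widths_neighbors = widths_neighbors
        self.seed = seed
        self.normalize = normalize
        self.scaler = None
        self.centers_ = None
        self.widths_ = None
        self.weights_ = None
        self.bias_ = None

    def _design(self, X):
        d2 = cdist(X, self.centers_, "sqeuclidean")
        return np.exp(-d2 / (2.0 * self.widths_**2))

    def fit(self, X, y):
        X, y = _as_2d(X), np.asarray(y, dtype=float).ravel()
        if self.normalize:
            self.scaler = fit_minmax(X)
            X = self.scaler.apply(X)
        m = self.n_centers if self.n_centers is not None else max(1, min(25, len(X) // 4))
        if not 1 <= m <= len(X):
            raise ValueError(f"n_centers must be in [1, {len(X)}], got {m}")
        if m < len(np.unique(X, axis=0)):
            km = KMeans(n_clusters=m, n_init=10, random_state=self.seed).fit(X)
            self.centers_ = km.cluster_centers_
        else:
            self.centers_ = np.unique(X, axis=0)
            m = len(self.centers_)
        if self.fixed_width is not None:
            self.widths_ = np.full(m, float(self.fixed_width))
        elif m == 1:
            self.widths_ = np.array([1.0])
        else:
            dc = cdist(self.centers_, self.centers_)
            np.fill_diagonal(dc, np.inf)
            p = min(self.widths_neighbors, m - 1)
            self.widths_ = np.sort(dc, axis=1)[:, :p].mean(axis=1)
            self.widths_ = np.maximum(self.widths_, 1e-12)
        phi = np.hstack([self._design(X), np.ones((len(X), 1))])
        A = phi.T @ phi + self.ridge * np.eye(phi.shape[1])
        coef = np.linalg.solve(A, phi.T @ y)
        self.weights_, self.bias_ = coef[:-1], float(coef[-1])
        for _ in range(self.refine_epochs):
            resid = phi @ np.append(self.weights_, self.bias_) - y
            grad = 2.0 * phi.T @ resid / len(y)
            self.weights_ -= self.refine_lr * grad[:-1]
            self.bias_ -= self.refine_lr * grad[-1]
        return self

    def predict(self, X):
        if self.centers_ is None:
            raise ValueError("RBF network is not fitted")
        X = _as_2d(X)
        if self.scaler is not None:
            X = self.scaler.apply(X)
        return self._design(X) @ self.weights_ + self.bias_


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class TrainingConfig:
    """Hyperparameters for the MLP (and RBF refinement) optimisers."""

    learning_rate: float = 0.05
    epochs: int = 4000
    batch_size: int | None = None  # None: full batch below 64 samples, else 32
    seed: int = 0
    patience: int | None = None  # early stop on stalled training loss

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("learning_rate and epochs must be positive")


class MLP:
    """4-128-1 multilayer perceptron trained by minibatch SGD backprop."""

    name = "MLP"
    n_hidden = 128

    def __init__(self, config: TrainingConfig | None = None, normalize=True):
        self.config = config or TrainingConfig()
        self.normalize = normalize
        self.scaler = None
        self.W1 = self.b1 = self.W2 = self.b2 = None
        self.y_mean_ = 0.0
        self.y_scale_ = 1.0
        self.loss_history_ = []

    def _init_weights(self, n_in, rng):
        r1 = 1.0 / np.sqrt(n_in)
        r2 = 1.0 / np.sqrt(self.n_hidden)
        self.W1 = rng.uniform(-r1, r1, (n_in, self.n_hidden))
        self.b1 = rng.uniform(-r1, r1, self.n_hidden)
        self.W2 = rng.uniform(-r2, r2, self.n_hidden)
        self.b2 = rng.uniform(-r2, r2)

    def _forward(self, X):
        H = _sigmoid(X @ self.W1 + self.b1)
        return H, H @ self.W2 + self.b2

    def _loss_and_grads(self, X, y_std):
        """Mean squared error on standardised targets and its gradients."""
        with np.errstate(over="ignore", invalid="ignore"):  # divergence is caught via the loss
            H, yhat = self._forward(X)
            resid = yhat - y_std
            loss = float(np.mean(resid**2))
            n = len(y_std)
            gy = 2.0 * resid / n
            gW2 = H.T @ gy
            gb2 = gy.sum()
            gH = np.outer(gy, self.W2) * H * (1.0 - H)
            gW1 = X.T @ gH
            gb1 = gH.sum(axis=0)
        return loss, (gW1, gb1, gW2, gb2)

    def fit(self, X, y):
        X, y = _as_2d(X), np.asarray(y, dtype=float).ravel()
        if self.normalize:
            self.scaler = fit_minmax(X)
            X = self.scaler.apply(X)
        self.y_mean_ = float(y.mean())
        self.y_scale_ = float(y.std()) or 1.0
        y_std = (y - self.y_mean_) / self.y_scale_
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self._init_weights(X.shape[1], rng)
        batch = cfg.batch_size or (len(y) if len(y) < 64 else 32)
        self.loss_history_ = []
        best, stalled = np.inf, 0
        for _ in range(cfg.epochs):
            order = rng.permutation(len(y))
            for start in range(0, len(y), batch):
                idx = order[start : start + batch]
                _, (gW1, gb1, gW2, gb2) = self._loss_and_grads(X[idx], y_std[idx])
                self.W1 -= cfg.learning_rate * gW1
                self.b1 -= cfg.learning_rate * gb1
                self.W2 -= cfg.learning_rate * gW2
                self.b2 -= cfg.learning_rate * gb2
            epoch_loss, _ = self._loss_and_grads(X, y_std)
            if not np.isfinite(epoch_loss):
                raise FloatingPointError(
                    "MLP training diverged (non-finite loss); lower the learning rate"
                )
            self.loss_history_.append(epoch_loss)
            if cfg.patience is not None:
                if epoch_loss < best - 1e-12:
                    best, stalled = epoch_loss, 0
                else:
                    stalled += 1
                    if stalled >= cfg.patience:
                        break
        return self

    def predict(self, X):
        if self.W1 is None:
            raise ValueError("MLP is not fitted")
        X = _as_2d(X)
        if self.scaler is not None:
            X = self.scaler.apply(X)
        _, yhat = self._forward(X)
        return yhat * self.y_scale_ + self.y_mean_


def make_model(name: str, seed: int = 0, **kwargs):
    """Instantiate one of the three surrogates by name."""
    name = name.lower()
    if name == "grnn":
        return GRNN(seed=seed, **kwargs)
    if name == "rbf":
        return RBFNetwork(seed=seed, **kwargs)
    if name == "mlp":
        cfg = kwargs.pop("config", None) or TrainingConfig(seed=seed, **kwargs)
        return MLP(config=cfg)
    raise ValueError(f"unknown model '{name}' (expected grnn, rbf or mlp)")


def treatment_aggregate(replicates, output, idx=None):
    """Observed treatment means and their dose vectors.

    The screen reports each treatment as the mean over its 7 vessels, so
    model quality is judged against these aggregates: per-vessel CFR is
    quantised to multiples of 25% (4 explants), a noise floor no model can
    beat at the record level.  ``idx`` restricts to the treatments that have
    at least one record in the given partition.
    """
    agg = replicates.groupby("treatment_id").agg(
        {**{h: "first" for h in ("bap", "kin", "naa", "iba")}, output: "mean"}
    )
    if idx is not None:
        tids = np.unique(replicates["treatment_id"].to_numpy()[np.asarray(idx)])
        agg = agg.loc[tids]
    return agg[["bap", "kin", "naa", "iba"]].to_numpy(dtype=float), agg[output].to_numpy(dtype=float)


@dataclass
class ModelComparison:
    """All 3 models x 2 outputs x 2 partitions, plus the winner per output."""

    reports: list[MetricsReport]
    best_model: dict[str, str] = field(default_factory=dict)
    models: dict[tuple[str, str], object] = field(default_factory=dict)

    def get(self, model, output, partition) -> MetricsReport:
        for r in self.reports:
            if (r.model, r.output, r.partition) == (model, output, partition):
                return r
        raise KeyError((model, output, partition))


def compare_models(replicates, seed=0, ratio=0.8, split_level="record",
                   metric_level="treatment",
                   model_names=("GRNN", "MLP", "RBF"),
                   outputs=("cfr", "cfw")) -> ModelComparison:
    """Fit every surrogate to every output on a shared train/test split.

    By default the 80:20 split is a random partition of the replicate
    records (the study's procedure) and metrics are computed per treatment
    against observed treatment means (see :func:`treatment_aggregate`).
    ``split_level="treatment"`` holds out whole treatments instead — the
    leakage-safe but much harder task — and ``metric_level="record"``
    scores raw vessels.  The best model per output is the one with the
    highest test R^2.
    """
    if len(replicates) < 20:
        raise ValueError("need at least 20 records to compare models")
    X = replicates[["bap", "kin", "naa", "iba"]].to_numpy(dtype=float)
    if split_level == "treatment":
        split = split_by_group(replicates["treatment_id"].to_numpy(), ratio=ratio, seed=seed)
    elif split_level == "record":
        from .metrics import split_train_test

        split = split_train_test(len(replicates), ratio=ratio, seed=seed)
    else:
        raise ValueError(f"split_level must be 'record' or 'treatment', got {split_level!r}")
    reports, models = [], {}
    for output in outputs:
        y = replicates[output].to_numpy(dtype=float)
        for name in model_names:
            model = make_model(name, seed=seed)
            model.fit(X[split.train], y[split.train])
            models[(name, output)] = model
            for part, idx in (("train", split.train), ("test", split.test)):
                if metric_level == "treatment":
                    Xa, ya = treatment_aggregate(replicates, output, idx)
                    reports.append(score(name, output, part, ya, model.predict(Xa)))
                else:
                    reports.append(score(name, output, part, y[idx], model.predict(X[idx])))
    best = {
        output: max(
            model_names,
            key=lambda m: next(
                r.r2 for r in reports
                if (r.model, r.output, r.partition) == (m, output, "test")
            ),
        )
        for output in outputs
    }
    return ModelComparison(reports=reports, best_model=best, models=models)
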