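"""The four learning algorithms behind one fit/predict contract.

Families and their hyperparameter search spaces:

* **PLS** — partial least squares regression; latent variables searched in
  [1, 100] (capped at min(n_features, n_train - 1) at fit time).
* **RF** — random forest; trees in {50, 100, 150, 200} x max-features in
  {"max", "sqrt", "log2"} ("max" = all features).
* **SVR** — RBF-kernel support vector regression; epsilon in {0.01, 0.025,
  0.05, 0.075, 0.10, 0.15, 0.20} x cost C in {2^-2 .. 2^9}.  The kernel width
  uses scikit-learn's "scale" heuristic (recorded in the fit), since only
  epsilon and C are searched.
* **CNN** — the NumPy 1-D convolutional network of :mod:`grapespec.cnn`; its
  structural and optimizer hyperparameters are tuned with Hyperband
  (successive halving over training epochs) rather than a full grid.

PLS and SVR inputs are standardized inside the fitted pipeline (statistics
from the training partition only); without that, one C/epsilon grid could not
serve pre-treatments with wildly different scales.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .cnn import MAX_EPOCHS, PATIENCE, CnnConfig, CnnModel

__all__ = [
    "FAMILIES",
    "HyperparameterGrid",
    "CnnSearchSpace",
    "HyperbandBudget",
    "FittedModel",
    "grid_for",
    "fit",
    "build_cnn",
    "hyperband_search",
    "derive_seed",
]

FAMILIES = ("PLS", "RF", "SVR", "CNN")

SVR_EPSILONS = (0.01, 0.025, 0.05, 0.075, 0.10, 0.15, 0.20)
SVR_COSTS = tuple(2.0 ** k for k in range(-2, 10))
RF_TREES = (50, 100, 150, 200)
RF_MAX_FEATURES = ("max", "sqrt", "log2")
PLS_MAX_COMPONENTS = 100


def derive_seed(master: int, *tags: int | str) -> int:
    """Deterministically derive a child seed (< 2**31) from a master seed and
    a sequence of tags, so every randomized stage of a run is reproducible."""
    import zlib

    keys = [int(master) & 0x7FFFFFFF]
    for t in tags:
        keys.append(zlib.crc32(str(t).encode()) & 0x7FFFFFFF)
    return int(np.random.SeedSequence(keys).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class HyperparameterGrid:
    """A deterministic Cartesian enumeration of hyperparameter sets."""

    family: str
    points: tuple[dict, ...]

    def __len__(self) -> int:
        return len(self.points)


def grid_for(family: str) -> HyperparameterGrid:
    """The printed search grid of a standard family (PLS, RF or SVR).

    Enumeration order is deterministic: points are sorted by parameter name,
    then value, so "first minimum" tie-breaking is reproducible.
    """
    if family == "PLS":
        points = tuple({"n_components": k} for k in range(1, PLS_MAX_COMPONENTS + 1))
    elif family == "RF":
        points = tuple(
            {"max_features": mf, "n_estimators": t}
            for mf in sorted(RF_MAX_FEATURES)
            for t in RF_TREES
        )
    elif family == "SVR":
        points = tuple(
            {"C": c, "epsilon": e} for c in SVR_COSTS for e in SVR_EPSILONS
        )
    else:
        raise KeyError(f"no grid for family {family!r} (CNN is tuned with Hyperband)")
    return HyperparameterGrid(family, points)


@dataclass
class FittedModel:
    """A fitted regressor with its provenance (family, hyperparameters, seed)."""

    family: str
    params: dict
    model: object
    seed: int
    info: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.model.predict(X)).ravel()


def fit(
    family: str,
    params: dict | CnnConfig,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    max_epochs: int = MAX_EPOCHS,
) -> FittedModel:
    """Fit one model family with explicit hyperparameters.

    For the CNN, ``X_val``/``y_val`` drive early stopping.  A constant target
    is fitted but flagged in ``info["constant_y"]``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    info: dict = {}
    if float(np.std(y)) == 0.0:
        info["constant_y"] = True

    if family == "PLS":
        cap = min(X.shape[1], X.shape[0] - 1)
        requested = int(params["n_components"])
        n_comp = min(requested, cap)
        if n_comp < requested:
            info["capped_components"] = n_comp
        model = Pipeline([
            ("scale", StandardScaler()),
            ("pls", PLSRegression(n_components=n_comp, scale=False)),
        ])
        with warnings.catch_warnings():
            # late latent variables can exhaust the y residual; harmless here
            warnings.filterwarnings("ignore", message="y residual is constant")
            model.fit(X, y)
    elif family == "RF":
        mf = params["max_features"]
        model = RandomForestRegressor(
            n_estimators=int(params["n_estimators"]),
            max_features=1.0 if mf == "max" else mf,
            random_state=int(seed) & 0x7FFFFFFF,
        )
        model.fit(X, y)
    elif family == "SVR":
        model = Pipeline([
            ("scale", StandardScaler()),
            ("svr", SVR(kernel="rbf", C=float(params["C"]),
                        epsilon=float(params["epsilon"]), gamma="scale")),
        ])
        model.fit(X, y)
        info["gamma"] = "scale"
    elif family == "CNN":
        config = params if isinstance(params, CnnConfig) else CnnConfig(**params)
        model = build_cnn(config, X.shape[1], seed=seed)
        model.fit(X, y, X_val=X_val, y_val=y_val, max_epochs=max_epochs)
        params = config
    else:
        raise KeyError(f"unknown model family {family!r}")

    pdict = params if isinstance(params, dict) else params.__dict__ | {
        "filters": list(params.filters), "dense_units": list(params.dense_units)
    }
    return FittedModel(family, dict(pdict), model, int(seed), info)


# ---------------------------------------------------------------------------
# CNN search space + Hyperband
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnnSearchSpace:
    """The tunable CNN hyperparameter ranges.

    Structural: 1-3 conv layers with 8-32 filters (even counts), kernel size
    in {3, 5, 7}, optional batch norm and max pooling (window 2); 1-3 dense
    layers of 8-64 (even) units.  Optimizer: batch size in {4, 6, 8}, Adam
    learning rate log-sampled in [1e-4, 1e-2].  Input standardization in
    {none, min-max, standard score}.
    """

    standardizations: tuple[str, ...] = ("none", "minmax", "standard")
    conv_layers: tuple[int, ...] = (1, 2, 3)
    filters: tuple[int, ...] = tuple(range(8, 33, 2))
    kernel_sizes: tuple[int, ...] = (3, 5, 7)
    batch_norm: tuple[bool, ...] = (False, True)
    max_pool: tuple[bool, ...] = (False, True)
    dense_layers: tuple[int, ...] = (1, 2, 3)
    dense_units: tuple[int, ...] = tuple(range(8, 65, 2))
    batch_sizes: tuple[int, ...] = (4, 6, 8)
    lr_bounds: tuple[float, float] = (1e-4, 1e-2)

    def sample(self, rng: np.random.Generator) -> CnnConfig:
        n_conv = int(rng.choice(self.conv_layers))
        n_dense = int(rng.choice(self.dense_layers))
        log_lo, log_hi = math.log10(self.lr_bounds[0]), math.log10(self.lr_bounds[1])
        return CnnConfig(
            standardization=str(rng.choice(self.standardizations)),
            filters=tuple(int(rng.choice(self.filters)) for _ in range(n_conv)),
            kernel_size=int(rng.choice(self.kernel_sizes)),
            batch_norm=bool(rng.choice(self.batch_norm)),
            max_pool=bool(rng.choice(self.max_pool)),
            dense_units=tuple(int(rng.choice(self.dense_units)) for _ in range(n_dense)),
            batch_size=int(rng.choice(self.batch_sizes)),
            learning_rate=float(10.0 ** rng.uniform(log_lo, log_hi)),
        )

    def validate(self, config: CnnConfig) -> None:
        ok = (
            config.standardization in self.standardizations
            and config.n_conv in self.conv_layers
            and all(f in self.filters for f in config.filters)
            and config.kernel_size in self.kernel_sizes
            and config.n_dense in self.dense_layers
            and all(u in self.dense_units for u in config.dense_units)
            and config.batch_size in self.batch_sizes
            and self.lr_bounds[0] <= config.learning_rate <= self.lr_bounds[1]
        )
        if not ok:
            raise ValueError(f"CNN config outside the search space: {config}")


def build_cnn(config: CnnConfig, n_features: int, seed: int = 0,
              space: CnnSearchSpace | None = None) -> CnnModel:
    """Instantiate a trainable CNN for a given config, validating the config
    against the search space ranges."""
    (space or CnnSearchSpace()).validate(config)
    return CnnModel(config, n_features, seed=seed)


@dataclass(frozen=True)
class HyperbandBudget:
    """Successive-halving budget: ``n_configs`` sampled configurations are
    whittled down by ``reduction`` per rung; the training-epoch resource grows
    geometrically up to ``max_epochs`` at the final rung."""

    n_configs: int = 8
    max_epochs: int = MAX_EPOCHS
    reduction: int = 3

    def rungs(self) -> list[tuple[int, int]]:
        """(n_survivors, epochs) per rung, ending with 1 config at max_epochs."""
        if self.n_configs < 1:
            raise ValueError("budget must allow at least one configuration")
        n_rungs = max(1, math.ceil(math.log(self.n_configs, self.reduction)) + 1)
        out = []
        n = self.n_configs
        for i in range(n_rungs):
            epochs = max(1, int(round(self.max_epochs / self.reduction ** (n_rungs - 1 - i))))
            out.append((n, epochs))
            n = max(1, math.ceil(n / self.reduction))
        return out


def hyperband_search(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    splits: Sequence[tuple[np.ndarray, np.ndarray]],
    seed: int,
    budget: HyperbandBudget = HyperbandBudget(),
    space: CnnSearchSpace | None = None,
    refit: bool = True,
    refit_val_fraction: float = 0.2,
) -> tuple[CnnConfig, FittedModel | None, dict]:
    """Hyperband (successive halving) search over the CNN space.

    Each configuration is scored by its mean validation RMSE across the
    supplied internal splits, training for the rung's epoch budget.  Survivors
    advance; the final rung trains at ``max_epochs``.  With ``refit=True`` the
    winning config is refit on all of (X_cal, y_cal), carving out a seeded
    ``refit_val_fraction`` validation split for the early-stopping rule.

    Fully deterministic given (data, splits, seed, budget).
    """
    if not splits:
        raise ValueError("hyperband needs at least one internal validation split")
    space = space or CnnSearchSpace()
    rng = np.random.default_rng(derive_seed(seed, "hyperband-sample"))
    configs = [space.sample(rng) for _ in range(budget.n_configs)]
    alive = list(range(len(configs)))
    scores: dict[int, float] = {}
    history: list[dict] = []

    models: dict[tuple[int, int], CnnModel] = {}  # survivors resume training
    for rung_i, (n_keep, epochs) in enumerate(budget.rungs()):
        alive = alive[:n_keep]
        if rung_i > 0 and len(alive) == 1:
            # a single survivor has already won; further rung training cannot
            # change the selection and the winner is refit afterwards anyway
            break
        for ci in alive:
            fold_rmse = []
            try:
                for si, (tr, va) in enumerate(splits):
                    key = (ci, si)
                    resume = key in models
                    if not resume:
                        models[key] = CnnModel(configs[ci], X_cal.shape[1],
                                               seed=derive_seed(seed, "hb-fit", ci, si))
                    m = models[key]
                    m.fit(X_cal[tr], y_cal[tr], X_val=X_cal[va], y_val=y_cal[va],
                          max_epochs=epochs, patience=PATIENCE, resume=resume)
                    pred = m.predict(X_cal[va])
                    fold_rmse.append(float(np.sqrt(np.mean((y_cal[va] - pred) ** 2))))
                scores[ci] = float(np.mean(fold_rmse))
            except ValueError:
                # config infeasible for this input length (pooled away)
                scores[ci] = np.inf
            history.append({"rung": rung_i, "config": ci, "epochs": epochs,
                            "mean_val_rmse": scores[ci]})
        alive.sort(key=lambda ci: scores[ci])

    best_i = alive[0]
    if not np.isfinite(scores[best_i]):
        raise ValueError("no sampled CNN configuration was feasible for this input size")
    best_config = configs[best_i]
    diagnostics = {
        "best_index": best_i,
        "best_mean_val_rmse": scores[best_i],
        "history": history,
        "n_configs": len(configs),
    }

    fitted = None
    if refit:
        n = X_cal.shape[0]
        rng_val = np.random.default_rng(derive_seed(seed, "hb-refit-val"))
        perm = rng_val.permutation(n)
        n_val = max(1, int(round(refit_val_fraction * n)))
        va, tr = perm[:n_val], perm[n_val:]
        model = CnnModel(best_config, X_cal.shape[1], seed=derive_seed(seed, "hb-refit"))
        model.fit(X_cal[tr], y_cal[tr], X_val=X_cal[va], y_val=y_cal[va],
                  max_epochs=budget.max_epochs, patience=PATIENCE)
        fitted = FittedModel("CNN", best_config.__dict__ | {
            "filters": list(best_config.filters),
            "dense_units": list(best_config.dense_units)}, model, int(seed),
            {"internal_val_rmse": scores[best_i]})
    return best_config, fitted, diagnostics
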