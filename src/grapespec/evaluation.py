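"""Nested 5-fold cross-validation and the three evaluation metrics.

The outer 5-fold loop estimates generalization error; within each calibration
set an inner 5-fold loop scores every candidate hyperparameter set (grid
families) or drives Hyperband (CNN).  The hyperparameter set minimizing the
*mean internal-validation RMSE* is refit on the full calibration set and
evaluated once on the held-out external fold — internal selection never sees
external test data.

Metrics (y observed, yhat predicted, N samples):

    R2   = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2
    RMSE = sqrt( mean (y_i - yhat_i)^2 )            [°Brix]
    RPIQ = (Q3(y) - Q1(y)) / RMSE

Quartiles use linear interpolation between order statistics, the same
convention as the library summaries.  Per-fold RPIQ uses the *fold's* observed
quartiles (which is why a fold-mean RPIQ differs from global IQR / mean RMSE);
a global-IQR variant is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pretreatments
from .model_zoo import (
    CnnSearchSpace,
    FittedModel,
    HyperbandBudget,
    derive_seed,
    fit,
    grid_for,
    hyperband_search,
)
from .spectral_library import SpectralLibrary

__all__ = [
    "FoldAssignment",
    "FoldMetrics",
    "CvReport",
    "make_folds",
    "r_squared",
    "rmse",
    "rpiq",
    "nested_cv_grid",
    "nested_cv_hyperband",
    "select_best",
]


@dataclass(frozen=True)
class FoldAssignment:
    """A seeded k-fold partition: each sample in exactly one fold, fold sizes
    differing by at most one."""

    n: int
    k: int
    seed: int
    fold_of: np.ndarray  # per-sample fold index in [0, k)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)

    def splits(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.train_indices(f), self.test_indices(f)) for f in range(self.k)]


def make_folds(n: int, k: int, seed: int, y: np.ndarray | None = None,
               stratify: bool = False) -> FoldAssignment:
    """Randomly partition n samples into k near-equal folds.

    With ``stratify=True`` (off by default) samples are first ordered by y
    quintile so each fold spans the target range evenly.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    if stratify:
        if y is None:
            raise ValueError("stratification requires y")
        perm = perm[np.argsort(np.asarray(y, dtype=float)[perm], kind="stable")]
    fold_of = np.empty(n, dtype=int)
    if stratify:
        # deal sorted samples round-robin so folds match in distribution
        for pos, idx in enumerate(perm):
            fold_of[idx] = pos % k
    else:
        for f, chunk in enumerate(np.array_split(perm, k)):
            fold_of[chunk] = f
    return FoldAssignment(n, k, seed, fold_of)


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size != yhat.size or y.size < 2:
        raise ValueError("y and yhat must have equal length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R2 undefined for constant observed values")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error, in °Brix."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size != yhat.size or y.size < 1:
        raise ValueError("y and yhat must have equal length >= 1")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rpiq(y: np.ndarray, yhat: np.ndarray) -> float:
    """Ratio of performance to interquartile range: (Q3 - Q1) / RMSE."""
    y = np.asarray(y, dtype=float)
    err = rmse(y, yhat)
    if err == 0:
        raise ValueError("undefined RPIQ (perfect fit)")
    q1, q3 = np.percentile(y, [25, 75])
    return float((q3 - q1) / err)


@dataclass
class FoldMetrics:
    fold: int
    n_test: int
    r2: float
    rmse: float
    rpiq: float
    chosen_params: dict
    internal_rmse: float  # mean internal-validation RMSE of the chosen set
    model: FittedModel | None = None


@dataclass
class CvReport:
    """Per-fold and mean metrics for one (variety, family, pre-treatment)."""

    variety: str
    family: str
    chain_label: str
    folds: list[FoldMetrics]
    predictions: pd.DataFrame  # fold, sample_id, y_true, y_pred
    audit: list[dict] = field(default_factory=list)

    @property
    def mean_r2(self) -> float:
        return float(np.mean([f.r2 for f in self.folds]))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean([f.rmse for f in self.folds]))

    @property
    def mean_rpiq(self) -> float:
        return float(np.mean([f.rpiq for f in self.folds]))

    @property
    def mean_internal_rmse(self) -> float:
        return float(np.mean([f.internal_rmse for f in self.folds]))

    @property
    def global_rpiq(self) -> float:
        """IQR of all observed values divided by the pooled prediction RMSE."""
        y = self.predictions["y_true"].to_numpy()
        yhat = self.predictions["y_pred"].to_numpy()
        return rpiq(y, yhat)

    def metrics_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variety": self.variety, "model": self.family,
                "pretreatment": self.chain_label, "fold": f.fold + 1,
                "n_test": f.n_test, "r2": f.r2, "rmse": f.rmse, "rpiq": f.rpiq,
                "chosen_hyperparameters": repr(f.chosen_params),
            }
            for f in self.folds
        ]
        return pd.DataFrame(rows)


def _prepare(library: SpectralLibrary, chain_label: str) -> tuple[np.ndarray, np.ndarray]:
    treated = pretreatments.apply_chain(chain_label, library)
    return treated.reflectance, treated.brix


def _variety_tag(library: SpectralLibrary) -> str:
    names = library.variety_names()
    return names[0] if len(names) == 1 else "all"


def nested_cv_grid(
    library: SpectralLibrary,
    chain_label: str,
    family: str,
    seed: int,
    k: int = 5,
    inner_k: int = 5,
    grid=None,
) -> CvReport:
    """Nested k-fold CV with exhaustive grid search for PLS/RF/SVR.

    The pre-treatments are per-spectrum (stateless), so they are applied once
    before splitting without leaking cross-sample information.
    """
    if len(library) < 10:
        raise ValueError("nested CV needs at least 10 samples")
    X, y = _prepare(library, chain_label)
    grid = grid if grid is not None else grid_for(family)
    outer = make_folds(len(library), k, derive_seed(seed, "outer-folds"))

    fold_rows: list[FoldMetrics] = []
    pred_rows: list[dict] = []
    audit: list[dict] = []
    for f in range(k):
        test_idx = outer.test_indices(f)
        cal_idx = outer.train_indices(f)
        inner = make_folds(cal_idx.size, inner_k, derive_seed(seed, "inner-folds", f))

        # PLS latent-variable counts above the fit-time cap collapse onto the
        # capped model; score each distinct effective point once
        points = list(grid.points)
        if family == "PLS":
            min_train = min(inner.train_indices(g).size for g in range(inner_k))
            cap = min(X.shape[1], min_train - 1)
            seen: set[int] = set()
            points = [p for p in points
                      if (eff := min(p["n_components"], cap)) not in seen
                      and not seen.add(eff)]

        best_params, best_score = None, np.inf
        for point in points:
            scores = []
            for g in range(inner_k):
                tr = cal_idx[inner.train_indices(g)]
                va = cal_idx[inner.test_indices(g)]
                m = fit(family, point, X[tr], y[tr],
                        seed=derive_seed(seed, "inner-fit", f, g))
                scores.append(rmse(y[va], m.predict(X[va])))
            score = float(np.mean(scores))
            if score < best_score:
                best_score, best_params = score, point

        final = fit(family, best_params, X[cal_idx], y[cal_idx],
                    seed=derive_seed(seed, "final-fit", f))
        yhat = final.predict(X[test_idx])
        fold_rows.append(FoldMetrics(
            fold=f, n_test=test_idx.size,
            r2=r_squared(y[test_idx], yhat),
            rmse=rmse(y[test_idx], yhat),
            rpiq=rpiq(y[test_idx], yhat),
            chosen_params=dict(best_params),
            internal_rmse=best_score,
            model=final,
        ))
        for i, yh in zip(test_idx, yhat):
            pred_rows.append({"fold": f + 1, "sample_id": library.sample_ids[i],
                              "y_true": float(y[i]), "y_pred": float(yh)})
        audit.append({"fold": f, "test_indices": set(test_idx.tolist()),
                      "internal_indices": set(cal_idx.tolist())})

    return CvReport(_variety_tag(library), family, chain_label, fold_rows,
                    pd.DataFrame(pred_rows), audit)


def nested_cv_hyperband(
    library: SpectralLibrary,
    chain_label: str,
    seed: int,
    budget: HyperbandBudget = HyperbandBudget(),
    k: int = 5,
    inner_k: int = 5,
    space: CnnSearchSpace | None = None,
) -> CvReport:
    """Nested k-fold CV for the CNN: the internal loop is Hyperband scored by
    internal-fold validation RMSE; the winning config is refit on the
    calibration set and evaluated on the held-out fold."""
    if len(library) < 10:
        raise ValueError("nested CV needs at least 10 samples")
    X, y = _prepare(library, chain_label)
    outer = make_folds(len(library), k, derive_seed(seed, "outer-folds"))

    fold_rows: list[FoldMetrics] = []
    pred_rows: list[dict] = []
    audit: list[dict] = []
    for f in range(k):
        test_idx = outer.test_indices(f)
        cal_idx = outer.train_indices(f)
        inner = make_folds(cal_idx.size, inner_k, derive_seed(seed, "inner-folds", f))
        splits = [(inner.train_indices(g), inner.test_indices(g)) for g in range(inner_k)]

        config, fitted, diag = hyperband_search(
            X[cal_idx], y[cal_idx], splits,
            seed=derive_seed(seed, "hyperband", f),
            budget=budget, space=space, refit=True,
        )
        yhat = fitted.predict(X[test_idx])
        fold_rows.append(FoldMetrics(
            fold=f, n_test=test_idx.size,
            r2=r_squared(y[test_idx], yhat),
            rmse=rmse(y[test_idx], yhat),
            rpiq=rpiq(y[test_idx], yhat),
            chosen_params=dict(fitted.params),
            internal_rmse=diag["best_mean_val_rmse"],
            model=fitted,
        ))
        for i, yh in zip(test_idx, yhat):
            pred_rows.append({"fold": f + 1, "sample_id": library.sample_ids[i],
                              "y_true": float(y[i]), "y_pred": float(yh)})
        audit.append({"fold": f, "test_indices": set(test_idx.tolist()),
                      "internal_indices": set(cal_idx.tolist())})

    return CvReport(_variety_tag(library), "CNN", chain_label, fold_rows,
                    pd.DataFrame(pred_rows), audit)


def select_best(reports: list[CvReport]) -> CvReport:
    """Pick the best pre-treatment among reports of one (variety, family).

    Selection is keyed on mean internal-validation RMSE (never test metrics);
    ties go to the chain with fewer steps, then to the lexicographically
    smaller label.
    """
    if not reports:
        raise ValueError("select_best needs at least one report")

    def key(rep: CvReport):
        chain = pretreatments.get_chain(rep.chain_label)
        return (rep.mean_internal_rmse, len(chain.steps), rep.chain_label)

    return min(reports, key=key)
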