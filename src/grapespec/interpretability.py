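"""Wavelength-importance analysis: pre-hoc screening and post-hoc attribution.

Four global importance methods, each producing a per-wavelength score profile:

* **MI** (pre-hoc) — mutual information between each band and °Brix,
  estimated with the k-nearest-neighbour estimator (k = 3, seeded); zero in
  expectation for independent pairs.
* **VIP** (PLS) — variable influence on projection: the share of
  output-variance explanation each band contributes through the retained
  latent variables; mean squared VIP equals 1 by construction.
* **Gini** (RF) — normalized total impurity (variance) reduction per band
  across the ensemble; non-negative, sums to 1.
* **SAGE** (any model) — Shapley additive global importance: each band's
  average marginal contribution to predictive-loss reduction, estimated by
  permutation sampling with held-out bands marginalized by background
  imputation.  Monte-Carlo standard errors are attached.

Profiles are computed per external CV fold and averaged ("mean" profile);
averaging both raw scores and per-fold ranks, as averaging across folds
yields a less sparse but more robust picture of which regions matter.
Importance is computed on the same pre-treated spectra the model consumed,
indexed by nominal band centers — note that derivative pre-treatments shift
apparent peaks slightly off the true absorption band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.feature_selection import mutual_info_regression

from .model_zoo import FittedModel

__all__ = [
    "ImportanceProfile",
    "mutual_information_profile",
    "vip_scores",
    "gini_importance",
    "sage_values",
    "mean_rank",
    "top_wavelengths",
]


@dataclass
class ImportanceProfile:
    """Per-wavelength importance scores for one method and one fold."""

    method: str                      # MI | VIP | GINI | SAGE
    scores: np.ndarray
    wavelengths: np.ndarray | None = None
    variety: str = ""
    family: str = ""                 # empty for the pre-hoc MI
    fold: str = "1"                  # "1".."5" or "mean"
    stderr: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths, dtype=float)

    def ranks(self) -> np.ndarray:
        """Rank per band, 1 = most important (descending score)."""
        order = np.argsort(-self.scores, kind="stable")
        r = np.empty_like(order)
        r[order] = np.arange(1, self.scores.size + 1)
        return r


def mutual_information_profile(
    X: np.ndarray, y: np.ndarray, seed: int = 0, n_neighbors: int = 3, **kw
) -> ImportanceProfile:
    """k-NN mutual-information estimate between each band and the target."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    constant = np.flatnonzero(X.std(axis=0) == 0)
    mi = mutual_info_regression(X, y, n_neighbors=n_neighbors,
                                random_state=int(seed) & 0x7FFFFFFF)
    mi = np.maximum(mi, 0.0)
    mi[constant] = 0.0
    diag = {"constant_bands": constant.tolist()} if constant.size else {}
    return ImportanceProfile("MI", mi, diagnostics=diag, **kw)


def _unwrap(fitted: FittedModel | object, cls_name: str):
    model = fitted.model if isinstance(fitted, FittedModel) else fitted
    if hasattr(model, "named_steps"):
        for step in model.named_steps.values():
            if type(step).__name__ == cls_name:
                return step
    if type(model).__name__ == cls_name:
        return model
    raise TypeError(f"expected a fitted {cls_name}, got {type(model).__name__}")


def vip_scores(fitted, **kw) -> ImportanceProfile:
    """VIP scores of a fitted PLS regression.

    VIP_j = sqrt( p * sum_a SS_a w_ja^2/||w_a||^2 / sum_a SS_a ) where
    SS_a = q_a^2 t_a't_a is the output variance explained by latent variable
    a, w_a its weight vector and p the number of bands.
    """
    pls = _unwrap(fitted, "PLSRegression")
    W = pls.x_weights_           # (p, A)
    T = pls.x_scores_            # (n, A)
    Q = pls.y_loadings_          # (1, A)
    p = W.shape[0]
    ss = (Q[0] ** 2) * np.einsum("na,na->a", T, T)
    wnorm2 = W ** 2 / np.sum(W ** 2, axis=0)
    vip = np.sqrt(p * (wnorm2 @ ss) / ss.sum())
    return ImportanceProfile("VIP", vip, **kw)


def gini_importance(fitted, **kw) -> ImportanceProfile:
    """Impurity-based importance of a fitted tree ensemble (sums to 1)."""
    rf = _unwrap(fitted, "RandomForestRegressor")
    return ImportanceProfile("GINI", rf.feature_importances_, **kw)


def sage_values(
    predict: Callable[[np.ndarray], np.ndarray] | FittedModel,
    X_background: np.ndarray,
    X_eval: np.ndarray,
    y_eval: np.ndarray,
    n_permutations: int = 256,
    seed: int = 0,
    max_background: int = 128,
    group_size: int | None = None,
    **kw,
) -> ImportanceProfile:
    """Shapley additive global importance by permutation sampling.

    For each sampled feature ordering, bands are revealed one by one; a band's
    credit is the drop in expected squared-error loss when it is revealed,
    with unrevealed bands marginalized by imputation from the background
    sample.  Scores are means over permutations and evaluation rows;
    Monte-Carlo standard errors (over permutations) are attached, along with a
    convergence diagnostic (largest stderr relative to the score spread).

    ``group_size`` (off by default, matching per-wavelength profiles) reveals
    contiguous bands in blocks of that width: the full Shapley game is then
    played over groups, and each band reports its group's score divided by the
    group width.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    predict_fn = predict.predict if isinstance(predict, FittedModel) else predict
    Xb = np.asarray(X_background, dtype=float)
    Xe = np.asarray(X_eval, dtype=float)
    ye = np.asarray(y_eval, dtype=float)
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    if Xb.shape[0] > max_background:
        Xb = Xb[rng.choice(Xb.shape[0], max_background, replace=False)]

    n_eval, d = Xe.shape
    n_bg = Xb.shape[0]
    if group_size is not None and group_size > 1:
        groups = [np.arange(s, min(s + group_size, d))
                  for s in range(0, d, group_size)]
    else:
        groups = [np.array([j]) for j in range(d)]
    n_units = len(groups)
    # imputed design: for each eval row, all background rows (progressively
    # overwritten column-wise as features are revealed)
    base_loss = None
    deltas = np.zeros((n_permutations, n_units))

    tiled_template = np.tile(Xb, (n_eval, 1))          # (n_eval*n_bg, d)
    eval_rep_index = np.repeat(np.arange(n_eval), n_bg)

    # loss with no features known: E[f] estimated from the background sample
    f_bg = np.asarray(predict_fn(Xb), dtype=float).ravel()
    f_marginal = float(f_bg.mean())
    base_loss = float(np.mean((ye - f_marginal) ** 2))

    for p in range(n_permutations):
        order = rng.permutation(n_units)
        work = tiled_template.copy()
        prev_loss = np.full(n_eval, np.nan)
        prev_loss[:] = (ye - f_marginal) ** 2
        for g in order:
            cols = groups[g]
            work[:, cols] = Xe[np.ix_(eval_rep_index, cols)]
            f = np.asarray(predict_fn(work), dtype=float).ravel()
            f_cond = f.reshape(n_eval, n_bg).mean(axis=1)
            loss = (ye - f_cond) ** 2
            deltas[p, g] = float(np.mean(prev_loss - loss))
            prev_loss = loss
    unit_scores = deltas.mean(axis=0)
    unit_stderr = deltas.std(axis=0, ddof=1) / np.sqrt(n_permutations) if n_permutations > 1 \
        else np.full(n_units, np.nan)
    scores = np.empty(d)
    stderr = np.empty(d)
    for g, cols in enumerate(groups):
        scores[cols] = unit_scores[g] / cols.size
        stderr[cols] = unit_stderr[g] / cols.size
    full_loss = float(np.mean(prev_loss))  # all features revealed (last permutation)
    diag = {
        "base_loss": base_loss,
        "full_model_loss": full_loss,
        "efficiency_gap": float(scores.sum() - (base_loss - full_loss)),
        "max_relative_stderr": float(np.nanmax(stderr) / (np.ptp(scores) or 1.0)),
        "n_background": n_bg,
        "n_permutations": n_permutations,
        "n_groups": n_units,
    }
    return ImportanceProfile("SAGE", scores, stderr=stderr, diagnostics=diag, **kw)


def mean_rank(profiles: Sequence[ImportanceProfile]) -> ImportanceProfile:
    """Fold-average a set of per-fold profiles of one method.

    Returns a profile whose scores are the element-wise mean of fold scores;
    the mean of per-fold ranks is attached as ``diagnostics["mean_ranks"]``.
    """
    if len(profiles) < 2:
        raise ValueError("mean_rank needs at least 2 fold profiles")
    first = profiles[0]
    for p in profiles[1:]:
        if p.method != first.method or p.scores.size != first.scores.size:
            raise ValueError("profiles must share one method and one grid")
        if (p.wavelengths is None) != (first.wavelengths is None) or (
            p.wavelengths is not None and not np.array_equal(p.wavelengths, first.wavelengths)
        ):
            raise ValueError("profiles must share one wavelength grid")
    scores = np.mean([p.scores for p in profiles], axis=0)
    ranks = np.mean([p.ranks() for p in profiles], axis=0)
    return ImportanceProfile(
        first.method, scores, wavelengths=first.wavelengths, variety=first.variety,
        family=first.family, fold="mean", diagnostics={"mean_ranks": ranks},
    )


def top_wavelengths(profile: ImportanceProfile, k: int = 5) -> np.ndarray:
    """The k band centers with the highest scores (requires wavelengths)."""
    if profile.wavelengths is None:
        raise ValueError("profile has no wavelength axis")
    order = np.argsort(-profile.scores, kind="stable")[:k]
    return profile.wavelengths[order]
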