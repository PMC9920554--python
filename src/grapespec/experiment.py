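"""Full study orchestration: per-variety, models x pre-treatments under
nested CV, best-pre-treatment selection, and importance analysis.

Modelling is always per variety (never pooled across varieties).  For each
(variety, family) every requested pre-treatment chain is evaluated under
nested 5-fold CV; the chain minimizing mean internal-validation RMSE is
selected; post-hoc importance is computed per fold on the selected models and
fold-averaged.  All outputs are plain CSV plus a JSON manifest so any
reported number can be recomputed from the prediction files.
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, interpretability, pretreatments, synthetic_data
from .model_zoo import FAMILIES, HyperbandBudget, derive_seed
from .spectral_library import DEFAULT_VARIETIES, SpectralLibrary, read_library

__all__ = ["ExperimentConfig", "RunBundle", "run_experiment", "report"]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """One experiment: which data, which cells of the design, which seeds."""

    library_path: str | None = None           # CSV library; if None, generate
    n_per_variety: int = 60                   # generator size when simulating
    varieties: tuple[str, ...] = DEFAULT_VARIETIES
    chains: tuple[str, ...] = pretreatments.CHAIN_LABELS
    families: tuple[str, ...] = FAMILIES
    master_seed: int = 0
    hyperband: HyperbandBudget = field(default_factory=HyperbandBudget)
    sage_permutations: int = 32
    sage_eval_rows: int = 40
    output_dir: str = "grapespec-run"

    def __post_init__(self) -> None:
        bad = set(self.chains) - set(pretreatments.CHAIN_LABELS)
        if bad:
            raise ValueError(f"unknown pre-treatment label(s): {sorted(bad)}")
        bad = set(self.families) - set(FAMILIES)
        if bad:
            raise ValueError(f"unknown model family/families: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "hyperband" in raw:
            raw["hyperband"] = HyperbandBudget(**raw["hyperband"])
        for key in ("varieties", "chains", "families"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunBundle:
    """In-memory results of a run, mirrored to CSVs in the output directory."""

    config: ExperimentConfig
    reports: dict = field(default_factory=dict)      # (variety, family) -> CvReport (best chain)
    all_reports: list = field(default_factory=list)  # every CvReport computed
    importance: list = field(default_factory=list)   # ImportanceProfile list
    failures: list = field(default_factory=list)     # (variety, family, chain, error)


def _load_library(config: ExperimentConfig) -> SpectralLibrary:
    if config.library_path:
        return read_library(config.library_path, varieties=None)
    presets = {v: p for v, p in synthetic_data.default_presets().items()
               if v in config.varieties}
    gen = synthetic_data.GeneratorConfig(
        presets=presets, n_per_variety=config.n_per_variety,
        master_seed=derive_seed(config.master_seed, "simulate"),
    )
    return synthetic_data.generate_library(gen)


def _post_hoc_importance(rep: evaluation.CvReport, library, config) -> list:
    """Per-fold post-hoc profiles for the best model of one (variety, family)."""
    treated = pretreatments.apply_chain(rep.chain_label, library)
    X, y = treated.reflectance, treated.brix
    wl = library.grid.wavelengths
    outer = evaluation.make_folds(len(library), len(rep.folds),
                                  derive_seed(config.master_seed, "outer-folds"))
    profiles = []
    for fm in rep.folds:
        kw = dict(wavelengths=wl, variety=rep.variety, family=rep.family,
                  fold=str(fm.fold + 1))
        if rep.family == "PLS":
            profiles.append(interpretability.vip_scores(fm.model, **kw))
        elif rep.family == "RF":
            profiles.append(interpretability.gini_importance(fm.model, **kw))
        else:  # SVR / CNN: model-agnostic SAGE
            cal = outer.train_indices(fm.fold)
            test = outer.test_indices(fm.fold)
            rng = np.random.default_rng(derive_seed(config.master_seed, "sage", fm.fold))
            ev = test if test.size <= config.sage_eval_rows else \
                rng.choice(test, config.sage_eval_rows, replace=False)
            profiles.append(interpretability.sage_values(
                fm.model, X[cal], X[ev], y[ev],
                n_permutations=config.sage_permutations,
                seed=derive_seed(config.master_seed, "sage-seed", fm.fold), **kw))
    return profiles


def run_experiment(config: ExperimentConfig) -> RunBundle:
    """Run the full design and write metrics/predictions/importance CSVs plus
    a manifest to ``config.output_dir``.  Per-cell failures are recorded and
    the run continues."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    library = _load_library(config)
    bundle = RunBundle(config)

    varieties = [v for v in config.varieties if v in library.variety_names()]
    for variety in varieties:
        sub = library.for_variety(variety)
        # pre-hoc MI on raw reflectance, per variety
        mi = interpretability.mutual_information_profile(
            sub.reflectance, sub.brix,
            seed=derive_seed(config.master_seed, "mi", variety),
            wavelengths=sub.grid.wavelengths, variety=variety, fold="mean")
        bundle.importance.append(mi)
        for family in config.families:
            candidates = []
            for chain in config.chains:
                logger.info(
                    "cell (%s, %s, %s): master seed %d -> outer-fold seed %d",
                    variety, family, chain, config.master_seed,
                    derive_seed(config.master_seed, "outer-folds"))
                try:
                    if family == "CNN":
                        rep = evaluation.nested_cv_hyperband(
                            sub, chain, seed=config.master_seed, budget=config.hyperband)
                    else:
                        rep = evaluation.nested_cv_grid(
                            sub, chain, family, seed=config.master_seed)
                    candidates.append(rep)
                    bundle.all_reports.append(rep)
                except Exception as exc:  # record and continue with other cells
                    logger.error("cell (%s, %s, %s) failed: %s", variety, family, chain, exc)
                    bundle.failures.append(
                        {"variety": variety, "family": family, "chain": chain,
                         "error": f"{exc}", "trace": traceback.format_exc()})
            if candidates:
                best = evaluation.select_best(candidates)
                bundle.reports[(variety, family)] = best
                try:
                    folds = _post_hoc_importance(best, sub, config)
                    bundle.importance.extend(folds)
                    bundle.importance.append(interpretability.mean_rank(folds))
                except Exception as exc:
                    logger.error("importance for (%s, %s) failed: %s", variety, family, exc)
                    bundle.failures.append({"variety": variety, "family": family,
                                            "chain": best.chain_label,
                                            "error": f"importance: {exc}",
                                            "trace": traceback.format_exc()})
    _write_bundle(bundle, out)
    return bundle


def _write_bundle(bundle: RunBundle, out: Path) -> None:
    cfg = bundle.config
    if bundle.all_reports:
        pd.concat([r.metrics_frame() for r in bundle.all_reports],
                  ignore_index=True).to_csv(out / "metrics.csv", index=False)
        rows = [
            {"variety": r.variety, "model": r.family, "pretreatment": r.chain_label,
             "r2": r.mean_r2, "rmse": r.mean_rmse, "rpiq": r.mean_rpiq,
             "global_rpiq": r.global_rpiq,
             "internal_rmse": r.mean_internal_rmse,
             "best": r is bundle.reports.get((r.variety, r.family))}
            for r in bundle.all_reports
        ]
        pd.DataFrame(rows).to_csv(out / "fold_means.csv", index=False)
        preds = []
        for r in bundle.all_reports:
            p = r.predictions.copy()
            p.insert(0, "variety", r.variety)
            p.insert(1, "model", r.family)
            p.insert(2, "pretreatment", r.chain_label)
            preds.append(p)
        pd.concat(preds, ignore_index=True).to_csv(out / "predictions.csv", index=False)
    if bundle.importance:
        rows = []
        for p in bundle.importance:
            wl = p.wavelengths if p.wavelengths is not None else np.arange(p.scores.size)
            se = p.stderr if p.stderr is not None else np.full(p.scores.size, np.nan)
            for w, s, e in zip(wl, p.scores, se):
                rows.append({"method": p.method, "variety": p.variety, "model": p.family,
                             "fold": p.fold, "wavelength_nm": w, "score": s,
                             "mc_stderr": e})
        pd.DataFrame(rows).to_csv(out / "importance.csv", index=False)
    manifest = {
        "master_seed": cfg.master_seed,
        "varieties": list(cfg.varieties),
        "chains": list(cfg.chains),
        "families": list(cfg.families),
        "hyperband": cfg.hyperband.__dict__,
        "n_failures": len(bundle.failures),
        "failures": [{k: v for k, v in f.items() if k != "trace"}
                     for f in bundle.failures],
        "best_cells": {
            f"{v}/{fam}": {
                "pretreatment": r.chain_label,
                "mean_r2": r.mean_r2, "mean_rmse": r.mean_rmse, "mean_rpiq": r.mean_rpiq,
                "chosen_hyperparameters": [f.chosen_params for f in r.folds],
            }
            for (v, fam), r in bundle.reports.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def syrah_cnn_benchmark(seed: int, n: int = 240,
                        n_configs: int = 8) -> evaluation.CvReport:
    """The headline benchmark on synthetic data: a Syrah-like library
    (default presets, n samples), first-derivative reflectance input
    (Ref+SG1), CNN family under nested 5-fold CV with a reduced Hyperband
    budget.  Returns the CvReport with fold-mean R²/RMSE/RPIQ."""
    library = synthetic_data.syrah_library(n=n, seed=derive_seed(seed, "benchmark-lib"))
    return evaluation.nested_cv_hyperband(
        library, "Ref+SG1", seed=seed, budget=HyperbandBudget(n_configs=n_configs))


def report(bundle: RunBundle) -> str:
    """Human-readable summary: per-variety best cells plus top wavelengths."""
    if not bundle.reports and not bundle.failures:
        raise ValueError("incomplete bundle: nothing was run")
    lines = ["variety  model  pretreatment  mean_R2  mean_RMSE  mean_RPIQ  best"]
    by_variety: dict[str, list] = {}
    for (v, fam), r in sorted(bundle.reports.items()):
        by_variety.setdefault(v, []).append(r)
    for v, reps in by_variety.items():
        champion = min(reps, key=lambda r: r.mean_internal_rmse)
        for r in reps:
            flag = "*" if r is champion else " "
            lines.append(f"{v}  {r.family}  {r.chain_label}  "
                         f"{r.mean_r2:.3f}  {r.mean_rmse:.3f}  {r.mean_rpiq:.3f}  {flag}")
    for f in bundle.failures:
        lines.append(f"{f['variety']}  {f['family']}  {f['chain']}  failed: {f['error']}")
    mean_profiles = [p for p in bundle.importance if p.fold == "mean"]
    for p in mean_profiles:
        if p.wavelengths is None:
            continue
        top = interpretability.top_wavelengths(p, 10)
        label = f"{p.method}/{p.variety}" + (f"/{p.family}" if p.family else "")
        lines.append(f"top-10 {label}: " + ", ".join(f"{w:.0f}" for w in top))
    return "\n".join(lines)
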