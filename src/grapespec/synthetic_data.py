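"""Synthetic grape-spectra generator.

Field VNIR-SWIR grape libraries are rarely deposited, so this module generates
libraries carrying the statistical structure the pipeline assumes:

* smooth reflectance baselines (a sigmoidal visible edge plus a gentle SWIR
  tilt), darker through 450-700 nm for the red variety (Syrah);
* fixed absorbance features near 680, 970, 1200, 1440 and 1920 nm (pigment and
  water bands), so mean spectra show the canonical dips;
* sugar-coupled Gaussian band depths at 680, 730, 920, 960 and 1150 nm —
  band depth increases linearly with °Brix, a Beer-Lambert-like coupling;
* per-sample multiplicative/additive scatter and per-detector-region noise
  (three detector regions: 350-1000, 1000-1910, 1910-2500 nm);
* truncated-normal °Brix distributions whose moments default to the observed
  per-variety field statistics (mean/sd/min/max per variety).

The generative model for one sample with sugar content ``b`` (°Brix) is::

    R(lam) = baseline(lam) * exp(-sum_k depth_k * G(lam; c_k, w_k))
             * (1 + m0 + m1 * t(lam)) + a0 + noise(lam)

    depth_k = (base_depth_k + coupling_k * b) * (1 + jitter_k)

with G a unit-height Gaussian, t(lam) a centered linear ramp, m0/m1/a0
per-sample scatter draws and jitter_k per-sample, per-band depth variation
independent of °Brix (the irreducible-noise term that caps the attainable
R-squared).  Reflectance is clipped to (0, 1.2].

The couplings are tunable stand-ins for the (unknown) °Brix/band-depth
relationship of real grapes; they are chosen so the noiseless linear signal
ceiling is about R² = 0.95, not estimated from grape chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .spectral_library import (
    CANONICAL_GRID,
    NATIVE_GRID,
    SpectralLibrary,
    WavelengthGrid,
)

__all__ = [
    "BandSpec",
    "VarietyPreset",
    "GeneratorConfig",
    "default_presets",
    "sample_brix",
    "generate_spectrum",
    "generate_library",
    "FIXED_BANDS",
    "SUGAR_BANDS",
]

#: Global plausibility window of field °Brix values.
GLOBAL_BRIX_RANGE = (4.2, 31.4)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    ``depth(b) = base_depth + sugar_coupling * b`` at °Brix ``b``; ``width``
    is the Gaussian sigma in nm; ``depth_jitter_sd`` is the s.d. of the
    per-sample multiplicative depth jitter (°Brix-independent)."""

    center: float
    width: float
    base_depth: float
    sugar_coupling: float = 0.0
    depth_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band at {self.center} nm: width must be > 0")
        if self.base_depth < 0:
            raise ValueError(f"band at {self.center} nm: base_depth must be >= 0")


#: Pigment and water bands present regardless of sugar content.
FIXED_BANDS = (
    BandSpec(center=680.0, width=25.0, base_depth=0.22, depth_jitter_sd=0.05),
    BandSpec(center=970.0, width=30.0, base_depth=0.16, depth_jitter_sd=0.05),
    BandSpec(center=1200.0, width=35.0, base_depth=0.45, depth_jitter_sd=0.05),
    BandSpec(center=1440.0, width=45.0, base_depth=0.60, depth_jitter_sd=0.05),
    BandSpec(center=1920.0, width=55.0, base_depth=1.00, depth_jitter_sd=0.05),
)

#: Sugar-coupled bands in the informative 550-1300 nm window.  Couplings are
#: calibrated so ordinary least squares on noiseless pseudo-absorbance spectra
#: attains about R² = 0.95 (the generator's signal ceiling).
SUGAR_BANDS = (
    BandSpec(center=680.0, width=22.0, base_depth=0.02, sugar_coupling=0.0110, depth_jitter_sd=0.11),
    BandSpec(center=730.0, width=20.0, base_depth=0.02, sugar_coupling=0.0130, depth_jitter_sd=0.11),
    BandSpec(center=920.0, width=24.0, base_depth=0.02, sugar_coupling=0.0100, depth_jitter_sd=0.11),
    BandSpec(center=960.0, width=18.0, base_depth=0.02, sugar_coupling=0.0085, depth_jitter_sd=0.11),
    BandSpec(center=1150.0, width=18.0, base_depth=0.02, sugar_coupling=0.0090, depth_jitter_sd=0.11),
)


@dataclass(frozen=True)
class VarietyPreset:
    """Everything needed to generate one variety's spectra and °Brix values."""

    name: str
    brix_mean: float
    brix_sd: float
    brix_min: float
    brix_max: float
    # baseline albedo: low + (high-low)*sigmoid((lam-edge)/edge_width) - swir_tilt*ramp
    baseline_low: float = 0.08
    baseline_high: float = 0.68
    baseline_edge: float = 560.0
    baseline_edge_width: float = 60.0
    swir_tilt: float = 0.12
    bands: tuple[BandSpec, ...] = FIXED_BANDS + SUGAR_BANDS
    scatter_mult_sd: float = 0.03
    scatter_slope_sd: float = 0.015
    scatter_add_sd: float = 0.008
    # per-detector noise sd (reflectance units): 350-1000 / 1000-1910 / 1910-2500 nm
    noise_sd: tuple[float, float, float] = (0.002, 0.004, 0.006)

    def __post_init__(self) -> None:
        lo, hi = GLOBAL_BRIX_RANGE
        if not (lo <= self.brix_min < self.brix_max <= hi):
            raise ValueError(
                f"preset {self.name}: °Brix window [{self.brix_min}, {self.brix_max}] "
                f"must lie within the global range [{lo}, {hi}]"
            )


def default_presets() -> dict[str, VarietyPreset]:
    """Presets for the four varieties, °Brix moments as observed in the field
    campaigns (per-variety mean/sd/min/max); Syrah (red) gets a lower albedo
    through the visible by shifting the baseline edge toward 700 nm."""
    common = dict(bands=FIXED_BANDS + SUGAR_BANDS)
    return {
        "Chardonnay": VarietyPreset(
            "Chardonnay", brix_mean=19.73, brix_sd=3.62, brix_min=10.0, brix_max=30.0, **common
        ),
        "Malagouzia": VarietyPreset(
            "Malagouzia", brix_mean=18.63, brix_sd=5.06, brix_min=6.8, brix_max=30.0, **common
        ),
        "Sauvignon-Blanc": VarietyPreset(
            "Sauvignon-Blanc", brix_mean=17.61, brix_sd=6.14, brix_min=4.2, brix_max=31.4, **common
        ),
        "Syrah": VarietyPreset(
            "Syrah", brix_mean=17.22, brix_sd=5.04, brix_min=4.9, brix_max=30.0,
            baseline_edge=690.0, baseline_edge_width=45.0, baseline_high=0.60, **common
        ),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration for library generation."""

    presets: dict[str, VarietyPreset] = field(default_factory=default_presets)
    n_per_variety: int = 60
    grid_step: float = 10.0  # 1.0 for the instrument-native grid
    master_seed: int = 0
    years: tuple[int, ...] = (2020, 2021)

    def __post_init__(self) -> None:
        if self.n_per_variety < 1:
            raise ValueError("n_per_variety must be >= 1")
        if self.grid_step not in (1.0, 10.0):
            raise ValueError("grid_step must be 1 (native) or 10 (canonical)")


def _grid_for_step(step: float) -> np.ndarray:
    return NATIVE_GRID if step == 1.0 else CANONICAL_GRID


def sample_brix(preset: VarietyPreset, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Truncated-normal °Brix draws with the preset's mean/sd, clipped to
    [preset.brix_min, preset.brix_max]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if preset.brix_sd == 0:
        return np.full(n, preset.brix_mean)
    a = (preset.brix_min - preset.brix_mean) / preset.brix_sd
    b = (preset.brix_max - preset.brix_mean) / preset.brix_sd
    return truncnorm.rvs(a, b, loc=preset.brix_mean, scale=preset.brix_sd,
                         size=n, random_state=rng)


def _baseline(preset: VarietyPreset, wl: np.ndarray) -> np.ndarray:
    edge = 1.0 / (1.0 + np.exp(-(wl - preset.baseline_edge) / preset.baseline_edge_width))
    ramp = np.clip((wl - 1000.0) / 1500.0, 0.0, None)
    return preset.baseline_low + (preset.baseline_high - preset.baseline_low) * edge \
        - preset.swir_tilt * ramp


def generate_spectrum(
    brix: float,
    preset: VarietyPreset,
    seed: int | np.random.Generator,
    wavelengths: np.ndarray | None = None,
    noise: bool = True,
    scatter: bool = True,
) -> np.ndarray:
    """Generate one reflectance spectrum for a sample with the given °Brix.

    ``noise=False`` and/or ``scatter=False`` switch off the stochastic terms
    (the depth jitter counts as scatter), which is useful for inspecting the
    deterministic part of the generative model.
    """
    rng = np.random.default_rng(seed)
    wl = NATIVE_GRID if wavelengths is None else np.asarray(wavelengths, dtype=float)

    absorb = np.zeros_like(wl)
    for band in preset.bands:
        depth = band.base_depth + band.sugar_coupling * brix
        if depth < 0:
            raise ValueError(
                f"band at {band.center} nm: depth {depth:.4f} < 0 at {brix} °Brix"
            )
        jitter = rng.normal(0.0, band.depth_jitter_sd) if scatter else 0.0
        depth = depth * max(0.0, 1.0 + jitter)
        absorb += depth * np.exp(-0.5 * ((wl - band.center) / band.width) ** 2)

    r = _baseline(preset, wl) * np.exp(-absorb)

    if scatter:
        m0 = rng.normal(0.0, preset.scatter_mult_sd)
        m1 = rng.normal(0.0, preset.scatter_slope_sd)
        a0 = rng.normal(0.0, preset.scatter_add_sd)
        t = (wl - wl.mean()) / (wl[-1] - wl[0])
        r = r * (1.0 + m0 + m1 * t) + a0

    if noise:
        sd = np.where(wl < 1000.0, preset.noise_sd[0],
                      np.where(wl < 1910.0, preset.noise_sd[1], preset.noise_sd[2]))
        r = r + rng.normal(0.0, 1.0, wl.size) * sd

    return np.clip(r, 1e-4, 1.2)


def generate_library(config: GeneratorConfig) -> SpectralLibrary:
    """Generate a full multi-variety library on the requested grid.

    Deterministic given ``config.master_seed``: the master seed is fanned out
    per variety and per sample via ``numpy.random.SeedSequence``.
    """
    wl = _grid_for_step(config.grid_step)
    ids: list[str] = []
    varieties: list[str] = []
    years: list[int] = []
    bunches: list[str] = []
    brix_all: list[float] = []
    spectra: list[np.ndarray] = []

    for vi, (name, preset) in enumerate(sorted(config.presets.items())):
        ss = np.random.SeedSequence([config.master_seed, vi])
        brix_rng, spec_rng, meta_rng = [np.random.default_rng(s) for s in ss.spawn(3)]
        brix = sample_brix(preset, config.n_per_variety, brix_rng)
        tag = name[:3].upper()
        for i in range(config.n_per_variety):
            ids.append(f"{tag}-{i:04d}")
            varieties.append(name)
            years.append(int(meta_rng.choice(config.years)))
            bunches.append(f"{tag}-B{int(meta_rng.integers(1, 31)):02d}")
            brix_all.append(float(brix[i]))
            spectra.append(generate_spectrum(brix[i], preset, spec_rng, wavelengths=wl))

    return SpectralLibrary(
        grid=WavelengthGrid(wl),
        sample_ids=ids,
        varieties=varieties,
        years=np.asarray(years),
        bunch_labels=bunches,
        brix=np.asarray(brix_all),
        reflectance=np.vstack(spectra),
    )


def load_presets(path) -> dict[str, VarietyPreset]:
    """Read variety presets from a declarative YAML document.

    Top level maps variety name -> preset fields; ``bands`` is a list of
    BandSpec field mappings and defaults to the built-in band set when absent.
    """
    import yaml

    raw = yaml.safe_load(open(path)) or {}
    presets = {}
    for name, fields in raw.items():
        fields = dict(fields)
        bands = fields.pop("bands", None)
        band_specs = tuple(BandSpec(**b) for b in bands) if bands \
            else FIXED_BANDS + SUGAR_BANDS
        if "noise_sd" in fields:
            fields["noise_sd"] = tuple(fields["noise_sd"])
        presets[name] = VarietyPreset(name=name, bands=band_specs, **fields)
    return presets


def dump_presets(presets: dict[str, VarietyPreset], path) -> None:
    """Write presets to YAML (inverse of :func:`load_presets`)."""
    import dataclasses

    import yaml

    doc = {}
    for name, p in presets.items():
        d = dataclasses.asdict(p)
        d.pop("name")
        d["noise_sd"] = list(d["noise_sd"])
        d["bands"] = [dict(b) for b in d["bands"]]
        doc[name] = d
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def syrah_library(n: int = 240, seed: int = 0, grid_step: float = 10.0) -> SpectralLibrary:
    """Convenience: a single-variety Syrah-like library (the red-grape preset)."""
    presets = {"Syrah": default_presets()["Syrah"]}
    cfg = GeneratorConfig(presets=presets, n_per_variety=n, grid_step=grid_step,
                          master_seed=seed)
    return generate_library(cfg)
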