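"""Spectral pre-treatments and the nine named spectral inputs.

Chemometric pre-treatments fall into scatter correction (SNV, continuum
removal) and derivatives (Savitzky-Golay).  Reflectance R may first be mapped
to pseudo-absorbance A = -log10(R), which the empirical Beer-Lambert law
suggests is more nearly linear in constituent concentration.  The registry
enumerates the nine spectral inputs used for modelling:

    Ref, Ref+SNV, Ref+SG1, Abs, Abs+SNV, Abs+SG1, Abs+SG1+SNV,
    Abs+SG2+SNV, CR

where SG1/SG2 are first/second Savitzky-Golay derivatives (window 5,
polynomial order 3) and CR divides reflectance by its upper convex hull.
All transforms are per-spectrum (stateless across samples), so they may be
applied before cross-validation splitting without information leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectral_library import SpectralLibrary, WavelengthGrid

__all__ = [
    "Transform",
    "PretreatmentChain",
    "snv",
    "to_absorbance",
    "savitzky_golay",
    "continuum_removal",
    "apply_chain",
    "apply_chain_matrix",
    "registry",
    "get_chain",
    "CHAIN_LABELS",
]

logger = logging.getLogger(__name__)

#: Reflectance floor applied before -log10; field spectra can contain
#: non-positive noise and an error would make whole libraries unusable.
ABSORBANCE_FLOOR = 1e-4

SG_WINDOW = 5
SG_POLY = 3


@dataclass(frozen=True)
class Transform:
    """One named pre-treatment step with its parameters."""

    name: str  # one of {"SNV", "SG", "Abs", "CR"}
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name == "SG":
            w, p, d = self.params["window"], self.params["poly"], self.params["deriv"]
            if w % 2 == 0 or w < p + 1:
                raise ValueError("SG window must be odd and >= poly + 1")
            if d not in (0, 1, 2) or d > p:
                raise ValueError("SG deriv must be in {0,1,2} and <= poly")
        elif self.name not in ("SNV", "Abs", "CR"):
            raise ValueError(f"unknown transform {self.name!r}")


@dataclass(frozen=True)
class PretreatmentChain:
    """A named, ordered pre-treatment sequence producing one spectral input."""

    label: str
    steps: tuple[Transform, ...]


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: center and scale one spectrum to unit sample
    (ddof=1) standard deviation."""
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise ValueError("SNV needs at least 2 bands")
    sd = np.std(x, ddof=1)
    if sd <= 1e-12 * max(1.0, abs(float(x.mean()))):
        raise ValueError("SNV undefined for a constant spectrum (zero variance)")
    return (x - x.mean()) / sd


def to_absorbance(spectrum: np.ndarray, floor: float = ABSORBANCE_FLOOR) -> np.ndarray:
    """Pseudo-absorbance A = -log10(R); reflectance below ``floor`` is clamped
    (and logged) so noisy non-positive values do not poison the spectrum."""
    x = np.asarray(spectrum, dtype=float)
    n_clamped = int(np.sum(x < floor))
    if n_clamped:
        logger.warning("to_absorbance: clamped %d reflectance value(s) to %g", n_clamped, floor)
        x = np.maximum(x, floor)
    return -np.log10(x)


def savitzky_golay(
    spectrum: np.ndarray,
    window: int = SG_WINDOW,
    poly: int = SG_POLY,
    deriv: int = 1,
    step: float = 10.0,
) -> np.ndarray:
    """Savitzky-Golay filtering/derivative: local least-squares polynomial fit
    per window.

    Derivatives are returned in per-nm units (scipy's ``delta=step``), so the
    result is invariant to the grid resolution.  At the edges the polynomial
    of the nearest full window is evaluated (asymmetric evaluation), keeping
    output length equal to input length.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.size < window:
        raise ValueError(f"spectrum length {x.size} < window {window}")
    Transform("SG", {"window": window, "poly": poly, "deriv": deriv})  # validate
    return savgol_filter(x, window_length=window, polyorder=poly, deriv=deriv,
                         delta=step, mode="interp")


def _upper_hull(wl: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Indices of the upper convex hull (monotone chain, left to right).

    Collinear points are retained as hull vertices, so a point lying exactly
    on the chord between its hull neighbours gets a continuum-removed value of
    exactly 1.
    """
    hull: list[int] = []
    for i in range(wl.size):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            cross = (wl[i1] - wl[i0]) * (r[i] - r[i0]) - (r[i1] - r[i0]) * (wl[i] - wl[i0])
            if cross > 0:  # i1 lies strictly below chord i0->i: not an upper-hull vertex
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def continuum_removal(spectrum: np.ndarray, grid: WavelengthGrid | np.ndarray) -> np.ndarray:
    """Divide a reflectance spectrum by its upper convex hull (the continuum).

    Output lies in (0, 1], equals 1 at hull vertices (always including both
    endpoints), and is invariant to multiplying the spectrum by a positive
    constant.
    """
    wl = grid.wavelengths if isinstance(grid, WavelengthGrid) else np.asarray(grid, dtype=float)
    r = np.asarray(spectrum, dtype=float)
    if r.size < 2:
        raise ValueError("continuum removal needs at least 2 bands")
    if np.any(r <= 0):
        raise ValueError("continuum removal requires positive reflectance")
    hull = _upper_hull(wl, r)
    continuum = np.interp(wl, wl[hull], r[hull])
    return r / continuum


def _chain(label: str, *steps: Transform) -> PretreatmentChain:
    return PretreatmentChain(label, tuple(steps))


def _sg(deriv: int) -> Transform:
    return Transform("SG", {"window": SG_WINDOW, "poly": SG_POLY, "deriv": deriv})


def registry() -> list[PretreatmentChain]:
    """The nine spectral inputs, in canonical order."""
    SNV, ABS, CR = Transform("SNV"), Transform("Abs"), Transform("CR")
    return [
        _chain("Ref"),
        _chain("Ref+SNV", SNV),
        _chain("Ref+SG1", _sg(1)),
        _chain("Abs", ABS),
        _chain("Abs+SNV", ABS, SNV),
        _chain("Abs+SG1", ABS, _sg(1)),
        _chain("Abs+SG1+SNV", ABS, _sg(1), SNV),
        _chain("Abs+SG2+SNV", ABS, _sg(2), SNV),
        _chain("CR", CR),
    ]


CHAIN_LABELS = tuple(c.label for c in registry())


def get_chain(label: str) -> PretreatmentChain:
    for chain in registry():
        if chain.label == label:
            return chain
    raise KeyError(f"unknown pre-treatment label {label!r}; valid labels: {list(CHAIN_LABELS)}")


def _apply_step(step: Transform, x: np.ndarray, wl: np.ndarray, grid_step: float) -> np.ndarray:
    if step.name == "SNV":
        return snv(x)
    if step.name == "Abs":
        return to_absorbance(x)
    if step.name == "SG":
        return savitzky_golay(x, step.params["window"], step.params["poly"],
                              step.params["deriv"], grid_step)
    if step.name == "CR":
        return continuum_removal(x, wl)
    raise ValueError(f"unknown transform {step.name!r}")


def apply_chain_matrix(
    chain: PretreatmentChain | str, X: np.ndarray, grid: WavelengthGrid
) -> np.ndarray:
    """Apply a chain to a (n_samples, n_bands) matrix, row by row."""
    if isinstance(chain, str):
        chain = get_chain(chain)
    wl = grid.wavelengths
    step_nm = grid.step
    out = np.asarray(X, dtype=float).copy()
    for t in chain.steps:
        out = np.vstack([_apply_step(t, row, wl, step_nm) for row in out])
    return out


def apply_chain(chain: PretreatmentChain | str, library: SpectralLibrary) -> SpectralLibrary:
    """Apply a pre-treatment chain to every spectrum of a library.

    Equals the left-to-right composition of the individual transforms; °Brix
    and metadata are untouched.  The label "Ref" is the identity.
    """
    if isinstance(chain, str):
        chain = get_chain(chain)
    return library.with_spectra(apply_chain_matrix(chain, library.reflectance, library.grid))
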