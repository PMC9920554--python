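"""Grape spectral library: data model, CSV I/O, downsampling, °Brix summaries.

A library couples per-sample VNIR-SWIR reflectance spectra (350-2500 nm) with
the refractometric ground truth (°Brix) and field metadata (variety, year,
bunch label).  All modelling downstream operates on one shared wavelength
grid; the canonical modelling grid is 350 + 10k nm for k = 0..215 (216 bands),
obtained from the 1 nm instrument grid (2151 points) by window-mean
downsampling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NATIVE_GRID",
    "CANONICAL_GRID",
    "DEFAULT_VARIETIES",
    "DEFAULT_BRIX_WINDOW",
    "LibraryError",
    "WavelengthGrid",
    "SampleRecord",
    "SpectralLibrary",
    "read_library",
    "write_library",
    "downsample",
    "summarize",
]

#: Instrument-native wavelength grid: 350..2500 nm at 1 nm (2151 points).
NATIVE_GRID = np.arange(350, 2501, 1, dtype=float)

#: Canonical modelling grid: 350..2500 nm at 10 nm (216 bands).
CANONICAL_GRID = np.arange(350, 2501, 10, dtype=float)

#: Default variety labels for validation in experiment configs.
DEFAULT_VARIETIES = ("Chardonnay", "Malagouzia", "Sauvignon-Blanc", "Syrah")

#: Plausibility window for °Brix: the refractometer scale is 0-32 °Brix.
DEFAULT_BRIX_WINDOW = (0.0, 32.0)

_META_COLUMNS = ["sample_id", "variety", "year", "bunch_label", "brix"]


class LibraryError(ValueError):
    """Raised for malformed library files or invalid library contents."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band centers in nm, all within [350, 2500]."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        if w.ndim != 1 or w.size < 1:
            raise LibraryError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(w) <= 0):
            raise LibraryError("non-monotone grid: wavelengths must be strictly increasing")
        if w[0] < 350.0 or w[-1] > 2500.0:
            raise LibraryError("wavelengths must lie within [350, 2500] nm")

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def step(self) -> float:
        """Uniform grid step in nm; raises if the grid is irregular."""
        d = np.diff(self.wavelengths)
        if d.size == 0:
            raise LibraryError("single-band grid has no step")
        if not np.allclose(d, d[0]):
            raise LibraryError("grid is not uniformly spaced")
        return float(d[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and bool(
            np.allclose(self.wavelengths, other.wavelengths)
        )


@dataclass(frozen=True)
class SampleRecord:
    """One grape measurement: a reflectance spectrum plus its °Brix value."""

    sample_id: str
    variety: str
    year: int
    bunch_label: str
    brix: float
    reflectance: np.ndarray


@dataclass
class SpectralLibrary:
    """An ordered collection of samples sharing one wavelength grid.

    Spectra are stored as a dense (n_samples, n_bands) matrix for efficient
    whole-library transforms; `records()` iterates row-wise views.
    """

    grid: WavelengthGrid
    sample_ids: list[str]
    varieties: list[str]
    years: np.ndarray
    bunch_labels: list[str]
    brix: np.ndarray
    reflectance: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        self.years = np.asarray(self.years, dtype=int)
        self.brix = np.asarray(self.brix, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float).reshape(n, len(self.grid))
        if len(set(self.sample_ids)) != n:
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise LibraryError(f"duplicate sample_id(s): {dupes}")
        for name, seq in (("varieties", self.varieties), ("bunch_labels", self.bunch_labels)):
            if len(seq) != n:
                raise LibraryError(f"{name} length {len(seq)} != {n} samples")
        if self.years.size != n or self.brix.size != n:
            raise LibraryError("metadata arrays must match the number of samples")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def records(self) -> Iterator[SampleRecord]:
        for i in range(len(self)):
            yield SampleRecord(
                self.sample_ids[i],
                self.varieties[i],
                int(self.years[i]),
                self.bunch_labels[i],
                float(self.brix[i]),
                self.reflectance[i],
            )

    def subset(self, index: Sequence[int]) -> "SpectralLibrary":
        idx = np.asarray(index, dtype=int)
        return SpectralLibrary(
            grid=self.grid,
            sample_ids=[self.sample_ids[i] for i in idx],
            varieties=[self.varieties[i] for i in idx],
            years=self.years[idx],
            bunch_labels=[self.bunch_labels[i] for i in idx],
            brix=self.brix[idx],
            reflectance=self.reflectance[idx],
        )

    def for_variety(self, variety: str) -> "SpectralLibrary":
        idx = [i for i, v in enumerate(self.varieties) if v == variety]
        if not idx:
            raise LibraryError(f"no samples for variety {variety!r}")
        return self.subset(idx)

    def variety_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.varieties:
            seen.setdefault(v)
        return list(seen)

    def with_spectra(self, X: np.ndarray, grid: WavelengthGrid | None = None) -> "SpectralLibrary":
        """Copy of the library with spectra (and optionally grid) replaced."""
        return SpectralLibrary(
            grid=grid or self.grid,
            sample_ids=list(self.sample_ids),
            varieties=list(self.varieties),
            years=self.years.copy(),
            bunch_labels=list(self.bunch_labels),
            brix=self.brix.copy(),
            reflectance=np.asarray(X, dtype=float),
        )

    def equals(self, other: "SpectralLibrary", rtol: float = 0.0, atol: float = 1e-6) -> bool:
        return (
            self.grid == other.grid
            and self.sample_ids == other.sample_ids
            and self.varieties == other.varieties
            and bool(np.array_equal(self.years, other.years))
            and self.bunch_labels == other.bunch_labels
            and bool(np.allclose(self.brix, other.brix, rtol=rtol, atol=atol))
            and bool(np.allclose(self.reflectance, other.reflectance, rtol=rtol, atol=atol))
        )


def _parse_grid_header(columns: Sequence[str]) -> WavelengthGrid:
    if list(columns[: len(_META_COLUMNS)]) != _META_COLUMNS:
        raise LibraryError(
            f"library CSV must start with columns {_META_COLUMNS}, got {list(columns[:5])}"
        )
    wl_cols = columns[len(_META_COLUMNS):]
    if not wl_cols:
        raise LibraryError("library CSV has no wavelength columns")
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise LibraryError(f"non-numeric wavelength column name: {exc}") from None
    return WavelengthGrid(wavelengths)


def read_library(
    path: str | Path | io.TextIOBase,
    brix_window: tuple[float, float] = DEFAULT_BRIX_WINDOW,
    varieties: Sequence[str] | None = None,
) -> SpectralLibrary:
    """Read a library CSV (``sample_id, variety, year, bunch_label, brix, 350, ...``).

    Row order is preserved.  Rejects duplicate/missing sample ids, non-numeric
    reflectance, a non-monotone wavelength header, or °Brix outside
    ``brix_window``, with row-level diagnostics in the error message.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "variety": str, "bunch_label": str})
    grid = _parse_grid_header(list(df.columns))

    problems: list[str] = []
    if df["sample_id"].isna().any() or (df["sample_id"].astype(str).str.strip() == "").any():
        rows = df.index[df["sample_id"].isna() | (df["sample_id"].astype(str).str.strip() == "")]
        problems.append(f"missing sample_id in rows {list(rows)}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        problems.append(f"duplicate sample_id(s): {sorted(set(dupes))}")

    brix = pd.to_numeric(df["brix"], errors="coerce")
    bad_brix = df.index[brix.isna()].tolist()
    if bad_brix:
        problems.append(f"non-numeric brix in rows {bad_brix}")
    lo, hi = brix_window
    out = df.index[(brix < lo) | (brix > hi)].tolist()
    if out:
        problems.append(f"brix outside [{lo}, {hi}] in rows {out}")

    refl = df.iloc[:, len(_META_COLUMNS):].apply(pd.to_numeric, errors="coerce")
    bad_cells = refl.isna()
    if bad_cells.to_numpy().any():
        rows = refl.index[bad_cells.any(axis=1)].tolist()
        problems.append(f"non-numeric reflectance in rows {rows}")

    if varieties is not None:
        unknown = sorted(set(df["variety"]) - set(varieties))
        if unknown:
            problems.append(f"unknown variety label(s): {unknown}")

    if problems:
        raise LibraryError("invalid library file: " + "; ".join(problems))

    return SpectralLibrary(
        grid=grid,
        sample_ids=df["sample_id"].tolist(),
        varieties=df["variety"].tolist(),
        years=df["year"].to_numpy(dtype=int),
        bunch_labels=df["bunch_label"].astype(str).tolist(),
        brix=brix.to_numpy(dtype=float),
        reflectance=refl.to_numpy(dtype=float),
    )


def write_library(library: SpectralLibrary, path: str | Path | io.TextIOBase) -> None:
    """Write the library CSV.  °Brix is printed with 2 decimals (refractometer
    resolution 0.2 °Brix); spectra with 8 significant digits."""
    wl = library.grid.wavelengths
    wl_names = [str(int(w)) if float(w).is_integer() else repr(float(w)) for w in wl]
    meta = pd.DataFrame(
        {
            "sample_id": library.sample_ids,
            "variety": library.varieties,
            "year": library.years,
            "bunch_label": library.bunch_labels,
            "brix": [f"{b:.2f}" for b in library.brix],
        }
    )
    spec = pd.DataFrame(library.reflectance, columns=wl_names)
    spec = spec.map(lambda v: f"{v:.8g}")
    pd.concat([meta, spec.set_index(meta.index)], axis=1).to_csv(path, index=False)


def downsample(
    library: SpectralLibrary, step: float, method: str = "mean"
) -> SpectralLibrary:
    """Downsample each spectrum to a coarser uniform grid.

    The output grid is {min_wl + step*k} truncated at the input maximum.  With
    ``method="mean"`` (default) each output band is the mean of input bands
    whose wavelength lies in the half-open centered window
    [wl_k - step/2, wl_k + step/2), intersected with the available range;
    ``method="decimate"`` keeps the sample at the band center.  Metadata and
    °Brix are unchanged.
    """
    in_step = library.grid.step
    if step < in_step:
        raise LibraryError(f"requested step {step} nm is finer than the input step {in_step} nm")
    ratio = step / in_step
    if abs(ratio - round(ratio)) > 1e-9:
        raise LibraryError(f"input step {in_step} nm does not divide the requested step {step} nm")

    wl = library.grid.wavelengths
    out_wl = np.arange(wl[0], wl[-1] + 1e-9, step)
    if method == "decimate":
        idx = np.searchsorted(wl, out_wl)
        X = library.reflectance[:, idx]
    elif method == "mean":
        X = np.empty((len(library), out_wl.size))
        for k, c in enumerate(out_wl):
            mask = (wl >= c - step / 2.0) & (wl < c + step / 2.0)
            X[:, k] = library.reflectance[:, mask].mean(axis=1)
    else:
        raise LibraryError(f"unknown downsampling method {method!r}")
    return library.with_spectra(X, grid=WavelengthGrid(out_wl))


def summarize(library: SpectralLibrary) -> pd.DataFrame:
    """Per-variety descriptive statistics of °Brix.

    Columns: count, mean, std, min, q1, q2, q3, max.  Quartiles use linear
    interpolation between order statistics (the spreadsheet convention, the
    same one the RPIQ metric uses); std is the sample (ddof=1) standard
    deviation, reported as 0 for a single record.
    """
    if len(library) == 0:
        raise LibraryError("cannot summarize an empty library")
    rows = []
    for variety in library.variety_names():
        b = library.brix[np.asarray(library.varieties) == variety]
        std = float(np.std(b, ddof=1)) if b.size > 1 else 0.0
        q1, q2, q3 = np.percentile(b, [25, 50, 75])
        rows.append(
            {
                "variety": variety,
                "count": int(b.size),
                "mean": float(np.mean(b)),
                "std": std,
                "min": float(np.min(b)),
                "q1": float(q1),
                "q2": float(q2),
                "q3": float(q3),
                "max": float(np.max(b)),
            }
        )
    return pd.DataFrame(rows).set_index("variety")
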