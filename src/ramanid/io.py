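"""Reading, writing and validation of labelled single-cell Raman spectrum sets.

A *Ramanome* is a collection of single-cell Raman spectra (SCRS) sampled from
a cell population.  On disk it is a plain delimited-text matrix: one row per
cell, one column per wavenumber, plus label columns identifying the cell, its
species/subspecies and its biological replicate.  In memory it is a
:class:`SpectrumSet` — an intensity matrix on a shared, strictly increasing
wavenumber axis with per-cell labels.

Two text formats are supported:

``wide-csv``
    columns ``cell_id,species,replicate,<wn1>,<wn2>,...`` — the canonical
    format; wavenumber column headers are the axis.
``long-csv``
    columns ``cell_id,species,replicate,wavenumber,intensity`` — one row per
    (cell, wavenumber) pair; every cell must carry the identical axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LABEL_COLUMNS = ("cell_id", "species", "replicate")

__all__ = [
    "LABEL_COLUMNS",
    "SpectrumSet",
    "SpectrumValidationError",
    "make_axis",
    "read_spectra",
    "write_spectra",
    "resample_to_grid",
]


class SpectrumValidationError(ValueError):
    """Raised when a spectrum collection violates a structural invariant."""


def make_axis(values: Iterable[float]) -> np.ndarray:
    """Validate and return a wavenumber axis (strictly increasing, finite, cm⁻¹).

    Unsorted input is an error, never silently reordered: column order in a
    spectral matrix is meaningful and a surprise beats a silent fix.
    """
    axis = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                      dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise SpectrumValidationError("wavenumber axis needs at least 2 points")
    if not np.all(np.isfinite(axis)):
        raise SpectrumValidationError("wavenumber axis contains non-finite values")
    if not np.all(np.diff(axis) > 0):
        raise SpectrumValidationError("wavenumber axis must be strictly increasing")
    return axis


@dataclass(eq=False)
class SpectrumSet:
    """Labelled intensity matrix on a shared wavenumber axis.

    Attributes
    ----------
    axis : ndarray, shape (p,)
        Strictly increasing wavenumbers in cm⁻¹.
    intensities : ndarray, shape (n_cells, p)
        Raman intensities (arbitrary counts before normalization).
    labels : DataFrame
        One row per cell with columns ``cell_id``, ``species``, ``replicate``.
    meta : dict
        Free-form provenance (e.g. the preprocessing config applied).
    """

    axis: np.ndarray
    intensities: np.ndarray
    labels: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = make_axis(self.axis)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.size == 0:
            self.intensities = self.intensities.reshape(0, self.axis.size)
        self.labels = pd.DataFrame(self.labels).reset_index(drop=True)
        missing = [c for c in LABEL_COLUMNS if c not in self.labels.columns]
        if missing:
            raise SpectrumValidationError(f"label table missing columns: {missing}")
        self.labels = self.labels.astype({c: str for c in LABEL_COLUMNS})
        if self.intensities.shape[0] != len(self.labels):
            raise SpectrumValidationError(
                f"{self.intensities.shape[0]} spectra but {len(self.labels)} label rows")
        if self.intensities.shape[1] != self.axis.size:
            raise SpectrumValidationError(
                f"{self.intensities.shape[1]} intensity columns but axis has "
                f"{self.axis.size} points")
        if not np.all(np.isfinite(self.intensities)):
            raise SpectrumValidationError("intensities contain non-finite values")
        ids = self.labels["cell_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise SpectrumValidationError(f"duplicate cell_ids: {dupes[:5]}")

    @property
    def n_cells(self) -> int:
        return self.intensities.shape[0]

    @property
    def species(self) -> np.ndarray:
        """Species label per cell, aligned with intensity rows."""
        return self.labels["species"].to_numpy()

    def select(self, mask) -> "SpectrumSet":
        """Subset cells by boolean mask or integer positions (labels follow)."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpectrumSet(self.axis, self.intensities[idx],
                           self.labels.iloc[idx], dict(self.meta))

    def equals(self, other: "SpectrumSet", rtol: float = 1e-9) -> bool:
        return (np.array_equal(self.axis, other.axis)
                and self.labels[list(LABEL_COLUMNS)].equals(
                    other.labels[list(LABEL_COLUMNS)])
                and np.allclose(self.intensities, other.intensities,
                                rtol=rtol, atol=0.0))


def read_spectra(path: str | Path, format: str = "wide-csv") -> SpectrumSet:
    """Read a labelled spectrum collection from delimited text.

    Parameters
    ----------
    path : file path
    format : {"wide-csv", "long-csv"}

    Raises
    ------
    SpectrumValidationError
        Missing label columns, inconsistent axes between cells, or
        non-numeric intensities (the offending row/column is named).
    """
    path = Path(path)
    if format == "wide-csv":
        return _read_wide(path)
    if format == "long-csv":
        return _read_long(path)
    raise ValueError(f"unknown format {format!r}; use 'wide-csv' or 'long-csv'")


def _read_wide(path: Path) -> SpectrumSet:
    df = pd.read_csv(path, dtype={c: str for c in LABEL_COLUMNS})
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise SpectrumValidationError(f"{path}: missing columns {missing}")
    wn_cols = [c for c in df.columns if c not in LABEL_COLUMNS]
    try:
        axis = make_axis([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SpectrumValidationError(
            f"{path}: non-numeric wavenumber column header ({exc})") from exc
    inten = np.empty((len(df), len(wn_cols)))
    for j, col in enumerate(wn_cols):
        try:
            inten[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise SpectrumValidationError(
                f"{path}: non-numeric intensity in column {col!r}, rows {bad[:5]}"
            ) from exc
    return SpectrumSet(axis, inten, df[list(LABEL_COLUMNS)],
                       meta={"source": str(path), "format": "wide-csv"})


def _read_long(path: Path) -> SpectrumSet:
    req = list(LABEL_COLUMNS) + ["wavenumber", "intensity"]
    df = pd.read_csv(path, dtype={c: str for c in LABEL_COLUMNS})
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise SpectrumValidationError(f"{path}: missing columns {missing}")
    for col in ("wavenumber", "intensity"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            bad = df.index[coerced.isna()].tolist()
            raise SpectrumValidationError(
                f"{path}: non-numeric {col} at rows {bad[:5]}")
        df[col] = coerced
    wide = df.pivot_table(index=list(LABEL_COLUMNS), columns="wavenumber",
                          values="intensity", aggfunc="first")
    if wide.isna().any().any():
        raise SpectrumValidationError(
            f"{path}: inconsistent axis — not every cell has every wavenumber")
    per_cell = df.groupby("cell_id")["wavenumber"].count()
    if per_cell.nunique() > 1:
        raise SpectrumValidationError(f"{path}: inconsistent axis across cells")
    axis = make_axis(wide.columns.to_numpy(dtype=float))
    labels = wide.index.to_frame(index=False)
    # pivot_table sorts the index; restore input cell order
    order = df["cell_id"].drop_duplicates().tolist()
    pos = {cid: i for i, cid in enumerate(order)}
    perm = labels["cell_id"].map(pos).argsort().to_numpy()
    return SpectrumSet(axis, wide.to_numpy()[perm], labels.iloc[perm],
                       meta={"source": str(path), "format": "long-csv"})


def write_spectra(s: SpectrumSet, path: str | Path, format: str = "wide-csv") -> Path:
    """Write a SpectrumSet to delimited text; round-trips through read_spectra."""
    path = Path(path)
    if format == "wide-csv":
        df = s.labels[list(LABEL_COLUMNS)].copy()
        wide = pd.DataFrame(s.intensities,
                            columns=[repr(float(v)) for v in s.axis],
                            index=df.index)
        pd.concat([df, wide], axis=1).to_csv(path, index=False)
    elif format == "long-csv":
        rows = []
        for i in range(s.n_cells):
            lab = s.labels.iloc[i]
            rows.append(pd.DataFrame({
                "cell_id": lab["cell_id"], "species": lab["species"],
                "replicate": lab["replicate"],
                "wavenumber": s.axis, "intensity": s.intensities[i]}))
        out = (pd.concat(rows, ignore_index=True) if rows else
               pd.DataFrame(columns=list(LABEL_COLUMNS) + ["wavenumber", "intensity"]))
        out.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def resample_to_grid(s: SpectrumSet, grid: Iterable[float]) -> SpectrumSet:
    """Linearly interpolate every cell onto a new wavenumber grid.

    The grid must lie within the span of ``s.axis``; extrapolation is refused.
    """
    grid = make_axis(grid)
    if grid[0] < s.axis[0] or grid[-1] > s.axis[-1]:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] extends outside the spectrum span "
            f"[{s.axis[0]}, {s.axis[-1]}]; extrapolation is not supported")
    out = np.empty((s.n_cells, grid.size))
    for i in range(s.n_cells):
        out[i] = np.interp(grid, s.axis, s.intensities[i])
    return SpectrumSet(grid, out, s.labels, dict(s.meta))
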