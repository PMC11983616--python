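"""Reading, writing, and resampling of reflectance spectra tables.

The interchange format is plain CSV: the first column holds sample
identifiers, the remaining column headers are wavelengths in nanometres.
All analysis happens on the canonical 1-nm grid from 350 to 2500 nm
(2151 bands), the grid produced by resampling field-spectrometer output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical wavelength grid: 350..2500 nm at 1 nm, 2151 bands.
CANONICAL_GRID = np.arange(350, 2501, dtype=float)
N_BANDS = CANONICAL_GRID.size


class SpectraParseError(ValueError):
    """Raised when a spectra CSV cannot be interpreted."""


@dataclass
class SpectraMatrix:
    """A sample x wavelength reflectance table.

    Attributes
    ----------
    sample_ids : list of str
        Row identifiers, unique, order-preserving.
    wavelengths : ndarray
        Strictly increasing wavelengths in nm.
    values : ndarray, shape (n_samples, n_bands)
    meta : dict
        Free-form provenance (preprocessing tag, reference source, ...).
    """

    sample_ids: list
    wavelengths: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {self.values.shape[0]} rows"
            )
        if self.wavelengths.size != self.values.shape[1]:
            raise ValueError(
                f"{self.wavelengths.size} wavelengths but {self.values.shape[1]} columns"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SpectraParseError("duplicated sample_id in spectra table")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise SpectraParseError("wavelengths are not strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def band_index(self, nm: float) -> int:
        """Index of the band closest to ``nm`` on this grid."""
        return int(np.argmin(np.abs(self.wavelengths - nm)))

    def subset(self, sample_ids) -> "SpectraMatrix":
        """Row subset, preserving the requested order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return SpectraMatrix(list(sample_ids), self.wavelengths,
                             self.values[idx], dict(self.meta))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.wavelengths)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def group_mean(self, sample_ids) -> np.ndarray:
        return self.subset(list(sample_ids)).values.mean(axis=0)


def write_spectra(matrix: SpectraMatrix, path) -> None:
    """Write a spectra CSV (sample_id + one column per wavelength)."""
    df = pd.DataFrame(matrix.values,
                      columns=[_fmt_wavelength(w) for w in matrix.wavelengths])
    df.insert(0, "sample_id", matrix.sample_ids)
    df.to_csv(path, index=False)


def _fmt_wavelength(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else repr(float(w))


def read_spectra(path) -> SpectraMatrix:
    """Read a spectra CSV written by :func:`write_spectra`.

    Tolerates Windows and Unix line endings. Raises
    :class:`SpectraParseError` with row/column context on malformed input.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SpectraParseError(f"{path}: expected sample_id plus wavelength columns")
    first = df.columns[0]
    try:
        wavelengths = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise SpectraParseError(f"{path}: non-numeric wavelength header: {exc}") from exc
    if np.any(np.diff(wavelengths) <= 0):
        raise SpectraParseError(f"{path}: wavelengths are not strictly increasing")
    sample_ids = df[first].astype(str).tolist()
    body = df.iloc[:, 1:]
    bad = body.columns[body.apply(lambda c: pd.to_numeric(c, errors="coerce").isna().any())]
    if len(bad):
        col = bad[0]
        row = int(pd.to_numeric(body[col], errors="coerce").isna().idxmax())
        raise SpectraParseError(
            f"{path}: non-numeric reflectance at row {row}, column {col}"
        )
    values = body.to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise SpectraParseError(f"{path}: missing value at row {r}, column {wavelengths[c]}")
    return SpectraMatrix(sample_ids, wavelengths, values)


def resample_to_canonical(wavelengths, reflectance,
                          sample_ids=None) -> SpectraMatrix:
    """Linearly interpolate spectra onto the canonical 1-nm grid.

    Parameters
    ----------
    wavelengths : array-like
        Strictly increasing source wavelengths covering [350, 2500] nm.
    reflectance : array-like, shape (n_samples, n_source) or (n_source,)

    Canonical input passes through bitwise unchanged.
    """
    w = np.asarray(wavelengths, dtype=float)
    r = np.atleast_2d(np.asarray(reflectance, dtype=float))
    if np.any(np.diff(w) <= 0):
        raise SpectraParseError("source wavelengths are not strictly increasing")
    if w[0] > CANONICAL_GRID[0] or w[-1] < CANONICAL_GRID[-1]:
        lo = max(w[0], CANONICAL_GRID[0])
        hi = min(w[-1], CANONICAL_GRID[-1])
        raise SpectraParseError(
            "source wavelengths do not cover the canonical grid: missing "
            f"[{CANONICAL_GRID[0]:g}, {w[0]:g}) nm" if w[0] > CANONICAL_GRID[0]
            else f"source wavelengths do not cover the canonical grid: missing "
                 f"({w[-1]:g}, {CANONICAL_GRID[-1]:g}] nm"
        )
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(r.shape[0])]
    if w.size == N_BANDS and np.array_equal(w, CANONICAL_GRID):
        return SpectraMatrix(list(sample_ids), CANONICAL_GRID.copy(), r.copy())
    out = np.empty((r.shape[0], N_BANDS))
    for i in range(r.shape[0]):
        out[i] = np.interp(CANONICAL_GRID, w, r[i])
    return SpectraMatrix(list(sample_ids), CANONICAL_GRID.copy(), out)
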