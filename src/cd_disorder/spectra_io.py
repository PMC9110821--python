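"""Reading, writing, validating and unit-converting far-UV CD spectra.

A spectrum is a per-residue circular dichroism curve sampled on a strictly
increasing wavelength grid (nm). Two amplitude conventions are supported:

* mean residue ellipticity (MRE, deg cm^2 dmol^-1), and
* mean-residue delta-epsilon (M^-1 cm^-1),

related by ``MRE = 3298.2 * delta_epsilon``. All classification in this
package runs on delta-epsilon values; loaders require an explicit unit flag
and never guess, since digitized literature spectra circulate in both units.
"""

from __future__ import annotations

import enum
import io
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CoverageError, SpectrumContentError, SpectrumParseError

#: Conversion factor between mean residue ellipticity and delta-epsilon:
#: MRE [deg cm^2 dmol^-1] = 3298.2 * delta_eps [M^-1 cm^-1].
MRE_PER_DELTA_EPSILON = 3298.2

#: Wavelengths a far-UV CD instrument can plausibly report (nm).
WAVELENGTH_BOUNDS = (170.0, 300.0)

#: Tolerance (nm) within which a query wavelength counts as lying on the grid.
GRID_MATCH_TOL_NM = 1e-6


class Units(enum.Enum):
    """Amplitude unit of a CD spectrum."""

    MRE = "mre"  # mean residue ellipticity, deg cm^2 dmol^-1
    DELTA_EPSILON = "depsilon"  # mean-residue delta-epsilon, M^-1 cm^-1

    @classmethod
    def parse(cls, token: str) -> "Units":
        token = token.strip().lower()
        aliases = {
            "mre": cls.MRE,
            "mean_residue_ellipticity": cls.MRE,
            "depsilon": cls.DELTA_EPSILON,
            "delta_epsilon": cls.DELTA_EPSILON,
            "deltaepsilon": cls.DELTA_EPSILON,
            "de": cls.DELTA_EPSILON,
        }
        try:
            return aliases[token]
        except KeyError:
            raise SpectrumContentError(f"unknown unit token {token!r}") from None


class SpectrumFormat(enum.Enum):
    """On-disk layout of a spectrum text file."""

    TWO_COLUMN = "two_column"
    PCDDB_LIKE = "pcddb_like"


@dataclass(frozen=True)
class CDSpectrum:
    """One protein's CD curve on a strictly increasing wavelength grid.

    Parameters
    ----------
    protein_id : str
        Identifier, unique within any labeled reference set.
    wavelengths_nm : numpy.ndarray
        Strictly increasing wavelengths in nm, all within [170, 300].
    values : numpy.ndarray
        Per-residue CD values, same length as the grid, all finite.
    units : Units
        Amplitude unit of ``values``.
    source : str
        Free-text provenance, e.g. ``"PCDDB"``, ``"SRCD"``, ``"literature"``.
    """

    protein_id: str
    wavelengths_nm: np.ndarray
    values: np.ndarray
    units: Units
    source: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        va = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", va)
        if wl.ndim != 1 or va.ndim != 1 or len(wl) != len(va):
            raise SpectrumContentError(
                f"{self.protein_id}: wavelengths and values must be 1-D and equal length"
            )
        if len(wl) < 2:
            raise SpectrumContentError(
                f"{self.protein_id}: a spectrum needs at least 2 data points, got {len(wl)}"
            )
        if not np.all(np.diff(wl) > 0):
            raise SpectrumContentError(
                f"{self.protein_id}: wavelengths must be strictly increasing"
            )
        lo, hi = WAVELENGTH_BOUNDS
        if wl[0] < lo or wl[-1] > hi:
            raise SpectrumContentError(
                f"{self.protein_id}: wavelengths must lie within [{lo}, {hi}] nm"
            )
        if not np.all(np.isfinite(va)):
            raise SpectrumContentError(f"{self.protein_id}: non-finite CD values")
        if not isinstance(self.units, Units):
            object.__setattr__(self, "units", Units.parse(str(self.units)))

    @property
    def min_wavelength_nm(self) -> float:
        """Lowest measured wavelength (the spectrum's own cutoff)."""
        return float(self.wavelengths_nm[0])

    @property
    def max_wavelength_nm(self) -> float:
        return float(self.wavelengths_nm[-1])

    def covers(self, lambda_nm: float) -> bool:
        return (
            self.min_wavelength_nm - GRID_MATCH_TOL_NM
            <= lambda_nm
            <= self.max_wavelength_nm + GRID_MATCH_TOL_NM
        )


def value_at(spectrum: CDSpectrum, lambda_nm: float) -> float:
    """CD value at an arbitrary wavelength inside the measured range.

    Returns the stored value when ``lambda_nm`` falls on a grid point (within
    1e-6 nm); otherwise linearly interpolates between the bracketing points.
    Reference data are recorded at 1 nm steps, so interpolation error is
    negligible in practice.

    Raises
    ------
    CoverageError
        If ``lambda_nm`` lies outside the measured wavelength range.
    """
    wl = spectrum.wavelengths_nm
    if not spectrum.covers(lambda_nm):
        raise CoverageError(
            f"{spectrum.protein_id}: {lambda_nm} nm outside measured range "
            f"[{wl[0]:g}, {wl[-1]:g}] nm"
        )
    idx = np.searchsorted(wl, lambda_nm)
    for j in (idx - 1, idx):
        if 0 <= j < len(wl) and abs(wl[j] - lambda_nm) <= GRID_MATCH_TOL_NM:
            return float(spectrum.values[j])
    return float(np.interp(lambda_nm, wl, spectrum.values))


def convert_units(spectrum: CDSpectrum, target: Units) -> CDSpectrum:
    """Convert a spectrum between MRE and delta-epsilon.

    The mapping is a bijection on finite values: dividing MRE by 3298.2 gives
    delta-epsilon and vice versa, so a round trip is the identity to numerical
    precision.
    """
    if target == spectrum.units:
        return replace(spectrum)
    if spectrum.units is Units.MRE and target is Units.DELTA_EPSILON:
        new = spectrum.values / MRE_PER_DELTA_EPSILON
    elif spectrum.units is Units.DELTA_EPSILON and target is Units.MRE:
        new = spectrum.values * MRE_PER_DELTA_EPSILON
    else:  # pragma: no cover - only two units exist
        raise SpectrumContentError(f"cannot convert {spectrum.units} -> {target}")
    return replace(spectrum, values=new, units=target)


_FLOAT_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _tokenize(line: str) -> list[str]:
    return [t for t in re.split(r"[,\s;]+", line.strip()) if t]


def _parse_rows(
    lines, path, n_value_columns_min: int
) -> list[tuple[int, list[float]]]:
    """Parse numeric rows, allowing '#' comments and one leading header row."""
    rows: list[tuple[int, list[float]]] = []
    header_allowance = 1
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = _tokenize(line)
        numeric = all(_FLOAT_RE.match(t) for t in tokens)
        if not numeric:
            if not rows and header_allowance:
                header_allowance = 0  # one optional column-header row
                continue
            raise SpectrumParseError(
                f"malformed row {raw.strip()!r}", path=path, line=lineno
            )
        if len(tokens) < 1 + n_value_columns_min:
            raise SpectrumParseError(
                f"expected at least {1 + n_value_columns_min} columns, got {len(tokens)}",
                path=path,
                line=lineno,
            )
        rows.append((lineno, [float(t) for t in tokens]))
    return rows


def read_spectrum(
    path,
    format: SpectrumFormat | str = SpectrumFormat.TWO_COLUMN,
    units: Units | str = Units.DELTA_EPSILON,
    protein_id: str | None = None,
    source: str = "",
    data_column: int = 1,
) -> CDSpectrum:
    """Read a CD spectrum from a delimited text file.

    Parameters
    ----------
    path : path-like
        File to read. ``'#'``-prefixed comments and one optional header row
        are allowed; fields may be separated by whitespace, commas or
        semicolons.
    format : SpectrumFormat or str
        ``two_column``: wavelength, value. ``pcddb_like``: multi-column text
        whose first column is the wavelength; ``data_column`` selects which
        of the remaining columns holds the CD values (1 = first data column).
    units : Units or str
        Unit of the stored values. Required explicitly — never guessed.
    protein_id : str, optional
        Defaults to the file stem.
    data_column : int
        1-based data-column index for the ``pcddb_like`` format.

    Notes
    -----
    Rows are sorted ascending by wavelength (descending-wavelength files are
    common instrument output and are silently normalized); duplicate
    wavelengths are rejected rather than averaged.
    """
    if isinstance(format, str):
        format = SpectrumFormat(format)
    if isinstance(units, str):
        units = Units.parse(units)
    path = str(path)
    if protein_id is None:
        protein_id = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]

    with io.open(path, "r", encoding="utf-8") as fh:
        rows = _parse_rows(fh, path, n_value_columns_min=1)

    if len(rows) < 2:
        raise SpectrumContentError(f"{path}: fewer than 2 data points")

    col = 1 if format is SpectrumFormat.TWO_COLUMN else data_column
    try:
        wl = np.array([r[0] for _, r in rows], dtype=float)
        va = np.array([r[col] for _, r in rows], dtype=float)
    except IndexError:
        raise SpectrumParseError(
            f"data column {col} missing", path=path, line=rows[0][0]
        ) from None

    order = np.argsort(wl, kind="stable")
    wl, va = wl[order], va[order]
    if np.any(np.diff(wl) == 0):
        dup = wl[np.flatnonzero(np.diff(wl) == 0)[0]]
        raise SpectrumContentError(f"{path}: duplicate wavelength {dup:g} nm")
    return CDSpectrum(protein_id, wl, va, units, source=source)


def write_spectrum(spectrum: CDSpectrum, path) -> None:
    """Write a spectrum as two-column text with unit-declaring header comments.

    The output round-trips bit-comparably through :func:`read_spectrum`.
    """
    with io.open(str(path), "w", encoding="utf-8") as fh:
        fh.write(f"# id: {spectrum.protein_id}\n")
        fh.write(f"# units: {spectrum.units.value}\n")
        if spectrum.source:
            fh.write(f"# source: {spectrum.source}\n")
        fh.write("# wavelength_nm\tvalue\n")
        for w, v in zip(spectrum.wavelengths_nm, spectrum.values):
            fh.write(f"{float(w)!r}\t{float(v)!r}\n")
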