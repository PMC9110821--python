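"""Labeled reference collections and wavelength-tuple feature extraction.

The classifier consumes only the CD values at two or three chosen wavelengths.
This module holds the labeled (ordered/disordered) spectrum collection,
applies the coverage rules that decide which spectra participate at a given
wavelength cutoff, and turns the survivors into a feature matrix in
delta-epsilon units.
"""

from __future__ import annotations

import csv
import enum
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import CoverageError, ManifestError
from .spectra_io import CDSpectrum, Units, convert_units, read_spectrum, value_at

#: Wavelength window the tuple search operates in (nm).
TUPLE_RANGE_NM = (175, 250)

#: Minimum pairwise separation between tuple members (nm).
MIN_TUPLE_SEPARATION_NM = 3


class Label(enum.Enum):
    """Binary structural class of a reference spectrum."""

    ORDERED = "ordered"
    DISORDERED = "disordered"

    @classmethod
    def parse(cls, token: str) -> "Label":
        try:
            return cls(token.strip().lower())
        except ValueError:
            raise ManifestError(
                f"unknown label {token!r}; expected 'ordered' or 'disordered'"
            ) from None


@dataclass(frozen=True, order=True)
class WavelengthTuple:
    """An increasing pair or triplet of integer wavelengths (nm).

    Members lie within [175, 250] nm with every pairwise difference >= 3 nm —
    close wavelengths carry nearly redundant CD information and are more
    vulnerable to correlated noise.
    """

    wavelengths: tuple[int, ...]

    def __post_init__(self):
        wl = tuple(int(w) for w in self.wavelengths)
        object.__setattr__(self, "wavelengths", wl)
        if len(wl) not in (2, 3):
            raise ValueError(f"tuple must have 2 or 3 wavelengths, got {len(wl)}")
        lo, hi = TUPLE_RANGE_NM
        if wl[0] < lo or wl[-1] > hi:
            raise ValueError(f"wavelengths must lie within [{lo}, {hi}] nm: {wl}")
        if any(b - a < MIN_TUPLE_SEPARATION_NM for a, b in zip(wl, wl[1:])):
            raise ValueError(
                f"wavelengths must increase by >= {MIN_TUPLE_SEPARATION_NM} nm: {wl}"
            )

    def __iter__(self):
        return iter(self.wavelengths)

    def __len__(self):
        return len(self.wavelengths)

    def __str__(self):
        return "-".join(str(w) for w in self.wavelengths)

    @classmethod
    def parse(cls, text: str) -> "WavelengthTuple":
        """Parse ``"197,206,233"`` or ``"197-206-233"``."""
        parts = [p for p in text.replace("-", ",").split(",") if p.strip()]
        return cls(tuple(int(p) for p in parts))


@dataclass(frozen=True)
class FeatureMatrix:
    """CD values at tuple wavelengths for a set of spectra, in delta-epsilon.

    ``X`` has one row per spectrum and one column per tuple wavelength, in
    tuple order; ``labels`` and ``ids`` are parallel to the rows.
    """

    X: np.ndarray
    labels: tuple[Label, ...]
    ids: tuple[str, ...]

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "ids", tuple(self.ids))
        if X.ndim != 2 or X.shape[0] != len(self.labels) or X.shape[0] != len(self.ids):
            raise ValueError("feature matrix rows, labels and ids must align")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def y(self) -> np.ndarray:
        """Labels as an integer array (0 = ordered, 1 = disordered)."""
        return np.array([1 if l is Label.DISORDERED else 0 for l in self.labels])

    def count(self, label: Label) -> int:
        return sum(1 for l in self.labels if l is label)


class LabeledSpectrumSet:
    """An ordered collection of (spectrum, label) pairs with unique ids."""

    def __init__(self, entries):
        self.entries: list[tuple[CDSpectrum, Label]] = list(entries)
        seen = set()
        for spec, label in self.entries:
            if not isinstance(label, Label):
                raise ManifestError(f"label of {spec.protein_id} is not a Label")
            if spec.protein_id in seen:
                raise ManifestError(f"duplicate protein id {spec.protein_id!r}")
            seen.add(spec.protein_id)

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def count(self, label: Label) -> int:
        return sum(1 for _, l in self.entries if l is label)

    @property
    def ids(self) -> list[str]:
        return [s.protein_id for s, _ in self.entries]

    def covering_subset(
        self, wl_tuple: WavelengthTuple, cutoff_nm: float
    ) -> "LabeledSpectrumSet":
        """Spectra usable for classification at this tuple and cutoff.

        A spectrum is kept iff its measured range contains every tuple member
        *and* its lowest measured wavelength is <= ``cutoff_nm``. The cutoff
        clause reflects how reference sets are defined per studied wavelength
        range: the cutoff-c dataset contains exactly the spectra measured down
        to c or below, while tuple coverage is checked independently so that,
        for a given tuple, all spectra covering those wavelengths are used.

        The result may be empty or single-class; consumers that need both
        classes must check.
        """
        kept = [
            (s, l)
            for s, l in self.entries
            if s.min_wavelength_nm <= cutoff_nm
            and all(s.covers(w) for w in wl_tuple)
        ]
        return LabeledSpectrumSet(kept)

    def features_at(self, wl_tuple: WavelengthTuple) -> FeatureMatrix:
        """Extract the CD values at the tuple wavelengths, in delta-epsilon.

        Raises
        ------
        CoverageError
            Naming the first spectrum that does not cover a tuple wavelength.
        """
        rows, labels, ids = [], [], []
        for spec, label in self.entries:
            for w in wl_tuple:
                if not spec.covers(w):
                    raise CoverageError(
                        f"{spec.protein_id} does not cover {w} nm "
                        f"(measured {spec.min_wavelength_nm:g}-{spec.max_wavelength_nm:g} nm)"
                    )
            de = convert_units(spec, Units.DELTA_EPSILON)
            rows.append([value_at(de, w) for w in wl_tuple])
            labels.append(label)
            ids.append(spec.protein_id)
        X = np.array(rows, dtype=float).reshape(len(rows), len(wl_tuple))
        return FeatureMatrix(X, tuple(labels), tuple(ids))


def load_reference(manifest_path) -> LabeledSpectrumSet:
    """Load a labeled spectrum collection from a manifest CSV.

    The manifest has columns ``id, path, label, units`` where ``label`` is
    ``ordered``/``disordered`` (case-insensitive), ``units`` is ``mre`` or
    ``depsilon``, and ``path`` is resolved relative to the manifest location.
    """
    manifest_path = str(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    entries = []
    with open(manifest_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "path", "label", "units"}
        if reader.fieldnames is None or not required.issubset(
            {f.strip().lower() for f in reader.fieldnames}
        ):
            raise ManifestError(
                f"{manifest_path}: manifest must have columns id, path, label, units"
            )
        for row in reader:
            row = {k.strip().lower(): (v or "").strip() for k, v in row.items()}
            label = Label.parse(row["label"])
            units = Units.parse(row["units"])
            spath = row["path"]
            if not os.path.isabs(spath):
                spath = os.path.join(base, spath)
            spec = read_spectrum(
                spath, units=units, protein_id=row["id"], source=row.get("source", "")
            )
            entries.append((spec, label))
    return LabeledSpectrumSet(entries)


def write_manifest(set_: LabeledSpectrumSet, manifest_path, paths, units) -> None:
    """Write a manifest CSV for spectra already on disk (parallel ``paths``)."""
    base = os.path.dirname(os.path.abspath(str(manifest_path)))
    with open(str(manifest_path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "path", "label", "units"])
        for (spec, label), p in zip(set_.entries, paths):
            rel = os.path.relpath(str(p), base)
            writer.writerow([spec.protein_id, rel, label.value, units.value])
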