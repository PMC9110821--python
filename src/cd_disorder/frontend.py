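"""End-user classification of a query spectrum, with triplet auto-selection.

The recommended protocol uses the cosine-metric KNN (k = 10) on the CD values
at three wavelengths. Spectra of good quality measured down to ~195 nm are
classified with the 197-206-233 nm triplet; spectra limited to longer
wavelengths — strongly absorbing buffers, denaturants, crowded conditions —
fall back to the 212-217-225 nm triplet, usable down to a 212 nm cutoff.
Because the cosine metric ignores the spectral amplitude, the verdict is
invariant under any positive rescaling of the query, i.e. free of
concentration-determination errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifiers import ClassifierSpec, predict_with_neighbors, train
from .errors import CoverageError, InsufficientDataError, UncoverableSpectrumError
from .reference_set import (
    Label,
    LabeledSpectrumSet,
    WavelengthTuple,
)
from .spectra_io import CDSpectrum, Units, convert_units, value_at

#: Triplet for spectra measured down to 197 nm or below (lower error).
LOW_TRIPLET = WavelengthTuple((197, 206, 233))
#: Fallback triplet for spectra measured only down to 198-212 nm.
HIGH_TRIPLET = WavelengthTuple((212, 217, 225))

#: Cutoff (nm) up to which the low triplet is used.
LOW_TRIPLET_MAX_CUTOFF_NM = 197.0
#: Highest usable spectrum cutoff (nm); above this no triplet is covered.
HIGH_TRIPLET_MAX_CUTOFF_NM = 212.0

#: Minimum reference spectra that must cover the triplet.
MIN_REFERENCE_SIZE = 10


@dataclass(frozen=True)
class Verdict:
    """Binary classification of one query spectrum.

    ``vote_fraction`` is the share of the k = 10 nearest reference spectra
    carrying the returned label (>= 0.5 by construction); ``neighbor_ids``
    lists those spectra nearest-first. ``cutoff_reached_nm`` is the query's
    own lowest measured wavelength.
    """

    label: Label
    triplet_used: WavelengthTuple
    vote_fraction: float
    neighbor_ids: tuple[str, ...]
    neighbor_labels: tuple[Label, ...]
    neighbor_distances: tuple[float, ...]
    cutoff_reached_nm: float
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "label": self.label.value,
            "triplet": str(self.triplet_used),
            "vote_fraction": self.vote_fraction,
            "neighbors": [
                {"id": i, "label": l.value, "distance": d}
                for i, l, d in zip(
                    self.neighbor_ids, self.neighbor_labels, self.neighbor_distances
                )
            ],
            "warnings": list(self.warnings),
        }


def select_triplet(min_wavelength_nm: float) -> WavelengthTuple:
    """Choose the wavelength triplet a spectrum's cutoff allows.

    Spectra measured down to 197 nm or below use 197-206-233 nm; cutoffs in
    (197, 212] nm use 212-217-225 nm; above 212 nm no recommended triplet is
    covered.
    """
    if min_wavelength_nm <= LOW_TRIPLET_MAX_CUTOFF_NM:
        return LOW_TRIPLET
    if min_wavelength_nm <= HIGH_TRIPLET_MAX_CUTOFF_NM:
        return HIGH_TRIPLET
    raise UncoverableSpectrumError(
        f"spectrum cutoff {min_wavelength_nm:g} nm > {HIGH_TRIPLET_MAX_CUTOFF_NM:g} nm: "
        "no recommended wavelength triplet is covered"
    )


def classify_spectrum(
    query: CDSpectrum,
    reference: LabeledSpectrumSet,
    force_high_triplet: bool = False,
) -> Verdict:
    """Classify one spectrum as ordered or disordered.

    Selects the triplet from the query's lowest measured wavelength
    (``force_high_triplet`` forces 212-217-225 nm for absorbing-buffer use),
    extracts the three delta-epsilon values, and runs the cosine-metric KNN
    (k = 10) against the triplet-covering reference subset. The verdict —
    label, vote fraction and neighbor list — is invariant under positive
    rescaling of the query.
    """
    warnings: list[str] = []
    if force_high_triplet:
        if query.min_wavelength_nm > HIGH_TRIPLET_MAX_CUTOFF_NM:
            raise UncoverableSpectrumError(
                f"spectrum cutoff {query.min_wavelength_nm:g} nm does not cover "
                f"the {HIGH_TRIPLET} nm triplet"
            )
        triplet = HIGH_TRIPLET
    else:
        triplet = select_triplet(query.min_wavelength_nm)
    if not query.covers(triplet.wavelengths[-1]):
        raise UncoverableSpectrumError(
            f"spectrum ends at {query.max_wavelength_nm:g} nm and does not cover "
            f"{triplet.wavelengths[-1]} nm"
        )

    subset = reference.covering_subset(triplet, cutoff_nm=triplet.wavelengths[0])
    if len(subset) < MIN_REFERENCE_SIZE:
        raise InsufficientDataError(
            f"only {len(subset)} reference spectra cover the {triplet} nm triplet; "
            f"need >= {MIN_REFERENCE_SIZE}"
        )
    fm = subset.features_at(triplet)
    model = train(ClassifierSpec.default("knn_cosine"), fm)

    de = convert_units(query, Units.DELTA_EPSILON)
    q = np.array([value_at(de, w) for w in triplet])
    label, vote, nbrs = predict_with_neighbors(model, q)
    inner = model._model
    dists = inner.distances(q)[nbrs]
    return Verdict(
        label=label,
        triplet_used=triplet,
        vote_fraction=vote,
        neighbor_ids=tuple(fm.ids[i] for i in nbrs),
        neighbor_labels=tuple(fm.labels[i] for i in nbrs),
        neighbor_distances=tuple(float(d) for d in dists),
        cutoff_reached_nm=query.min_wavelength_nm,
        warnings=tuple(warnings),
    )


def export_2d_coordinates(set_: LabeledSpectrumSet):
    """Per-spectrum (200 nm, 222 nm) mean-residue-ellipticity coordinates.

    The classical double-wavelength disorder plot. Entries not covering both
    wavelengths are skipped and listed separately. Returns
    ``(pandas.DataFrame, skipped_ids)`` with columns id, label, mre_200, mre_222.
    """
    import pandas as pd

    records, skipped = [], []
    for spec, label in set_.entries:
        if not (spec.covers(200.0) and spec.covers(222.0)):
            skipped.append(spec.protein_id)
            continue
        mre = convert_units(spec, Units.MRE)
        records.append(
            {
                "id": spec.protein_id,
                "label": label.value,
                "mre_200": value_at(mre, 200.0),
                "mre_222": value_at(mre, 222.0),
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["id", "label", "mre_200", "mre_222"]
    ), skipped
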