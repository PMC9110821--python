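"""Wavelength-tuple enumeration, leave-one-out cross-validation and ranking.

The optimal classification method is found by exhaustive search: every
increasing integer wavelength pair or triplet in 175-250 nm with pairwise
gaps of at least 3 nm is combined with each candidate classifier, scored by
leave-one-out cross-validation (LOOCV) on the coverage-filtered reference
subset, and ranked by global error, then disordered-class error, then a
preference for higher wavelengths (higher-wavelength data survive absorbing
buffers and lower-quality instruments).

Error rates are reported separately for ordered and disordered proteins and
globally; the global rate is by construction the class-count-weighted mean of
the per-class rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifiers import (
    KNN_FAMILIES,
    ClassifierSpec,
    TrainedClassifier,
    _KNNModel,
    _vote,
    predict,
    train,
)
from .errors import InsufficientDataError
from .reference_set import (
    MIN_TUPLE_SEPARATION_NM,
    TUPLE_RANGE_NM,
    FeatureMatrix,
    Label,
    LabeledSpectrumSet,
    WavelengthTuple,
)
from .spectra_io import Units, convert_units, value_at


def enumerate_tuples(
    size: int,
    lo: int = TUPLE_RANGE_NM[0],
    hi: int = TUPLE_RANGE_NM[1],
    min_sep: int = MIN_TUPLE_SEPARATION_NM,
) -> list[WavelengthTuple]:
    """All increasing integer wavelength tuples in [lo, hi] with gaps >= min_sep.

    Returned in lexicographic order. Infeasible constraints yield an empty
    list, not an error. ``lo``, ``hi`` and ``min_sep`` must respect the
    :class:`WavelengthTuple` domain (175-250 nm, separation >= 3 nm).
    """
    if size not in (2, 3):
        raise ValueError("tuple size must be 2 or 3")
    if lo >= hi:
        raise ValueError("lo must be < hi")
    if lo < TUPLE_RANGE_NM[0] or hi > TUPLE_RANGE_NM[1]:
        raise ValueError(f"[lo, hi] must lie within {TUPLE_RANGE_NM} nm")
    if min_sep < MIN_TUPLE_SEPARATION_NM:
        raise ValueError(f"min_sep must be >= {MIN_TUPLE_SEPARATION_NM} nm")
    out: list[WavelengthTuple] = []
    if size == 2:
        for a in range(lo, hi + 1):
            for b in range(a + min_sep, hi + 1):
                out.append(WavelengthTuple((a, b)))
    else:
        for a in range(lo, hi + 1):
            for b in range(a + min_sep, hi + 1):
                for c in range(b + min_sep, hi + 1):
                    out.append(WavelengthTuple((a, b, c)))
    return out


@dataclass(frozen=True)
class CVResult:
    """Per-class and global LOOCV error rates with counts.

    ``err_global`` always equals the class-count-weighted mean of the
    per-class errors.
    """

    n_ordered: int
    n_disordered: int
    err_ordered: float
    err_disordered: float
    err_global: float
    misclassified_ids: tuple[str, ...] = ()

    @classmethod
    def from_counts(
        cls,
        n_ordered: int,
        n_disordered: int,
        wrong_ordered: float,
        wrong_disordered: float,
        misclassified_ids=(),
    ) -> "CVResult":
        n = n_ordered + n_disordered
        return cls(
            n_ordered=n_ordered,
            n_disordered=n_disordered,
            err_ordered=wrong_ordered / n_ordered if n_ordered else 0.0,
            err_disordered=wrong_disordered / n_disordered if n_disordered else 0.0,
            err_global=(wrong_ordered + wrong_disordered) / n if n else 0.0,
            misclassified_ids=tuple(misclassified_ids),
        )


def _loocv_predicted_classes(fm: FeatureMatrix, spec: ClassifierSpec) -> np.ndarray:
    """Predicted class (0 ordered / 1 disordered) for each held-out row.

    KNN families use a precomputed-distance path that is exactly equivalent
    to naive refitting: holding out row i only removes i from the candidate
    neighbors, so distances are computed once against the full matrix and the
    self-distance is masked. Other families refit per held-out row.
    """
    X, y = fm.X, fm.y
    n = X.shape[0]
    pred = np.empty(n, dtype=int)
    if spec.family in KNN_FAMILIES:
        p = spec.params
        full = _KNNModel(X, y, p["k"], p["metric"], p["weighted"])
        k_eff = min(p["k"], n - 1)
        for i in range(n):
            d = full.distances(X[i])
            d[i] = np.inf  # leave one out
            order = np.argsort(d, kind="stable")
            nbrs = order[:k_eff]
            pred[i], _ = _vote(d[nbrs], y[nbrs], p["weighted"])
        return pred
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        sub = FeatureMatrix(
            X[keep], tuple(l for j, l in enumerate(fm.labels) if keep[j]),
            tuple(s for j, s in enumerate(fm.ids) if keep[j]),
        )
        model = train(spec, sub)
        label, _ = predict(model, X[i])
        pred[i] = 1 if label is Label.DISORDERED else 0
        keep[i] = True
    return pred


def _result_from_predictions(fm: FeatureMatrix, pred: np.ndarray) -> CVResult:
    y = fm.y
    wrong = pred != y
    return CVResult.from_counts(
        n_ordered=int(np.sum(y == 0)),
        n_disordered=int(np.sum(y == 1)),
        wrong_ordered=int(np.sum(wrong & (y == 0))),
        wrong_disordered=int(np.sum(wrong & (y == 1))),
        misclassified_ids=tuple(fm.ids[i] for i in np.flatnonzero(wrong)),
    )


def _check_class_sizes(subset: LabeledSpectrumSet) -> None:
    for label in (Label.ORDERED, Label.DISORDERED):
        if subset.count(label) < 2:
            raise InsufficientDataError(
                f"covering subset has {subset.count(label)} {label.value} "
                "spectra; leave-one-out needs at least 2 per class"
            )


def loocv_error(
    set_: LabeledSpectrumSet,
    wl_tuple: WavelengthTuple,
    spec: ClassifierSpec,
    cutoff_nm: float,
) -> CVResult:
    """Leave-one-out cross-validation error of one (tuple, classifier) pair.

    Each retained spectrum is classified by a model trained on all the
    others; misclassified spectra are summed and divided by the totals, per
    class and globally. The retained subset is the coverage-filtered set at
    ``cutoff_nm`` (see :meth:`LabeledSpectrumSet.covering_subset`), so the
    effective n varies with the tuple — results report it.
    """
    subset = set_.covering_subset(wl_tuple, cutoff_nm)
    _check_class_sizes(subset)
    fm = subset.features_at(wl_tuple)
    pred = _loocv_predicted_classes(fm, spec)
    return _result_from_predictions(fm, pred)


@dataclass(frozen=True)
class SearchRow:
    cutoff_nm: float
    spec: ClassifierSpec
    wl_tuple: WavelengthTuple
    result: CVResult | None
    skip_reason: str | None = None


@dataclass
class SearchReport:
    """Ranked LOOCV results for every evaluated (classifier, tuple) pair.

    Rows are sorted by global error, then disordered-class error, then by a
    preference for higher wavelengths (larger smallest member first, then
    lexicographically larger tuple first); the sort is stable, so equal keys
    keep evaluation order.
    """

    rows: list[SearchRow]
    skipped: list[SearchRow]

    @property
    def best(self) -> SearchRow | None:
        return self.rows[0] if self.rows else None

    def to_dataframe(self):
        import pandas as pd

        records = []
        for row in self.rows:
            r = row.result
            rec = {"cutoff": row.cutoff_nm, "family": row.spec.family.value}
            for j, w in enumerate(row.wl_tuple, start=1):
                rec[f"wl{j}"] = w
            rec.update(
                n_ordered=r.n_ordered,
                n_disordered=r.n_disordered,
                err_ordered=round(100.0 * r.err_ordered, 1),
                err_disordered=round(100.0 * r.err_disordered, 1),
                err_global=round(100.0 * r.err_global, 1),
            )
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def write_csv(self, path) -> None:
        """Error-table CSV: percentages with one decimal."""
        self.to_dataframe().to_csv(path, index=False)


def _rank_key(row: SearchRow):
    r = row.result
    return (
        r.err_global,
        r.err_disordered,
        tuple(-w for w in row.wl_tuple),
    )


def search_best(
    set_: LabeledSpectrumSet,
    cutoff_nm: float,
    tuple_size: int,
    specs,
    lo: int = TUPLE_RANGE_NM[0],
    hi: int = TUPLE_RANGE_NM[1],
    min_sep: int = MIN_TUPLE_SEPARATION_NM,
    tuples=None,
) -> SearchReport:
    """Exhaustive (classifier, wavelength-tuple) search ranked by LOOCV error.

    Feature values at every candidate wavelength are precomputed per spectrum,
    so the tens of thousands of tuple evaluations reuse one interpolation
    pass; results are identical to calling :func:`loocv_error` per tuple.
    Combinations whose covering subset is too small are recorded as skipped
    rows rather than raised.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("specs must be nonempty")
    if tuples is None:
        tuples = enumerate_tuples(tuple_size, lo=lo, hi=hi, min_sep=min_sep)

    grid = sorted({w for t in tuples for w in t})
    col = {w: j for j, w in enumerate(grid)}
    n = len(set_)
    V = np.full((n, len(grid)), np.nan)
    labels, ids, min_wl = [], [], np.empty(n)
    for i, (spec_i, label) in enumerate(set_.entries):
        de = convert_units(spec_i, Units.DELTA_EPSILON)
        labels.append(label)
        ids.append(spec_i.protein_id)
        min_wl[i] = spec_i.min_wavelength_nm
        for w in grid:
            if spec_i.covers(w):
                V[i, col[w]] = value_at(de, w)

    rows: list[SearchRow] = []
    skipped: list[SearchRow] = []
    for wl_tuple in tuples:
        cols = [col[w] for w in wl_tuple]
        mask = (min_wl <= cutoff_nm) & np.all(np.isfinite(V[:, cols]), axis=1)
        idx = np.flatnonzero(mask)
        sub_labels = tuple(labels[i] for i in idx)
        n_ord = sum(1 for l in sub_labels if l is Label.ORDERED)
        n_dis = len(sub_labels) - n_ord
        if n_ord < 2 or n_dis < 2:
            reason = (
                f"covering subset too small (ordered={n_ord}, disordered={n_dis})"
            )
            for spec in specs:
                skipped.append(SearchRow(cutoff_nm, spec, wl_tuple, None, reason))
            continue
        fm = FeatureMatrix(
            V[np.ix_(idx, cols)], sub_labels, tuple(ids[i] for i in idx)
        )
        for spec in specs:
            pred = _loocv_predicted_classes(fm, spec)
            rows.append(
                SearchRow(cutoff_nm, spec, wl_tuple, _result_from_predictions(fm, pred))
            )
    rows.sort(key=_rank_key)
    return SearchReport(rows, skipped)
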