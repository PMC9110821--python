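"""Sensitivity of classification error to amplitude rescaling and noise.

Two perturbations a real CD experiment suffers are emulated on top of the
leave-one-out protocol:

* **Concentration error** — the spectral amplitude scales linearly with the
  assumed protein concentration, so a mis-measured concentration rescales the
  whole curve. The sweep multiplies each held-out feature row by a factor
  (default 0.5-2.0) before prediction, training rows untouched. The
  cosine-metric KNN is exactly flat across factors; margin- and
  distance-based models are not.

* **Experimental noise** — i.i.d. Gaussian noise (mu = 0, sigma in
  delta-epsilon units, M^-1 cm^-1) is added to each held-out feature value
  and the LOOCV errors are averaged over many Monte Carlo repetitions
  (default 1,000). Per-repetition noise streams are derived from one root
  seed, so runs are reproducible and extending ``n_reps`` does not reshuffle
  earlier repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifiers import (
    KNN_FAMILIES,
    ClassifierSpec,
    _KNNModel,
    _vote,
    predict,
    train,
)
from .model_selection import (
    CVResult,
    _check_class_sizes,
    _result_from_predictions,
)
from .reference_set import (
    FeatureMatrix,
    Label,
    LabeledSpectrumSet,
    WavelengthTuple,
)


def _default_factors() -> tuple[float, ...]:
    # 0.5 .. 2.0 inclusive, step 0.05 (31 points, 1.0 included)
    return tuple(round(0.5 + 0.05 * i, 2) for i in range(31))


@dataclass(frozen=True)
class ScalingConfig:
    """Amplitude factors applied to held-out spectra (concentration error)."""

    factors: tuple[float, ...] = field(default_factory=_default_factors)

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(float(f) for f in self.factors))
        if any(f <= 0 for f in self.factors):
            raise ValueError("scaling factors must be positive")
        if 1.0 not in self.factors:
            raise ValueError("the identity factor 1.0 must be included")


@dataclass(frozen=True)
class NoiseConfig:
    """Additive Gaussian noise on held-out feature values (delta-epsilon)."""

    sigma: float
    n_reps: int = 1000
    seed: int = 0
    mu: float = 0.0  # fixed at zero; kept explicit for the record

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.mu != 0.0:
            raise ValueError("the noise model is zero-mean")


class LeaveOneOutPredictor:
    """Predict perturbed held-out rows against their leave-one-out models.

    Training never sees the perturbations, so the n leave-one-out models are
    built once and reused across scaling factors / noise repetitions. For KNN
    families, holding out row i is equivalent to masking the self-distance in
    a full-set model, which avoids refitting entirely; other families keep
    one fitted model per held-out row. Both routes give results identical to
    naive refitting.
    """

    def __init__(self, fm: FeatureMatrix, spec: ClassifierSpec):
        self.fm = fm
        self.spec = spec
        n = fm.n
        if spec.family in KNN_FAMILIES:
            p = spec.params
            self._full = _KNNModel(fm.X, fm.y, p["k"], p["metric"], p["weighted"])
            self._k_eff = min(p["k"], n - 1)
            self._weighted = p["weighted"]
            self._models = None
        else:
            self._full = None
            self._models = []
            keep = np.ones(n, dtype=bool)
            for i in range(n):
                keep[i] = False
                sub = FeatureMatrix(
                    fm.X[keep],
                    tuple(l for j, l in enumerate(fm.labels) if keep[j]),
                    tuple(s for j, s in enumerate(fm.ids) if keep[j]),
                )
                self._models.append(train(spec, sub))
                keep[i] = True

    def predict_rows(self, rows: np.ndarray) -> np.ndarray:
        """Class (0/1) of each row i under the model trained without row i."""
        n = self.fm.n
        pred = np.empty(n, dtype=int)
        if self._full is not None:
            y = self._full.y
            for i in range(n):
                d = self._full.distances(rows[i])
                d[i] = np.inf
                nbrs = np.argsort(d, kind="stable")[: self._k_eff]
                pred[i], _ = _vote(d[nbrs], y[nbrs], self._weighted)
            return pred
        for i, model in enumerate(self._models):
            label, _ = predict(model, rows[i])
            pred[i] = 1 if label is Label.DISORDERED else 0
        return pred


def _prepare(set_, wl_tuple, spec, cutoff_nm):
    subset = set_.covering_subset(wl_tuple, cutoff_nm)
    _check_class_sizes(subset)
    fm = subset.features_at(wl_tuple)
    return fm, LeaveOneOutPredictor(fm, spec)


def scaling_sweep(
    set_: LabeledSpectrumSet,
    wl_tuple: WavelengthTuple,
    spec: ClassifierSpec,
    cutoff_nm: float,
    cfg: ScalingConfig = ScalingConfig(),
) -> dict[float, CVResult]:
    """LOOCV error as a function of the test-spectrum amplitude factor.

    For each factor f, every held-out feature row is multiplied by f before
    prediction; the training rows stay at nominal amplitude. The f = 1 entry
    equals the unperturbed LOOCV result exactly. Deterministic.
    """
    fm, predictor = _prepare(set_, wl_tuple, spec, cutoff_nm)
    curve: dict[float, CVResult] = {}
    for f in cfg.factors:
        pred = predictor.predict_rows(fm.X * f)
        curve[f] = _result_from_predictions(fm, pred)
    return curve


@dataclass(frozen=True)
class NoiseResult:
    """Monte Carlo average of LOOCV errors under additive Gaussian noise."""

    mean: CVResult
    std_err_ordered: float
    std_err_disordered: float
    std_err_global: float
    per_rep_err_global: np.ndarray


def noise_mc(
    set_: LabeledSpectrumSet,
    wl_tuple: WavelengthTuple,
    spec: ClassifierSpec,
    cutoff_nm: float,
    cfg: NoiseConfig,
) -> NoiseResult:
    """Average LOOCV error over Monte Carlo repetitions of additive noise.

    Each repetition draws i.i.d. Gaussian(0, sigma) noise for every held-out
    feature value (delta-epsilon units), recomputes the LOOCV errors and
    averages across repetitions. With sigma = 0 every repetition equals the
    noiseless result exactly; a fixed seed reproduces the averages
    bit-identically. The reported spread is the standard deviation of the
    per-repetition error rates.
    """
    fm, predictor = _prepare(set_, wl_tuple, spec, cutoff_nm)
    y = fm.y
    n_ord = int(np.sum(y == 0))
    n_dis = int(np.sum(y == 1))
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(cfg.n_reps)
    eo = np.empty(cfg.n_reps)
    ed = np.empty(cfg.n_reps)
    wrong_count = np.zeros(fm.n)
    for r in range(cfg.n_reps):
        rng = np.random.default_rng(streams[r])
        noisy = fm.X + rng.normal(0.0, cfg.sigma, size=fm.X.shape)
        pred = predictor.predict_rows(noisy)
        wrong = pred != y
        wrong_count += wrong
        eo[r] = np.sum(wrong & (y == 0)) / n_ord
        ed[r] = np.sum(wrong & (y == 1)) / n_dis
    eg = (eo * n_ord + ed * n_dis) / (n_ord + n_dis)
    mean = CVResult(
        n_ordered=n_ord,
        n_disordered=n_dis,
        err_ordered=float(np.mean(eo)),
        err_disordered=float(np.mean(ed)),
        err_global=float(np.mean(eg)),
        misclassified_ids=tuple(
            fm.ids[i] for i in np.flatnonzero(wrong_count > 0.5 * cfg.n_reps)
        ),
    )
    return NoiseResult(
        mean=mean,
        std_err_ordered=float(np.std(eo)),
        std_err_disordered=float(np.std(ed)),
        std_err_global=float(np.std(eg)),
        per_rep_err_global=eg,
    )


def write_curve_csv(curve, path, x_name: str) -> None:
    """Write a (factor or sigma) -> CVResult curve as CSV for replotting."""
    import pandas as pd

    records = []
    for x, r in curve.items():
        records.append(
            {
                x_name: x,
                "err_ordered": r.err_ordered,
                "err_disordered": r.err_disordered,
                "err_global": r.err_global,
                "n": r.n_ordered + r.n_disordered,
            }
        )
    pd.DataFrame.from_records(records).to_csv(path, index=False)
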