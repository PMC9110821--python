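"""The 13 screened classifier variants behind one train/predict contract.

The screened family comprises decision trees (simple/medium leaf budgets),
support vector machines (linear and RBF kernels), k-nearest-neighbor variants
(Euclidean with k = 1/10/100, squared-inverse-distance weighted k = 10, and
cosine-metric k = 10), and Gaussian discriminant analyses (linear, quadratic
and their diagonal-covariance restrictions).

The KNN variants — including the flagship cosine-distance classifier, whose
scale invariance makes it immune to protein-concentration errors — are
implemented here with fully deterministic tie-break rules. Trees and SVMs
delegate to scikit-learn; the Gaussian discriminants are implemented as one
closed-form model covering the pooled/per-class and full/diagonal covariance
combinations.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import DegenerateInputError, TrainingError
from .reference_set import FeatureMatrix, Label


class ClassifierFamily(enum.Enum):
    TREE_SIMPLE = "tree_simple"
    TREE_MEDIUM = "tree_medium"
    SVM_LINEAR = "svm_linear"
    SVM_RBF = "svm_rbf"
    KNN_FINE = "knn_fine"
    KNN_MEDIUM = "knn_medium"
    KNN_COARSE = "knn_coarse"
    KNN_WEIGHTED = "knn_weighted"
    KNN_COSINE = "knn_cosine"
    DISCR_LINEAR = "discr_linear"
    DISCR_QUADRATIC = "discr_quadratic"
    DISCR_DIAGLINEAR = "discr_diaglinear"
    DISCR_DIAGQUADRATIC = "discr_diagquadratic"


KNN_FAMILIES = {
    ClassifierFamily.KNN_FINE,
    ClassifierFamily.KNN_MEDIUM,
    ClassifierFamily.KNN_COARSE,
    ClassifierFamily.KNN_WEIGHTED,
    ClassifierFamily.KNN_COSINE,
}

#: Default hyperparameters per family. KNN neighbor counts follow the
#: fine/medium/coarse = 1/10/100 convention; the weighted and cosine variants
#: use 10 neighbors; trees cap at 4 (simple) or 20 (medium) leaves.
_DEFAULTS: dict[ClassifierFamily, dict] = {
    ClassifierFamily.TREE_SIMPLE: {"max_leaves": 4},
    ClassifierFamily.TREE_MEDIUM: {"max_leaves": 20},
    ClassifierFamily.SVM_LINEAR: {"margin_penalty": 1.0, "standardize": True},
    # kernel_scale None -> median-pairwise-distance heuristic at fit time
    ClassifierFamily.SVM_RBF: {
        "margin_penalty": 1.0,
        "kernel_scale": None,
        "standardize": True,
    },
    ClassifierFamily.KNN_FINE: {"k": 1, "metric": "euclidean", "weighted": False},
    ClassifierFamily.KNN_MEDIUM: {"k": 10, "metric": "euclidean", "weighted": False},
    ClassifierFamily.KNN_COARSE: {"k": 100, "metric": "euclidean", "weighted": False},
    ClassifierFamily.KNN_WEIGHTED: {"k": 10, "metric": "euclidean", "weighted": True},
    ClassifierFamily.KNN_COSINE: {"k": 10, "metric": "cosine", "weighted": False},
    ClassifierFamily.DISCR_LINEAR: {"pooled": True, "diagonal": False, "standardize": True},
    ClassifierFamily.DISCR_QUADRATIC: {"pooled": False, "diagonal": False, "standardize": True},
    ClassifierFamily.DISCR_DIAGLINEAR: {"pooled": True, "diagonal": True, "standardize": True},
    ClassifierFamily.DISCR_DIAGQUADRATIC: {"pooled": False, "diagonal": True, "standardize": True},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Identifies one screened model: a family plus resolved hyperparameters."""

    family: ClassifierFamily
    hyperparams: tuple = ()

    @classmethod
    def default(cls, family: ClassifierFamily | str) -> "ClassifierSpec":
        if isinstance(family, str):
            family = ClassifierFamily(family.strip().lower())
        return cls(family, tuple(sorted(_DEFAULTS[family].items())))

    @classmethod
    def from_config(cls, config: dict) -> "ClassifierSpec":
        """Build from a mapping like ``{"family": "knn_cosine", "k": 10}``."""
        cfg = dict(config)
        family = ClassifierFamily(str(cfg.pop("family")).strip().lower())
        params = dict(_DEFAULTS[family])
        for key, value in cfg.items():
            if key not in params:
                raise ValueError(f"{family.value} has no hyperparameter {key!r}")
            params[key] = value
        return cls(family, tuple(sorted(params.items())))

    def to_config(self) -> dict:
        return {"family": self.family.value, **dict(self.hyperparams)}

    @property
    def params(self) -> dict:
        if self.hyperparams:
            return dict(self.hyperparams)
        return dict(_DEFAULTS[self.family])


def all_default_specs() -> list[ClassifierSpec]:
    """The full 13-member screened family with default hyperparameters."""
    return [ClassifierSpec.default(f) for f in ClassifierFamily]


def cosine_distance(x, y) -> float:
    """``1 - cos(angle)`` between two vectors seen from the origin.

    Lies in [0, 2] and is invariant under multiplication of either argument
    by any positive scalar — the property that makes the cosine-metric KNN
    immune to spectral-amplitude (concentration) errors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("cosine_distance needs two equal-length vectors (>= 2)")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise DegenerateInputError("cosine distance undefined for the zero vector")
    return float(1.0 - float(np.dot(x / nx, y / ny)))


# --------------------------------------------------------------------------
# K-nearest neighbors
# --------------------------------------------------------------------------


class _KNNModel:
    """Lazy KNN with deterministic tie handling.

    Tie-break rules: equidistant neighbors at the k-th rank are included by
    stable training-index order; a tied (weighted) vote is broken by the label
    of the single nearest neighbor; under squared-inverse-distance weighting an
    exact-match neighbor (distance 0) wins outright, the 1/d^2 limit.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, k: int, metric: str, weighted: bool):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self.metric = metric
        self.weighted = weighted
        self.k = int(k)
        self.k_eff = min(self.k, len(self.y))  # clamp when the set is smaller than k
        if metric == "cosine":
            norms = np.linalg.norm(self.X, axis=1)
            if np.any(norms == 0.0):
                raise DegenerateInputError(
                    "cosine metric undefined for zero training vectors"
                )
            self._Xhat = self.X / norms[:, None]

    def distances(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if self.metric == "cosine":
            nq = np.linalg.norm(q)
            if nq == 0.0:
                raise DegenerateInputError("cosine metric undefined for zero query")
            return 1.0 - self._Xhat @ (q / nq)
        diff = self.X - q
        return np.sqrt(np.einsum("ij,ij->i", diff, diff))

    def predict(self, q: np.ndarray) -> tuple[int, float, np.ndarray]:
        """Return (class, vote fraction for that class, neighbor indices)."""
        d = self.distances(q)
        order = np.argsort(d, kind="stable")
        nbrs = order[: self.k_eff]
        return _vote(d[nbrs], self.y[nbrs], self.weighted) + (nbrs,)


def _vote(d: np.ndarray, labels: np.ndarray, weighted: bool) -> tuple[int, float]:
    """Majority / weighted-majority vote among neighbors sorted by distance."""
    if weighted and np.any(d == 0.0):
        exact = labels[d == 0.0]
        c1 = int(np.sum(exact == 1))
        c0 = len(exact) - c1
        if c1 == c0:
            return int(labels[0]), 0.5
        win = 1 if c1 > c0 else 0
        return win, max(c0, c1) / len(exact)
    if weighted:
        w = 1.0 / d**2
        w1 = float(np.sum(w[labels == 1]))
        w0 = float(np.sum(w)) - w1
        if w1 == w0:
            return int(labels[0]), 0.5
        win = 1 if w1 > w0 else 0
        return win, max(w0, w1) / (w0 + w1)
    c1 = int(np.sum(labels == 1))
    c0 = len(labels) - c1
    if c1 == c0:
        return int(labels[0]), 0.5
    win = 1 if c1 > c0 else 0
    return win, max(c0, c1) / len(labels)


# --------------------------------------------------------------------------
# Gaussian discriminants
# --------------------------------------------------------------------------


class _GaussianDiscriminant:
    """Gaussian class-conditional classifier with empirical priors.

    ``pooled=True`` shares one covariance across classes (linear decision
    surface); ``pooled=False`` fits per-class covariances (quadratic surface).
    ``diagonal=True`` zeroes the off-diagonal covariances. Singular
    covariances are ridged by ``1e-9 * trace/dim`` on the diagonal.
    """

    def __init__(self, X, y, pooled: bool, diagonal: bool):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes = np.array([0, 1])
        n, d = X.shape
        self.priors = np.array([np.mean(y == c) for c in self.classes])
        self.means = np.stack([X[y == c].mean(axis=0) for c in self.classes])
        covs = []
        if pooled:
            scatter = np.zeros((d, d))
            for c in self.classes:
                diff = X[y == c] - self.means[c]
                scatter += diff.T @ diff
            cov = scatter / max(n - len(self.classes), 1)
            covs = [cov, cov]
        else:
            for c in self.classes:
                diff = X[y == c] - self.means[c]
                covs.append(diff.T @ diff / max((y == c).sum() - 1, 1))
        self.covs = []
        for cov in covs:
            if diagonal:
                cov = np.diag(np.diag(cov))
            ridge = 1e-9 * np.trace(cov) / d
            cov = cov + (ridge if ridge > 0 else 1e-12) * np.eye(d)
            self.covs.append(cov)

    def log_likelihoods(self, q: np.ndarray) -> np.ndarray:
        out = np.empty(2)
        for i, c in enumerate(self.classes):
            cov = self.covs[i]
            sign, logdet = np.linalg.slogdet(cov)
            diff = q - self.means[i]
            maha = float(diff @ np.linalg.solve(cov, diff))
            out[i] = math.log(self.priors[i]) - 0.5 * (logdet + maha)
        return out

    def predict(self, q: np.ndarray) -> tuple[int, float]:
        ll = self.log_likelihoods(np.asarray(q, dtype=float))
        win = int(np.argmax(ll))  # tie -> ordered (class 0), deterministic
        post = 1.0 / (1.0 + math.exp(-abs(ll[win] - ll[1 - win])))
        return int(self.classes[win]), post


# --------------------------------------------------------------------------
# Unified train / predict surface
# --------------------------------------------------------------------------


@dataclass
class TrainedClassifier:
    """A fitted model; ``predict`` accepts queries of the training dimension."""

    spec: ClassifierSpec
    n_features: int
    _model: object
    _scaler: tuple[np.ndarray, np.ndarray] | None = None  # (mean, std)

    def _transform(self, q: np.ndarray) -> np.ndarray:
        if self._scaler is None:
            return q
        mean, std = self._scaler
        return (q - mean) / std


def train(spec: ClassifierSpec, features: FeatureMatrix) -> TrainedClassifier:
    """Fit one screened model on a feature matrix.

    Distance-based (KNN) families act on raw delta-epsilon values; SVM and
    discriminant families standardize each dimension to the training mean and
    variance. Fitting is deterministic: two fits on identical input yield
    identical predictions for every family.

    Raises
    ------
    TrainingError
        If the features contain a single class or fewer than 2 rows.
    """
    X, y = features.X, features.y
    if features.n < 2:
        raise TrainingError(f"need at least 2 training spectra, got {features.n}")
    if len(set(y.tolist())) < 2:
        only = features.labels[0].value
        raise TrainingError(f"training set contains a single class ({only})")
    params = spec.params
    fam = spec.family
    scaler = None
    if params.get("standardize"):
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std == 0.0, 1.0, std)
        scaler = (mean, std)
        X = (X - mean) / std

    if fam in KNN_FAMILIES:
        model = _KNNModel(X, y, params["k"], params["metric"], params["weighted"])
    elif fam in (ClassifierFamily.TREE_SIMPLE, ClassifierFamily.TREE_MEDIUM):
        model = DecisionTreeClassifier(
            criterion="gini", max_leaf_nodes=params["max_leaves"], random_state=0
        ).fit(X, y)
    elif fam is ClassifierFamily.SVM_LINEAR:
        model = SVC(kernel="linear", C=params["margin_penalty"], random_state=0).fit(X, y)
    elif fam is ClassifierFamily.SVM_RBF:
        scale = params.get("kernel_scale")
        if scale is None:
            scale = _median_pairwise_distance(X)
        gamma = 1.0 / (2.0 * scale**2) if scale > 0 else 1.0
        model = SVC(kernel="rbf", C=params["margin_penalty"], gamma=gamma, random_state=0).fit(X, y)
    else:
        model = _GaussianDiscriminant(X, y, params["pooled"], params["diagonal"])
    return TrainedClassifier(spec, X.shape[1], model, scaler)


def _median_pairwise_distance(X: np.ndarray) -> float:
    n = len(X)
    iu = np.triu_indices(n, k=1)
    diff = X[iu[0]] - X[iu[1]]
    d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    return float(np.median(d)) if d.size else 1.0


def predict(model: TrainedClassifier, query) -> tuple[Label, float]:
    """Classify one feature vector; returns (label, confidence in [0, 1]).

    For KNN families the confidence is the (weighted) vote fraction of the
    returned label; for the margin/likelihood families it is a monotone
    transform of the decision margin. Cosine-metric predictions are invariant
    under positive rescaling of the query.
    """
    q = np.asarray(query, dtype=float).ravel()
    if q.size != model.n_features:
        raise ValueError(
            f"query has dimension {q.size}, model expects {model.n_features}"
        )
    q = model._transform(q)
    inner = model._model
    if isinstance(inner, _KNNModel):
        cls, score, _ = inner.predict(q)
    elif isinstance(inner, _GaussianDiscriminant):
        cls, score = inner.predict(q)
    elif isinstance(inner, SVC):
        margin = float(inner.decision_function(q[None, :])[0])
        cls = int(inner.predict(q[None, :])[0])
        score = 1.0 / (1.0 + math.exp(-abs(margin)))
    else:  # decision tree
        proba = inner.predict_proba(q[None, :])[0]
        idx = int(np.argmax(proba))
        cls = int(inner.classes_[idx])
        score = float(proba[idx])
    return (Label.DISORDERED if cls == 1 else Label.ORDERED), float(score)


def predict_with_neighbors(
    model: TrainedClassifier, query
) -> tuple[Label, float, np.ndarray]:
    """Like :func:`predict` but also returns KNN neighbor training indices."""
    inner = model._model
    if not isinstance(inner, _KNNModel):
        raise ValueError("neighbor lists exist only for KNN families")
    q = model._transform(np.asarray(query, dtype=float).ravel())
    cls, score, nbrs = inner.predict(q)
    return (Label.DISORDERED if cls == 1 else Label.ORDERED), float(score), nbrs
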