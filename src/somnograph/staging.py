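"""Feature assembly, normalization, splitting and the sleep-stage classifier grid.

Per-epoch feature vectors combine the vectorized connectivity matrix with the
global graph-feature block. For the symmetric SL matrix only the strictly
lower triangle is kept (M(M-1)/2 distinct values, 171 at 19 channels), plus
the 7 undirected graph features: 178 dimensions. For the asymmetric RWE matrix
all off-diagonal entries are kept (M(M-1), 342 at 19 channels) plus 5 directed
graph features plus the 5 band-energy ratios: 352 dimensions.

Features are min-max normalized to [0, 1] per feature, with the scaler fitted
on the training split only. The classifier grid mirrors the three families
commonly compared for this task: k-nearest neighbours (k in {1,3,5} x
{euclidean, cityblock, cosine}), support vector machines (C in {0.1, 10, 100}
x {linear, poly d=3, poly d=5, gaussian}), and feed-forward neural networks
(1-2 hidden layers from {10, 30, 50, 100}). The train/test split is stratified
at epoch level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .graphs import GraphFeatures
from .preprocess import STAGES
from .rwe import BandRatios, RWEMatrix
from .sl import SLMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

def assemble_features(
    mat: SLMatrix | RWEMatrix,
    gfeat: GraphFeatures,
    ratios: BandRatios | None = None,
) -> np.ndarray:
    """Concatenate the vectorized connectivity matrix with its summary block.

    SL: strictly-lower-triangle entries in row-major order, then the 7
    undirected graph features. RWE: all off-diagonal entries in row-major
    order, then the 5 directed graph features, then the 5 band ratios
    (required for RWE, rejected for SL).
    """
    values = mat.values
    m = values.shape[0]
    gvec = gfeat.as_array()
    if isinstance(mat, SLMatrix):
        if ratios is not None:
            raise ValueError("Band ratios belong to the RWE feature vector only")
        if gvec.size != 7:
            raise ValueError(
                f"SL feature block needs 7 graph features, got {gvec.size}"
            )
        il = np.tril_indices(m, k=-1)
        conn = values[il]
    elif isinstance(mat, RWEMatrix):
        if ratios is None:
            raise ValueError("RWE feature vector requires the 5 band ratios")
        if gvec.size != 5:
            raise ValueError(
                f"RWE feature block needs 5 graph features, got {gvec.size}"
            )
        off = ~np.eye(m, dtype=bool)
        conn = values[off]  # row-major off-diagonal order
        gvec = np.concatenate([gvec, ratios.as_array()])
    else:
        raise TypeError(f"Cannot assemble features from {type(mat).__name__}")
    vec = np.concatenate([conn, gvec])
    if not np.all(np.isfinite(vec)):
        raise ValueError("Feature vector contains non-finite values")
    return vec


def feature_length(method: str, n_channels: int) -> int:
    """Expected vector length: M(M-1)/2 + 7 for SL, M(M-1) + 10 for RWE."""
    m = n_channels
    if method == "SL":
        return m * (m - 1) // 2 + 7
    if method == "RWE":
        return m * (m - 1) + 10
    raise ValueError(f"Unknown method {method!r}")


@dataclass
class Dataset:
    """A labelled feature matrix for one connectivity method."""

    x: np.ndarray
    y: np.ndarray
    method: str = "SL"
    split_tag: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y)
        if self.x.ndim != 2 or self.x.shape[0] != self.y.shape[0]:
            raise ValueError("Feature matrix and labels are misaligned")
        bad = set(self.y) - set(STAGES)
        if bad:
            raise ValueError(f"Labels outside stage vocabulary: {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.x.shape[0]


# ---------------------------------------------------------------------------
# normalization and splitting
# ---------------------------------------------------------------------------

@dataclass
class MinMaxScaler:
    """Per-feature affine map to [0, 1] fitted on the training split.

    Constant features map to 0; transformed values are clipped to [0, 1], so
    test values outside the training range saturate.
    """

    lo: np.ndarray = field(default_factory=lambda: np.empty(0))
    span: np.ndarray = field(default_factory=lambda: np.empty(0))

    def fit(self, x: np.ndarray) -> "MinMaxScaler":
        x = np.asarray(x, dtype=np.float64)
        self.lo = x.min(axis=0)
        self.span = x.max(axis=0) - self.lo
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(self.span > 0, (x - self.lo) / self.span, 0.0)
        return np.clip(out, 0.0, 1.0)


def minmax_normalize(
    train: Dataset, test: Dataset
) -> tuple[Dataset, Dataset, MinMaxScaler]:
    """Fit the [0, 1] scaler on train only and apply it to both splits."""
    if train.n == 0:
        raise ValueError("Cannot fit a scaler on an empty training set")
    scaler = MinMaxScaler().fit(train.x)
    tr = Dataset(scaler.transform(train.x), train.y, train.method, "train")
    te = Dataset(scaler.transform(test.x), test.y, test.method, "test")
    return tr, te, scaler


def stratified_split(
    ds: Dataset, train_frac: float = 0.7, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Seeded stratified epoch-level split into train/test.

    Each class contributes round(train_frac * n_class) epochs to train (always
    leaving at least one per side). Deterministic given seed.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in sorted(set(ds.y)):
        idx = np.flatnonzero(ds.y == cls)
        if idx.size < 2:
            raise ValueError(
                f"Class {cls!r} has {idx.size} member(s); need >= 2 to split"
            )
        idx = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return (
        Dataset(ds.x[tr], ds.y[tr], ds.method, "train"),
        Dataset(ds.x[te], ds.y[te], ds.method, "test"),
    )


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family with hyperparameters (scalars or candidate lists).

    kNN params: k, metric in {euclidean, cityblock, cosine}. SVM params: C,
    kernel in {linear, poly, gaussian}, degree (poly), sigma (gaussian). NN
    params: layers (tuple of hidden-layer sizes).
    """

    family: str
    params: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.family not in ("kNN", "SVM", "NN"):
            raise ValueError(f"Unknown classifier family {self.family!r}")

    @classmethod
    def make(cls, family: str, **params) -> "ClassifierSpec":
        def freeze(v):
            return tuple(v) if isinstance(v, list) else v
        return cls(family, tuple((k, freeze(v)) for k, v in sorted(params.items())))

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    def describe(self) -> str:
        inner = ", ".join(f"{k}={v}" for k, v in self.params)
        return f"{self.family}({inner})"


def _build_estimator(family: str, params: dict, seed: int):
    if family == "kNN":
        metric = params.get("metric", "euclidean")
        # cosine handled as a similarity: nearest = largest cosine similarity,
        # identical to smallest cosine distance, which sklearn implements
        metric = {"euclidean": "euclidean", "cityblock": "manhattan",
                  "cosine": "cosine"}[metric]
        return KNeighborsClassifier(n_neighbors=int(params.get("k", 1)),
                                    metric=metric)
    if family == "SVM":
        kernel = params.get("kernel", "linear")
        c = float(params.get("C", 1.0))
        if kernel == "linear":
            return SVC(C=c, kernel="linear", random_state=seed)
        if kernel == "poly":
            return SVC(C=c, kernel="poly", degree=int(params.get("degree", 3)),
                       coef0=1.0, gamma="scale", random_state=seed)
        if kernel == "gaussian":
            sigma = float(params.get("sigma", 1.0))
            return SVC(C=c, kernel="rbf", gamma=1.0 / (2.0 * sigma ** 2),
                       random_state=seed)
        raise ValueError(f"Unknown SVM kernel {kernel!r}")
    if family == "NN":
        layers = tuple(int(s) for s in params.get("layers", (10,)))
        return MLPClassifier(
            hidden_layer_sizes=layers, activation="relu", solver="adam",
            early_stopping=True, validation_fraction=0.1, max_iter=500,
            random_state=seed,
        )
    raise ValueError(f"Unknown classifier family {family!r}")


def _candidates(spec: ClassifierSpec) -> list[dict]:
    """Expand list-valued hyperparameters, ordered simplest-first.

    Simplicity order used for CV tie-breaking: smaller C, fewer then smaller
    hidden layers.
    """
    grids: list[dict] = [{}]
    for key, val in spec.params:
        vals = list(val) if isinstance(val, tuple) and key != "layers" else [val]
        if key == "layers" and val and isinstance(val[0], tuple):
            vals = list(val)  # a tuple of layer tuples = candidates
        grids = [dict(g, **{key: v}) for g in grids for v in vals]

    def complexity(g: dict):
        c = float(g.get("C", 0.0))
        layers = g.get("layers", ())
        return (c, len(layers), sum(layers) if layers else 0)

    return sorted(grids, key=complexity)


def train_classifier(
    spec: ClassifierSpec,
    train: Dataset,
    cv_folds: int = 10,
    seed: int = 0,
):
    """Fit one classifier; list-valued SVM/NN hyperparameters are CV-selected.

    Selection uses stratified cv_folds-fold accuracy on the training split
    only; ties go to the simpler model. kNN is fitted directly.
    """
    if train.n < 2 or len(set(train.y)) < 2:
        raise ValueError("Training set is degenerate (needs >= 2 classes)")

    def build(params: dict):
        est = _build_estimator(spec.family, params, seed)
        # early stopping needs a meaningful validation carve-out
        if spec.family == "NN" and train.n < 50:
            est.set_params(early_stopping=False)
        return est

    candidates = _candidates(spec)
    if spec.family == "kNN" or len(candidates) == 1:
        return build(candidates[0]).fit(train.x, train.y)
    best, best_score = None, -np.inf
    n_splits = min(cv_folds, int(np.bincount(
        np.unique(train.y, return_inverse=True)[1]).min()))
    cv = StratifiedKFold(n_splits=max(2, n_splits), shuffle=True,
                         random_state=seed)
    for params in candidates:
        score = cross_val_score(build(params), train.x, train.y, cv=cv).mean()
        logger.debug("CV %s %s: %.4f", spec.family, params, score)
        if score > best_score:  # strict: first (simplest) wins ties
            best, best_score = params, score
    return build(best).fit(train.x, train.y)


@dataclass
class EvalReport:
    """Accuracy summary; confusion rows = predicted, columns = true stage."""

    overall_accuracy: float
    per_class_accuracy: dict[str, float]
    confusion: pd.DataFrame


def evaluate(model, test: Dataset) -> EvalReport:
    """Confusion matrix and accuracies of a fitted model on the test split."""
    pred = model.predict(test.x)
    bad = set(pred) - set(STAGES)
    if bad:
        raise ValueError(f"Predictions outside stage vocabulary: {sorted(bad)}")
    conf = pd.DataFrame(0, index=list(STAGES), columns=list(STAGES), dtype=int)
    for p, t in zip(pred, test.y):
        conf.loc[p, t] += 1
    overall = float(np.trace(conf.values) / test.n * 100.0)
    per_class = {}
    for s in STAGES:
        col = conf[s].sum()
        per_class[s] = float(conf.loc[s, s] / col * 100.0) if col else float("nan")
    return EvalReport(overall, per_class, conf)


# ---------------------------------------------------------------------------
# the grid
# ---------------------------------------------------------------------------

def default_grid(method: str) -> list[ClassifierSpec]:
    """The 31-spec comparison grid (9 kNN + 15 SVM + 7 NN).

    Gaussian-kernel widths differ by feature method (SL: 1.95/1.45,
    RWE: 0.25/0.75), reflecting the different feature scales.
    """
    sigmas = {"SL": (1.95, 1.45), "RWE": (0.25, 0.75)}[method]
    grid: list[ClassifierSpec] = []
    for metric in ("euclidean", "cityblock", "cosine"):
        for k in (1, 3, 5):
            grid.append(ClassifierSpec.make("kNN", k=k, metric=metric))
    for kernel, extra in (
        ("linear", {}),
        ("poly", {"degree": 3}),
        ("poly", {"degree": 5}),
        ("gaussian", {"sigma": sigmas[0]}),
        ("gaussian", {"sigma": sigmas[1]}),
    ):
        for c in (0.1, 10.0, 100.0):
            grid.append(ClassifierSpec.make("SVM", C=c, kernel=kernel, **extra))
    for layers in ((10,), (30,), (50,), (100,), (50, 50), (100, 50),
                   (100, 100)):
        grid.append(ClassifierSpec.make("NN", layers=layers))
    return grid


def compact_grid(method: str) -> list[ClassifierSpec]:
    """A small representative grid (5 specs) spanning all three families.

    Used where the full 31-spec comparison is too slow: two kNN variants, a
    linear and a gaussian SVM (method-matched width), and one small network.
    """
    sigma = {"SL": 1.95, "RWE": 0.25}[method]
    return [
        ClassifierSpec.make("kNN", k=1, metric="euclidean"),
        ClassifierSpec.make("kNN", k=5, metric="cosine"),
        ClassifierSpec.make("SVM", C=10.0, kernel="linear"),
        ClassifierSpec.make("SVM", C=10.0, kernel="gaussian", sigma=sigma),
        ClassifierSpec.make("NN", layers=(30,)),
    ]


def run_grid(
    features: dict[str, Dataset],
    grid: dict[str, Sequence[ClassifierSpec]] | Sequence[ClassifierSpec] | None = None,
    train_frac: float = 0.7,
    seed: int = 0,
    cv_folds: int = 10,
) -> pd.DataFrame:
    """Train and evaluate every (feature set, spec) combination.

    ``features`` maps method name ("SL"/"RWE") to its full Dataset; the same
    seeded stratified split is applied per feature set. Returns a tidy table
    with one row per combination: method, family, params, train and test
    accuracy (%).
    """
    rows = []
    for method, ds in features.items():
        specs = (grid[method] if isinstance(grid, dict)
                 else grid if grid is not None else default_grid(method))
        train, test = stratified_split(ds, train_frac=train_frac, seed=seed)
        train, test, _ = minmax_normalize(train, test)
        for spec in specs:
            model = train_classifier(spec, train, cv_folds=cv_folds, seed=seed)
            rep_tr = evaluate(model, train)
            rep_te = evaluate(model, test)
            rows.append({
                "method": method,
                "family": spec.family,
                "params": spec.describe(),
                "train_acc": rep_tr.overall_accuracy,
                "test_acc": rep_te.overall_accuracy,
            })
            logger.info("%s %s: train %.2f%% test %.2f%%", method,
                        spec.describe(), rep_tr.overall_accuracy,
                        rep_te.overall_accuracy)
    return pd.DataFrame(rows)
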