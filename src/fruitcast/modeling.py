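"""Feature assembly and ridge regression to harvest mass.

Each quality-controlled fruit contributes one row: its anchor masses
(estimated size at the scheme's fixed thermal times), optionally the mean
air temperature over its prediction period, and its actual harvest mass as
the target.  Features are z-score normalised on the training split only,
and a ridge regression is fitted in closed form,

    w = (X^T X + lambda I)^-1 X^T y_c,

with the intercept unpenalised (features centred/scaled, target left in
grams, intercept = mean training mass).  The regularisation strength is
chosen by repeated k-fold cross-validation maximising mean R^2.

Tree-ensemble alternatives (extra-trees, gradient boosting) are available
behind the same fit/predict interface via :func:`make_model`; ridge is the
reference model and the only one implemented from first principles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    DegenerateDataError,
    DomainError,
    InsufficientDataError,
    SchemaError,
    SolverError,
)
from .evaluation import r_squared
from .growth_curve import AnchorScheme

__all__ = [
    "FeatureRow",
    "Normalizer",
    "RidgeModel",
    "SplitSpec",
    "build_feature_table",
    "split_train_test",
    "fit_ridge",
    "cv_select_lambda",
    "predict",
    "make_model",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID: Tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class FeatureRow:
    """Explanatory features and harvest-mass target for one fruit."""

    fruit_id: str
    features: Tuple[float, ...]
    target: float  # harvest mass, g

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(float(f) for f in self.features))
        if self.target <= 0:
            raise DomainError(f"harvest mass must be positive, got {self.target}")


def _as_matrix(rows: Sequence[FeatureRow]) -> Tuple[np.ndarray, np.ndarray]:
    if not rows:
        raise InsufficientDataError("no feature rows")
    k = len(rows[0].features)
    if any(len(r.features) != k for r in rows):
        raise SchemaError("inconsistent feature count across rows")
    X = np.array([r.features for r in rows], dtype=float)
    y = np.array([r.target for r in rows], dtype=float)
    return X, y


def build_feature_table(
    fruits: Iterable,
    scheme: AnchorScheme,
    include_mean_temp: bool = False,
) -> List[FeatureRow]:
    """Assemble the model table from anchored fruit records.

    ``fruits`` are records with attributes ``fruit_id``, ``scheme``,
    ``anchor_values``, ``qc_pass``, ``harvest_mass`` and ``mean_temp``
    (see :class:`fruitcast.pipeline.AnchorRecord`).  Fruits failing the
    r^2 gate or lacking a harvest mass are dropped; rows are sorted by
    fruit id for determinism.
    """
    rows: List[FeatureRow] = []
    for f in fruits:
        if getattr(f, "scheme", scheme.name) != scheme.name:
            raise SchemaError(
                f"record {f.fruit_id} carries scheme {f.scheme!r}, expected {scheme.name!r}"
            )
        if not f.qc_pass or f.harvest_mass is None:
            continue
        feats = tuple(f.anchor_values)
        if len(feats) != len(scheme.anchors):
            raise SchemaError(f"record {f.fruit_id} has {len(feats)} anchors")
        if include_mean_temp:
            if f.mean_temp is None:
                raise SchemaError(f"record {f.fruit_id} lacks mean temperature")
            feats = feats + (float(f.mean_temp),)
        rows.append(FeatureRow(str(f.fruit_id), feats, float(f.harvest_mass)))
    if not rows:
        raise InsufficientDataError("no usable fruits (qc_pass with harvest mass)")
    rows.sort(key=lambda r: r.fruit_id)
    return rows


@dataclass(frozen=True)
class Normalizer:
    """Per-feature z-score statistics, fitted on training rows only.

    Sample standard deviation (ddof=1) is used.
    """

    means: Tuple[float, ...]
    sds: Tuple[float, ...]

    @classmethod
    def fit(cls, X: np.ndarray) -> "Normalizer":
        if X.shape[0] < 2:
            raise InsufficientDataError("need >= 2 training rows to normalise")
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        bad = np.nonzero(sds <= 0)[0]
        if bad.size:
            raise DegenerateDataError(
                f"zero-variance feature column(s) {bad.tolist()}; cannot z-score"
            )
        return cls(tuple(means), tuple(sds))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.means):
            raise SchemaError(
                f"expected {len(self.means)} features, got {X.shape[1]}"
            )
        return (X - np.asarray(self.means)) / np.asarray(self.sds)


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test partition: fraction of rows used for training."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise DomainError("train_fraction must be in (0, 1)")


def split_train_test(
    rows: Sequence[FeatureRow], spec: SplitSpec
) -> Tuple[List[FeatureRow], List[FeatureRow]]:
    """Seed-deterministic random split; |train| = round(train_fraction * n)."""
    n = len(rows)
    if n < 5:
        raise InsufficientDataError(f"need >= 5 rows to split, got {n}")
    n_train = int(np.floor(spec.train_fraction * n + 0.5))
    perm = np.random.default_rng(spec.seed).permutation(n)
    train = [rows[i] for i in sorted(perm[:n_train])]
    test = [rows[i] for i in sorted(perm[n_train:])]
    return train, test


@dataclass(frozen=True)
class RidgeModel:
    """Closed-form ridge fit in normalised feature space.

    ``weights`` act on z-scored features; ``intercept`` is in grams and is
    never penalised.  Predictions are therefore directly in grams.
    """

    weights: Tuple[float, ...]
    intercept: float
    lam: float
    normalizer: Normalizer

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "ridge",
                "weights": list(self.weights),
                "intercept": self.intercept,
                "lambda": self.lam,
                "feature_means": list(self.normalizer.means),
                "feature_sds": list(self.normalizer.sds),
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RidgeModel":
        d = json.loads(text)
        if d.get("model") != "ridge":
            raise SchemaError(f"not a ridge model file: {d.get('model')!r}")
        return cls(
            weights=tuple(d["weights"]),
            intercept=float(d["intercept"]),
            lam=float(d["lambda"]),
            normalizer=Normalizer(tuple(d["feature_means"]), tuple(d["feature_sds"])),
        )


def _solve_ridge(Xn: np.ndarray, y: np.ndarray, lam: float) -> Tuple[np.ndarray, float]:
    """Ridge weights on pre-normalised features; intercept = mean(y)."""
    if lam < 0:
        raise DomainError("lambda must be non-negative")
    ybar = float(y.mean())
    yc = y - ybar
    A = Xn.T @ Xn + lam * np.eye(Xn.shape[1])
    try:
        if lam == 0 and np.linalg.cond(A) > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned")
        w = np.linalg.solve(A, Xn.T @ yc)
    except np.linalg.LinAlgError as e:
        raise SolverError(
            "normal equations singular at lambda = 0 (collinear features); "
            "use lambda > 0"
        ) from e
    return w, ybar


def fit_ridge(train_rows: Sequence[FeatureRow], lam: float) -> RidgeModel:
    """Fit ridge regression; with lambda = 0 this is ordinary least squares."""
    X, y = _as_matrix(train_rows)
    norm = Normalizer.fit(X)
    w, b = _solve_ridge(norm.transform(X), y, lam)
    return RidgeModel(weights=tuple(w), intercept=b, lam=float(lam), normalizer=norm)


def predict(model: RidgeModel, rows: Sequence[FeatureRow]) -> np.ndarray:
    """Predicted harvest masses in grams (test rows pass through the
    training normaliser; test statistics are never refitted)."""
    X, _ = _as_matrix(rows)
    return model.normalizer.transform(X) @ np.asarray(model.weights) + model.intercept


def cv_select_lambda(
    train_rows: Sequence[FeatureRow],
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    k_folds: int = 10,
    repeats: int = 3,
    seed: int = 0,
) -> float:
    """Pick the grid lambda maximising mean R^2 under repeated k-fold CV.

    Rows are ordered by fruit id before folding, so the selection is
    invariant to the caller's row order.  Ties break toward the larger
    lambda (more regularisation at equal accuracy).
    """
    if not len(grid):
        raise DomainError("lambda grid is empty")
    rows = sorted(train_rows, key=lambda r: r.fruit_id)
    n = len(rows)
    if n < k_folds:
        raise InsufficientDataError(f"{n} rows < {k_folds} folds")
    rng = np.random.default_rng(seed)
    fold_plans = [rng.permutation(n) for _ in range(repeats)]
    scores = np.zeros(len(grid))
    for perm in fold_plans:
        folds = np.array_split(perm, k_folds)
        for fold in folds:
            mask = np.zeros(n, dtype=bool)
            mask[fold] = True
            tr = [rows[i] for i in range(n) if not mask[i]]
            te = [rows[i] for i in range(n) if mask[i]]
            te_y = [r.target for r in te]
            if len(te) < 2 or np.ptp(te_y) == 0:
                continue  # fold too small/degenerate to score
            X, y = _as_matrix(tr)
            norm = Normalizer.fit(X)
            Xn = norm.transform(X)
            Xte = norm.transform(np.array([r.features for r in te]))
            for j, lam in enumerate(grid):
                w, b = _solve_ridge(Xn, y, float(lam))
                scores[j] += r_squared(Xte @ w + b, te_y)
    best = np.nonzero(scores >= scores.max() - 1e-12)[0]
    return float(sorted(float(grid[j]) for j in best)[-1])


# -- pluggable alternatives ---------------------------------------------


class _SklearnWrapper:
    """Adapts a scikit-learn regressor to the FeatureRow fit/predict surface."""

    def __init__(self, estimator):
        self._est = estimator
        self._norm: Optional[Normalizer] = None

    def fit(self, rows: Sequence[FeatureRow]) -> "_SklearnWrapper":
        X, y = _as_matrix(rows)
        self._norm = Normalizer.fit(X)
        self._est.fit(self._norm.transform(X), y)
        return self

    def predict(self, rows: Sequence[FeatureRow]) -> np.ndarray:
        if self._norm is None:
            raise DomainError("model not fitted")
        X, _ = _as_matrix(rows)
        return np.asarray(self._est.predict(self._norm.transform(X)), dtype=float)


class _RidgeFrontend:
    """Ridge with CV-selected lambda behind the common fit/predict surface."""

    def __init__(self, lambda_grid=DEFAULT_LAMBDA_GRID, k_folds=10, repeats=3, seed=0):
        self.lambda_grid = tuple(lambda_grid)
        self.k_folds = k_folds
        self.repeats = repeats
        self.seed = seed
        self.model: Optional[RidgeModel] = None

    def fit(self, rows: Sequence[FeatureRow]) -> "_RidgeFrontend":
        lam = cv_select_lambda(
            rows, self.lambda_grid, k_folds=self.k_folds, repeats=self.repeats, seed=self.seed
        )
        self.model = fit_ridge(rows, lam)
        return self

    def predict(self, rows: Sequence[FeatureRow]) -> np.ndarray:
        if self.model is None:
            raise DomainError("model not fitted")
        return predict(self.model, rows)


def make_model(name: str, seed: int = 0, **kwargs):
    """Build a regression model by name: ``ridge``, ``extra_trees`` or ``gbdt``.

    The tree ensembles are scikit-learn backed plug-ins offered for
    comparison; ridge is the reference implementation.
    """
    if name == "ridge":
        return _RidgeFrontend(seed=seed, **kwargs)
    if name == "extra_trees":
        from sklearn.ensemble import ExtraTreesRegressor

        return _SklearnWrapper(ExtraTreesRegressor(random_state=seed, **kwargs))
    if name == "gbdt":
        from sklearn.ensemble import GradientBoostingRegressor

        return _SklearnWrapper(GradientBoostingRegressor(random_state=seed, **kwargs))
    raise DomainError(f"unknown model {name!r}; choose ridge, extra_trees or gbdt")
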