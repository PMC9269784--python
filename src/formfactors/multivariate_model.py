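"""Linear-SVM benign/malignant classification over base and extended feature sets.

The *base* set holds the conventional size features (maximum 3D diameter,
surface area, volume); the *extended* set adds the four form factors that
discriminate the groups in both reference cohorts (AFL, ACO, KFL, MPS).
Features are Z-scored per dataset, feature by feature, with each dataset
blind to the other; the SVM penalty C is grid-searched over
{0.01, 0.1, 1.0, 10.0}. Evaluation is leave-one-out within a dataset and
plain holdout across datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import DomainError

#: Conventional size features.
BASE_FEATURES = ("max3ddiam", "surfarea", "volume")
#: Base plus the four discriminative form factors.
EXTENDED_FEATURES = BASE_FEATURES + ("afl", "aco", "kfl", "mps")

FEATURE_SETS = {"base": BASE_FEATURES, "extended": EXTENDED_FEATURES}

_LABEL_CODES = {"benign": 0, "malignant": 1}


@dataclass(frozen=True)
class ClassifierConfig:
    """Linear-SVM configuration: penalty grid and feature set."""

    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    feature_set: str = "extended"
    tol: float = 1e-6
    max_iter: int = 100_000

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.c_grid):
            raise DomainError("all penalty values must be positive")
        if self.feature_set not in FEATURE_SETS:
            raise DomainError(f"unknown feature set {self.feature_set!r}")

    @property
    def features(self) -> tuple[str, ...]:
        return FEATURE_SETS[self.feature_set]


@dataclass(frozen=True)
class EvalResult:
    """Accuracy of one train/test combination."""

    train_id: str
    test_id: str
    feature_set: str
    correct: int
    total: int
    chosen_c: float

    @property
    def accuracy(self) -> float:
        return self.correct / self.total

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.correct / self.total

    def formatted(self) -> str:
        """Accuracy as printed in study tables, e.g. ``"49.4 (41/83)"``."""
        return f"{self.accuracy_pct:.1f} ({self.correct}/{self.total})"


@dataclass(frozen=True)
class ZScoreParams:
    """Per-feature location/scale fitted on one dataset (population SD)."""

    features: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray


def zscore_fit(cohort: pd.DataFrame, features=EXTENDED_FEATURES) -> ZScoreParams:
    """Fit per-feature Z-score parameters on one dataset.

    Uses the population (n denominator) SD. A zero-variance feature gets
    scale 1 with a warning, so it maps to all zeros after centering.
    """
    if len(cohort) < 2:
        raise DomainError("need at least 2 samples to fit normalization")
    X = cohort.loc[:, list(features)].to_numpy(float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    zero = scale == 0
    if zero.any():
        warnings.warn(
            f"zero-variance features mapped to zeros: "
            f"{[f for f, z in zip(features, zero) if z]}",
            stacklevel=2,
        )
        scale = np.where(zero, 1.0, scale)
    return ZScoreParams(tuple(features), mean, scale)


def zscore_apply(params: ZScoreParams, cohort: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``cohort`` with the fitted features standardised."""
    out = cohort.copy()
    X = out.loc[:, list(params.features)].to_numpy(float)
    out.loc[:, list(params.features)] = (X - params.mean) / params.scale
    return out


def _labels_to_codes(labels) -> np.ndarray:
    codes = []
    for v in labels:
        if v in _LABEL_CODES:
            codes.append(_LABEL_CODES[v])
        elif v in (0, 1):
            codes.append(int(v))
        else:
            raise DomainError(f"unknown class label {v!r}")
    y = np.asarray(codes, dtype=int)
    if len(np.unique(y)) < 2:
        raise DomainError("both classes must be present")
    return y


def train_lsvm(X: np.ndarray, y, c: float, tol: float = 1e-6,
               max_iter: int = 100_000) -> SVC:
    """Fit a deterministic soft-margin linear SVM at penalty ``c``."""
    y = _labels_to_codes(y)
    clf = SVC(kernel="linear", C=c, tol=tol, max_iter=max_iter)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def loo_eval(
    cohort: pd.DataFrame,
    feature_set: str = "extended",
    c: float = 1.0,
    dataset_id: str | None = None,
    strict_normalization: bool = False,
) -> EvalResult:
    """Leave-one-out accuracy of the linear SVM on one dataset.

    By default the Z-score parameters are fitted once on the whole dataset
    and reused in every fold (the per-dataset normalisation protocol; it
    leaks the held-out sample's contribution to the feature moments, which
    is documented). ``strict_normalization`` refits them inside each fold.
    """
    n = len(cohort)
    if n < 3:
        raise DomainError("leave-one-out needs at least 3 samples")
    features = list(FEATURE_SETS[feature_set])
    y = _labels_to_codes(cohort["label"])
    if not strict_normalization:
        params = zscore_fit(cohort, features)
        X = zscore_apply(params, cohort).loc[:, features].to_numpy(float)
    else:
        X = cohort.loc[:, features].to_numpy(float)
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        Xtr, Xte = X[tr], X[i : i + 1]
        if strict_normalization:
            mean = Xtr.mean(axis=0)
            scale = Xtr.std(axis=0)
            scale = np.where(scale == 0, 1.0, scale)
            Xtr = (Xtr - mean) / scale
            Xte = (Xte - mean) / scale
        if len(np.unique(y[tr])) < 2:
            # a fold can lose the minority class entirely (tiny cohorts);
            # the only consistent rule is to predict the remaining class
            pred = y[tr][0]
        else:
            clf = train_lsvm(Xtr, y[tr], c)
            pred = clf.predict(Xte)[0]
        correct += int(pred == y[i])
    ds = dataset_id or _dataset_id(cohort)
    return EvalResult(ds, ds, feature_set, correct, n, c)


def cross_eval(
    train: pd.DataFrame,
    test: pd.DataFrame,
    feature_set: str = "extended",
    c: float = 1.0,
) -> EvalResult:
    """Train on one dataset and test on another, each Z-scored on its own.

    The test cohort is normalised with parameters fitted on the test
    cohort itself, never the training one (the two datasets are mutually
    blind). Note ``cross_eval(d, d, ...)`` equals whole-set training
    accuracy.
    """
    features = list(FEATURE_SETS[feature_set])
    missing = [f for f in features if f not in test.columns]
    if missing:
        raise DomainError(f"test cohort lacks features {missing}")
    ytr = _labels_to_codes(train["label"])
    yte = np.asarray(
        [_LABEL_CODES.get(v, v) for v in test["label"]], dtype=int
    )
    Xtr = zscore_apply(zscore_fit(train, features), train).loc[:, features]
    Xte = zscore_apply(zscore_fit(test, features), test).loc[:, features]
    clf = train_lsvm(Xtr.to_numpy(float), ytr, c)
    pred = clf.predict(Xte.to_numpy(float))
    return EvalResult(
        _dataset_id(train), _dataset_id(test), feature_set,
        int((pred == yte).sum()), len(test), c,
    )


def grid_search_c(
    train: pd.DataFrame,
    eval_protocol: str = "loo",
    config: ClassifierConfig = ClassifierConfig(),
    test: pd.DataFrame | None = None,
) -> tuple[float, EvalResult]:
    """Evaluate every C in the grid and keep the best accuracy.

    ``eval_protocol`` is ``"loo"`` (leave-one-out on ``train``) or
    ``"holdout"`` (evaluate on ``test``). Ties are broken toward the
    smallest C (strongest regularisation).
    """
    best: EvalResult | None = None
    for c in sorted(config.c_grid):
        if eval_protocol == "loo":
            res = loo_eval(train, config.feature_set, c)
        elif eval_protocol == "holdout":
            if test is None:
                raise DomainError("holdout protocol requires a test cohort")
            res = cross_eval(train, test, config.feature_set, c)
        else:
            raise DomainError(f"unknown protocol {eval_protocol!r}")
        if best is None or res.correct > best.correct:
            best = res
    return best.chosen_c, best


def gain(base: EvalResult, extended: EvalResult) -> tuple[float, int, int]:
    """Accuracy gain of the extended over the base feature set.

    Returns ``(percentage points, correct-count difference, total)``; e.g.
    63.8% vs 49.4% on 83 samples is 14.5 pp (12/83).
    """
    if (base.train_id, base.test_id) != (extended.train_id, extended.test_id):
        raise DomainError("gain requires the same train/test pair")
    if base.total != extended.total:
        raise DomainError("gain requires the same test set size")
    return (
        extended.accuracy_pct - base.accuracy_pct,
        extended.correct - base.correct,
        base.total,
    )


def _dataset_id(cohort: pd.DataFrame) -> str:
    if "dataset" in cohort.columns:
        ids = cohort["dataset"].unique()
        if len(ids) == 1:
            return str(ids[0])
    return "dataset"
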