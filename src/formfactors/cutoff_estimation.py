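"""Accuracy-maximising univariate cutoff thresholds for the form factors.

For a feature with a fixed decision direction ("greater implies malignant"
or "less implies malignant"), the optimal cutoff is the threshold that
maximises overall classification accuracy. Candidates are the midpoints
between consecutive distinct sorted values, plus +/-infinity sentinels
representing the classify-everything-one-way rules, so the search is total
even for a useless feature and the achieved accuracy is never below the
majority-class prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

#: Decision direction of each discriminative form factor: malignant lesions
#: are more compact/equant (higher ACO, MPS) and less flat (lower AFL, KFL).
DEFAULT_DIRECTIONS = {
    "aco": "greater",
    "mps": "greater",
    "afl": "less",
    "kfl": "less",
}

_LABEL_CODES = {"benign": 0, "malignant": 1}


@dataclass(frozen=True)
class CutoffResult:
    """An optimal univariate cutoff for one feature on one scope.

    ``direction`` is ``"greater"`` (value > threshold implies malignant) or
    ``"less"`` (value < threshold implies malignant).
    """

    feature: str
    direction: str
    threshold: float
    correct: int
    total: int
    scope: str = ""

    @property
    def accuracy(self) -> float:
        return self.correct / self.total

    def formatted(self) -> str:
        sign = ">" if self.direction == "greater" else "<"
        return f"{sign}{self.threshold:.3f}"


def _codes(labels) -> np.ndarray:
    y = np.asarray([_LABEL_CODES.get(v, v) for v in labels], dtype=int)
    if len(np.unique(y)) < 2:
        raise DomainError("both classes must be present")
    return y


def optimal_cutoff(
    values, labels, direction: str = "greater", feature: str = "",
    scope: str = "",
) -> CutoffResult:
    """Threshold maximising overall accuracy for a one-feature rule.

    Ties in accuracy are broken toward the lowest winning threshold for
    direction ``"greater"`` and the highest for ``"less"``, which makes the
    rule symmetric under negation of the values.
    """
    v = np.asarray(values, dtype=float)
    y = _codes(labels)
    if direction not in ("greater", "less"):
        raise DomainError(f"unknown direction {direction!r}")
    distinct = np.unique(v)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate(([-np.inf], mids, [np.inf]))
    best_thr, best_correct = None, -1
    order = candidates if direction == "greater" else candidates[::-1]
    for thr in order:
        pred = (v > thr) if direction == "greater" else (v < thr)
        correct = int((pred.astype(int) == y).sum())
        if correct > best_correct:
            best_thr, best_correct = float(thr), correct
    return CutoffResult(
        feature=feature, direction=direction, threshold=best_thr,
        correct=best_correct, total=len(v), scope=scope,
    )


def cutoff_table(
    ds1: pd.DataFrame,
    ds2: pd.DataFrame,
    features: dict[str, str] | tuple[str, ...] = tuple(DEFAULT_DIRECTIONS),
    infer_directions: bool = False,
) -> pd.DataFrame:
    """Cutoffs per feature on each dataset, pooled, and dataset-averaged.

    ``features`` is either a mapping feature -> direction or a tuple of
    feature names whose directions come from :data:`DEFAULT_DIRECTIONS`
    (or, with ``infer_directions``, from the pooled group means: the class
    with the larger malignant mean gets direction "greater").

    Returns a DataFrame with columns ``feature, direction, threshold_ds1,
    threshold_ds2, threshold_pooled, threshold_avg``.
    """
    if isinstance(features, dict):
        directions = dict(features)
    else:
        directions = {}
        for f in features:
            if infer_directions:
                pooled = pd.concat([ds1, ds2], ignore_index=True)
                mal = pooled.loc[pooled["label"] == "malignant", f].mean()
                ben = pooled.loc[pooled["label"] == "benign", f].mean()
                directions[f] = "greater" if mal >= ben else "less"
            else:
                try:
                    directions[f] = DEFAULT_DIRECTIONS[f]
                except KeyError:
                    raise DomainError(
                        f"no default direction for feature {f!r}; "
                        "pass a mapping or infer_directions=True"
                    ) from None
    pooled = pd.concat([ds1, ds2], ignore_index=True)
    rows = []
    for feat, direction in directions.items():
        r1 = optimal_cutoff(ds1[feat], ds1["label"], direction, feat, "ds1")
        r2 = optimal_cutoff(ds2[feat], ds2["label"], direction, feat, "ds2")
        rp = optimal_cutoff(
            pooled[feat], pooled["label"], direction, feat, "pooled"
        )
        rows.append(
            {
                "feature": feat,
                "direction": direction,
                "threshold_ds1": r1.threshold,
                "threshold_ds2": r2.threshold,
                "threshold_pooled": rp.threshold,
                "threshold_avg": (r1.threshold + r2.threshold) / 2.0,
            }
        )
    return pd.DataFrame(rows)
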