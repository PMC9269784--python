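"""Univariate benign-vs-malignant feature screening.

Each feature is compared between the two groups with the nonparametric
Mann-Whitney U test (two-sided); multiplicity across the feature panel is
controlled with the Benjamini-Hochberg step-up procedure at FDR 0.05.
Group summaries are reported as mean +/- sample SD (n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError
from .shape_features import FEATURE_NAMES


@dataclass(frozen=True)
class StatsConfig:
    """Configuration of the univariate screening stage.

    ``fdr`` is the Benjamini-Hochberg false-discovery rate. ``lt_cap`` is
    the numeric stand-in used when re-analysing published tables whose
    p-value column contains censored entries like "<0.001"; any value below
    the censoring point yields the same flags, 0.0005 is the default.
    """

    fdr: float = 0.05
    alternative: str = "two-sided"
    lt_cap: float = 0.0005

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise DomainError(f"fdr must be in (0, 1), got {self.fdr}")


@dataclass(frozen=True)
class UnivariateRow:
    """One row of the univariate screening table."""

    feature: str
    benign_mean: float
    benign_sd: float
    malignant_mean: float
    malignant_sd: float
    p_value: float
    significant: bool


def mann_whitney_u(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U statistic of ``x`` and its two-sided p-value.

    ``U`` counts pairs with ``x_i > y_j`` plus half the ties. The exact
    null distribution is used when both samples have at most 25 values and
    the pooled sample is tie-free; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 25 and y.size <= 25 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def bh_flags(p_values, fdr: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags, in input order.

    Sorts the m p-values ascending, finds the largest k with
    ``p_(k) <= k * fdr / m`` and flags the k smallest.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return reject


def univariate_table(
    cohort: pd.DataFrame,
    config: StatsConfig = StatsConfig(),
    features: tuple[str, ...] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Group summaries, Mann-Whitney p-values and BH flags for a cohort.

    ``cohort`` needs one column per feature plus a ``label`` column with
    values ``benign``/``malignant``; both classes must be present. The BH
    correction is applied across the given feature panel (m = len(features)).

    Returns a DataFrame with columns ``feature, benign_mean, benign_sd,
    malignant_mean, malignant_sd, p_value, significant``.
    """
    labels = set(cohort["label"].unique())
    if not {"benign", "malignant"} <= labels:
        raise DomainError(
            f"cohort must contain both classes, found {sorted(labels)}"
        )
    ben = cohort[cohort["label"] == "benign"]
    mal = cohort[cohort["label"] == "malignant"]
    rows = []
    for feat in features:
        x, y = ben[feat].to_numpy(float), mal[feat].to_numpy(float)
        _, p = mann_whitney_u(x, y, alternative=config.alternative)
        rows.append(
            {
                "feature": feat,
                "benign_mean": x.mean(),
                "benign_sd": x.std(ddof=1),
                "malignant_mean": y.mean(),
                "malignant_sd": y.std(ddof=1),
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    table["significant"] = bh_flags(table["p_value"].to_numpy(), config.fdr)
    return table


def reanalyze_printed_pvalues(
    p_strings, fdr: float = 0.05, lt_cap: float = 0.0005
) -> np.ndarray:
    """BH flags for a published p-value column that may contain "<x" entries.

    Censored entries ("<0.001") are replaced by ``lt_cap`` before the
    step-up; the flags are insensitive to the exact stand-in as long as it
    is below the censoring point.
    """
    p = np.array(
        [lt_cap if str(s).strip().startswith("<") else float(s) for s in p_strings]
    )
    return bh_flags(p, fdr)
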