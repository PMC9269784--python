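"""End-to-end study orchestration: univariate screening, classification,
cutoffs, and report rendering for a two-dataset benign/malignant study."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .cutoff_estimation import DEFAULT_DIRECTIONS, cutoff_table
from .errors import ConfigurationError
from .multivariate_model import (
    ClassifierConfig,
    EvalResult,
    gain,
    grid_search_c,
)
from .shape_features import FEATURE_NAMES
from .synthetic_data import load_calibration, simulate_cohort
from .univariate_stats import StatsConfig, univariate_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full study run.

    ``dataset1``/``dataset2`` are each either a built-in calibration name
    (``"SSR1"``, ``"LUNGx"``), a calibration CSV path (cohorts are then
    simulated with ``seed``), or a path to a feature-table CSV that already
    holds ``lesion_id, dataset, label`` plus the 11 feature columns.
    """

    dataset1: str = "SSR1"
    dataset2: str = "LUNGx"
    seed: int = 0
    fdr: float = 0.05
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    cutoff_features: tuple[str, ...] = tuple(DEFAULT_DIRECTIONS)
    output_dir: str | Path = "results"


@dataclass
class AnalysisReport:
    """Machine-readable twin of the study's result tables."""

    univariate: dict[str, pd.DataFrame]
    accuracy: pd.DataFrame
    cutoffs: pd.DataFrame
    provenance: dict

    def write(self, outdir: str | Path) -> list[Path]:
        """Serialise every table to CSV under ``outdir``; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for ds, table in self.univariate.items():
            p = outdir / f"univariate_{_safe(ds)}.csv"
            table.to_csv(p, index=False, float_format="%.6g")
            written.append(p)
        p = outdir / "accuracy.csv"
        self.accuracy.to_csv(p, index=False, float_format="%.6g")
        written.append(p)
        p = outdir / "cutoffs.csv"
        self.cutoffs.to_csv(p, index=False, float_format="%.6g")
        written.append(p)
        p = outdir / "provenance.json"
        p.write_text(json.dumps(self.provenance, indent=2, sort_keys=True))
        written.append(p)
        return written


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name)


def _load_dataset(source: str, seed: int) -> pd.DataFrame:
    path = Path(source)
    if path.exists() and path.suffix == ".csv":
        head = pd.read_csv(path, comment="#", nrows=1)
        if "label" in head.columns and set(FEATURE_NAMES) <= set(head.columns):
            return pd.read_csv(path, comment="#")
    try:
        calibration = load_calibration(source)
    except Exception as exc:
        raise ConfigurationError(
            f"dataset source {source!r} is neither a feature table nor a "
            f"readable calibration: {exc}"
        ) from exc
    return simulate_cohort(calibration, seed=seed)


def run_study(config: RunConfig) -> AnalysisReport:
    """Execute the full pipeline on two datasets and return the report.

    Stages: per-dataset univariate screening (Mann-Whitney + BH), the
    2 feature sets x 4 train/test combinations linear-SVM accuracy grid
    (leave-one-out within a dataset, holdout across), and the form-factor
    cutoff table (per dataset, pooled, averaged). Deterministic given the
    config.
    """
    if not config.dataset1 or not config.dataset2:
        raise ConfigurationError("both dataset1 and dataset2 must be set")
    t0 = time.perf_counter()
    ds1 = _load_dataset(config.dataset1, seed=config.seed)
    ds2 = _load_dataset(config.dataset2, seed=config.seed + 1)
    id1 = str(ds1["dataset"].iloc[0])
    id2 = str(ds2["dataset"].iloc[0])
    logger.info("loaded datasets %s (n=%d) and %s (n=%d) in %.2fs",
                id1, len(ds1), id2, len(ds2), time.perf_counter() - t0)

    stats_cfg = StatsConfig(fdr=config.fdr)
    univariate = {
        id1: univariate_table(ds1, stats_cfg),
        id2: univariate_table(ds2, stats_cfg),
    }

    rows = []
    pairs = [(ds1, ds1), (ds2, ds2), (ds1, ds2), (ds2, ds1)]
    for train, test in pairs:
        intra = train is test
        results: dict[str, EvalResult] = {}
        for fset in ("base", "extended"):
            cfg = ClassifierConfig(c_grid=tuple(config.c_grid), feature_set=fset)
            if intra:
                _, res = grid_search_c(train, "loo", cfg)
            else:
                _, res = grid_search_c(train, "holdout", cfg, test=test)
            results[fset] = res
        pp, dcorrect, total = gain(results["base"], results["extended"])
        rows.append(
            {
                "train": results["base"].train_id,
                "test": results["base"].test_id,
                "base_accuracy_pct": results["base"].accuracy_pct,
                "base_correct": results["base"].correct,
                "base_c": results["base"].chosen_c,
                "extended_accuracy_pct": results["extended"].accuracy_pct,
                "extended_correct": results["extended"].correct,
                "extended_c": results["extended"].chosen_c,
                "total": total,
                "gain_pp": pp,
                "gain_correct": dcorrect,
            }
        )
    accuracy = pd.DataFrame(rows)

    cutoffs = cutoff_table(ds1, ds2, features=tuple(config.cutoff_features))
    cutoffs = cutoffs.rename(
        columns={"threshold_ds1": f"threshold_{_safe(id1)}",
                 "threshold_ds2": f"threshold_{_safe(id2)}"}
    )

    from . import __version__

    cfg_repr = json.dumps(
        {k: str(v) for k, v in asdict(config).items()}, sort_keys=True
    )
    provenance = {
        "config": json.loads(cfg_repr),
        "config_sha256": hashlib.sha256(cfg_repr.encode()).hexdigest(),
        "seed": config.seed,
        "package_version": __version__,
        "datasets": {id1: len(ds1), id2: len(ds2)},
    }
    logger.info("study complete in %.2fs", time.perf_counter() - t0)
    return AnalysisReport(univariate, accuracy, cutoffs, provenance)


def render_report(
    report: AnalysisReport,
    outdir: str | Path,
    cohorts: dict[str, pd.DataFrame] | None = None,
) -> list[Path]:
    """Write a human-readable summary and, when cohorts are supplied,
    boxplot/stripplot images for every significant feature.

    Plot numbers are drawn from the cohorts; every number in the text
    summary is read from the report tables, never recomputed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    lines = ["Form-factor biomarker study summary", "=" * 36, ""]
    for ds, table in report.univariate.items():
        sig = table[table["significant"]]
        lines.append(f"{ds}: {len(sig)}/{len(table)} features significant "
                     f"after BH correction")
        for _, row in sig.iterrows():
            lines.append(
                f"  {row['feature']}: benign {row['benign_mean']:.3g} +/- "
                f"{row['benign_sd']:.3g}, malignant {row['malignant_mean']:.3g} "
                f"+/- {row['malignant_sd']:.3g}, p={row['p_value']:.3g}"
            )
        lines.append("")
    lines.append("Classification accuracy (percent, base -> extended, gain pp):")
    for _, row in report.accuracy.iterrows():
        lines.append(
            f"  {row['train']}/{row['test']}: "
            f"{row['base_accuracy_pct']:.1f} -> {row['extended_accuracy_pct']:.1f} "
            f"({row['gain_pp']:+.1f} pp)"
        )
    lines.append("")
    lines.append("Cutoff thresholds for malignancy:")
    for _, row in report.cutoffs.iterrows():
        sign = ">" if row["direction"] == "greater" else "<"
        lines.append(
            f"  {row['feature']}: pooled {sign}{row['threshold_pooled']:.3f}, "
            f"dataset-average {sign}{row['threshold_avg']:.3f}"
        )
    summary = outdir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written.append(summary)

    if cohorts:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for ds, table in report.univariate.items():
            if ds not in cohorts:
                continue
            cohort = cohorts[ds]
            for feat in sorted(table.loc[table["significant"], "feature"]):
                fig, ax = plt.subplots(figsize=(3.5, 3.5))
                groups = [
                    cohort.loc[cohort["label"] == cls, feat].to_numpy()
                    for cls in ("benign", "malignant")
                ]
                ax.boxplot(groups, tick_labels=["benign", "malignant"],
                           showfliers=False)
                rng_x = [1, 2]
                for xi, g in zip(rng_x, groups):
                    jitter = (pd.Series(range(len(g))) % 7 - 3) / 40.0
                    ax.plot(xi + jitter, g, ".", alpha=0.4, markersize=3)
                ax.set_title(f"{feat} ({ds})")
                ax.set_ylabel(feat)
                fig.tight_layout()
                p = outdir / f"boxplot_{_safe(ds)}_{feat}.png"
                fig.savefig(p, dpi=120)
                plt.close(fig)
                written.append(p)
    return written
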