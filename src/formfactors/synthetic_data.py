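"""Synthetic phantoms and calibrated two-group feature cohorts.

Two complementary generators make every pipeline stage testable without
patient data:

* geometric voxel phantoms (ellipsoids, cuboids, superellipsoids) whose
  shape features have closed forms, serving as oracles for the feature
  extractor;
* statistical cohorts whose per-feature, per-class marginals are
  moment-matched to the published group summaries of the two reference
  cohorts (SSR-1 and LUNGx): beta distributions for the [0, 1]-bounded
  features, lognormals for the positive size features.

The statistical cohorts sample features independently within a class, so
they reproduce the published univariate structure but no cross-feature
identities; the geometric cohort generator builds actual voxel lesions and
extracts features from them, so identities such as AEL + AFL + ACO = 1 hold
per lesion there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import CalibrationError, DomainError
from .mask_io import VoxelMask
from .shape_features import DIMENSIONLESS_FEATURES, FEATURE_NAMES, extract_all

SIZE_FEATURES = ("max3ddiam", "surfarea", "volume")

_BUILTIN_CALIBRATIONS = {
    "ssr1": "ssr1_calibration.csv",
    "lungx": "lungx_calibration.csv",
}
_BUILTIN_PVALUES = {
    "ssr1": "ssr1_reported_pvalues.csv",
    "lungx": "lungx_reported_pvalues.csv",
}


# ---------------------------------------------------------------------------
# geometric phantoms


@dataclass(frozen=True)
class PhantomSpec:
    """A voxelised analytic solid.

    ``semi_axes`` are in mm; ``rotation`` is an optional 3x3 rotation matrix
    applied to the solid before voxelisation; ``seed`` enables a smooth
    stochastic radial perturbation of amplitude ``perturb`` (fraction of the
    implicit radius), useful for lesions that are not perfect quadrics.
    """

    shape: str = "ellipsoid"
    semi_axes: tuple[float, float, float] = (10.0, 10.0, 10.0)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    rotation: np.ndarray | None = None
    seed: int | None = None
    perturb: float = 0.05
    exponent: float = 4.0  # superellipsoid only

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise DomainError("semi-axes must be positive")
        if any(s <= 0 for s in self.spacing):
            raise DomainError("spacing must be positive")
        if self.shape not in ("ellipsoid", "cuboid", "superellipsoid"):
            raise DomainError(f"unknown phantom shape {self.shape!r}")


def make_phantom(spec: PhantomSpec) -> VoxelMask:
    """Voxelise an analytic solid: a voxel is foreground iff its centre is inside."""
    a = np.asarray(spec.semi_axes, dtype=float)
    spacing = np.asarray(spec.spacing, dtype=float)
    if np.any(2 * a < spacing):
        raise DomainError(
            f"degenerate phantom: extent {tuple(2 * a)} smaller than one "
            f"voxel at spacing {spec.spacing}"
        )
    # conservative half-extent: rotation can put any semi-axis anywhere
    half = float(a.max()) if spec.rotation is not None else a
    half = np.broadcast_to(np.asarray(half, dtype=float), (3,)) * (
        1.0 + (spec.perturb if spec.seed is not None else 0.0)
    )
    n = np.ceil(2 * half / spacing).astype(int) + 4
    coords = [
        (np.arange(ni) + 0.5) * si - ni * si / 2.0
        for ni, si in zip(n, spacing)
    ]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    pts = np.stack([X, Y, Z])
    if spec.rotation is not None:
        R = np.asarray(spec.rotation, dtype=float)
        pts = np.einsum("ji,jxyz->ixyz", R, pts)  # rotate solid = R^T on points
    u = pts / a[:, None, None, None]
    if spec.shape == "ellipsoid":
        implicit = (u**2).sum(axis=0)
    elif spec.shape == "cuboid":
        implicit = np.abs(u).max(axis=0)
    else:
        implicit = (np.abs(u) ** spec.exponent).sum(axis=0)
    if spec.seed is not None:
        rng = np.random.default_rng(spec.seed)
        noise = rng.standard_normal(implicit.shape)
        noise = ndimage.gaussian_filter(noise, sigma=3.0)
        noise /= max(np.abs(noise).max(), 1e-12)
        implicit = implicit * (1.0 + spec.perturb * noise)
    grid = implicit <= 1.0
    if not grid.any():
        raise DomainError(
            f"degenerate phantom: solid {spec.semi_axes} smaller than one "
            f"voxel at spacing {spec.spacing}"
        )
    return VoxelMask(grid=grid, spacing=tuple(spacing))


# ---------------------------------------------------------------------------
# moment matching


def moment_matched_beta(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters with the given analytic mean and SD.

    Requires ``sd^2 < mean * (1 - mean)`` (feasibility on [0, 1]).
    """
    if not 0 < mean < 1:
        raise CalibrationError(f"beta mean must be in (0, 1), got {mean}")
    var = sd * sd
    if var <= 0 or var >= mean * (1 - mean):
        raise CalibrationError(
            f"infeasible beta moments mean={mean}, sd={sd}: "
            f"need 0 < sd^2 < mean*(1-mean) = {mean * (1 - mean):.6g}"
        )
    k = mean * (1 - mean) / var - 1.0
    return mean * k, (1.0 - mean) * k


def moment_matched_lognormal(mean: float, sd: float) -> tuple[float, float]:
    """Lognormal ``(mu, sigma)`` with the given analytic mean and SD."""
    if mean <= 0 or sd <= 0:
        raise CalibrationError("lognormal moments must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


# ---------------------------------------------------------------------------
# calibrated statistical cohorts


@dataclass(frozen=True)
class CohortCalibration:
    """Per-feature, per-class target moments plus group sizes for one dataset.

    ``stats`` maps ``(feature, class)`` to ``(mean, sd)`` on the published
    scale; sizes are the benign/malignant group counts.
    """

    dataset_id: str
    n_benign: int
    n_malignant: int
    stats: dict[tuple[str, str], tuple[float, float]]

    def __post_init__(self) -> None:
        if self.n_benign < 2 or self.n_malignant < 2:
            raise CalibrationError("each group needs at least 2 lesions")
        for (feat, cls), (mean, sd) in self.stats.items():
            if sd <= 0:
                raise CalibrationError(f"SD must be positive for {feat}/{cls}")
            # validate feasibility eagerly so a bad file fails at load time
            if feat in DIMENSIONLESS_FEATURES:
                moment_matched_beta(mean, sd)
            else:
                moment_matched_lognormal(mean, sd)


def _data_path(filename: str):
    return resources.files("formfactors.data").joinpath(filename)


def load_calibration(source: str | Path) -> CohortCalibration:
    """Load a built-in calibration (``"SSR1"``, ``"LUNGx"``) or a CSV file.

    File format: comment lines start with ``#``; columns
    ``feature,class,mean,sd``; rows with feature ``n`` give the group sizes
    (the count in the ``mean`` column).
    """
    key = str(source).lower().replace("-", "")
    if key in _BUILTIN_CALIBRATIONS:
        path = _data_path(_BUILTIN_CALIBRATIONS[key])
        dataset_id = "SSR-1" if key == "ssr1" else "LUNGx"
    else:
        path = Path(source)
        dataset_id = path.stem
    with resources.as_file(path) if not isinstance(path, Path) else _nullctx(path) as p:
        df = pd.read_csv(p, comment="#")
    sizes = df[df["feature"] == "n"].set_index("class")["mean"]
    body = df[df["feature"] != "n"]
    stats = {
        (row["feature"], row["class"]): (float(row["mean"]), float(row["sd"]))
        for _, row in body.iterrows()
    }
    return CohortCalibration(
        dataset_id=dataset_id,
        n_benign=int(sizes["benign"]),
        n_malignant=int(sizes["malignant"]),
        stats=stats,
    )


class _nullctx:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def load_reported_pvalues(dataset: str) -> pd.DataFrame:
    """Published univariate p-values for a reference cohort, as printed.

    Censored entries are kept as strings (e.g. ``"<0.001"``).
    """
    key = str(dataset).lower().replace("-", "")
    path = _data_path(_BUILTIN_PVALUES[key])
    with resources.as_file(path) as p:
        return pd.read_csv(p, comment="#", dtype={"p_value": str})


def simulate_cohort(
    calibration: CohortCalibration, seed: int | None = None
) -> pd.DataFrame:
    """Sample a two-group feature cohort with moment-matched marginals.

    Each feature is drawn independently within a class from the
    class-specific moment-matched distribution (beta for the dimensionless
    features, lognormal for the size features). Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for cls, n in (
        ("benign", calibration.n_benign),
        ("malignant", calibration.n_malignant),
    ):
        cols = {}
        for feat in FEATURE_NAMES:
            mean, sd = calibration.stats[(feat, cls)]
            if feat in DIMENSIONLESS_FEATURES:
                a, b = moment_matched_beta(mean, sd)
                cols[feat] = rng.beta(a, b, size=n)
            else:
                mu, sigma = moment_matched_lognormal(mean, sd)
                cols[feat] = rng.lognormal(mu, sigma, size=n)
        frame = pd.DataFrame(cols)
        frame.insert(0, "label", cls)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "dataset", calibration.dataset_id)
    out.insert(0, "lesion_id", [f"{calibration.dataset_id}-{i:04d}" for i in range(len(out))])
    return out


# ---------------------------------------------------------------------------
# geometric cohorts (internally consistent feature vectors)

#: Aspect-ratio distributions per class: benign lesions flatter (lower t/b).
DEFAULT_ASPECTS = {
    "benign": {
        "length_mean": 20.0, "length_sd": 6.0,
        "b_over_l_mean": 0.80, "b_over_l_sd": 0.10,
        "t_over_b_mean": 0.62, "t_over_b_sd": 0.14,
    },
    "malignant": {
        "length_mean": 24.0, "length_sd": 6.0,
        "b_over_l_mean": 0.82, "b_over_l_sd": 0.10,
        "t_over_b_mean": 0.86, "t_over_b_sd": 0.08,
    },
}


def simulate_geometric_cohort(
    aspects: dict | None = None,
    n: tuple[int, int] = (20, 20),
    spacing: float | None = None,
    seed: int | None = None,
    dataset_id: str = "synthetic",
) -> tuple[list[VoxelMask], pd.DataFrame]:
    """Sample voxel lesions per class and extract their features end to end.

    Per lesion, box dimensions ``(l, b, t)`` are drawn from class-specific
    distributions (length lognormal, the ratios ``b/l`` and ``t/b`` beta);
    an ellipsoid phantom with those extents is voxelised and passed through
    the full feature extractor, so all cross-feature identities hold. With
    the default aspect distributions the benign arm is flatter (lower
    ``t/b``), mirroring the benign-vs-malignant contrast seen in patient
    cohorts. ``spacing`` defaults to an adaptive ``t/8`` per lesion.

    Returns the masks and the cohort feature table.
    """
    aspects = aspects or DEFAULT_ASPECTS
    rng = np.random.default_rng(seed)
    masks: list[VoxelMask] = []
    rows = []
    for cls, n_cls in zip(("benign", "malignant"), n):
        cfg = aspects[cls]
        mu, sg = moment_matched_lognormal(cfg["length_mean"], cfg["length_sd"])
        a_bl, b_bl = moment_matched_beta(cfg["b_over_l_mean"], cfg["b_over_l_sd"])
        a_tb, b_tb = moment_matched_beta(cfg["t_over_b_mean"], cfg["t_over_b_sd"])
        for i in range(n_cls):
            l = rng.lognormal(mu, sg)
            b = l * rng.beta(a_bl, b_bl)
            t = b * rng.beta(a_tb, b_tb)
            sp = spacing if spacing is not None else max(t / 8.0, l / 40.0)
            spec = PhantomSpec(
                shape="ellipsoid",
                semi_axes=(l / 2.0, b / 2.0, t / 2.0),
                spacing=(sp, sp, sp),
            )
            mask = make_phantom(spec)
            fv = extract_all(mask)
            masks.append(mask)
            rows.append(
                {"lesion_id": f"{dataset_id}-{cls}-{i:03d}",
                 "dataset": dataset_id, "label": cls, **fv.as_dict()}
            )
    return masks, pd.DataFrame(rows)
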