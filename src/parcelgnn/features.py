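"""Per-vertex training features from resting-state time series.

The central feature is *regionalized connectivity*: each vertex's Pearson
correlation with the mean time series of every region of a coarse anatomical
atlas. Column ``k`` then means "connectivity to region k" for every subject,
regardless of mesh resolution or registration. Alternatively, group-level
spatial component maps can be dual-regressed onto a subject's data to obtain
subject-level component loadings. Connectivity (or component) columns are
concatenated with spectral coordinates and scalar maps into the model's
feature matrix X (N vertices x F features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from parcelgnn.labels import LabelMap
from parcelgnn.surface import SpectralCoordinates

__all__ = [
    "TimeSeriesMatrix",
    "RegionalTimeSeries",
    "ConnectivityFeatures",
    "FeatureMatrix",
    "regional_mean_series",
    "connectivity_features",
    "dual_regression",
    "assemble_features",
    "standardize_feature_set",
]

_VAR_FLOOR = 1e-12  # variance floor for correlation denominators


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """N x t BOLD-like series, one row per vertex."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError(f"time series must be 2-D, got shape {v.shape}")
        if v.shape[1] < 2:
            raise ValueError("need at least 2 time points")
        if not np.isfinite(v).all():
            raise ValueError("time series contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n_vertices(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_timepoints(self) -> int:
        return int(self.values.shape[1])


@dataclass(frozen=True)
class RegionalTimeSeries:
    """K x t matrix of per-region mean series, rows ordered by ``region_ids``."""

    values: np.ndarray
    region_ids: np.ndarray


@dataclass(frozen=True)
class ConnectivityFeatures:
    """N x K Pearson correlations between vertex series and regional mean series."""

    values: np.ndarray
    region_ids: np.ndarray


@dataclass(frozen=True)
class FeatureMatrix:
    """N x F feature matrix with unique column names."""

    values: np.ndarray
    column_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        names = tuple(self.column_names)
        if v.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(names) != v.shape[1]:
            raise ValueError(
                f"{len(names)} column names for {v.shape[1]} columns"
            )
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature column names")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "column_names", names)

    @property
    def n_vertices(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.values.shape[1])


def regional_mean_series(ts: TimeSeriesMatrix, atlas: LabelMap) -> RegionalTimeSeries:
    """Mean time series of every atlas region (unlabeled vertices excluded).

    Row ``k`` is the vertex-mean of region ``region_ids[k]``. Regions present
    in the atlas code range but with zero vertices are skipped with a warning.
    """
    if atlas.n_vertices != ts.n_vertices:
        raise ValueError(
            f"atlas has {atlas.n_vertices} vertices, time series has {ts.n_vertices}"
        )
    regions = atlas.present_labels()
    if regions.size == 0:
        raise ValueError("atlas labels every vertex as unlabeled")
    expected = np.arange(1, atlas.num_classes + 1)
    missing = np.setdiff1d(expected, regions)
    if missing.size:
        warnings.warn(
            f"atlas regions with zero vertices excluded: {missing.tolist()}",
            stacklevel=2,
        )
    rows = np.stack(
        [ts.values[atlas.labels == r].mean(axis=0) for r in regions]
    )
    return RegionalTimeSeries(values=rows, region_ids=regions)


def _center_scale(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-demeaned matrix and row standard deviations (biased, for Pearson)."""
    centered = x - x.mean(axis=1, keepdims=True)
    sd = np.sqrt((centered**2).mean(axis=1))
    return centered, sd


def connectivity_features(
    ts: TimeSeriesMatrix, regional: RegionalTimeSeries
) -> ConnectivityFeatures:
    """Pearson correlation of every vertex series with every regional mean series.

    Entries involving a zero-variance series are set to 0 with a warning.
    """
    t = ts.n_timepoints
    if regional.values.shape[1] != t:
        raise ValueError(
            f"time-point mismatch: vertices have {t}, regions have "
            f"{regional.values.shape[1]}"
        )
    vc, v_sd = _center_scale(ts.values)
    rc, r_sd = _center_scale(regional.values)
    flat_v = v_sd < np.sqrt(_VAR_FLOOR)
    flat_r = r_sd < np.sqrt(_VAR_FLOOR)
    if flat_v.any() or flat_r.any():
        warnings.warn(
            f"zero-variance series ({int(flat_v.sum())} vertices, "
            f"{int(flat_r.sum())} regions); their correlations set to 0",
            stacklevel=2,
        )
    v_sd = np.where(flat_v, 1.0, v_sd)
    r_sd = np.where(flat_r, 1.0, r_sd)
    r = (vc / v_sd[:, None]) @ (rc / r_sd[:, None]).T / t
    r[flat_v, :] = 0.0
    r[:, flat_r] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    return ConnectivityFeatures(values=r, region_ids=regional.region_ids.copy())


def dual_regression(group_maps: np.ndarray, ts: TimeSeriesMatrix) -> np.ndarray:
    """Project group-level spatial components onto a subject's data.

    Stage 1 regresses each time point's spatial pattern on the group maps,
    giving C subject-specific component time courses; stage 2 regresses each
    vertex's series on those time courses, giving the subject's N x C spatial
    component loadings.
    """
    g = np.asarray(group_maps, dtype=np.float64)
    if g.ndim != 2:
        raise ValueError("group maps must be N x C")
    n, c = g.shape
    if n != ts.n_vertices:
        raise ValueError(f"group maps have {n} vertices, series has {ts.n_vertices}")
    if c >= min(n, ts.n_timepoints):
        raise ValueError("number of components must be < min(N, t)")
    _, r_diag, pivots = scipy.linalg.qr(g, mode="economic", pivoting=True)
    r_diag = np.abs(np.diag(r_diag))
    tol = max(n, c) * np.finfo(np.float64).eps * (r_diag.max() if r_diag.size else 0.0)
    deficient = r_diag <= tol
    if deficient.any():
        bad = sorted(int(p) for p in pivots[deficient])
        raise ValueError(f"group maps are rank-deficient; collinear columns: {bad}")
    # stage 1: C x t time courses
    courses = np.linalg.lstsq(g, ts.values, rcond=None)[0]
    # stage 2: per-vertex regression on the time courses
    maps = np.linalg.lstsq(courses.T, ts.values.T, rcond=None)[0].T
    return maps


def assemble_features(
    connectivity: ConnectivityFeatures | np.ndarray | None = None,
    spectral: SpectralCoordinates | None = None,
    scalars: Mapping[str, np.ndarray] | None = None,
    *,
    standardize: bool | Sequence[str] = ("spectral", "scalar"),
    train_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> FeatureMatrix:
    """Concatenate feature blocks column-wise: connectivity | spectral | scalars.

    Parameters
    ----------
    connectivity
        Regionalized correlations or dual-regression component loadings
        (N x K array).
    spectral
        Aligned spectral coordinates.
    scalars
        Named per-vertex scalar maps (thickness, curvature, sulcal depth,
        myelin, ...).
    standardize
        Which blocks to z-score: ``True`` (all), ``False`` (none), or a
        sequence drawn from {"connectivity", "spectral", "scalar"}. Default
        standardizes the unbounded spectral/scalar blocks and leaves the
        already-bounded correlation block untouched.
    train_stats
        ``(mean, sd)`` per column, as returned in a training call via
        ``FeatureMatrix`` statistics; when supplied, applied instead of the
        matrix's own statistics so test features use training normalization.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    block_kinds: list[str] = []
    if connectivity is not None:
        vals = connectivity.values if isinstance(connectivity, ConnectivityFeatures) else np.asarray(connectivity, dtype=np.float64)
        if isinstance(connectivity, ConnectivityFeatures):
            cols = [f"conn_region_{int(r)}" for r in connectivity.region_ids]
        else:
            cols = [f"component_{i}" for i in range(vals.shape[1])]
        blocks.append(vals)
        names.extend(cols)
        block_kinds.extend(["connectivity"] * vals.shape[1])
    if spectral is not None:
        blocks.append(spectral.eigenvectors)
        names.extend(f"spectral_{i + 1}" for i in range(spectral.dim))
        block_kinds.extend(["spectral"] * spectral.dim)
    if scalars:
        for name, vec in scalars.items():
            v = np.asarray(vec, dtype=np.float64).ravel()[:, None]
            blocks.append(v)
            names.append(f"scalar_{name}")
            block_kinds.append("scalar")
    if not blocks:
        raise ValueError("no feature blocks supplied")
    n_set = {b.shape[0] for b in blocks}
    if len(n_set) != 1:
        raise ValueError(f"feature blocks disagree on vertex count: {sorted(n_set)}")
    x = np.concatenate(blocks, axis=1)

    if standardize is True:
        do = {"connectivity", "spectral", "scalar"}
    elif standardize is False:
        do = set()
    else:
        do = set(standardize)
    col_mask = np.array([k in do for k in block_kinds])
    if col_mask.any():
        if train_stats is not None:
            mean, sd = train_stats
        else:
            mean = x.mean(axis=0)
            sd = x.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        x = x.copy()
        x[:, col_mask] = (x[:, col_mask] - mean[col_mask]) / sd[col_mask]
    return FeatureMatrix(values=x, column_names=tuple(names))


def _column_kind(name: str) -> str:
    if name.startswith(("conn_", "component_")):
        return "connectivity"
    if name.startswith("spectral_"):
        return "spectral"
    return "scalar"


def standardize_feature_set(
    mats: Sequence[FeatureMatrix],
    train_indices: Sequence[int],
    blocks: Sequence[str] = ("spectral", "scalar"),
) -> tuple[list[FeatureMatrix], tuple[np.ndarray, np.ndarray]]:
    """Z-score selected blocks of every matrix using training-set statistics.

    Column means/sds are estimated over the stacked rows of the training
    matrices only, then applied identically to every matrix, so test
    features see exactly the training normalization.
    """
    if not mats:
        raise ValueError("no feature matrices supplied")
    names = mats[0].column_names
    for m in mats[1:]:
        if m.column_names != names:
            raise ValueError("feature matrices disagree on column names")
    stacked = np.concatenate([mats[i].values for i in train_indices], axis=0)
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    do = set(blocks)
    mask = np.array([_column_kind(n) in do for n in names])
    out = []
    for m in mats:
        x = m.values.copy()
        x[:, mask] = (x[:, mask] - mean[mask]) / sd[mask]
        out.append(FeatureMatrix(values=x, column_names=names))
    return out, (mean, sd)
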