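"""Parcellation-quality statistics.

Covers classification accuracy against ground-truth maps, Dice-coefficient
reproducibility of repeated-session predictions, the hop-distance profile of
misclassified vertices relative to ground-truth areal boundaries, functional
homogeneity (percent variance of a parcel's vertex-to-cortex correlation
matrix explained by its first singular component), scalar-map homogeneity
(within-parcel variance over between-parcel variance of parcel means),
consensus (modal) parcellations, subject-mean probability maps, and a
bootstrap standard error for test-set accuracy.

All statistics exclude vertices carrying the unlabeled code (the medial
wall convention) and use unbiased (n-1) variance estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from parcelgnn.features import TimeSeriesMatrix
from parcelgnn.labels import LabelMap
from parcelgnn.surface import SurfaceGraph, geodesic_hops

__all__ = [
    "EvaluationReport",
    "accuracy",
    "dice",
    "mean_dice",
    "boundary_error_profile",
    "functional_homogeneity",
    "scalar_homogeneity",
    "consensus",
    "mean_probability_maps",
    "bootstrap_se",
]


@dataclass
class EvaluationReport:
    """Aggregate of the per-subject and cohort statistics."""

    accuracy_percent: float | None = None
    per_vertex_correct: np.ndarray | None = None
    dice_per_area: dict[int, float] = field(default_factory=dict)
    boundary_error_fractions: dict[int, float] = field(default_factory=dict)
    homogeneity_functional: float | None = None
    homogeneity_scalar: dict[str, float] = field(default_factory=dict)
    bootstrap_se_percent: float | None = None


def accuracy(pred: LabelMap, truth: LabelMap) -> tuple[float, np.ndarray]:
    """Percentage of correctly predicted vertex labels over truth-labeled vertices.

    Returns the percentage and the per-vertex correctness booleans (False at
    truth-unlabeled vertices).
    """
    if pred.n_vertices != truth.n_vertices:
        raise ValueError("prediction and truth differ in vertex count")
    mask = truth.labeled_mask
    if not mask.any():
        raise ValueError("truth map has no labeled vertices")
    correct = (pred.labels == truth.labels) & mask
    pct = 100.0 * correct.sum() / mask.sum()
    return float(pct), correct


def dice(pred_a: LabelMap, pred_b: LabelMap, area: int) -> float:
    """Dice(J, K) = 2|J∩K| / (|J|+|K|) for the vertex sets assigned ``area``.

    Returns NaN ("missing") when the area is absent from both maps.
    """
    if pred_a.n_vertices != pred_b.n_vertices:
        raise ValueError("maps differ in vertex count")
    j = pred_a.labels == area
    k = pred_b.labels == area
    denom = int(j.sum()) + int(k.sum())
    if denom == 0:
        return float("nan")
    return 2.0 * int((j & k).sum()) / denom


def mean_dice(pred_a: LabelMap, pred_b: LabelMap) -> float:
    """Dice averaged over all areas present in either map; missing areas skipped."""
    areas = np.union1d(pred_a.present_labels(), pred_b.present_labels())
    vals = [dice(pred_a, pred_b, int(a)) for a in areas]
    vals = [v for v in vals if not np.isnan(v)]
    if not vals:
        raise ValueError("no areas present in either map")
    return float(np.mean(vals))


def _boundary_vertices(truth: LabelMap, g: SurfaceGraph) -> np.ndarray:
    """Truth-labeled vertices adjacent to a vertex with a different truth label."""
    labels = truth.labels
    adj = g.adjacency.tocoo()
    differs = labels[adj.row] != labels[adj.col]
    both_labeled = (labels[adj.row] != truth.unlabeled_code) & (
        labels[adj.col] != truth.unlabeled_code
    )
    return np.unique(adj.row[differs & both_labeled])


def boundary_error_profile(
    pred: LabelMap, truth: LabelMap, g: SurfaceGraph
) -> dict[int, float]:
    """Fraction of misclassified vertices at each hop distance from areal boundaries.

    Boundaries are defined on the ground truth: labeled vertices directly
    adjacent to a vertex with a different label. Returns an empty dict when
    the prediction is perfect.
    """
    boundary = _boundary_vertices(truth, g)
    if boundary.size == 0:
        raise ValueError("truth map has a single label; no areal boundaries exist")
    mask = truth.labeled_mask
    wrong = np.flatnonzero((pred.labels != truth.labels) & mask)
    if wrong.size == 0:
        return {}
    hops = geodesic_hops(g, boundary)
    dists, counts = np.unique(hops[wrong], return_counts=True)
    return {int(d): float(c) / wrong.size for d, c in zip(dists, counts)}


def functional_homogeneity(
    ts: TimeSeriesMatrix, parcels: LabelMap
) -> tuple[float, dict[int, float]]:
    """Percent variance of each parcel's vertex-to-cortex correlation matrix
    explained by its first singular component; mean over parcels.

    For parcel l with vertex set V_l, R_l holds Pearson correlations of each
    parcel-vertex series with every cortical vertex series; with singular
    values s_i of R_l, homogeneity is 100 * s_1^2 / sum(s_i^2). A singleton
    parcel is trivially rank one and scores 100 (flagged with a warning).
    """
    labels = parcels.labels
    x = ts.values
    centered = x - x.mean(axis=1, keepdims=True)
    sd = np.sqrt((centered**2).mean(axis=1))
    sd = np.where(sd < 1e-12, 1.0, sd)
    z = centered / sd[:, None]  # rows have unit variance
    t = ts.n_timepoints
    per_parcel: dict[int, float] = {}
    for area in parcels.present_labels():
        members = np.flatnonzero(labels == area)
        if members.size == 1:
            warnings.warn(
                f"parcel {int(area)} has a single vertex; homogeneity set to 100",
                stacklevel=2,
            )
            per_parcel[int(area)] = 100.0
            continue
        r = z[members] @ z.T / t  # n_l x N correlation matrix
        s = np.linalg.svd(r, compute_uv=False)
        per_parcel[int(area)] = float(100.0 * s[0] ** 2 / (s**2).sum())
    return float(np.mean(list(per_parcel.values()))), per_parcel


def scalar_homogeneity(feature: np.ndarray, parcels: LabelMap) -> float:
    """Within-parcel variance relative to between-parcel variance (dimensionless).

    Mean over parcels of the (unbiased) within-parcel variance, divided by
    the (unbiased) variance of the parcel means. Smaller is more homogeneous.
    Returns NaN when the parcel means are identical (between-variance 0).
    """
    feature = np.asarray(feature, dtype=np.float64).ravel()
    if feature.size != parcels.n_vertices:
        raise ValueError("feature length does not match parcellation")
    areas = parcels.present_labels()
    if areas.size < 2:
        raise ValueError("need at least 2 parcels")
    within = []
    means = []
    for area in areas:
        vals = feature[parcels.labels == area]
        if vals.size < 2:
            raise ValueError(f"parcel {int(area)} has fewer than 2 vertices")
        within.append(vals.var(ddof=1))
        means.append(vals.mean())
    between = np.var(means, ddof=1)
    if between < 1e-300:
        return float("nan")
    return float(np.mean(within) / between)


def consensus(preds: Sequence[LabelMap]) -> LabelMap:
    """Per-vertex modal label across predictions; ties broken by smallest code."""
    maps = list(preds)
    if not maps:
        raise ValueError("no predictions supplied")
    n = maps[0].n_vertices
    stack = np.stack([m.labels for m in maps])  # S x N
    max_code = int(stack.max())
    out = np.zeros(n, dtype=np.int64)
    # per-vertex vote count over codes 0..max_code; argmax takes smallest on ties
    for v in range(n):
        votes = np.bincount(stack[:, v], minlength=max_code + 1)
        out[v] = int(votes.argmax())
    return LabelMap(
        labels=out,
        unlabeled_code=maps[0].unlabeled_code,
        num_classes=max(m.num_classes for m in maps),
    )


def mean_probability_maps(
    prob_stacks: Sequence[np.ndarray], threshold: float | None = None
) -> np.ndarray:
    """Element-wise mean of subject probability matrices.

    ``threshold`` (default 1/C, the probability of a uniformly random
    assignment) zeroes sub-threshold entries in the returned display copy;
    pass 0 to disable.
    """
    stacks = [np.asarray(p, dtype=np.float64) for p in prob_stacks]
    if not stacks:
        raise ValueError("no probability matrices supplied")
    shape = stacks[0].shape
    for p in stacks:
        if p.shape != shape:
            raise ValueError(f"inconsistent probability shapes: {p.shape} vs {shape}")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
    mean = np.mean(stacks, axis=0)
    if threshold is None:
        threshold = 1.0 / shape[1]
    out = mean.copy()
    out[out < threshold] = 0.0
    return out


def bootstrap_se(
    per_subject_accuracies: Sequence[float],
    sample_size: int = 100,
    reps: int = 1000,
    seed: int = 0,
) -> float:
    """Bootstrap standard error of mean test accuracy.

    Draws ``sample_size`` subjects with replacement, averages their
    accuracies, repeats ``reps`` times, and returns the standard deviation
    of the resampled means.
    """
    acc = np.asarray(list(per_subject_accuracies), dtype=np.float64)
    if acc.size == 0:
        raise ValueError("no accuracies supplied")
    if reps < 2:
        raise ValueError("need at least 2 bootstrap repetitions")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, acc.size, size=(reps, sample_size))
    means = acc[draws].mean(axis=1)
    return float(means.std(ddof=1))
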