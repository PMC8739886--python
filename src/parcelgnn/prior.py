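"""Vertex-wise spatial prior over candidate labels.

Training and test surfaces share vertex correspondence, so a label never
observed at a vertex in any training parcellation can be excluded from that
vertex's candidate set at test time. The prior is the per-vertex union of
observed labels; applying it drives unsupported logits to -inf so their
softmax probability is exactly 0. It is strictly a test-time operator and
plays no role in training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from parcelgnn.labels import LabelMap

__all__ = ["PriorMask", "build_prior", "apply_prior", "write_prior", "read_prior"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PriorMask:
    """N x C boolean support matrix; entry (v, c) is True iff label c+1 was
    assigned to vertex v in at least one training map."""

    support: np.ndarray
    source_count: int

    def __post_init__(self) -> None:
        s = np.asarray(self.support, dtype=bool)
        if s.ndim != 2:
            raise ValueError("support must be N x C")
        if not s.any(axis=1).all():
            raise ValueError("every vertex must support at least one label")
        object.__setattr__(self, "support", s)


def build_prior(train_labels: Sequence[LabelMap], num_classes: int | None = None) -> PriorMask:
    """Union of observed labels per vertex across training parcellations.

    Unlabeled codes are ignored. A vertex unlabeled in *every* training map
    gets an uninformative all-true support row, with a warning in the log.
    """
    maps = list(train_labels)
    if not maps:
        raise ValueError("need at least one training label map")
    n = maps[0].n_vertices
    c = num_classes or max(m.num_classes for m in maps)
    support = np.zeros((n, c), dtype=bool)
    for m in maps:
        if m.n_vertices != n:
            raise ValueError("training maps disagree on vertex count")
        labeled = m.labeled_mask
        support[np.flatnonzero(labeled), m.labels[labeled] - 1] = True
    never = ~support.any(axis=1)
    if never.any():
        logger.warning(
            "%d vertices unlabeled in every training map; their prior is uninformative",
            int(never.sum()),
        )
        support[never] = True
    return PriorMask(support=support, source_count=len(maps))


def apply_prior(logits: np.ndarray, mask: PriorMask) -> np.ndarray:
    """Mask logits so unsupported labels get softmax probability exactly 0.

    Supported logits pass through unchanged; unsupported entries become
    -inf, so the argmax always lands on a supported label.
    """
    logits = np.asarray(logits, dtype=np.float64)
    if logits.shape != mask.support.shape:
        raise ValueError(
            f"shape mismatch: logits {logits.shape} vs prior {mask.support.shape}"
        )
    return np.where(mask.support, logits, -np.inf)


def write_prior(mask: PriorMask, path: str | Path) -> None:
    """Sparse text format: a header line `N C source_count`, then one
    `vertex label` pair (0-based vertex, 1-based label) per line."""
    n, c = mask.support.shape
    rows, cols = np.nonzero(mask.support)
    with open(path, "w") as fh:
        fh.write(f"{n} {c} {mask.source_count}\n")
        for v, k in zip(rows, cols):
            fh.write(f"{v} {k + 1}\n")


def read_prior(path: str | Path) -> PriorMask:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 3:
            raise ValueError(f"malformed prior header in {path}")
        n, c, sources = (int(x) for x in header)
        support = np.zeros((n, c), dtype=bool)
        for line in fh:
            v, k = (int(x) for x in line.split())
            support[v, k - 1] = True
    return PriorMask(support=support, source_count=sources)
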