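"""Vertex-wise integer label maps (parcellations, atlases).

Labels follow the surface label-file convention: code 0 marks unlabeled
vertices (the medial wall in real data), and parcels carry codes ``1..C``.
Internally, classifiers index classes ``0..C-1``; the mapping happens at the
training/evaluation boundary, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabelMap"]


@dataclass(frozen=True)
class LabelMap:
    """A per-vertex parcel assignment.

    Parameters
    ----------
    labels
        Integer vector of length ``N``. Values are ``unlabeled_code`` or
        positive parcel codes.
    unlabeled_code
        The code marking vertices excluded from training and scoring
        (default 0).
    num_classes
        Number of parcel classes ``C``. Inferred as the maximum positive
        code when omitted.
    """

    labels: np.ndarray
    unlabeled_code: int = 0
    num_classes: int = field(default=0)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64).ravel()
        object.__setattr__(self, "labels", labels)
        if labels.size == 0:
            raise ValueError("label map is empty")
        if np.any((labels != self.unlabeled_code) & (labels < 0)):
            raise ValueError("negative label codes are not allowed")
        inferred = int(labels.max(initial=0))
        if self.num_classes == 0:
            object.__setattr__(self, "num_classes", inferred)
        elif inferred > self.num_classes:
            raise ValueError(
                f"label code {inferred} exceeds num_classes={self.num_classes}"
            )

    @property
    def n_vertices(self) -> int:
        return int(self.labels.size)

    @property
    def labeled_mask(self) -> np.ndarray:
        """Boolean mask of vertices carrying a real parcel code."""
        return self.labels != self.unlabeled_code

    def present_labels(self) -> np.ndarray:
        """Sorted array of parcel codes present in the map (unlabeled excluded)."""
        vals = np.unique(self.labels)
        return vals[vals != self.unlabeled_code]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelMap):
            return NotImplemented
        return (
            self.unlabeled_code == other.unlabeled_code
            and self.num_classes == other.num_classes
            and np.array_equal(self.labels, other.labels)
        )
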