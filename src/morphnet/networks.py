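"""Morphological brain network construction and feature extraction.

A morphological brain network (MBN) for one subject and one cortical
attribute is the symmetric ``R x R`` matrix whose entry ``(i, j)`` is the
absolute difference between the attribute's mean value in ROIs ``i`` and
``j`` — a morphological *dissimilarity* network, not a physical-connection
network.  Stacking one such matrix per attribute gives the subject's
multi-view MBN (M-MBN).

Feature extraction takes the strict lower triangle of each matrix in a fixed
column-wise order (``j`` outer, ``i = j+1..R`` inner; equivalently MATLAB's
``tril`` linearization), then fuses the per-view vectors either by
concatenation (CON) or by elementwise averaging (AVG).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import CorticalAttributeCohort

__all__ = [
    "FeatureIndexMap",
    "FeatureMatrix",
    "MorphNetworkTensor",
    "build_network",
    "build_tensor",
    "vectorize",
    "unvectorize",
    "fuse_con",
    "fuse_avg",
    "cohort_features",
]

#: Absolute tolerance when validating that an input matrix is symmetric with
#: zero diagonal.  Constructed matrices are exactly symmetric; the tolerance
#: only guards text-file round trips.
SYMMETRY_ATOL = 1e-9


def _tri_order(r: int) -> tuple[np.ndarray, np.ndarray]:
    """Lower-triangle (i, j) index arrays, 0-based, in column-wise order."""
    ju, iu = np.triu_indices(r, k=1)  # upper triangle row-major == lower col-major
    return iu, ju


@dataclass(frozen=True)
class FeatureIndexMap:
    """Invertible map from feature index to ``(view, roi_i, roi_j)``.

    Entries use 1-based view and ROI indices with ``roi_i > roi_j``; entry
    order defines the feature-vector layout.  For CON fusion the map covers
    every view's lower triangle, view-major.
    """

    entries: tuple[tuple[int, int, int], ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, idx: int) -> tuple[int, int, int]:
        return self.entries[idx]

    @classmethod
    def single_view(cls, n_rois: int, view: int = 1) -> "FeatureIndexMap":
        ii, jj = _tri_order(n_rois)
        return cls(tuple((view, int(i) + 1, int(j) + 1) for i, j in zip(ii, jj)))

    @classmethod
    def concatenated(cls, n_rois: int, n_views: int) -> "FeatureIndexMap":
        entries: list[tuple[int, int, int]] = []
        for m in range(1, n_views + 1):
            entries.extend(cls.single_view(n_rois, view=m).entries)
        return cls(tuple(entries))

    def subset(self, idx: Sequence[int]) -> "FeatureIndexMap":
        return FeatureIndexMap(tuple(self.entries[i] for i in idx))


@dataclass
class FeatureMatrix:
    """Subjects x connectional-features matrix with feature provenance."""

    values: np.ndarray  # (N, F)
    index_map: FeatureIndexMap
    fusion: str  # "con", "avg" or "view<m>"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (subjects x features)")
        if self.values.shape[1] != len(self.index_map):
            raise ValueError(
                f"F={self.values.shape[1]} columns but index map has "
                f"{len(self.index_map)} entries"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class MorphNetworkTensor:
    """One subject's stack of per-view dissimilarity matrices (M x R x R)."""

    subject_id: str
    matrices: np.ndarray

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be M x R x R")


def build_network(roi_values: np.ndarray) -> np.ndarray:
    """Build one MBN: ``out[i, j] = |roi_values[i] - roi_values[j]|``.

    The result is symmetric, nonnegative, with zero diagonal; it is invariant
    to adding a constant to all ROI values and equivariant under scaling
    (scaling the input by ``s`` scales the network by ``|s|``).
    """
    a = np.asarray(roi_values, dtype=float)
    if a.ndim != 1:
        raise ValueError("roi_values must be a 1-D vector")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite ROI value; mask the ROI instead")
    return np.abs(a[:, None] - a[None, :])


def build_tensor(cohort: CorticalAttributeCohort, subject: int) -> MorphNetworkTensor:
    """All M networks for one subject (0-based position in the cohort)."""
    if not 0 <= subject < cohort.n_subjects:
        raise IndexError(f"subject index {subject} out of range")
    values = cohort.attributes[subject]
    if cohort.roi_mask is not None:
        values = values[:, cohort.roi_mask]
    mats = np.stack([build_network(values[m]) for m in range(values.shape[0])])
    return MorphNetworkTensor(subject_id=cohort.subject_ids[subject], matrices=mats)


def _check_symmetric(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=SYMMETRY_ATOL, rtol=0.0):
        raise ValueError(f"matrix asymmetric beyond tolerance {SYMMETRY_ATOL}")
    if not np.allclose(np.diag(matrix), 0.0, atol=SYMMETRY_ATOL):
        raise ValueError("matrix diagonal is not zero")
    return matrix


def vectorize(matrix: np.ndarray, view: int = 1) -> tuple[np.ndarray, FeatureIndexMap]:
    """Strict lower triangle of a symmetric matrix as a feature vector.

    Order is column-wise: ``(2,1), (3,1), ..., (R,1), (3,2), ...`` in 1-based
    ``(roi_i, roi_j)`` terms; length ``R(R-1)/2``.
    """
    matrix = _check_symmetric(matrix)
    r = matrix.shape[0]
    ii, jj = _tri_order(r)
    return matrix[ii, jj].copy(), FeatureIndexMap.single_view(r, view=view)


def unvectorize(vector: np.ndarray, n_rois: int) -> np.ndarray:
    """Inverse of :func:`vectorize`: rebuild the symmetric zero-diagonal matrix."""
    vector = np.asarray(vector, dtype=float)
    expected = n_rois * (n_rois - 1) // 2
    if vector.shape != (expected,):
        raise ValueError(f"expected vector of length {expected}, got {vector.shape}")
    out = np.zeros((n_rois, n_rois))
    ii, jj = _tri_order(n_rois)
    out[ii, jj] = vector
    out[jj, ii] = vector
    return out


def fuse_con(vectors: Sequence[np.ndarray], n_rois: int) -> tuple[np.ndarray, FeatureIndexMap]:
    """Concatenate per-view feature vectors in view order (CON fusion)."""
    vectors = [np.asarray(v, dtype=float) for v in vectors]
    expected = n_rois * (n_rois - 1) // 2
    for m, v in enumerate(vectors, start=1):
        if v.shape != (expected,):
            raise ValueError(
                f"view {m} vector has length {v.shape}, expected {expected}"
            )
    return np.concatenate(vectors), FeatureIndexMap.concatenated(n_rois, len(vectors))


def fuse_avg(
    vectors: Sequence[np.ndarray],
    n_rois: int,
    zscore_views: bool = False,
) -> tuple[np.ndarray, FeatureIndexMap]:
    """Elementwise mean of per-view feature vectors (AVG fusion).

    With ``zscore_views`` each view is standardized before averaging; the
    default averages raw values even though views carry incommensurate units.
    """
    vectors = [np.asarray(v, dtype=float) for v in vectors]
    expected = n_rois * (n_rois - 1) // 2
    for m, v in enumerate(vectors, start=1):
        if v.shape != (expected,):
            raise ValueError(
                f"view {m} vector has length {v.shape}, expected {expected}"
            )
    stack = np.stack(vectors)
    if zscore_views:
        sd = stack.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        stack = (stack - stack.mean(axis=1, keepdims=True)) / sd
    return stack.mean(axis=0), FeatureIndexMap.single_view(n_rois, view=1)


def cohort_features(
    cohort: CorticalAttributeCohort,
    fusion: str = "con",
    zscore_views: bool = False,
) -> FeatureMatrix:
    """Build the full subjects x features matrix for a cohort.

    Parameters
    ----------
    fusion
        ``"con"``, ``"avg"`` or ``"view<m>"`` (1-based single view, e.g.
        ``"view2"`` for mean cortical thickness in the default layout).
    zscore_views
        Standardize views before AVG fusion (ignored otherwise).
    """
    n_rois = (
        int(cohort.roi_mask.sum()) if cohort.roi_mask is not None else cohort.n_rois
    )
    fusion = fusion.lower()
    rows = []
    index_map: FeatureIndexMap | None = None
    for k in range(cohort.n_subjects):
        tensor = build_tensor(cohort, k)
        vecs = [vectorize(tensor.matrices[m])[0] for m in range(cohort.n_views)]
        if fusion == "con":
            row, index_map = fuse_con(vecs, n_rois)
        elif fusion == "avg":
            row, index_map = fuse_avg(vecs, n_rois, zscore_views=zscore_views)
        elif fusion.startswith("view"):
            m = int(fusion[4:])
            if not 1 <= m <= cohort.n_views:
                raise ValueError(f"view index {m} out of range (M={cohort.n_views})")
            row = vecs[m - 1]
            index_map = FeatureIndexMap.single_view(n_rois, view=m)
        else:
            raise ValueError(f"unknown fusion {fusion!r}")
        rows.append(row)
    assert index_map is not None
    return FeatureMatrix(values=np.stack(rows), index_map=index_map, fusion=fusion)
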