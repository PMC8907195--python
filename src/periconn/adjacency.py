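"""Weighted adjacency matrices: the unit of analysis.

A structural connectome is represented as a symmetric, non-negative,
region-labelled matrix of streamline counts. This module holds the
container type, CSV readers/writers, and the matrix-level preprocessing
steps: diagonal zeroing, hemisphere subsetting, density-based edge
thresholding and binarization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SYMMETRY_ATOL = 1e-9


class AdjacencyError(ValueError):
    """Base class for adjacency validation failures."""


class NonSquareError(AdjacencyError):
    pass


class AsymmetryError(AdjacencyError):
    pass


class NegativeWeightError(AdjacencyError):
    pass


class LabelError(AdjacencyError):
    """Duplicate, missing or mismatched region labels."""


@dataclass(frozen=True)
class WeightedAdjacency:
    """Symmetric non-negative region-by-region connectivity matrix.

    Parameters
    ----------
    labels
        Ordered region names; the public identifiers of nodes.
    weights
        ``(n, n)`` array of non-negative streamline counts (unitless).
        Must be symmetric within ``SYMMETRY_ATOL``.
    """

    labels: tuple
    weights: np.ndarray = field(repr=False)

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NonSquareError(f"weights must be square, got shape {w.shape}")
        if len(labels) != w.shape[0]:
            raise LabelError(
                f"{len(labels)} labels for a {w.shape[0]}x{w.shape[1]} matrix"
            )
        if len(set(labels)) != len(labels):
            raise LabelError("region labels must be unique")
        if not np.isfinite(w).all():
            raise AdjacencyError("weights must be finite")
        asym = np.abs(w - w.T).max(initial=0.0)
        if asym > SYMMETRY_ATOL:
            raise AsymmetryError(
                f"matrix asymmetric: max |w_ij - w_ji| = {asym:.3g} > {SYMMETRY_ATOL}"
            )
        if (w < 0).any():
            raise NegativeWeightError("negative weights are not allowed")
        # exact symmetry internally; tolerance applies only at the boundary
        w = (w + w.T) / 2.0
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise LabelError(f"label {label!r} not in matrix") from None

    def weight(self, a: str, b: str) -> float:
        return float(self.weights[self.index(a), self.index(b)])

    def edge_count(self) -> int:
        """Number of non-zero upper-triangle (off-diagonal) edges."""
        iu = np.triu_indices(self.n, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def density(self) -> float:
        """Fraction of possible off-diagonal edges present."""
        possible = self.n * (self.n - 1) // 2
        return self.edge_count() / possible if possible else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.labels, columns=self.labels)


def read_adjacency(path, expected_labels: Sequence[str] | None = None) -> WeightedAdjacency:
    """Read a labelled adjacency CSV (header row + label column).

    Raises a distinct :class:`AdjacencyError` subclass on a non-square
    matrix, asymmetry beyond tolerance, negative entries, or a label
    mismatch with ``expected_labels``.
    """
    df = pd.read_csv(path, index_col=0)
    row_labels = [str(x) for x in df.index]
    col_labels = [str(x) for x in df.columns]
    if row_labels != col_labels:
        raise LabelError(f"{path}: row labels differ from column labels")
    try:
        weights = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise AdjacencyError(f"{path}: non-numeric entries ({exc})") from None
    A = WeightedAdjacency(tuple(row_labels), weights)
    if expected_labels is not None and list(A.labels) != [str(x) for x in expected_labels]:
        raise LabelError(f"{path}: labels do not match the expected label list")
    return A


def write_adjacency(A: WeightedAdjacency, path) -> Path:
    """Write the labelled CSV dialect read by :func:`read_adjacency`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    A.to_dataframe().to_csv(path, float_format="%.12g")
    return path


def zero_diagonal(A: WeightedAdjacency) -> WeightedAdjacency:
    """Set self-connections to zero (idempotent)."""
    w = A.weights.copy()
    np.fill_diagonal(w, 0.0)
    return WeightedAdjacency(A.labels, w)


def subset_hemisphere(A: WeightedAdjacency, labels: Iterable[str]) -> WeightedAdjacency:
    """Principal submatrix restricted to ``labels``, in that order.

    Implements isolation of the hemisphere of interest (and the drop of
    small sub-cerebellar regions) from a whole-brain matrix.
    """
    labels = [str(x) for x in labels]
    idx = np.array([A.index(lab) for lab in labels], dtype=int)
    return WeightedAdjacency(tuple(labels), A.weights[np.ix_(idx, idx)])


def density_threshold(A: WeightedAdjacency, remove_fraction: float = 0.25) -> WeightedAdjacency:
    """Remove the weakest ``remove_fraction`` of non-zero edges.

    The candidate population is the non-zero upper-triangle entries
    (zeros are absent edges). The ``floor(remove_fraction * m)`` weakest
    edges are zeroed in both triangles; ties are broken deterministically
    by ascending (weight, row, column). Surviving weights are unchanged.
    """
    if not (0.0 <= remove_fraction < 1.0):
        raise ValueError(f"remove_fraction must be in [0, 1), got {remove_fraction}")
    w = A.weights.copy()
    iu, ju = np.triu_indices(A.n, k=1)
    nz = w[iu, ju] > 0
    ei, ej, ew = iu[nz], ju[nz], w[iu, ju][nz]
    m = ew.size
    k = math.floor(remove_fraction * m)
    if k > 0:
        order = np.lexsort((ej, ei, ew))  # weight, then row, then column
        drop = order[:k]
        w[ei[drop], ej[drop]] = 0.0
        w[ej[drop], ei[drop]] = 0.0
    return WeightedAdjacency(A.labels, w)


def binarize(A: WeightedAdjacency) -> WeightedAdjacency:
    """Map every non-zero weight to 1 (idempotent)."""
    return WeightedAdjacency(A.labels, (A.weights > 0).astype(float))
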