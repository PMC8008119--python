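"""Principal coordinates (PCoA) and spatial eigenvectors (PCNM).

PCoA follows Gower: double-centre -0.5 * D^2, eigendecompose, keep axes with
eigenvalue above tolerance and report (without correcting) negative
eigenvalues. PCNM truncates a geographic distance matrix at the longest
minimum-spanning-tree edge, replaces larger entries by four times the
truncation distance, and keeps the positive-eigenvalue PCoA axes as spatial
predictors.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from skbio.stats.distance import DistanceMatrix

from .errors import DegenerateInputError

EIG_TOL = 1e-10


@dataclasses.dataclass
class OrdinationResult:
    """Axis coordinates, eigenvalues and variance fractions.

    Axes are ordered by decreasing eigenvalue; ``coordinates`` columns are
    ``Axis1..AxisK`` scaled by sqrt(eigenvalue), so for Euclidean-embeddable
    input the pairwise coordinate distances reproduce the input distances.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    n_negative_eigenvalues: int
    negative_eigenvalues: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(dm: DistanceMatrix, eig_tol: float = EIG_TOL) -> OrdinationResult:
    """Classical metric multidimensional scaling of a distance matrix."""
    d = dm.data
    n = d.shape[0]
    if n < 2:
        raise DegenerateInputError("PCoA needs at least 2 items")
    a = -0.5 * d**2
    centred = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    eigvals, eigvecs = np.linalg.eigh(centred)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0)
    pos = eigvals > eig_tol * scale
    neg = eigvals < -eig_tol * scale
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    # deterministic sign: largest-magnitude loading positive
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    total = eigvals[pos].sum()
    frame = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"Axis{i+1}" for i in range(coords.shape[1])]
    )
    return OrdinationResult(
        coordinates=frame,
        eigenvalues=eigvals[pos],
        proportion_explained=eigvals[pos] / total if total > 0 else eigvals[pos],
        n_negative_eigenvalues=int(neg.sum()),
        negative_eigenvalues=eigvals[neg],
    )


def pcnm_truncation_distance(geo: DistanceMatrix) -> float:
    """Longest edge of the minimum spanning tree of the sites."""
    mst = minimum_spanning_tree(geo.data)
    return float(mst.data.max())


def pcnm(geo: DistanceMatrix, truncation: float | None = None) -> OrdinationResult:
    """Principal coordinates of neighbour matrices.

    Distances beyond the truncation threshold t (default: longest MST edge)
    are replaced by 4t before PCoA; only positive-eigenvalue eigenvectors are
    returned, mutually orthogonal by construction.
    """
    d = geo.data
    if np.all(d == 0):
        raise DegenerateInputError("PCNM undefined on an all-zero distance matrix")
    t = pcnm_truncation_distance(geo) if truncation is None else float(truncation)
    trunc = np.where(d > t, 4.0 * t, d)
    np.fill_diagonal(trunc, 0.0)
    res = pcoa(DistanceMatrix((trunc + trunc.T) / 2, ids=list(geo.ids)))
    cols = [f"PCNM{i+1}" for i in range(res.coordinates.shape[1])]
    res.coordinates.columns = cols
    return res
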