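"""Non-metric multidimensional scaling by Kruskal stress minimization.

The embedding seeks coordinates whose Euclidean distances reproduce the
*rank order* of the input dissimilarities.  Each iteration alternates
isotonic (monotone) regression of the embedded distances on the input
ranks — producing the disparities d-hat — with a Guttman majorization
step on the coordinates.  The goodness of fit is the normalized stress

    S = sum_ij (dhat_ij - ||phi_i - phi_j||)^2 / sum_ij ||phi_i - phi_j||^2,

whose square root is Kruskal's stress-1; both are reported.  The initial
configuration is the classical metric MDS (principal coordinates) of the
input matrix, so runs are deterministic; the seed is used only if that
initialization degenerates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .distance import DistanceMatrix


@dataclass
class Embedding:
    """A low-dimensional configuration with its final stress."""

    labels: list[str]
    coords: np.ndarray  # (n, dims)
    stress: float  # normalized squared-form stress
    n_iter: int
    converged: bool
    stress_history: list[float] = field(default_factory=list)

    @property
    def stress1(self) -> float:
        """Kruskal's stress-1: the square root of the normalized stress."""
        return float(np.sqrt(self.stress))

    def to_tsv(self, path) -> None:
        import pandas as pd

        cols = [f"PHI{i + 1}" for i in range(self.coords.shape[1])]
        df = pd.DataFrame(self.coords, index=self.labels, columns=cols)
        df.index.name = "SAMPLE"
        df.to_csv(path, sep="\t", float_format="%.6f")


def stress(
    D: np.ndarray, coords: np.ndarray, disparities: Optional[np.ndarray] = None
) -> float:
    """Normalized stress of a configuration against dissimilarities ``D``.

    ``disparities`` are the monotone-fitted values for the condensed
    (upper-triangle) dissimilarity order; if omitted, the raw
    dissimilarities serve as disparities (metric stress).
    """
    d_flat = squareform(np.asarray(D, dtype=np.float64), checks=False)
    dist = pdist(coords)
    if disparities is None:
        disparities = d_flat
    denom = float(np.sum(dist**2))
    if denom == 0:
        raise ValueError("all embedded points coincide; stress undefined")
    return float(np.sum((disparities - dist) ** 2) / denom)


def _pcoa(D: np.ndarray, dims: int) -> np.ndarray:
    """Classical metric MDS (principal coordinates) of a dissimilarity matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:dims]
    vals = np.clip(eigval[order], 0.0, None)
    return eigvec[:, order] * np.sqrt(vals)[None, :]


def _disparities(d_flat: np.ndarray, dist: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Monotone regression of embedded distances on the dissimilarity order.

    Kruskal's primary approach to ties: tied dissimilarities may take
    unequal disparities (they are fitted in their sorted order without a
    tie constraint).
    """
    iso = IsotonicRegression(increasing=True)
    fitted_sorted = iso.fit_transform(np.arange(order.size), dist[order])
    disparities = np.empty_like(d_flat)
    disparities[order] = fitted_sorted
    return disparities


def nmds(
    D: DistanceMatrix,
    dims: int = 2,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> Embedding:
    """Embed a distance matrix by non-metric MDS.

    Stops when the stress improvement falls below ``tol`` or after
    ``max_iter`` iterations; a step that would increase the stress is
    rejected and iteration stops, so stress is non-increasing across
    accepted iterations.
    """
    values = np.asarray(D.values, dtype=np.float64)
    n = values.shape[0]
    if n < 3:
        raise ValueError("non-metric MDS needs at least 3 samples")
    if not np.allclose(values, values.T):
        raise ValueError("distance matrix must be symmetric")
    if np.isnan(values).any():
        raise ValueError("distance matrix contains NaN")
    d_flat = squareform(values, checks=False)
    if np.all(d_flat == 0):
        raise ValueError("all dissimilarities are zero; embedding undefined")
    order = np.argsort(d_flat, kind="stable")

    coords = _pcoa(values, dims)
    if np.allclose(coords, 0):  # degenerate initialization: random restart
        rng = np.random.default_rng(seed)
        coords = rng.normal(scale=np.mean(d_flat), size=(n, dims))

    dist = pdist(coords)
    if np.all(dist == 0):
        raise ValueError("initial configuration collapsed to a point")
    disp = _disparities(d_flat, dist, order)
    current = float(np.sum((disp - dist) ** 2) / np.sum(dist**2))
    history = [current]
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # Guttman transform with the current disparities
        dist_m = squareform(dist)
        disp_m = squareform(disp)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist_m > 0, disp_m / dist_m, 0.0)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        new_coords = B @ coords / n
        new_dist = pdist(new_coords)
        if np.all(new_dist == 0):
            break
        new_disp = _disparities(d_flat, new_dist, order)
        new_stress = float(np.sum((new_disp - new_dist) ** 2) / np.sum(new_dist**2))
        if new_stress > current:  # reject the step; keep the best configuration
            break
        improvement = current - new_stress
        coords, dist, disp, current = new_coords, new_dist, new_disp, new_stress
        history.append(current)
        if improvement < tol:
            converged = True
            break
    return Embedding(list(D.labels), coords, current, n_iter, converged, history)
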