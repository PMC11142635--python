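"""Weighted brain networks: density thresholding, distances, EDR surrogates.

Networks are undirected, weighted graphs over atlas ROIs with coupling
weights in [0, 1] (functional-connectivity convention: 0.5 = no coupling,
1 = perfect correlation). Proportional thresholding keeps the strongest
fraction ``rho`` of off-diagonal link slots at their original weights
("thresholded but not binarized").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

__all__ = [
    "BrainNetwork",
    "DistanceMatrix",
    "EDRSpec",
    "threshold_density",
    "shortest_path_distances",
    "giant_component",
    "generate_edr_network",
    "density_for_mean_degree",
    "read_adjacency",
    "write_adjacency",
    "read_coordinates",
]

DistanceConvention = Literal["hop", "inverse_weight"]


@dataclass(frozen=True)
class BrainNetwork:
    """Symmetric weighted ROI graph.

    Parameters
    ----------
    roi_labels : tuple of str
        Ordered ROI identifiers (length N).
    weights : ndarray, shape (N, N)
        Symmetric coupling matrix, ``w_ij`` in [0, 1], zero diagonal.
    density : float
        Fraction of retained off-diagonal link slots, in (0, 1].
    """

    roi_labels: tuple
    weights: np.ndarray
    density: float = 1.0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if len(self.roi_labels) != w.shape[0]:
            raise ValueError("roi_labels length must match weight matrix size")
        if not np.allclose(w, w.T, atol=1e-9):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))

    @property
    def n_roi(self) -> int:
        return self.weights.shape[0]

    @property
    def n_links(self) -> int:
        """Number of nonzero links (upper triangle)."""
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def index_of(self, label: str) -> int:
        return self.roi_labels.index(label)

    def to_sparse(self) -> csr_matrix:
        return csr_matrix(self.weights)


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs shortest-path distances (np.inf for disconnected pairs)."""

    d: np.ndarray
    convention: DistanceConvention = "inverse_weight"


@dataclass
class EDRSpec:
    """Exponential-distance-rule surrogate connectome specification.

    Structural connection weights in the mammalian brain decay roughly
    exponentially with inter-areal distance, ``w_ij ~ exp(-alpha * d_ij)``.
    The surrogate places ROIs at ``coordinates`` (or random two-cluster
    positions if omitted), applies the exponential rule and rescales the
    weights affinely into ``rescale_range`` so they inhabit the same range
    as rescaled amplitude-envelope-correlation networks.
    """

    n_roi: int
    alpha: float = 1.0
    coordinates: np.ndarray | None = None
    rescale_range: tuple = (0.5, 1.0)

    def __post_init__(self):
        if self.n_roi < 2:
            raise ValueError("n_roi must be >= 2")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def _n_links_at_density(rho: float, n: int) -> int:
    # round-half-away-from-zero to match the printed link-count arithmetic
    return int(np.floor(rho * n * (n - 1) / 2 + 0.5))


def threshold_density(net: BrainNetwork, rho: float) -> BrainNetwork:
    """Keep the ``round(rho * N(N-1)/2)`` strongest links at original weight.

    Ties at the cutoff are broken by (weight desc, i asc, j asc), which makes
    link sets nested across densities. If the network has fewer nonzero links
    than requested, all are kept and a warning is issued.
    """
    if not (0 < rho <= 1):
        raise ValueError(f"density must lie in (0, 1], got {rho}")
    n = net.n_roi
    iu, ju = np.triu_indices(n, k=1)
    w = net.weights[iu, ju]
    k = _n_links_at_density(rho, n)
    nonzero = np.count_nonzero(w)
    if nonzero < k:
        warnings.warn(
            f"requested {k} links at density {rho} but only {nonzero} nonzero "
            "links available; keeping all",
            stacklevel=2,
        )
        k = nonzero
    # stable order: weight desc, then i asc, j asc
    order = np.lexsort((ju, iu, -w))
    keep = order[:k]
    out = np.zeros_like(net.weights)
    out[iu[keep], ju[keep]] = w[keep]
    out += out.T
    return BrainNetwork(net.roi_labels, out, density=rho)


def shortest_path_distances(
    net: BrainNetwork, convention: DistanceConvention = "inverse_weight"
) -> DistanceMatrix:
    """All-pairs shortest-path distances.

    ``hop``: every nonzero link has unit length. ``inverse_weight``: link
    length is ``1 / w_ij``, so strong couplings are short. Disconnected
    pairs get np.inf.
    """
    lengths = _edge_lengths(net.weights, convention)
    d = dijkstra(csr_matrix(lengths), directed=False)
    return DistanceMatrix(d=d, convention=convention)


def _edge_lengths(weights: np.ndarray, convention: DistanceConvention) -> np.ndarray:
    mask = weights > 0
    lengths = np.zeros_like(weights)
    if convention == "hop":
        lengths[mask] = 1.0
    elif convention == "inverse_weight":
        lengths[mask] = 1.0 / weights[mask]
    else:
        raise ValueError(f"unknown distance convention: {convention!r}")
    return lengths


def giant_component(net: BrainNetwork) -> set:
    """ROI indices of the largest connected component.

    Size ties are broken toward the component containing the smallest ROI
    index. Isolated nodes form singleton components.
    """
    return _giant_component_from_weights(net.weights)


def _giant_component_from_weights(weights: np.ndarray) -> set:
    n_comp, labels = connected_components(csr_matrix(weights), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    best = np.max(sizes)
    # scipy labels components by order of first appearance, so among equal-size
    # components the lowest label contains the smallest node index
    giant_label = int(np.flatnonzero(sizes == best)[0])
    return set(np.flatnonzero(labels == giant_label).tolist())


def density_for_mean_degree(mean_degree: float, n: int) -> float:
    """Density rho giving the requested mean degree at network size n."""
    return min(1.0, mean_degree / (n - 1))


def generate_edr_network(spec: EDRSpec, seed: int | None = None) -> BrainNetwork:
    """Build an EDR surrogate connectome.

    If ``spec.coordinates`` is None, ROIs are placed in two 3-D Gaussian
    clusters (a crude left/right hemisphere layout) whose centres are 1.5
    spatial units apart with unit spread, so the strongest links are
    short-range but the two blocks remain bridged. Weights
    ``exp(-alpha * d)`` are rescaled affinely into ``rescale_range``.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_roi
    if spec.coordinates is not None:
        xyz = np.asarray(spec.coordinates, dtype=float)
        if xyz.shape != (n, 3):
            raise ValueError("coordinates must have shape (n_roi, 3)")
    else:
        half = n // 2
        centres = np.array([[-0.75, 0.0, 0.0], [0.75, 0.0, 0.0]])
        assignment = np.repeat([0, 1], [half, n - half])
        xyz = centres[assignment] + rng.normal(scale=1.0, size=(n, 3))
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    iu, ju = np.triu_indices(n, k=1)
    if np.all(d[iu, ju] == 0):
        raise ValueError("degenerate coordinates: all ROIs coincide")
    w = np.exp(-spec.alpha * d)
    lo, hi = spec.rescale_range
    wmin, wmax = w[iu, ju].min(), w[iu, ju].max()
    out = np.zeros_like(w)
    if wmax == wmin:
        out[iu, ju] = hi
    else:
        out[iu, ju] = lo + (w[iu, ju] - wmin) * (hi - lo) / (wmax - wmin)
    out += out.T
    labels = tuple(f"roi{i:03d}" for i in range(n))
    return BrainNetwork(labels, out, density=1.0)


# ---------------------------------------------------------------------------
# I/O


def read_adjacency(path) -> BrainNetwork:
    """Read a labelled adjacency matrix (TSV/CSV, labels in first row+column).

    Asymmetries beyond 1e-9 are symmetrized by averaging, with a warning.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    w = df.to_numpy(dtype=float)
    if not np.allclose(w, w.T, atol=1e-9):
        warnings.warn(f"{path}: adjacency not symmetric; averaging w and w.T", stacklevel=2)
        w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return BrainNetwork(tuple(df.index.astype(str)), w)


def write_adjacency(net: BrainNetwork, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(net.weights, index=net.roi_labels, columns=net.roi_labels).to_csv(
        path, sep=sep
    )


def read_coordinates(path) -> pd.DataFrame:
    """Read an ROI coordinate table with columns roi,x,y,z."""
    df = pd.read_csv(path)
    missing = {"roi", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"coordinate file missing columns: {sorted(missing)}")
    return df
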