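"""Direct connection embedding and the Gaussian graph kernel built on it.

For graphs with a fixed node correspondence, the upper triangle of the
adjacency matrix is a lossless vector representation (the *direct connection
embedding*): a graph with ``l`` nodes maps to a vector of length
``t = l(l-1)/2``.  A Gaussian (RBF) kernel on these vectors,

    k(G1, G2) = exp(-||f(G1) - f(G2)||^2 / (2 sigma^2)),

is a characteristic positive definite kernel on such graph collections — the
composition of a bijective embedding with the characteristic Gaussian kernel
on R^t — which is what licenses its use in the kernel two-sample test.

The bandwidth ``sigma`` defaults to the median of all pairwise embedded
distances, the standard label-free heuristic for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .graphs import BrainGraph, LabeledGraphDataset


def dce_embed(graph: BrainGraph) -> np.ndarray:
    """Unfold the upper triangle of the adjacency matrix, row-major.

    Returns the vector ``(A[0,1], A[0,2], ..., A[l-2,l-1])`` of length
    ``l(l-1)/2``.  Any fixed consistent ordering yields identical pairwise
    distances; row-major upper triangle is the documented choice.
    """
    w = np.asarray(graph.weights)
    iu = np.triu_indices(w.shape[0], k=1)
    return w[iu].astype(float, copy=True)


def embedding_from_vector(
    vector: np.ndarray, node_labels, modality, subject_id: str = ""
) -> BrainGraph:
    """Inverse of :func:`dce_embed`: rebuild the graph from its vector."""
    vector = np.asarray(vector, dtype=float)
    l = len(node_labels)
    if vector.shape != (l * (l - 1) // 2,):
        raise ValueError(
            f"vector length {vector.shape} does not match {l} nodes"
        )
    w = np.zeros((l, l))
    iu = np.triu_indices(l, k=1)
    w[iu] = vector
    w = w + w.T
    return BrainGraph.from_matrix(node_labels, w, modality, subject_id)


def embed_dataset(dataset: LabeledGraphDataset) -> np.ndarray:
    """Stack the embedded vectors of all graphs into an ``(N, t)`` matrix."""
    return np.stack([dce_embed(g) for g in dataset.graphs])


def median_sigma(vectors: np.ndarray, method: str = "median") -> float:
    """Bandwidth heuristic: median (or mean) of pairwise Euclidean distances.

    ``vectors`` is an ``(N, t)`` array of embedded graphs, ``N >= 2``.  The
    median is taken over the ``N(N-1)/2`` distinct pairs (self-pairs
    excluded); for an even number of pairs numpy's median averages the two
    central order statistics.  Raises if the heuristic value is zero (all
    vectors identical) — the caller must then supply sigma explicitly.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValueError("median_sigma needs at least 2 embedded vectors")
    d = pdist(vectors)
    sigma = float(np.median(d) if method == "median" else np.mean(d))
    if sigma <= 0.0:
        raise ValueError(
            "pairwise-distance bandwidth heuristic is 0 (all embedded "
            "vectors identical); supply sigma explicitly"
        )
    return sigma


def kde(g1: BrainGraph, g2: BrainGraph, sigma: float) -> float:
    """Direct embedding kernel between two graphs: exp(-d^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if g1.node_labels != g2.node_labels:
        raise ValueError("graphs do not share a node ordering")
    diff = dce_embed(g1) - dce_embed(g2)
    return float(np.exp(-(diff @ diff) / (2.0 * sigma**2)))


@dataclass(frozen=True)
class KernelMatrix:
    """Pairwise graph-kernel matrix with the bandwidth that produced it.

    Invariants: symmetric, unit diagonal, entries in (0, 1], numerically
    positive semidefinite.
    """

    values: np.ndarray
    sigma: float
    subject_order: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def kernel_matrix(
    dataset: LabeledGraphDataset,
    sigma: float | str = "auto",
    sigma_method: str = "median",
) -> KernelMatrix:
    """Direct-embedding-kernel matrix over a dataset.

    ``sigma="auto"`` applies the pairwise-distance heuristic to the dataset's
    own embeddings (labels play no role, so there is no leakage into a
    subsequent permutation test).
    """
    X = embed_dataset(dataset)
    if sigma == "auto":
        sigma = median_sigma(X, method=sigma_method)
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    K = np.exp(-d2 / (2.0 * sigma**2))
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, sigma, dataset.subject_ids)


def write_kernel_matrix(km: KernelMatrix, path, delimiter: str = ",") -> None:
    """Export a kernel matrix as delimited text with subject ids as header."""
    lines = [delimiter.join(km.subject_order)]
    for row in km.values:
        lines.append(delimiter.join(format(v, ".17g") for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
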