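"""Common representation space and the differential statistic MMD^2_SF.

Structural weights (streamline counts) and functional weights (correlations)
live on incommensurable scales, so the two modalities' MMD values cannot be
compared directly.  The fix is a rank transform: pool every nonzero edge
weight of one modality across all of its graphs into a multiset Omega, form
the pooled empirical CDF

    F_hat(x) = |{w in Omega : w <= x}| / |Omega|,

and replace each present edge's weight by its ECDF value.  If the raw
weights are i.i.d. draws from a continuous distribution, the transformed
weights are uniform on (0, 1] in both modalities, so the transformed graphs
share one representation space.  Absent edges (weight 0) stay 0, preserving
sparsity.

In that space MMD^2_S and MMD^2_F (each computed with one shared bandwidth)
are directly comparable, and the differential statistic

    MMD^2_SF = MMD^2_S - MMD^2_F

is positive when the condition separates the classes more in structural than
in functional connectivity.  Its null distribution is approximated by
permuting class labels independently within each modality (the four group
sizes are preserved) and recomputing the difference on the fixed transformed
kernel matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .graphs import BrainGraph, LabeledGraphDataset, Modality
from .kernels import KernelMatrix, embed_dataset, median_sigma
from .ktst import _group_mask, mmd2u, mmd2u_null, p_value_from_null


@dataclass(frozen=True)
class EdgeWeightECDF:
    """Pooled empirical CDF of one modality's present (nonzero) edge weights."""

    sorted_weights: np.ndarray
    modality: Modality

    def __post_init__(self):
        w = np.asarray(self.sorted_weights, dtype=float)
        if w.size == 0:
            raise ValueError("ECDF needs at least one nonzero edge weight")
        object.__setattr__(self, "sorted_weights", np.sort(w))

    def __len__(self) -> int:
        return len(self.sorted_weights)

    def evaluate(self, x):
        """F_hat(x) = (number of pooled weights <= x) / (pool size).

        Accepts scalars or arrays; ties count with "<=" (no midranks).
        """
        idx = np.searchsorted(self.sorted_weights, x, side="right")
        out = idx / len(self.sorted_weights)
        return float(out) if np.isscalar(x) else out


def pooled_ecdf(dataset: LabeledGraphDataset) -> EdgeWeightECDF:
    """Pool every nonzero upper-triangle weight of every graph (both classes).

    Class labels play no role, so the ECDF is invariant under the label
    permutations used downstream and can be built once.
    """
    l = dataset.n_nodes
    iu = np.triu_indices(l, k=1)
    pooled = np.concatenate(
        [np.asarray(g.weights)[iu] for g in dataset.graphs]
    )
    pooled = pooled[pooled != 0.0]
    if pooled.size == 0:
        raise ValueError(
            f"{dataset.modality.value} dataset has no nonzero edge weights"
        )
    return EdgeWeightECDF(pooled, dataset.modality)


def transform_graphs(
    dataset: LabeledGraphDataset, ecdf: EdgeWeightECDF
) -> LabeledGraphDataset:
    """Map each graph into the common space: nonzero weights -> ECDF values.

    Zero (absent) entries remain exactly 0; node ordering, class labels and
    subject ids are preserved.  All transformed present-edge weights lie in
    (0, 1] because every present weight is itself a member of the pool.
    """
    if ecdf.modality != dataset.modality:
        raise ValueError(
            f"ECDF built from {ecdf.modality.value} data cannot transform a "
            f"{dataset.modality.value} dataset"
        )
    new_graphs = []
    for g in dataset.graphs:
        w = np.asarray(g.weights)
        out = np.zeros_like(w)
        nz = w != 0.0
        out[nz] = ecdf.evaluate(w[nz])
        out.flags.writeable = False
        new_graphs.append(dc_replace(g, weights=out))
    return LabeledGraphDataset(
        tuple(new_graphs), dataset.class_labels, dataset.shared_node_labels
    )


def _transformed_pair(ds: LabeledGraphDataset, df: LabeledGraphDataset):
    if ds.modality is not Modality.STRUCTURAL:
        raise ValueError("first dataset must be structural")
    if df.modality is not Modality.FUNCTIONAL:
        raise ValueError("second dataset must be functional")
    ds_t = transform_graphs(ds, pooled_ecdf(ds))
    df_t = transform_graphs(df, pooled_ecdf(df))
    return ds_t, df_t


def _common_space_kernels(
    ds_t: LabeledGraphDataset,
    df_t: LabeledGraphDataset,
    per_modality_sigma: bool = False,
    sigma_method: str = "median",
):
    """Kernel matrices of the two transformed datasets.

    By default one bandwidth, from the pairwise distances of the POOLED
    transformed embeddings, is shared by both modalities — required for the
    two statistics to be measured against one scale.
    """
    Xs = embed_dataset(ds_t)
    Xf = embed_dataset(df_t)
    if per_modality_sigma:
        sig_s = median_sigma(Xs, method=sigma_method)
        sig_f = median_sigma(Xf, method=sigma_method)
    else:
        sig_s = sig_f = median_sigma(
            np.vstack([Xs, Xf]), method=sigma_method
        )

    def _K(X, sigma, subjects):
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        K = np.exp(-d2 / (2.0 * sigma**2))
        K = (K + K.T) / 2.0
        np.fill_diagonal(K, 1.0)
        return KernelMatrix(K, sigma, subjects)

    return (
        _K(Xs, sig_s, ds_t.subject_ids),
        _K(Xf, sig_f, df_t.subject_ids),
    )


def common_space_mmds(
    ds: LabeledGraphDataset,
    df: LabeledGraphDataset,
    per_modality_sigma: bool = False,
    sigma_method: str = "median",
) -> tuple[float, float, float | tuple[float, float]]:
    """MMD^2_S and MMD^2_F on the common-space datasets, plus the bandwidth.

    Returns ``(mmd2_s, mmd2_f, sigma)``; ``sigma`` is a pair when
    ``per_modality_sigma`` is set.
    """
    ds_t, df_t = _transformed_pair(ds, df)
    Ks, Kf = _common_space_kernels(ds_t, df_t, per_modality_sigma, sigma_method)
    m_s = mmd2u(Ks, ds_t.class_labels)
    m_f = mmd2u(Kf, df_t.class_labels)
    sigma = (Ks.sigma, Kf.sigma) if per_modality_sigma else Ks.sigma
    return m_s, m_f, sigma


@dataclass(frozen=True)
class DifferentialTestResult:
    """Outcome of the cross-modality differential test."""

    mmd2_s: float
    mmd2_f: float
    mmd2_sf: float
    null_sample: np.ndarray
    p_value: float
    p_structural: float
    p_functional: float
    iterations: int
    seed: int | None
    sigma: float | tuple[float, float]
    group_sizes: tuple[int, int, int, int]


def mmd_sf_test(
    ds: LabeledGraphDataset,
    df: LabeledGraphDataset,
    T: int = 100_000,
    seed: int | None = None,
    two_sided: bool = False,
    per_modality_sigma: bool = False,
    sigma_method: str = "median",
) -> DifferentialTestResult:
    """Differential kernel two-sample test: is structure more affected?

    The observed statistic is MMD^2_SF = MMD^2_S - MMD^2_F on the common
    space.  Each of the T iterations shuffles class labels within the
    structural dataset and, independently, within the functional dataset
    (preserving all four group sizes), recomputes both MMDs on the fixed
    transformed kernel matrices, and collects the difference.  The default
    p-value is one-sided (structural more affected); ``two_sided`` doubles
    the smaller tail.  The ECDFs and the bandwidth never see class labels,
    so they are computed once and reused across permutations.

    Per-modality p-values of MMD^2_S and MMD^2_F against their own
    within-modality permutation nulls (from the same iterations) are
    reported alongside.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    ds_t, df_t = _transformed_pair(ds, df)
    Ks, Kf = _common_space_kernels(ds_t, df_t, per_modality_sigma, sigma_method)
    m_s = mmd2u(Ks, ds_t.class_labels)
    m_f = mmd2u(Kf, df_t.class_labels)
    observed = m_s - m_f

    rng = np.random.default_rng(seed)
    null_s = mmd2u_null(Ks, _group_mask(ds_t.class_labels), T, rng)
    null_f = mmd2u_null(Kf, _group_mask(df_t.class_labels), T, rng)
    null_sf = null_s - null_f

    p_upper = p_value_from_null(null_sf, observed)
    if two_sided:
        lower = int(np.count_nonzero(null_sf <= observed))
        p_lower = max(lower, 1) / T
        p = min(1.0, 2.0 * min(p_upper, p_lower))
    else:
        p = p_upper

    sigma = (Ks.sigma, Kf.sigma) if per_modality_sigma else Ks.sigma
    return DifferentialTestResult(
        mmd2_s=m_s,
        mmd2_f=m_f,
        mmd2_sf=observed,
        null_sample=null_sf,
        p_value=p,
        p_structural=p_value_from_null(null_s, m_s),
        p_functional=p_value_from_null(null_f, m_f),
        iterations=T,
        seed=seed,
        sigma=sigma,
        group_sizes=tuple(ds.group_sizes()) + tuple(df.group_sizes()),  # type: ignore[arg-type]
    )


def shared_null_reference(
    ds: LabeledGraphDataset,
    df: LabeledGraphDataset,
    T: int,
    seed: int | None = None,
    sigma_method: str = "median",
) -> np.ndarray:
    """One shared reference null over the pooled common-space graphs.

    Used only to display MMD^2_S and MMD^2_F against a single scale: each
    iteration shuffles the pooled transformed graphs (both modalities
    together) and computes MMD^2_u between two random groups whose sizes
    alternate between the structural and the functional class design.  It
    plays no role in any p-value.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    ds_t, df_t = _transformed_pair(ds, df)
    X = np.vstack([embed_dataset(ds_t), embed_dataset(df_t)])
    sigma = median_sigma(X, method=sigma_method)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-d2 / (2.0 * sigma**2))
    N = K.shape[0]
    rng = np.random.default_rng(seed)
    designs = [ds_t.group_sizes(), df_t.group_sizes()]
    out = np.empty(T)
    for i in range(T):
        a, b = designs[i % 2]
        idx = rng.permutation(N)[: a + b]
        sub = K[np.ix_(idx, idx)]
        labels = np.r_[np.zeros(a, dtype=int), np.ones(b, dtype=int)]
        out[i] = mmd2u(sub, labels)
    return out
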