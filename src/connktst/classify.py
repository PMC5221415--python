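"""Baseline comparator: kernel SVM with leave-one-subject-out CV.

Each fold trains a support vector machine on the precomputed
direct-embedding-kernel matrix of all but one subject and predicts the
held-out subject; the bandwidth is recomputed per fold from the training
embeddings only, so the held-out subject never influences it.  Above-chance
accuracy is assessed with an exact binomial test on the number of
misclassified subjects r at chance probability 1/2:

    p = sum_{i=0}^{r} C(n, i) / 2^n.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.svm import SVC

from .graphs import LabeledGraphDataset
from .kernels import embed_dataset


@dataclass(frozen=True)
class CvResult:
    """Leave-one-out cross-validation outcome."""

    predictions: tuple
    accuracy: float
    misclassified: int
    p_value: float
    folds: int


def binomial_pvalue(r: int, n: int) -> float:
    """Exact cumulative binomial tail Pr(i <= r | p=1/2) over n folds.

    Computed with exact integer binomial coefficients; the division by 2^n
    is the only floating-point step.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= r <= n:
        raise ValueError(f"r must be in [0, {n}], got {r}")
    return sum(comb(n, i) for i in range(r + 1)) / (1 << n)


def loso_cv(
    dataset: LabeledGraphDataset,
    sigma: float | str = "auto",
    regularization: float = 1.0,
    sigma_method: str = "median",
) -> CvResult:
    """Leave-one-subject-out CV of a precomputed-kernel SVM.

    Returns per-subject predictions (aligned with dataset order), accuracy,
    the misclassification count r, and its exact binomial p-value.  With
    ``sigma="auto"`` the bandwidth is the median pairwise embedded distance
    of the N-1 training subjects of each fold.
    """
    if regularization <= 0:
        raise ValueError("regularization must be positive")
    labels = np.asarray(dataset.class_labels)
    for c in dataset.classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 graphs")
    X = embed_dataset(dataset)
    N = len(dataset)
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    predictions = []
    for held_out in range(N):
        train = np.setdiff1d(np.arange(N), [held_out])
        if len(set(labels[train].tolist())) < 2:
            raise ValueError(
                f"training fold for subject index {held_out} has one class only"
            )
        d2_tr = d2[np.ix_(train, train)]
        if sigma == "auto":
            iu = np.triu_indices(len(train), k=1)
            dist = np.sqrt(d2_tr[iu])
            fold_sigma = float(
                np.median(dist) if sigma_method == "median" else np.mean(dist)
            )
            if fold_sigma <= 0:
                raise ValueError(
                    "training embeddings are all identical; supply sigma"
                )
        else:
            fold_sigma = float(sigma)
        K_tr = np.exp(-d2_tr / (2.0 * fold_sigma**2))
        clf = SVC(C=regularization, kernel="precomputed")
        clf.fit(K_tr, labels[train])
        k_te = np.exp(-d2[held_out, train] / (2.0 * fold_sigma**2))
        predictions.append(clf.predict(k_te[None, :])[0])
    predictions = np.asarray(predictions)
    r = int(np.sum(predictions != labels))
    return CvResult(
        predictions=tuple(predictions.tolist()),
        accuracy=1.0 - r / N,
        misclassified=r,
        p_value=binomial_pvalue(r, N),
        folds=N,
    )
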