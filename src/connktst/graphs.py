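"""Graph data model for fixed-node-correspondence connectivity networks.

A connectome here is a simple, undirected, edge-weighted graph over a fixed,
ordered set of labeled brain regions.  Because every graph in a study shares
the same node ordering (the fixed-cardinality vertex sequence, FCVS,
property), each graph is fully described by its symmetric adjacency matrix,
and matrices from different subjects are entry-wise comparable.

Two modalities are distinguished only by the nature of the edge weights:
``structural`` weights are nonnegative streamline counts from tractography,
``functional`` weights are Pearson correlations between regional BOLD time
courses (in [-1, 1] before thresholding, [0, 1] after).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Maximum tolerated |A - A.T| entry on ingestion; larger asymmetry is rejected
#: rather than silently averaged away.
SYMMETRY_TOL = 1e-9

#: Functional correlations are clipped to +/-(1 - FISHER_CLIP) before atanh.
FISHER_CLIP = 1e-7


class Modality(str, Enum):
    """Connectivity modality: what an edge weight measures."""

    STRUCTURAL = "structural"
    FUNCTIONAL = "functional"


@dataclass(frozen=True)
class BrainGraph:
    """One subject's weighted undirected connectivity network.

    Parameters
    ----------
    node_labels
        Ordered region identifiers; the ordering defines the row/column
        ordering of ``weights``.
    weights
        ``(l, l)`` symmetric matrix of edge weights; absent edges are exact 0
        and the diagonal is 0 (no self-loops).
    modality
        ``Modality.STRUCTURAL`` or ``Modality.FUNCTIONAL``.
    subject_id
        Opaque subject identifier, used in validation reports.
    """

    node_labels: tuple[str, ...]
    weights: np.ndarray
    modality: Modality
    subject_id: str = ""

    @classmethod
    def from_matrix(
        cls,
        node_labels: Sequence[str],
        weights: np.ndarray,
        modality: Modality | str,
        subject_id: str = "",
    ) -> "BrainGraph":
        """Build a graph, enforcing the adjacency-matrix invariants.

        The matrix must be square with side ``len(node_labels)`` and symmetric
        to within ``SYMMETRY_TOL``; it is then exactly symmetrized as
        ``(A + A.T) / 2`` and the diagonal is forced to zero (correlation
        matrices carry 1s there, which hold no between-region information).
        """
        modality = Modality(modality)
        labels = tuple(str(x) for x in node_labels)
        w = np.asarray(weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(
                f"adjacency matrix must be square, got shape {w.shape}"
            )
        if w.shape[0] != len(labels):
            raise ValueError(
                f"matrix side {w.shape[0]} does not match "
                f"{len(labels)} node labels"
            )
        asym = np.max(np.abs(w - w.T)) if w.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(
                f"adjacency matrix of subject {subject_id!r} is asymmetric "
                f"(max |A - A.T| = {asym:.3g} > {SYMMETRY_TOL:g})"
            )
        w = (w + w.T) / 2.0
        if np.any(np.diagonal(w) != 0.0):
            logger.debug(
                "zeroing %d nonzero diagonal entries of subject %r",
                int(np.count_nonzero(np.diagonal(w))),
                subject_id,
            )
            np.fill_diagonal(w, 0.0)
        if modality is Modality.STRUCTURAL and np.any(w < 0):
            raise ValueError(
                f"structural graph {subject_id!r} has negative weights"
            )
        if modality is Modality.FUNCTIONAL and (
            np.any(w < -1.0) or np.any(w > 1.0)
        ):
            raise ValueError(
                f"functional graph {subject_id!r} has weights outside [-1, 1]"
            )
        w.flags.writeable = False
        return cls(labels, w, modality, subject_id)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)


@dataclass(frozen=True)
class LabeledGraphDataset:
    """Graphs of one modality sharing a node ordering, with binary class labels."""

    graphs: tuple[BrainGraph, ...]
    class_labels: tuple
    shared_node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if not self.graphs:
            raise ValueError("dataset must contain at least one graph")
        if len(self.class_labels) != len(self.graphs):
            raise ValueError(
                f"{len(self.class_labels)} class labels for "
                f"{len(self.graphs)} graphs"
            )
        if not self.shared_node_labels:
            object.__setattr__(
                self, "shared_node_labels", self.graphs[0].node_labels
            )
        object.__setattr__(self, "graphs", tuple(self.graphs))
        object.__setattr__(self, "class_labels", tuple(self.class_labels))
        object.__setattr__(
            self, "shared_node_labels", tuple(self.shared_node_labels)
        )

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self) -> Iterator[BrainGraph]:
        return iter(self.graphs)

    @property
    def modality(self) -> Modality:
        return self.graphs[0].modality

    @property
    def n_nodes(self) -> int:
        return len(self.shared_node_labels)

    @property
    def classes(self) -> tuple:
        """The two class values, in sorted order."""
        return tuple(sorted(set(self.class_labels)))

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(g.subject_id for g in self.graphs)

    def group_sizes(self) -> tuple[int, ...]:
        labels = np.asarray(self.class_labels)
        return tuple(int(np.sum(labels == c)) for c in self.classes)


def validate_fcvs(dataset: LabeledGraphDataset) -> list[str]:
    """Check the fixed-cardinality vertex sequence invariants of a dataset.

    Returns a list of human-readable violation messages (one per violated
    invariant, naming the offending subject); an empty list means the dataset
    is valid.  Validation never raises.
    """
    report: list[str] = []
    shared = dataset.shared_node_labels
    l = len(shared)
    for g in dataset.graphs:
        who = f"subject {g.subject_id!r}"
        if g.node_labels != shared:
            if set(g.node_labels) == set(shared):
                report.append(
                    f"{who}: node labels are a permutation of the shared "
                    "ordering, not equal to it"
                )
            else:
                report.append(
                    f"{who}: node labels do not match the shared ordering"
                )
        w = np.asarray(g.weights)
        if w.ndim != 2 or w.shape != (l, l):
            report.append(
                f"{who}: weights matrix has shape {w.shape}, expected ({l}, {l})"
            )
            continue
        asym = float(np.max(np.abs(w - w.T))) if w.size else 0.0
        if asym > SYMMETRY_TOL:
            report.append(
                f"{who}: weights asymmetric (max |A - A.T| = {asym:.3g})"
            )
        if np.any(np.diagonal(w) != 0.0):
            report.append(f"{who}: nonzero diagonal entries (self-loops)")
        if g.modality != dataset.modality:
            report.append(
                f"{who}: modality {g.modality.value!r} differs from dataset "
                f"modality {dataset.modality.value!r}"
            )
    if len(set(dataset.class_labels)) != 2:
        report.append(
            f"dataset has {len(set(dataset.class_labels))} distinct class "
            "labels; exactly two are required"
        )
    return report


def threshold_positive(graph: BrainGraph, threshold: float = 0.0) -> BrainGraph:
    """Keep only correlations above ``threshold``; set the rest to zero.

    Functional edge weights must be similarities (larger = stronger coupling)
    for the kernel machinery, so negative correlations are removed.  The
    default threshold 0 keeps exactly the positive correlations; values up to
    0.5 are accepted for sensitivity analyses.

    Raises if applied to a structural graph — streamline counts are already
    nonnegative and thresholding them would signal a pipeline wiring bug.
    """
    if graph.modality is not Modality.FUNCTIONAL:
        raise ValueError(
            "threshold_positive applies to functional graphs only, got "
            f"{graph.modality.value!r} for subject {graph.subject_id!r}"
        )
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"threshold must be in [0, 0.5], got {threshold}")
    w = np.where(np.asarray(graph.weights) > threshold, graph.weights, 0.0)
    w.flags.writeable = False
    return replace(graph, weights=w)


def group_average(
    graphs: Sequence[BrainGraph], modality: Modality | str | None = None
) -> BrainGraph:
    """Group-level average connectivity matrix.

    Structural matrices are averaged element-wise on the raw streamline
    counts.  Functional correlation matrices are Fisher z-transformed
    (atanh), averaged, and back-transformed (tanh), which is the standard way
    of averaging correlations; values are clipped to ``+/-(1 - 1e-7)`` first
    because atanh diverges at exactly +/-1.
    """
    graphs = list(graphs)
    if not graphs:
        raise ValueError("group_average requires at least one graph")
    modalities = {g.modality for g in graphs}
    if len(modalities) > 1:
        raise ValueError(
            f"mixed modalities in group_average: "
            f"{sorted(m.value for m in modalities)}"
        )
    if modality is not None and Modality(modality) != graphs[0].modality:
        raise ValueError(
            f"graphs are {graphs[0].modality.value!r}, "
            f"requested {Modality(modality).value!r}"
        )
    orderings = {g.node_labels for g in graphs}
    if len(orderings) > 1:
        raise ValueError("graphs passed to group_average differ in node ordering")
    stack = np.stack([np.asarray(g.weights) for g in graphs])
    if graphs[0].modality is Modality.STRUCTURAL:
        mean = stack.mean(axis=0)
    else:
        z = np.arctanh(np.clip(stack, -(1 - FISHER_CLIP), 1 - FISHER_CLIP))
        mean = np.tanh(z.mean(axis=0))
    return BrainGraph.from_matrix(
        graphs[0].node_labels, mean, graphs[0].modality, "group_average"
    )
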