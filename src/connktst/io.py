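"""Reading and writing adjacency matrices and dataset manifests.

The on-disk formats are deliberately plain:

* adjacency matrices — delimited text (CSV/TSV), full square matrix, with an
  optional single header row of node labels;
* node labels — plain text, one label per line, order significant;
* manifest — a YAML file listing one record per graph (``path``, ``subject``,
  ``class``, ``modality``) plus global fields ``node_labels``,
  ``functional_threshold`` and ``delimiter``.

The statistical core never touches files; everything enters through
:func:`read_dataset`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .graphs import (
    BrainGraph,
    LabeledGraphDataset,
    Modality,
    threshold_positive,
    validate_fcvs,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ManifestEntry:
    path: Path
    subject_id: str
    class_label: str
    modality: Modality


@dataclass(frozen=True)
class DatasetManifest:
    """Parsed dataset manifest: graph records plus global options."""

    entries: tuple[ManifestEntry, ...]
    node_labels_path: Path
    functional_threshold: float = 0.0
    delimiter: str | None = None  # None = sniff comma/tab per file

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetManifest":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"manifest not found: {path}")
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "graphs" not in doc:
            raise ValueError(f"manifest {path} must be a mapping with a 'graphs' list")
        base = path.parent
        entries = []
        for rec in doc["graphs"]:
            try:
                entries.append(
                    ManifestEntry(
                        path=(base / rec["path"]).resolve(),
                        subject_id=str(rec["subject"]),
                        class_label=str(rec["class"]),
                        modality=Modality(rec["modality"]),
                    )
                )
            except KeyError as exc:
                raise ValueError(
                    f"manifest {path}: graph record {rec!r} missing field {exc}"
                ) from exc
        if "node_labels" not in doc:
            raise ValueError(f"manifest {path} missing 'node_labels'")
        return cls(
            entries=tuple(entries),
            node_labels_path=(base / doc["node_labels"]).resolve(),
            functional_threshold=float(doc.get("functional_threshold", 0.0)),
            delimiter=doc.get("delimiter"),
        )


def read_node_labels(path: str | Path) -> tuple[str, ...]:
    """Read one region label per line; blank lines are ignored."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"node labels file not found: {path}")
    labels = tuple(
        line.strip() for line in path.read_text().splitlines() if line.strip()
    )
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate node labels in {path}")
    return labels


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_adjacency(
    path: str | Path,
    node_labels: Sequence[str],
    modality: Modality | str,
    subject_id: str | None = None,
    delimiter: str | None = None,
) -> BrainGraph:
    """Read one square delimited adjacency matrix into a :class:`BrainGraph`.

    An optional first header row of labels is accepted and, if present, must
    equal ``node_labels`` in order.  Errors name the file and the offending
    cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"adjacency file not found: {path}")
    node_labels = tuple(str(x) for x in node_labels)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty adjacency file")
    if delimiter is None:
        delimiter = _sniff_delimiter(lines[0])

    first = [tok.strip() for tok in lines[0].split(delimiter)]

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    if not all(_is_number(tok) for tok in first):
        header = tuple(first)
        if header != node_labels:
            raise ValueError(
                f"{path}: header row {header[:5]}... does not match the "
                "expected node labels"
            )
        lines = lines[1:]

    l = len(node_labels)
    if len(lines) != l:
        raise ValueError(
            f"{path}: expected {l} matrix rows, found {len(lines)}"
        )
    rows = []
    for i, line in enumerate(lines):
        toks = [tok.strip() for tok in line.split(delimiter)]
        if len(toks) != l:
            raise ValueError(
                f"{path}: row {i} has {len(toks)} columns, expected {l} "
                "(matrix must be square)"
            )
        row = []
        for j, tok in enumerate(toks):
            try:
                row.append(float(tok))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {tok!r} at row {i}, column {j}"
                ) from None
        rows.append(row)
    weights = np.array(rows, dtype=float)
    return BrainGraph.from_matrix(
        node_labels,
        weights,
        modality,
        subject_id if subject_id is not None else path.stem,
    )


def write_adjacency(
    graph: BrainGraph, path: str | Path, delimiter: str = ",", header: bool = True
) -> None:
    """Write a full square matrix as delimited text.

    Floats are written with 17 significant digits so a read-back reproduces
    the doubles bit-faithfully.
    """
    path = Path(path)
    lines = []
    if header:
        lines.append(delimiter.join(graph.node_labels))
    for row in np.asarray(graph.weights):
        lines.append(delimiter.join(format(v, ".17g") for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_dataset(
    manifest: DatasetManifest | str | Path,
) -> tuple[LabeledGraphDataset | None, LabeledGraphDataset | None]:
    """Load a manifest into (structural, functional) labeled datasets.

    Functional graphs are thresholded at the manifest's
    ``functional_threshold`` (default 0: keep positive correlations only).
    Each present modality must contain exactly two classes with at least two
    graphs per class, and must pass FCVS validation.  A modality with no
    entries yields ``None``.
    """
    if not isinstance(manifest, DatasetManifest):
        manifest = DatasetManifest.from_yaml(manifest)
    node_labels = read_node_labels(manifest.node_labels_path)
    out: dict[Modality, LabeledGraphDataset | None] = {}
    for modality in (Modality.STRUCTURAL, Modality.FUNCTIONAL):
        entries = [e for e in manifest.entries if e.modality is modality]
        if not entries:
            out[modality] = None
            continue
        graphs, labels = [], []
        for e in entries:
            g = read_adjacency(
                e.path, node_labels, modality, e.subject_id, manifest.delimiter
            )
            if modality is Modality.FUNCTIONAL:
                g = threshold_positive(g, manifest.functional_threshold)
            graphs.append(g)
            labels.append(e.class_label)
        classes = sorted(set(labels))
        if len(classes) != 2:
            raise ValueError(
                f"{modality.value} data: two classes required, found {classes}"
            )
        for c in classes:
            if labels.count(c) < 2:
                raise ValueError(
                    f"{modality.value} data: class {c!r} has fewer than 2 graphs"
                )
        dataset = LabeledGraphDataset(tuple(graphs), tuple(labels), node_labels)
        violations = validate_fcvs(dataset)
        if violations:
            raise ValueError(
                f"{modality.value} dataset failed validation:\n  "
                + "\n  ".join(violations)
            )
        logger.info(
            "loaded %s: %s",
            modality.value,
            ", ".join(f"{labels.count(c)} x {c!r}" for c in classes),
        )
        out[modality] = dataset
    return out[Modality.STRUCTURAL], out[Modality.FUNCTIONAL]
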