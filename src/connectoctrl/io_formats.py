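"""Text-format I/O for connectivity matrices, binary graphs and analysis reports.

Node identity throughout the package is the integer ROI label of the
Brainnetome parcellation (odd IDs left hemisphere, even IDs right); the
positional index of a node inside a matrix is an internal detail and never
appears in any output.  Matrices travel as headerless delimited text with a
JSON sidecar carrying labels, modality and group; graphs as two-column TSV
edge lists; study reports as a single JSON document.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "ValidationError",
    "RoiLabelSet",
    "ConnectivityMatrix",
    "BinaryGraph",
    "DMN_LABELS_LEFT",
    "DMN_LABELS_RIGHT",
    "default_dmn_labels",
    "read_connectivity_matrix",
    "write_connectivity_matrix",
    "read_graph_edgelist",
    "write_graph_edgelist",
    "write_report",
    "read_report",
]

#: Default-mode-network ROI IDs of the Brainnetome atlas, 13 per hemisphere.
DMN_LABELS_RIGHT = (12, 14, 42, 82, 84, 136, 138, 144, 152, 154, 176, 182, 188)
DMN_LABELS_LEFT = (11, 13, 41, 81, 83, 135, 137, 143, 151, 153, 175, 181, 187)

#: Asymmetry beyond this is treated as a corrupt file, below it as rounding noise.
SYMMETRY_TOLERANCE = 1e-6


class FormatError(ValueError):
    """A file does not parse as the expected format."""


class ValidationError(ValueError):
    """Parsed data violates a structural invariant."""


@dataclass(frozen=True)
class RoiLabelSet:
    """Ordered, unique, positive-integer ROI identifiers for matrix rows.

    Hemisphere membership follows the Brainnetome convention: odd IDs are
    left-hemisphere parcels, even IDs right-hemisphere parcels.
    """

    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        labels = tuple(int(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) == 0:
            raise ValidationError("label set must be non-empty")
        if any(x <= 0 for x in labels):
            raise ValidationError("ROI labels must be positive integers")
        if len(set(labels)) != len(labels):
            raise ValidationError("ROI labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[int]:
        return iter(self.labels)

    def index_of(self, label: int) -> int:
        return self.labels.index(label)

    def hemisphere(self, label: int) -> str:
        if label not in self.labels:
            raise KeyError(f"unknown ROI label {label}")
        return "left" if label % 2 == 1 else "right"

    @property
    def hemisphere_map(self) -> dict[int, str]:
        return {x: self.hemisphere(x) for x in self.labels}


def default_dmn_labels() -> RoiLabelSet:
    """The 26 DMN ROIs of the study, in ascending label order."""
    return RoiLabelSet(tuple(sorted(DMN_LABELS_LEFT + DMN_LABELS_RIGHT)))


@dataclass(frozen=True)
class ConnectivityMatrix:
    """A labelled symmetric weighted connectivity matrix for one group x modality.

    The diagonal is a structural zero: self-connectivity carries no edge
    information and every downstream operation ignores it.  SC (structural)
    matrices are non-negative streamline-derived edge weights; FC (functional)
    matrices hold Fisher-z-transformed correlations and may be negative.
    """

    values: np.ndarray
    labels: RoiLabelSet
    modality: str  # "SC" | "FC"
    group: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise FormatError(f"connectivity matrix must be square, got {v.shape}")
        if v.shape[0] != len(self.labels):
            raise ValidationError(
                f"{len(self.labels)} labels for a {v.shape[0]}x{v.shape[0]} matrix"
            )
        if np.max(np.abs(v - v.T), initial=0.0) > 1e-10:
            raise ValidationError("matrix not symmetric within 1e-10")
        v = v.copy()
        np.fill_diagonal(v, 0.0)
        if self.modality not in ("SC", "FC"):
            raise ValidationError(f"modality must be 'SC' or 'FC', got {self.modality!r}")
        if self.modality == "SC" and np.min(v) < 0:
            raise ValidationError("SC matrix has negative off-diagonal weights")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class BinaryGraph:
    """An unweighted undirected simple graph over labelled ROIs.

    ``provenance`` records the construction method and the parameters /
    cutoff actually used, so every downstream number is auditable.
    """

    adjacency: np.ndarray
    labels: RoiLabelSet
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise FormatError(f"adjacency must be square, got {a.shape}")
        if a.shape[0] != len(self.labels):
            raise ValidationError("label count does not match adjacency dimension")
        if not np.isin(a, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0/1")
        a = a.astype(np.int8)
        if (a != a.T).any():
            raise ValidationError("adjacency must be symmetric")
        if np.diagonal(a).any():
            raise ValidationError("self-loops are not allowed")
        a.setflags(write=False)
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "provenance", dict(self.provenance))

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> list[tuple[int, int]]:
        """Edges as sorted (label_i, label_j) pairs with label_i < label_j."""
        lab = self.labels.labels
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        pairs = [tuple(sorted((lab[i], lab[j]))) for i, j in zip(ii, jj)]
        return sorted(pairs)

    def degree(self) -> dict[int, int]:
        return {
            lab: int(d) for lab, d in zip(self.labels.labels, self.adjacency.sum(axis=0))
        }

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.labels.labels)
        g.add_edges_from(self.edges())
        return g


# ---------------------------------------------------------------------------
# connectivity matrices
# ---------------------------------------------------------------------------

def _sniff_delimiter(first_line: str) -> str:
    if "," in first_line:
        return ","
    if "\t" in first_line:
        return "\t"
    return " "


def read_connectivity_matrix(path, labels_path) -> ConnectivityMatrix:
    """Read an N x N delimited-text matrix plus its JSON sidecar.

    Asymmetry within ``SYMMETRY_TOLERANCE`` (export rounding noise) is
    repaired by averaging (M + M.T)/2; anything beyond it is rejected.  The
    diagonal is zeroed on read.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delim = _sniff_delimiter(first)
    try:
        m = np.loadtxt(path, delimiter=None if delim == " " else delim, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: not a rectangular numeric matrix ({exc})") from exc
    if m.shape[0] != m.shape[1]:
        raise FormatError(f"{path}: matrix is {m.shape[0]}x{m.shape[1]}, not square")
    asym = float(np.max(np.abs(m - m.T), initial=0.0))
    if asym > SYMMETRY_TOLERANCE:
        raise ValidationError(
            f"{path}: asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOLERANCE:g}"
        )
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)

    with open(labels_path) as fh:
        meta = json.load(fh)
    for key in ("labels", "modality", "group"):
        if key not in meta:
            raise FormatError(f"{labels_path}: sidecar missing key {key!r}")
    labels = RoiLabelSet(tuple(meta["labels"]))
    if len(labels) != m.shape[0]:
        raise ValidationError(
            f"{labels_path}: {len(labels)} labels for a {m.shape[0]}-node matrix"
        )
    return ConnectivityMatrix(m, labels, meta["modality"], meta["group"])


def write_connectivity_matrix(matrix: ConnectivityMatrix, path, labels_path) -> None:
    """Write a matrix as comma-delimited text plus a JSON sidecar (round-trips)."""
    np.savetxt(path, matrix.values, delimiter=",", fmt="%.17g")
    sidecar = {
        "labels": list(matrix.labels.labels),
        "modality": matrix.modality,
        "group": matrix.group,
    }
    with open(labels_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# binary graphs
# ---------------------------------------------------------------------------

def write_graph_edgelist(graph: BinaryGraph, path) -> None:
    """One line per edge, ``label_i<TAB>label_j`` with label_i < label_j, sorted."""
    with open(path, "w") as fh:
        for i, j in graph.edges():
            fh.write(f"{i}\t{j}\n")


def read_graph_edgelist(path, labels: RoiLabelSet) -> BinaryGraph:
    """Read an edge list back over a known label set."""
    n = len(labels)
    idx = {lab: k for k, lab in enumerate(labels.labels)}
    a = np.zeros((n, n), dtype=np.int8)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated labels")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer label") from exc
            if u not in idx or v not in idx:
                raise ValidationError(f"{path}:{lineno}: unknown ROI label in edge {u}-{v}")
            a[idx[u], idx[v]] = 1
            a[idx[v], idx[u]] = 1
    return BinaryGraph(a, labels, {"method": "edgelist", "path": str(path)})


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _round_floats(obj, sig: int = 12):
    """Recursively round floats to `sig` significant digits for stable JSON."""
    if isinstance(obj, float):
        if not math.isfinite(obj):
            return obj
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), sig)
    return obj


def write_report(reports: Mapping[str, Mapping] | Iterable, path) -> None:
    """Serialize a report collection to one JSON document.

    ``reports`` is either a mapping of "group/modality" (or any string key)
    to plain dictionaries, or an iterable of objects exposing ``to_dict()``
    and ``key()``.  Numbers are written with 12 significant digits and keys
    sorted, so identical analyses yield byte-identical files.
    """
    if not isinstance(reports, Mapping):
        reports = {r.key(): r.to_dict() for r in reports}
    payload = _round_floats({str(k): dict(v) for k, v in reports.items()})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
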