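"""Graph construction: four schemes turning weighted connectivity into a binary graph.

* percentage (proportional) thresholding — remove the weakest fixed fraction
  of present connections; the cutoff may be derived from a reference
  (control-group) matrix and then applied to patient matrices, which is the
  study's default comparison convention.
* adaptive thresholding (ATH) — the largest cutoff, found by bisection to an
  absolute error below 1e-4, at which the graph is still connected.
* partial correlation (PCM) — invert the correlation matrix, normalize the
  precision to partial correlations, keep |rho| above a soft threshold.
* Chow-Liu tree (CLA) — the maximum-weight spanning tree; always N - 1 edges.

All schemes threshold on magnitudes |w_ij|: functional matrices carry
negative correlations and magnitude thresholding is the usual connectomics
convention (signed thresholding is available via ``signed=True`` where it
makes sense).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .io_formats import BinaryGraph, ConnectivityMatrix

__all__ = [
    "ThresholdSpec",
    "DisconnectedGraphError",
    "NotPositiveDefiniteError",
    "percentage_threshold",
    "adaptive_threshold",
    "partial_correlation_graph",
    "chow_liu_tree",
]

log = logging.getLogger(__name__)

#: canonical study fractions for the lowest-percentage threshold sweep
STUDY_FRACTIONS = (0.025, 0.05, 0.10, 0.20, 0.30)


class DisconnectedGraphError(ValueError):
    """An operation that presupposes a connected graph received a disconnected one."""


class NotPositiveDefiniteError(ValueError):
    """The correlation matrix to invert is not positive definite."""


@dataclass(frozen=True)
class ThresholdSpec:
    """Parameters of a graph-construction scheme.

    ``fraction`` applies to the percentage method only; ``reference`` is the
    matrix the cutoff is computed from (control group in the study design);
    ``soft_threshold`` applies to PCM; ``tolerance`` is the ATH bisection
    accuracy on the cutoff value.
    """

    method: str = "percentage"  # percentage | adaptive | pcm | chowliu | zero
    fraction: float = 0.0
    reference: Optional[ConnectivityMatrix] = None
    soft_threshold: float = 0.1
    tolerance: float = 1e-4
    signed: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("percentage", "adaptive", "pcm", "chowliu", "zero"):
            raise ValueError(f"unknown construction method {self.method!r}")
        if not (0.0 <= self.fraction < 1.0):
            raise ValueError("fraction must lie in [0, 1)")
        if self.soft_threshold < 0:
            raise ValueError("soft_threshold must be >= 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


def _magnitudes(matrix: ConnectivityMatrix, signed: bool) -> np.ndarray:
    w = matrix.values
    return w.copy() if signed else np.abs(w)


def _upper_offdiag(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(values, k=1)
    return values[iu]


def _graph_at_cutoff(matrix: ConnectivityMatrix, cutoff: float,
                     signed: bool, provenance: dict) -> BinaryGraph:
    w = _magnitudes(matrix, signed)
    a = (w > cutoff).astype(np.int8)
    np.fill_diagonal(a, 0)
    return BinaryGraph(a, matrix.labels, provenance)


def _n_components(adjacency: np.ndarray) -> int:
    if adjacency.shape[0] == 0:
        return 0
    n, _ = connected_components(csr_matrix(adjacency), directed=False)
    return int(n)


def percentage_threshold(matrix: ConnectivityMatrix,
                         spec: ThresholdSpec) -> BinaryGraph:
    """Remove the weakest ``fraction`` of present connections.

    The cutoff is the largest magnitude among the removed fraction of the
    *reference* matrix (the matrix itself when no reference is set): with m
    strictly positive off-diagonal magnitudes sorted ascending, the cutoff is
    the value at rank ceil(fraction * m).  An edge survives iff its own
    magnitude strictly exceeds the cutoff, so ties at the cutoff are removed.
    ``fraction = 0`` is the zero-threshold method (keep every non-zero
    connection).
    """
    if spec.reference is not None:
        ref = spec.reference
        if ref.labels.labels != matrix.labels.labels:
            raise ValueError("reference matrix has different ROI labels")
        if ref.modality != matrix.modality:
            raise ValueError("reference matrix has different modality")
    else:
        ref = matrix
    vals = _upper_offdiag(np.abs(ref.values))
    vals = np.sort(vals[vals > 0])
    k = math.ceil(spec.fraction * len(vals))
    cutoff = float(vals[k - 1]) if k >= 1 else 0.0
    prov = {
        "method": "percentage",
        "fraction": spec.fraction,
        "cutoff": cutoff,
        "reference_group": ref.group if spec.reference is not None else None,
        "signed": spec.signed,
    }
    graph = _graph_at_cutoff(matrix, cutoff, spec.signed, prov)
    if graph.n_edges == 0:
        log.warning(
            "percentage threshold fraction=%.3g removed every edge of %s/%s",
            spec.fraction, matrix.group, matrix.modality,
        )
    return graph


def adaptive_threshold(matrix: ConnectivityMatrix,
                       spec: ThresholdSpec | None = None
                       ) -> tuple[BinaryGraph, float]:
    """Largest cutoff keeping the graph connected, by bisection.

    Bisects t over [0, max|w|]; the graph at t has edges where |w| > t.
    Returns the largest t* within the spec tolerance (absolute, default
    1e-4) such that the graph is still connected, together with that graph.
    Raising the returned cutoff by twice the tolerance disconnects the graph.
    """
    spec = spec or ThresholdSpec(method="adaptive")
    w = np.abs(matrix.values)
    lo = 0.0
    a0 = (w > lo).astype(np.int8)
    np.fill_diagonal(a0, 0)
    if _n_components(a0) != 1:
        raise DisconnectedGraphError(
            "adaptive threshold undefined on disconnected input "
            f"({matrix.group}/{matrix.modality})"
        )
    hi = float(w.max())
    # graph at hi is empty (strict inequality), hence disconnected for N >= 2
    while hi - lo > spec.tolerance:
        mid = 0.5 * (lo + hi)
        a = (w > mid).astype(np.int8)
        np.fill_diagonal(a, 0)
        if _n_components(a) == 1:
            lo = mid
        else:
            hi = mid
    prov = {"method": "adaptive", "cutoff": lo, "tolerance": spec.tolerance}
    return _graph_at_cutoff(matrix, lo, signed=False, provenance=prov), lo


def partial_correlation_graph(matrix: ConnectivityMatrix,
                              spec: ThresholdSpec | None = None) -> BinaryGraph:
    """Partial-correlation graph from a functional connectivity matrix.

    The stored Fisher-z values are mapped back to correlations (tanh), the
    unit diagonal restored, and the precision P = R^-1 normalized to partial
    correlations rho_ij = -P_ij / sqrt(P_ii P_jj).  An edge survives iff
    |rho_ij| strictly exceeds the soft threshold.

    Raises :class:`NotPositiveDefiniteError` (naming the offending
    eigenvalue) when R is not invertible as a correlation matrix; ridge
    regularization is suggested in the message but never applied silently.
    """
    spec = spec or ThresholdSpec(method="pcm")
    if matrix.modality != "FC":
        raise ValueError("partial correlation requires an FC matrix")
    r = np.tanh(matrix.values)
    np.fill_diagonal(r, 1.0)
    smallest = float(np.linalg.eigvalsh(r)[0])
    if smallest <= 1e-10:
        raise NotPositiveDefiniteError(
            f"correlation matrix is not positive definite (smallest eigenvalue "
            f"{smallest:.3g}); consider ridge regularization of the input"
        )
    p = np.linalg.inv(r)
    d = np.sqrt(np.diag(p))
    rho = -p / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    a = (np.abs(rho) > spec.soft_threshold).astype(np.int8)
    prov = {"method": "pcm", "soft_threshold": spec.soft_threshold}
    return BinaryGraph(a, matrix.labels, prov)


def chow_liu_tree(matrix: ConnectivityMatrix) -> BinaryGraph:
    """Maximum-weight spanning tree over edge magnitudes (Chow-Liu algorithm).

    Kruskal on descending |w_ij| with ties broken by ascending
    (label_i, label_j), which makes the tree canonical.  The output has
    exactly N - 1 edges and is connected; a disconnected input is refused
    rather than silently returned as a forest (a forest would report
    spurious dependencies).
    """
    w = np.abs(matrix.values)
    n = matrix.n_nodes
    mask = (w > 0).astype(np.int8)
    np.fill_diagonal(mask, 0)
    if _n_components(mask) != 1:
        raise DisconnectedGraphError(
            "Chow-Liu tree undefined on a disconnected connectivity graph"
        )
    labels = matrix.labels.labels
    iu, ju = np.triu_indices(n, k=1)
    edges = [
        (float(w[i, j]), labels[i], labels[j], i, j)
        for i, j in zip(iu, ju)
        if w[i, j] > 0
    ]
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    a = np.zeros((n, n), dtype=np.int8)
    taken = 0
    for _, _, _, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            a[i, j] = a[j, i] = 1
            taken += 1
            if taken == n - 1:
                break
    prov = {"method": "chowliu"}
    return BinaryGraph(a, matrix.labels, prov)
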