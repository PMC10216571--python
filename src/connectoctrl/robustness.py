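"""Spectral robustness measures for binarized connectomes.

Two eigenvalue-based summaries of how well a network resists random
failures or targeted attack:

* algebraic connectivity  a(G) = lambda_2(L), the second-smallest Laplacian
  eigenvalue (Fiedler value); zero exactly when the graph is disconnected.
* natural connectivity    ln( (1/N) * sum_i exp(lambda_i) ) over adjacency
  eigenvalues; strictly monotone under edge addition/removal, minimal (0)
  on the empty graph and maximal on the complete graph at fixed N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .controllability import laplacian
from .io_formats import BinaryGraph

__all__ = [
    "RobustnessReport",
    "algebraic_connectivity",
    "natural_connectivity",
    "robustness_report",
]


@dataclass(frozen=True)
class RobustnessReport:
    algebraic: float
    natural: float
    n_nodes: int
    n_edges: int
    method_provenance: dict

    def to_dict(self) -> dict:
        return {
            "algebraic_connectivity": self.algebraic,
            "natural_connectivity": self.natural,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "provenance": dict(self.method_provenance),
        }


def _adjacency(graph) -> np.ndarray:
    if isinstance(graph, BinaryGraph):
        return np.asarray(graph.adjacency, dtype=float)
    a = np.asarray(graph, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    return a


def algebraic_connectivity(graph) -> float:
    """Second-smallest Laplacian eigenvalue of the (binary) graph.

    No connectivity pre-check is performed: a disconnected graph scoring 0
    is the signal, not an error.
    """
    a = _adjacency(graph)
    if a.shape[0] < 2:
        raise ValueError("algebraic connectivity needs at least 2 nodes")
    w = np.linalg.eigvalsh(laplacian(a))
    return float(w[1])


def natural_connectivity(graph) -> float:
    """ln of the average exponentiated adjacency eigenvalue (log-sum-exp)."""
    a = _adjacency(graph)
    n = a.shape[0]
    if n < 1:
        raise ValueError("natural connectivity needs at least 1 node")
    w = np.linalg.eigvalsh(a)
    return float(logsumexp(w) - np.log(n))


def robustness_report(graph: BinaryGraph) -> RobustnessReport:
    """Both measures plus graph provenance, ready for the group report."""
    return RobustnessReport(
        algebraic=algebraic_connectivity(graph),
        natural=natural_connectivity(graph),
        n_nodes=graph.n_nodes,
        n_edges=graph.n_edges,
        method_provenance=dict(graph.provenance),
    )
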