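"""Exact controllability of undirected binary networks.

The network state follows the noise-free linear discrete-time model

    x(t+1) = A x(t) + B_K u_K(t)

with A the symmetric 0/1 adjacency matrix and B_K a unit-column input matrix
selecting the driver nodes K.  For an undirected network the minimum number
of drivers equals the maximum geometric multiplicity over the eigenvalues of
A (which, A being symmetric, equals the algebraic multiplicity), and a
concrete driver set is read off the column canonical form of M = lambda_M I - A
for the eigenvalue lambda_M of maximum multiplicity: the rows of M that are
linearly dependent on the others index the nodes that must receive input.

Worked anchors used throughout the tests: on N = 26 nodes a chain needs 1
driver, a star 24, and the complete graph 25.

A subtlety the implementation handles explicitly: the max-multiplicity count
is the controllability statistic, but a driver set derived from lambda_M
alone is not always sufficient when another eigenvalue's eigenspace is
entirely unsupported on the chosen nodes (this can happen for graphs with
several spectral components, e.g. a triangle plus an isolated node).
``identify_drivers`` therefore verifies the Popov-Belevitch-Hautus (PBH)
rank condition over every eigenvalue class and augments the set minimally
when required, flagging the result.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import BinaryGraph, RoiLabelSet

__all__ = [
    "EigenClass",
    "DriverResult",
    "CriticalNodeResult",
    "eigen_multiplicities",
    "driver_count",
    "identify_drivers",
    "is_controllable",
    "critical_nodes",
    "laplacian",
]


@dataclass(frozen=True)
class EigenClass:
    """A cluster of numerically coincident eigenvalues."""

    value: float
    multiplicity: int


@dataclass(frozen=True)
class DriverResult:
    """Minimum driver count plus one concrete, canonical driver-node set.

    ``count`` is the exact-controllability minimum (max eigenvalue
    multiplicity).  ``drivers`` always passes the PBH test; it coincides with
    ``count`` nodes except in degenerate spectra, where ``augmented`` is set
    and the extra nodes are the price of actual controllability with
    unit-column inputs.
    """

    count: int
    drivers: tuple[int, ...]
    eigenvalue_used: float
    multiplicity: int
    augmented: bool = False

    def to_dict(self) -> dict:
        return {
            "count": self.count,
            "drivers": sorted(self.drivers),
            "eigenvalue_used": self.eigenvalue_used,
            "multiplicity": self.multiplicity,
            "augmented": self.augmented,
        }


@dataclass(frozen=True)
class CriticalNodeResult:
    """Nodes whose removal strictly increases the minimum driver count."""

    critical: tuple[int, ...]
    detail: dict[int, tuple[int, int]]  # label -> (count_before, count_after)

    def to_dict(self) -> dict:
        return {
            "critical": sorted(self.critical),
            "detail": {str(k): list(v) for k, v in sorted(self.detail.items())},
        }


def _as_adjacency(A) -> np.ndarray:
    if isinstance(A, BinaryGraph):
        return np.asarray(A.adjacency, dtype=float)
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    return A


def _default_tol(eigenvalues: np.ndarray) -> float:
    n = len(eigenvalues)
    scale = float(np.max(np.abs(eigenvalues), initial=0.0))
    return max(n * np.finfo(float).eps * scale, 1e-9)


def eigen_multiplicities(A, tol: float | None = None) -> list[EigenClass]:
    """Cluster the spectrum of a symmetric matrix into coincidence classes.

    Eigenvalues whose neighbours in the sorted spectrum differ by at most
    ``tol`` are merged into one class represented by the class mean.  The
    default tolerance is scale-aware, N*eps*max|lambda| with a 1e-9 floor.
    """
    A = _as_adjacency(A)
    w = np.linalg.eigvalsh(A)
    if tol is None:
        tol = _default_tol(w)
    classes: list[EigenClass] = []
    start = 0
    for i in range(1, len(w) + 1):
        if i == len(w) or w[i] - w[i - 1] > tol:
            block = w[start:i]
            classes.append(EigenClass(float(block.mean()), len(block)))
            start = i
    return classes


def driver_count(A, tol: float | None = None) -> int:
    """Minimum number of driver nodes: the maximum eigenvalue multiplicity."""
    classes = eigen_multiplicities(A, tol)
    return max(c.multiplicity for c in classes)


def _dependent_rows(M: np.ndarray, tol: float) -> list[int]:
    """Indices of rows of symmetric M linearly dependent on earlier rows.

    Rows are processed in ascending index (ROI-label) order; elimination uses
    partial pivoting on magnitude, first index winning ties, which fixes a
    canonical choice among the generally non-unique dependent sets.
    """
    n = M.shape[0]
    pivots: list[tuple[int, np.ndarray]] = []
    used = np.zeros(n, dtype=bool)
    dependent: list[int] = []
    for j in range(n):
        w = M[j].astype(float).copy()
        for pos, vec in pivots:
            w -= w[pos] * vec
        mag = np.abs(w)
        mag[used] = 0.0
        p = int(np.argmax(mag))
        if mag[p] > tol:
            pivots.append((p, w / w[p]))
            used[p] = True
        else:
            dependent.append(j)
    return dependent


def _eigvec_classes(A: np.ndarray, tol: float | None):
    """Eigen-decomposition grouped into (class value, eigenvector block)."""
    w, U = np.linalg.eigh(A)
    if tol is None:
        tol = _default_tol(w)
    out = []
    start = 0
    for i in range(1, len(w) + 1):
        if i == len(w) or w[i] - w[i - 1] > tol:
            out.append((float(w[start:i].mean()), U[:, start:i]))
            start = i
    return out


def _pbh_ok(classes, support: Sequence[int]) -> bool:
    """PBH over all eigenvalue classes with unit input columns on `support`.

    rank([lambda I - A, B]) = N for symmetric A reduces to: the rows of each
    eigenvector block indexed by the driver nodes have full column rank.
    """
    s = list(support)
    if not s:
        return False
    for _, V in classes:
        sub = V[s, :]
        if np.linalg.matrix_rank(sub, tol=1e-8) < V.shape[1]:
            return False
    return True


def _residual_gain(row: np.ndarray, basis: list[np.ndarray]) -> float:
    """Norm of `row` after projecting out an orthonormal basis."""
    r = row.astype(float).copy()
    for b in basis:
        r -= (r @ b) * b
    return float(np.linalg.norm(r))


def _greedy_joint_set(classes, n: int, m: int, primary_idx: int) -> list[int] | None:
    """Try to pick m nodes jointly covering every eigenspace.

    Each chosen node must increase the covered rank of the maximum-
    multiplicity class; among such candidates the one raising coverage in
    the most still-deficient classes wins, lowest index breaking ties.
    """
    bases: list[list[np.ndarray]] = [[] for _ in classes]
    chosen: list[int] = []
    for _ in range(m):
        best = None
        for v in range(n):
            if v in chosen:
                continue
            gain_primary = _residual_gain(classes[primary_idx][1][v], bases[primary_idx])
            if gain_primary <= 1e-8:
                continue
            score = sum(
                1
                for ci, (_, V) in enumerate(classes)
                if len(bases[ci]) < V.shape[1]
                and _residual_gain(V[v], bases[ci]) > 1e-8
            )
            if best is None or score > best[0]:
                best = (score, v)
        if best is None:
            return None
        v = best[1]
        chosen.append(v)
        for ci, (_, V) in enumerate(classes):
            r = V[v].astype(float).copy()
            for b in bases[ci]:
                r -= (r @ b) * b
            nrm = np.linalg.norm(r)
            if nrm > 1e-8:
                bases[ci].append(r / nrm)
    return chosen


#: exhaustive-search budget (number of candidate subsets) for degenerate spectra
_EXHAUSTIVE_BUDGET = 20000


def _resolve_driver_set(classes, n: int, mult: int, canonical: list[int]) -> list[int]:
    """Driver set for degenerate spectra where the canonical CCF set fails PBH.

    The minimum driver count (max multiplicity) is always achievable with a
    dense input matrix, but with one unit input column per driver node a
    lambda_M-derived set can leave another eigenspace uncovered.  Search
    order: a same-size set by greedy joint coverage of all eigenspaces, then
    bounded exhaustive search by increasing size (globally minimal when it
    runs), then greedy augmentation of the canonical set as a last resort.
    Any support of size < mult fails PBH outright (the lambda_M block cannot
    reach full column rank), so a returned set of size mult is minimal.
    """
    primary_idx = max(
        range(len(classes)),
        key=lambda i: (classes[i][1].shape[1], -classes[i][0]),
    )
    greedy = _greedy_joint_set(classes, n, mult, primary_idx)
    if greedy is not None and _pbh_ok(classes, greedy):
        return sorted(greedy)
    for k in range(mult, n + 1):
        if math.comb(n, k) > _EXHAUSTIVE_BUDGET:
            break
        for cand in itertools.combinations(range(n), k):
            if _pbh_ok(classes, cand):
                return list(cand)
    # large-n fallback: grow the canonical set until every eigenspace is covered
    support = list(canonical)
    guard = 0
    while not _pbh_ok(classes, support):
        for _, V in classes:
            sub = V[support, :]
            if np.linalg.matrix_rank(sub, tol=1e-8) < V.shape[1]:
                _, _, vt = np.linalg.svd(sub)
                x = np.abs(V @ vt[-1])
                x[support] = 0.0
                support.append(int(np.argmax(x)))
                break
        guard += 1
        if guard > n:
            raise ArithmeticError("PBH augmentation failed to converge")
    for node in sorted(support[len(canonical):], reverse=True):
        trial = [s for s in support if s != node]
        if _pbh_ok(classes, trial):
            support = trial
    return sorted(support)


def identify_drivers(
    A, labels: RoiLabelSet | None = None, tol: float | None = None
) -> DriverResult:
    """Canonical minimum driver set by the column-canonical-form rule.

    Let lambda_M be the eigenvalue class of maximum multiplicity (smallest
    value on ties).  The rows of M = lambda_M I - A without a pivot under
    ascending-label elimination with magnitude pivoting are the drivers;
    their number equals the multiplicity of lambda_M.  The set is then
    checked against the PBH criterion for *all* eigenvalue classes and, in
    the rare degenerate case that another eigenspace is unsupported on it,
    augmented with the fewest additional nodes that restore controllability
    (``augmented=True`` on the result).
    """
    if isinstance(A, BinaryGraph) and labels is None:
        labels = A.labels
    Am = _as_adjacency(A)
    n = Am.shape[0]
    classes = _eigvec_classes(Am, tol)
    lam, mult = max(
        ((v, V.shape[1]) for v, V in classes), key=lambda c: (c[1], -c[0])
    )
    M = lam * np.eye(n) - Am
    scale = max(1.0, float(np.max(np.abs(M))))
    dep = _dependent_rows(M, tol=1e-8 * n * scale)
    if len(dep) != mult:
        # fall back to a rank-revealing threshold consistent with the known rank
        for f in (1e-6, 1e-10, 1e-12):
            dep = _dependent_rows(M, tol=f * n * scale)
            if len(dep) == mult:
                break
    if len(dep) != mult:
        raise ArithmeticError(
            f"CCF row elimination found {len(dep)} dependent rows, "
            f"expected multiplicity {mult}"
        )

    support = list(dep)
    augmented = False
    if not _pbh_ok(classes, support):
        support = _resolve_driver_set(classes, n, mult, dep)
        augmented = len(support) > mult

    if labels is not None:
        drivers = tuple(sorted(labels.labels[i] for i in support))
    else:
        drivers = tuple(sorted(support))
    return DriverResult(
        count=mult,
        drivers=drivers,
        eigenvalue_used=lam,
        multiplicity=mult,
        augmented=augmented,
    )


def is_controllable(A, drivers, labels: RoiLabelSet | None = None,
                    tol: float | None = None) -> bool:
    """PBH rank test for the unit-column input matrix built from `drivers`.

    ``drivers`` are ROI labels when ``labels`` is given (or when A is a
    BinaryGraph), positional indices otherwise.  Used as the verification
    oracle in tests; the main pipeline never integrates the dynamics.
    """
    if isinstance(A, BinaryGraph) and labels is None:
        labels = A.labels
    Am = _as_adjacency(A)
    if labels is not None:
        support = [labels.index_of(int(d)) for d in drivers]
    else:
        support = [int(d) for d in drivers]
    if not support:
        return False
    classes = _eigvec_classes(Am, tol)
    return _pbh_ok(classes, support)


def critical_nodes(A, labels: RoiLabelSet | None = None,
                   tol: float | None = None) -> CriticalNodeResult:
    """Remove each node in turn and recount drivers.

    A node is critical iff the driver count of the reduced graph strictly
    exceeds that of the original graph (the comparison is against the
    original count even though N shrinks by one).  Node removal deletes the
    incident edges; nodes isolated by the removal remain in the graph.
    """
    if isinstance(A, BinaryGraph) and labels is None:
        labels = A.labels
    Am = _as_adjacency(A)
    n = Am.shape[0]
    if n < 2:
        raise ValueError("critical-node analysis needs at least 2 nodes")
    names = labels.labels if labels is not None else tuple(range(n))
    before = driver_count(Am, tol)
    detail: dict[int, tuple[int, int]] = {}
    crit: list[int] = []
    for v in range(n):
        keep = [i for i in range(n) if i != v]
        after = driver_count(Am[np.ix_(keep, keep)], tol)
        detail[names[v]] = (before, after)
        if after > before:
            crit.append(names[v])
    return CriticalNodeResult(tuple(sorted(crit)), detail)


def laplacian(graph: BinaryGraph | np.ndarray) -> np.ndarray:
    """Graph Laplacian L = D - A: l_ij = -1 on edges, degree on the diagonal.

    Rows sum to zero; L is symmetric positive semi-definite with smallest
    eigenvalue 0.
    """
    A = _as_adjacency(graph)
    return np.diag(A.sum(axis=0)) - A
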