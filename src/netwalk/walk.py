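"""Data-biased random walk with restart and its stationary distribution.

The walker moves from node i to a downstream neighbor j with probability
proportional to j's data value, ``p_ij = w_j / sum_{k in N_i} w_k``, and with
probability ``q`` per step restarts at a node drawn from the restart
distribution (either uniform, or biased proportionally to the data).  The
stationary visitation frequency ``g`` solves the fixed point

    g = (1 - q) * g P + q * r

and is found by power iteration from the uniform start.  A background run
with all data values set to 1 gives ``g_r``, the purely topological
visitation; the ratio ``g' = g / g_r`` corrects node relevance for hubness.

Dangling nodes (no downstream neighbors) jump uniformly to any of the n
nodes.  Their rows are kept out of the sparse matrix and applied as a
rank-one correction, so sparsity is preserved at scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph_model import DataVector, InteractionNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of the random walk with restart.

    q : per-step restart probability (default 0.01)
    bias_restart : restart at node i with probability proportional to w_i
        (True) or uniformly (False)
    tol : L1 convergence tolerance of the power iteration
    max_iter : iteration cap
    seed : seed for any randomized auxiliary procedure; the solver itself
        is deterministic
    """

    q: float = 0.01
    bias_restart: bool = True
    tol: float = 1e-12
    max_iter: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"restart probability q must be in [0, 1], got {self.q}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition matrix in sparse form.

    ``matrix`` holds only the real arcs; rows of dangling nodes are all-zero
    there and are completed implicitly by ``dangling`` (uniform 1/n over all
    nodes).  ``dense()`` materializes the full stochastic matrix for small
    problems and test oracles.
    """

    matrix: sp.csr_matrix
    dangling: np.ndarray  # boolean mask of dangling rows
    nodes: tuple

    @property
    def n(self) -> int:
        return len(self.nodes)

    def dense(self) -> np.ndarray:
        full = self.matrix.toarray()
        full[self.dangling, :] = 1.0 / self.n
        return full

    def row_sums(self) -> np.ndarray:
        s = np.asarray(self.matrix.sum(axis=1)).ravel()
        s[self.dangling] += 1.0
        return s

    def propagate(self, g: np.ndarray) -> np.ndarray:
        """Return g P including the dangling rank-one correction."""
        out = g @ self.matrix
        mass = g[self.dangling].sum()
        if mass:
            out = out + mass / self.n
        return out


def align_data(net: InteractionNetwork, w: DataVector | np.ndarray | None) -> np.ndarray:
    """Data values in node order; genes absent from the vector count as 1."""
    if w is None:
        return np.ones(net.n)
    if isinstance(w, DataVector):
        arr = w.to_array(net, fill=1.0)
    else:
        arr = np.asarray(w, dtype=float)
        if arr.shape != (net.n,):
            raise ValueError(f"data array has shape {arr.shape}, expected ({net.n},)")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("all data values must be positive and finite")
    return arr


def build_transition_matrix(net: InteractionNetwork, w: DataVector | np.ndarray | None) -> TransitionMatrix:
    """Build the data-biased row-stochastic matrix P.

    For node i with downstream neighbors N_i, ``p_ij = w_j / sum_{k in N_i} w_k``;
    a node without downstream neighbors transitions uniformly to all n nodes
    (kept implicit, see TransitionMatrix).  Parallel arcs of different
    interaction types between the same node pair collapse to a single
    transition (the walker sees the adjacency, not the type multiplicity).
    """
    if net.n == 0:
        raise ValueError("cannot build a transition matrix for an empty network")
    warr = align_data(net, w)
    rows, cols = [], []
    seen = set()
    for i, j, _e in net.arcs():
        if (i, j) in seen:
            continue
        seen.add((i, j))
        rows.append(i)
        cols.append(j)
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    vals = warr[cols]
    m = sp.csr_matrix((vals, (rows, cols)), shape=(net.n, net.n))
    out_sum = np.asarray(m.sum(axis=1)).ravel()
    dangling = out_sum == 0
    inv = np.ones_like(out_sum)
    inv[~dangling] = 1.0 / out_sum[~dangling]
    m = sp.diags(inv) @ m
    return TransitionMatrix(matrix=m.tocsr(), dangling=dangling, nodes=net.nodes)


def restart_vector(
    w: DataVector | np.ndarray | None, config: WalkConfig, net: InteractionNetwork
) -> np.ndarray:
    """Restart distribution: r_i proportional to w_i if biased, else uniform."""
    if not config.bias_restart:
        return np.full(net.n, 1.0 / net.n)
    warr = align_data(net, w)
    return warr / warr.sum()


def stationary_distribution(
    P: TransitionMatrix, r: np.ndarray, config: WalkConfig
) -> tuple[np.ndarray, int, bool]:
    """Power-iterate g <- (1-q) g P + q r from the uniform start.

    Returns (g, iterations, converged).  For q > 0 and r > 0 everywhere the
    fixed point is unique; with q = 0 on a periodic or disconnected graph the
    limit may depend on the start, which is warned about.
    """
    n = P.n
    q = config.q
    r = np.asarray(r, dtype=float)
    if r.shape != (n,):
        raise ValueError("restart vector misaligned with transition matrix")
    if abs(r.sum() - 1.0) > 1e-9:
        raise ValueError("restart vector must sum to 1")
    if q == 0.0:
        n_comp = sp.csgraph.connected_components(P.matrix, directed=True, connection="strong")[0]
        if n_comp > 1:
            warnings.warn(
                "q = 0 on a graph that is not strongly connected: the stationary "
                "distribution may not be unique",
                stacklevel=2,
            )
    g = np.full(n, 1.0 / n)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        g_new = (1.0 - q) * P.propagate(g) + q * r
        delta = np.abs(g_new - g).sum()
        g = g_new
        if delta < config.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"power iteration did not converge in {config.max_iter} iterations "
            f"(last L1 change {delta:.3e})",
            stacklevel=2,
        )
    # guard against drift in long runs; a stochastic update conserves mass
    g = g / g.sum()
    return g, it, converged


@dataclass(frozen=True)
class VisitationResult:
    """Foreground, background, and relative visitation frequencies per node."""

    nodes: tuple
    g: np.ndarray
    g_r: np.ndarray
    g_rel: np.ndarray
    iterations: int
    converged: bool

    def as_dict(self, which: str = "g_rel") -> dict:
        return dict(zip(self.nodes, getattr(self, which)))


def run_walk(
    net: InteractionNetwork, w: DataVector | np.ndarray | None, config: WalkConfig
) -> VisitationResult:
    """Run the data-biased walk and the all-ones background walk.

    The background uses the same q and the same code path with w = 1
    everywhere (a biased restart over uniform data is the uniform restart),
    so uniform input data yields g identical to g_r and g_rel identically 1.
    """
    warr = align_data(net, w)
    P = build_transition_matrix(net, warr)
    r = restart_vector(warr, config, net)
    g, it, conv = stationary_distribution(P, r, config)

    ones = np.ones(net.n)
    P_r = build_transition_matrix(net, ones)
    r_r = restart_vector(ones, config, net)
    g_r, it_r, conv_r = stationary_distribution(P_r, r_r, config)

    with np.errstate(divide="ignore", invalid="ignore"):
        g_rel = np.where(g_r > 0, g / g_r, np.nan)
    return VisitationResult(
        nodes=net.nodes,
        g=g,
        g_r=g_r,
        g_rel=g_rel,
        iterations=max(it, it_r),
        converged=conv and conv_r,
    )


def solve_stationary_dense(P: TransitionMatrix, r: np.ndarray, q: float) -> np.ndarray:
    """Direct dense solve of g (I - (1-q) P) = q r; small-problem reference.

    Intended for cross-checks against the power iteration; requires q > 0
    so the linear system is nonsingular.
    """
    if q <= 0:
        raise ValueError("direct solve requires q > 0")
    n = P.n
    A = np.eye(n) - (1.0 - q) * P.dense()
    g = np.linalg.solve(A.T, q * np.asarray(r, dtype=float))
    return g / g.sum()
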