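"""Linear solvers for tree-structured sparse systems.

The transport discretization produces a system whose sparsity graph is the
node tree itself, so it can be solved exactly in O(N) by leaf-to-root
elimination followed by root-to-leaf substitution -- a generalized Thomas
algorithm. That direct tree solver is the default. A BiCGSTAB path (with
the previous solution as the initial iterate) and a scipy sparse-LU path
are provided for cross-checking and for matrices that are not trees.

The system is stored in ``(diag, lower, upper)`` form indexed by node:
``lower[i] = A[parent(i), i]`` and ``upper[i] = A[i, parent(i)]``; node
indices must be in topological order (parents before children).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def _solve_tree_kernel(parent, diag, lower, upper, rhs):
    n = diag.shape[0]
    d = diag.copy()
    b = rhs.copy()
    for i in range(n - 1, 0, -1):
        p = parent[i]
        if p >= 0:
            f = lower[i] / d[i]
            d[p] -= f * upper[i]
            b[p] -= f * b[i]
    x = np.empty(n)
    for i in range(n):
        p = parent[i]
        if p >= 0:
            x[i] = (b[i] - upper[i] * x[p]) / d[i]
        else:
            x[i] = b[i] / d[i]
    return x


def solve_tree(parent, diag, lower, upper, rhs):
    """Exact direct solve of a tree-sparse system (O(N))."""
    return _solve_tree_kernel(
        np.ascontiguousarray(parent, dtype=np.int64),
        np.ascontiguousarray(diag, dtype=np.float64),
        np.ascontiguousarray(lower, dtype=np.float64),
        np.ascontiguousarray(upper, dtype=np.float64),
        np.ascontiguousarray(rhs, dtype=np.float64),
    )


def tree_to_csr(parent, diag, lower, upper):
    """Assemble the tree system as a scipy CSR matrix."""
    from scipy import sparse

    n = diag.shape[0]
    child = np.flatnonzero(parent >= 0)
    rows = np.concatenate([np.arange(n), parent[child], child])
    cols = np.concatenate([np.arange(n), child, parent[child]])
    vals = np.concatenate([diag, lower[child], upper[child]])
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def solve_bicgstab(parent, diag, lower, upper, rhs, x0=None,
                   rtol: float = 1e-10, maxiter: int = 2000):
    """Stabilized bi-conjugate-gradient solve with a direct sparse
    fallback when the iteration does not converge."""
    from scipy.sparse.linalg import bicgstab, spsolve

    mat = tree_to_csr(parent, diag, lower, upper)
    x, info = bicgstab(mat, rhs, x0=x0, rtol=rtol, atol=0.0,
                       maxiter=maxiter)
    if info != 0:
        x = spsolve(mat.tocsc(), rhs)
    return x
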