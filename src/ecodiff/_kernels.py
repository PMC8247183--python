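"""Time-stepping kernels for the homogenized diffusion solver.

The inner loop is the cost centre of MCMC (one PDE solve per proposal), so a
numba-compiled dense path is provided for small coarse grids, with a pure
numpy fallback when numba is unavailable.  Both paths implement the same
scheme: backward-Euler diffusion (precomputed dense propagator ``M``)
followed by a per-cell reaction update, either the exact logistic step or a
forward-Euler step.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def _run_dense(M, c0, r, g, gamma_dt, steps_per_snap, n_snaps, scheme_euler):
    """Propagate state c through n_snaps * steps_per_snap steps.

    M : (n, n) dense backward-Euler diffusion propagator
    c0 : (n,) initial state (c = delta * lambda)
    r : (n,) reaction coefficient, average of 1/(delta K)
    g : exp(gamma * dt)   (exact-logistic multiplier)
    gamma_dt : gamma * dt (euler scheme)
    Returns (n_snaps + 1, n) snapshots including the initial state.
    """
    n = c0.shape[0]
    out = np.empty((n_snaps + 1, n))
    c = c0.copy()
    cnew = np.empty(n)
    out[0] = c
    for s in range(n_snaps):
        for _ in range(steps_per_snap):
            # hand-rolled matvec: fixed summation order, so results are
            # bit-identical regardless of BLAS threading
            for i in range(n):
                acc = 0.0
                for j in range(n):
                    acc += M[i, j] * c[j]
                cnew[i] = acc
            c, cnew = cnew, c
            if scheme_euler:
                for i in range(n):
                    c[i] = c[i] + gamma_dt * c[i] * (1.0 - r[i] * c[i])
                    if c[i] < 0.0:
                        c[i] = 0.0
            else:
                for i in range(n):
                    ci = c[i] * g
                    c[i] = ci / (1.0 + r[i] * c[i] * (g - 1.0))
        out[s + 1] = c
    return out


def _run_dense_numpy(M, c0, r, g, gamma_dt, steps_per_snap, n_snaps, scheme_euler):
    out = np.empty((n_snaps + 1, c0.shape[0]))
    c = c0.copy()
    out[0] = c
    for s in range(n_snaps):
        for _ in range(steps_per_snap):
            c = M @ c
            if scheme_euler:
                c = np.maximum(c + gamma_dt * c * (1.0 - r * c), 0.0)
            else:
                c = c * g / (1.0 + r * c * (g - 1.0))
        out[s + 1] = c
    return out


def run_dense(M, c0, r, g, gamma_dt, steps_per_snap, n_snaps, scheme_euler=False):
    args = (
        np.ascontiguousarray(M, dtype=np.float64),
        np.ascontiguousarray(c0, dtype=np.float64),
        np.ascontiguousarray(r, dtype=np.float64),
        float(g),
        float(gamma_dt),
        int(steps_per_snap),
        int(n_snaps),
        bool(scheme_euler),
    )
    if _HAVE_NUMBA:
        return _run_dense(*args)
    return _run_dense_numpy(*args)


def run_sparse(lu_solve, c0, r, g, gamma_dt, steps_per_snap, n_snaps, scheme_euler=False):
    """Sparse-factorization path for large grids (lu_solve from splu)."""
    out = np.empty((n_snaps + 1, c0.shape[0]))
    c = np.asarray(c0, dtype=float).copy()
    out[0] = c
    for s in range(n_snaps):
        for _ in range(steps_per_snap):
            c = lu_solve(c)
            if scheme_euler:
                c = np.maximum(c + gamma_dt * c * (1.0 - r * c), 0.0)
            else:
                c = c * g / (1.0 + r * c * (g - 1.0))
        out[s + 1] = c
    return out
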