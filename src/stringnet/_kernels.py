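"""Compiled inner loop of the batched Newton solver.

Same algorithm as the pure-numpy path in :mod:`stringnet.solver` (engineering
strain on the current chord, tension-only elements, stiffness floor on the
tangent only, capped Newton steps, convergence on the free-DOF residual
infinity norm); the tests assert both paths agree to round-off.  Kept in a
separate module so the solver works, just more slowly, if numba is absent.

Material encoding: kind 0 = linear with params[0] = E; kind 1 = tendon with
params = (E_linear, eps_toe, shape, sigma_toe).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _stress_tangent(eps, kind, params):
    """(sigma, dsigma/deps) from the taut side; zero for negative strain."""
    if eps < 0.0:
        return 0.0, 0.0
    if kind == 0:
        return params[0] * eps, params[0]
    E_lin, eps_toe, shape, sigma_toe = params[0], params[1], params[2], params[3]
    if eps_toe == 0.0:
        return E_lin * eps, E_lin
    if eps >= eps_toe:
        return sigma_toe + E_lin * (eps - eps_toe), E_lin
    em1 = np.expm1(shape)
    ex = np.exp(shape * eps / eps_toe)
    return sigma_toe * (ex - 1.0) / em1, sigma_toe * (shape / eps_toe) * ex / em1


@njit(cache=True)
def newton_batch(X, conn, l0b, areab, Feb, free, tol, max_iter, floor, max_step,
                 mat_kind, mat_params):
    """Batched Newton-Raphson equilibrium for items sharing one structure.

    Returns (U (b, nd), F_int (b, nd), converged (b,)).
    """
    b = Feb.shape[0]
    m = conn.shape[0]
    n = X.shape[0]
    nd = 2 * n
    nf = free.shape[0]
    U_all = np.zeros((b, nd))
    F_all = np.zeros((b, nd))
    conv = np.zeros(b, dtype=np.bool_)

    for item in range(b):
        U = np.zeros(nd)
        F = np.zeros(nd)
        Fe = Feb[item]
        for it in range(max_iter + 1):
            # internal forces and residual
            for d in range(nd):
                F[d] = 0.0
            K = np.zeros((nd, nd))
            for e in range(m):
                i = conn[e, 0]
                j = conn[e, 1]
                dx = X[j, 0] + U[2 * j] - X[i, 0] - U[2 * i]
                dy = X[j, 1] + U[2 * j + 1] - X[i, 1] - U[2 * i + 1]
                length = np.sqrt(dx * dx + dy * dy)
                l0 = l0b[item, e]
                if length < l0 or length == 0.0:
                    continue
                eps = (length - l0) / l0
                sigma, dsig = _stress_tangent(eps, mat_kind, mat_params)
                A = areab[item, e]
                axial = sigma * A
                nx = dx / length
                ny = dy / length
                F[2 * i] -= axial * nx
                F[2 * i + 1] -= axial * ny
                F[2 * j] += axial * nx
                F[2 * j + 1] += axial * ny
                km = dsig * A / l0
                kg = axial / length
                kxx = km * nx * nx + kg * (1.0 - nx * nx)
                kxy = (km - kg) * nx * ny
                kyy = km * ny * ny + kg * (1.0 - ny * ny)
                # scatter the 2x2 block with the [[k,-k],[-k,k]] pattern
                K[2 * i, 2 * i] += kxx
                K[2 * i, 2 * i + 1] += kxy
                K[2 * i + 1, 2 * i] += kxy
                K[2 * i + 1, 2 * i + 1] += kyy
                K[2 * j, 2 * j] += kxx
                K[2 * j, 2 * j + 1] += kxy
                K[2 * j + 1, 2 * j] += kxy
                K[2 * j + 1, 2 * j + 1] += kyy
                K[2 * i, 2 * j] -= kxx
                K[2 * i, 2 * j + 1] -= kxy
                K[2 * i + 1, 2 * j] -= kxy
                K[2 * i + 1, 2 * j + 1] -= kyy
                K[2 * j, 2 * i] -= kxx
                K[2 * j, 2 * i + 1] -= kxy
                K[2 * j + 1, 2 * i] -= kxy
                K[2 * j + 1, 2 * i + 1] -= kyy

            res = 0.0
            for a in range(nf):
                r = abs(F[free[a]] - Fe[free[a]])
                if r > res:
                    res = r
            if res <= tol:
                conv[item] = True
                break
            if it == max_iter:
                break

            Kff = np.empty((nf, nf))
            gf = np.empty(nf)
            for a in range(nf):
                fa = free[a]
                gf[a] = -(F[fa] - Fe[fa])
                for c in range(nf):
                    Kff[a, c] = K[fa, free[c]]
                Kff[a, a] += floor
            dU = np.linalg.solve(Kff, gf)
            ok = True
            step = 0.0
            for a in range(nf):
                if not np.isfinite(dU[a]):
                    ok = False
                    break
                if abs(dU[a]) > step:
                    step = abs(dU[a])
            if not ok:
                break
            scale = 1.0 if step <= max_step else max_step / step
            for a in range(nf):
                U[free[a]] += scale * dU[a]

        U_all[item] = U
        F_all[item] = F
    return U_all, F_all, conv
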