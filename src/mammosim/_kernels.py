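"""Numba-accelerated element force kernel (optional fast path).

Implements exactly the same math as `ElementKernel.forces` for the common
case of at most one Prony term; the numpy implementation remains the
reference and the fallback when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is pre-installed in CI
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def tet_forces(X, u, tets, DmInv, V0, mu, K, W_node,
               g, tau, dt, h, P_prev, use_visco, first_step):
    """Fused total-Lagrangian force pass.

    Returns ``(f_int, J, P_el, ok)``; ``h`` (viscous history) and ``P_prev``
    are updated in place.  ``ok`` is False when an element inverted.
    """
    m = tets.shape[0]
    nn = X.shape[0]
    J = np.empty(m)
    P_el = np.empty((m, 3, 3))
    FinvT = np.empty((m, 3, 3))
    F_all = np.empty((m, 3, 3))
    Jn = np.zeros(nn)
    f_int = np.zeros((nn, 3))

    # pass 1: kinematics, elastic deviatoric Piola, nodal J accumulation
    for e in range(m):
        n0, n1, n2, n3 = tets[e, 0], tets[e, 1], tets[e, 2], tets[e, 3]
        d00 = X[n1, 0] + u[n1, 0] - X[n0, 0] - u[n0, 0]
        d10 = X[n1, 1] + u[n1, 1] - X[n0, 1] - u[n0, 1]
        d20 = X[n1, 2] + u[n1, 2] - X[n0, 2] - u[n0, 2]
        d01 = X[n2, 0] + u[n2, 0] - X[n0, 0] - u[n0, 0]
        d11 = X[n2, 1] + u[n2, 1] - X[n0, 1] - u[n0, 1]
        d21 = X[n2, 2] + u[n2, 2] - X[n0, 2] - u[n0, 2]
        d02 = X[n3, 0] + u[n3, 0] - X[n0, 0] - u[n0, 0]
        d12 = X[n3, 1] + u[n3, 1] - X[n0, 1] - u[n0, 1]
        d22 = X[n3, 2] + u[n3, 2] - X[n0, 2] - u[n0, 2]
        B = DmInv[e]
        F00 = d00 * B[0, 0] + d01 * B[1, 0] + d02 * B[2, 0]
        F01 = d00 * B[0, 1] + d01 * B[1, 1] + d02 * B[2, 1]
        F02 = d00 * B[0, 2] + d01 * B[1, 2] + d02 * B[2, 2]
        F10 = d10 * B[0, 0] + d11 * B[1, 0] + d12 * B[2, 0]
        F11 = d10 * B[0, 1] + d11 * B[1, 1] + d12 * B[2, 1]
        F12 = d10 * B[0, 2] + d11 * B[1, 2] + d12 * B[2, 2]
        F20 = d20 * B[0, 0] + d21 * B[1, 0] + d22 * B[2, 0]
        F21 = d20 * B[0, 1] + d21 * B[1, 1] + d22 * B[2, 1]
        F22 = d20 * B[0, 2] + d21 * B[1, 2] + d22 * B[2, 2]
        c00 = F11 * F22 - F12 * F21
        c01 = F12 * F20 - F10 * F22
        c02 = F10 * F21 - F11 * F20
        det = F00 * c00 + F01 * c01 + F02 * c02
        if det <= 0.0:
            return f_int, J, P_el, False
        J[e] = det
        F_all[e, 0, 0] = F00
        F_all[e, 0, 1] = F01
        F_all[e, 0, 2] = F02
        F_all[e, 1, 0] = F10
        F_all[e, 1, 1] = F11
        F_all[e, 1, 2] = F12
        F_all[e, 2, 0] = F20
        F_all[e, 2, 1] = F21
        F_all[e, 2, 2] = F22
        # inverse transpose = cofactor matrix / det
        FinvT[e, 0, 0] = c00 / det
        FinvT[e, 0, 1] = c01 / det
        FinvT[e, 0, 2] = c02 / det
        FinvT[e, 1, 0] = (F02 * F21 - F01 * F22) / det
        FinvT[e, 1, 1] = (F00 * F22 - F02 * F20) / det
        FinvT[e, 1, 2] = (F01 * F20 - F00 * F21) / det
        FinvT[e, 2, 0] = (F01 * F12 - F02 * F11) / det
        FinvT[e, 2, 1] = (F02 * F10 - F00 * F12) / det
        FinvT[e, 2, 2] = (F00 * F11 - F01 * F10) / det
        I1 = (F00 * F00 + F01 * F01 + F02 * F02 + F10 * F10 + F11 * F11
              + F12 * F12 + F20 * F20 + F21 * F21 + F22 * F22)
        scale = mu[e] * det ** (-2.0 / 3.0)
        third = I1 / 3.0
        for i in range(3):
            for j in range(3):
                P_el[e, i, j] = scale * (F_all[e, i, j] - third * FinvT[e, i, j])
        w = 0.25 * V0[e]
        Jn[n0] += w * det
        Jn[n1] += w * det
        Jn[n2] += w * det
        Jn[n3] += w * det

    for a in range(nn):
        Jn[a] /= W_node[a]

    # pass 2: element pressure from averaged J, scattered back to nodes
    pn = np.zeros(nn)
    for e in range(m):
        n0, n1, n2, n3 = tets[e, 0], tets[e, 1], tets[e, 2], tets[e, 3]
        Jbar = 0.25 * (Jn[n0] + Jn[n1] + Jn[n2] + Jn[n3])
        pbar = K[e] * (Jbar - 1.0)
        w = 0.25 * V0[e]
        pn[n0] += w * pbar
        pn[n1] += w * pbar
        pn[n2] += w * pbar
        pn[n3] += w * pbar
    for a in range(nn):
        pn[a] /= W_node[a]

    # pass 3: viscous update, total Piola, force scatter
    if use_visco:
        x = dt / tau
        decay = np.exp(-x)
        alpha = (1.0 - decay) / x
    for e in range(m):
        n0, n1, n2, n3 = tets[e, 0], tets[e, 1], tets[e, 2], tets[e, 3]
        p_eff = 0.25 * (pn[n0] + pn[n1] + pn[n2] + pn[n3]) * J[e]
        B = DmInv[e]
        v0e = V0[e]
        g0 = 0.0
        g1 = 0.0
        g2 = 0.0
        for i in range(3):
            for j in range(3):
                Pij = P_el[e, i, j]
                if use_visco:
                    Pold = 0.0 if first_step else P_prev[e, i, j]
                    hij = decay * h[e, i, j] + g * (
                        Pij - decay * Pold - alpha * (Pij - Pold))
                    h[e, i, j] = hij
                    Papp = Pij - hij
                else:
                    Papp = Pij
                Papp += p_eff * FinvT[e, i, j]
                # G columns: force contributions of nodes 1..3
                if True:
                    gr0 = v0e * Papp * B[0, j]
                    gr1 = v0e * Papp * B[1, j]
                    gr2 = v0e * Papp * B[2, j]
                    f_int[n1, i] += gr0
                    f_int[n2, i] += gr1
                    f_int[n3, i] += gr2
                    f_int[n0, i] -= gr0 + gr1 + gr2
        if use_visco:
            for i in range(3):
                for j in range(3):
                    P_prev[e, i, j] = P_el[e, i, j]

    return f_int, J, P_el, True
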