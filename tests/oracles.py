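"""Independent numerical oracles used by the solver and acceptance tests.

These deliberately avoid the package's force/assembly code paths:
- `linear_fe_displacement`: small-strain linear tetrahedral FE (sparse direct
  solve) with nodal volumetric-strain averaging, built from B-matrices.
- `static_minimum`: quasi-static solution by direct minimization of the total
  potential (strain energy + gravity) with scipy's L-BFGS.
"""

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize


def _shape_gradients(nodes, tets):
    """Per-element shape-function gradients (4, 3) and volumes."""
    X = nodes[tets]
    d = X[:, 1:] - X[:, :1]
    V = np.linalg.det(d) / 6.0
    Dm_inv = np.linalg.inv(np.swapaxes(d, 1, 2))  # columns = edge vectors
    grads = np.empty((len(tets), 4, 3))
    grads[:, 1:] = Dm_inv  # grad N_a = row (a-1) of Dm^-1
    grads[:, 0] = -grads[:, 1:].sum(axis=1)
    return grads, V


def linear_stiffness(mesh, mu, K):
    """Assembled small-strain stiffness: deviatoric element part plus a
    volumetric term on the nodal-averaged dilatation (the solver's locking
    treatment in the linear limit)."""
    nodes, tets = mesh.nodes, mesh.tets
    n_nodes = len(nodes)
    ndof = 3 * n_nodes
    grads, V = _shape_gradients(nodes, tets)

    rows, cols, vals = [], [], []

    # deviatoric part: 2 mu * (eps_dev : eps_dev) via the standard B-matrix
    # with the volumetric column removed
    for e in range(len(tets)):
        B = np.zeros((6, 12))
        for a in range(4):
            gx, gy, gz = grads[e, a]
            B[0, 3 * a] = gx
            B[1, 3 * a + 1] = gy
            B[2, 3 * a + 2] = gz
            B[3, 3 * a] = gy
            B[3, 3 * a + 1] = gx
            B[4, 3 * a + 1] = gz
            B[4, 3 * a + 2] = gy
            B[5, 3 * a] = gz
            B[5, 3 * a + 2] = gx
        # deviatoric material matrix: 2 mu (I_dev) in Voigt form
        D = np.zeros((6, 6))
        D[:3, :3] = 2 * mu * (np.eye(3) - np.ones((3, 3)) / 3.0)
        D[3:, 3:] = mu * np.eye(3)
        Ke = V[e] * B.T @ D @ B
        dof = np.repeat(3 * tets[e], 3) + np.tile([0, 1, 2], 4)
        rows.append(np.repeat(dof, 12))
        cols.append(np.tile(dof, 12))
        vals.append(Ke.ravel())

    # volumetric part: 0.5 K (avg(div u))^2 with the same two-pass nodal
    # averaging as the nonlinear solver (scatter to nodes, gather element
    # mean) -> E_vol = 0.5 (M b u)^T diag(V K) (M b u)
    b_rows, b_cols, b_vals = [], [], []
    for e in range(len(tets)):
        for a in range(4):
            for k in range(3):
                b_rows.append(e)
                b_cols.append(3 * tets[e, a] + k)
                b_vals.append(grads[e, a, k])
    Bdiv = sp.coo_matrix((b_vals, (b_rows, b_cols)), shape=(len(tets), ndof)).tocsr()
    w = V / 4.0
    W_node = np.zeros(n_nodes)
    np.add.at(W_node, tets.ravel(), np.repeat(w, 4))
    S = sp.coo_matrix((np.repeat(w, 4), (tets.ravel(), np.repeat(np.arange(len(tets)), 4))),
                      shape=(n_nodes, len(tets))).tocsr()
    S = sp.diags(1.0 / W_node) @ S
    G = sp.coo_matrix((np.full(4 * len(tets), 0.25),
                       (np.repeat(np.arange(len(tets)), 4), tets.ravel())),
                      shape=(len(tets), n_nodes)).tocsr()
    M = G @ S  # element -> element averaging
    A = M @ Bdiv
    K_vol = A.T @ sp.diags(V * K) @ A

    K_dev = sp.coo_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(ndof, ndof)).tocsr()
    return (K_dev + K_vol).tocsr()


def linear_fe_displacement(mesh, mu, K, rho, gravity, fixed_dofs):
    """Small-strain linear FE solve under lumped gravity load.

    Returns the nodal displacement array (n, 3).
    """
    nodes, tets = mesh.nodes, mesh.tets
    n_nodes = len(nodes)
    ndof = 3 * n_nodes
    _, V = _shape_gradients(nodes, tets)
    K_tot = linear_stiffness(mesh, mu, K)

    mass = np.zeros(n_nodes)
    np.add.at(mass, tets.ravel(), np.repeat(rho * V / 4.0, 4))
    f = (mass[:, None] * np.asarray(gravity)).ravel()

    free = np.ones(ndof, dtype=bool)
    free[fixed_dofs] = False
    K_ff = K_tot[free][:, free]
    u = np.zeros(ndof)
    u[free] = spla.spsolve(K_ff.tocsc(), f[free])
    return u.reshape(n_nodes, 3)


def static_minimum(model, gravity, fixed_mask, u0=None):
    """Quasi-static displacement by direct minimization of strain energy
    minus gravity work over the free DOFs (L-BFGS with analytic gradient)."""
    from mammosim.solver import ElementKernel

    mesh = model.mesh
    kernel = ElementKernel(mesh, model.materials)
    mass = kernel.lumped_mass
    g = np.asarray(gravity, dtype=float)
    free = ~fixed_mask.ravel()

    def unpack(x):
        u = np.zeros((mesh.n_nodes, 3))
        u.ravel()[free] = x
        return u

    def fun(x):
        u = unpack(x)
        try:
            F, J = kernel.kinematics(u)
        except Exception:
            # inverted trial state: signal the line search to backtrack
            return np.inf, np.zeros(free.sum())
        E = kernel.strain_energy(F, J) - float((mass[:, None] * g * u).sum())
        grad = kernel.forces(u)[0] - mass[:, None] * g
        return E, grad.ravel()[free]

    x0 = np.zeros(free.sum()) if u0 is None else np.asarray(u0).ravel()[free]
    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 20000, "ftol": 1e-18, "gtol": 1e-12,
                            "maxcor": 30})
    return unpack(res.x)
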