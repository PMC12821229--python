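"""Explicit central-difference finite-element dynamics.

Total-Lagrangian constant-gradient tetrahedra with the visco-hyperelastic
law from `mammosim.constitutive`, nodal-volume-averaged dilatation (F-bar
type) against volumetric locking, lumped (row-sum) mass, symmetry Dirichlet
sets, rigid chest-wall contact (small-sliding penalty with Coulomb friction,
or a fixed tie), an energy ledger, and the nipple closest-approach stopping
criterion.

Sign conventions: displacements are measured from the stress-free reference
(prone) configuration; gravity for the supine pose points along -y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from mammosim import _kernels
from mammosim.constitutive import InvertedElementError, PronySeries, visco_update
from mammosim.geometry_io import TetMesh, TriSurface

__all__ = [
    "ContactSpec",
    "SimulationConfig",
    "Trajectory",
    "stable_timestep",
    "ElementKernel",
    "internal_forces",
    "contact_forces",
    "ContactState",
    "run_simulation",
    "select_stop_state",
]


def _det3(M: np.ndarray) -> np.ndarray:
    """Determinant of batched 3x3 matrices (faster than np.linalg.det)."""
    return (M[..., 0, 0] * (M[..., 1, 1] * M[..., 2, 2] - M[..., 1, 2] * M[..., 2, 1])
            - M[..., 0, 1] * (M[..., 1, 0] * M[..., 2, 2] - M[..., 1, 2] * M[..., 2, 0])
            + M[..., 0, 2] * (M[..., 1, 0] * M[..., 2, 1] - M[..., 1, 1] * M[..., 2, 0]))


def _invT3(M: np.ndarray, det: np.ndarray) -> np.ndarray:
    """Inverse-transpose of batched 3x3 matrices via the adjugate."""
    out = np.empty_like(M)
    out[..., 0, 0] = M[..., 1, 1] * M[..., 2, 2] - M[..., 1, 2] * M[..., 2, 1]
    out[..., 0, 1] = M[..., 1, 2] * M[..., 2, 0] - M[..., 1, 0] * M[..., 2, 2]
    out[..., 0, 2] = M[..., 1, 0] * M[..., 2, 1] - M[..., 1, 1] * M[..., 2, 0]
    out[..., 1, 0] = M[..., 0, 2] * M[..., 2, 1] - M[..., 0, 1] * M[..., 2, 2]
    out[..., 1, 1] = M[..., 0, 0] * M[..., 2, 2] - M[..., 0, 2] * M[..., 2, 0]
    out[..., 1, 2] = M[..., 0, 1] * M[..., 2, 0] - M[..., 0, 0] * M[..., 2, 1]
    out[..., 2, 0] = M[..., 0, 1] * M[..., 1, 2] - M[..., 0, 2] * M[..., 1, 1]
    out[..., 2, 1] = M[..., 0, 2] * M[..., 1, 0] - M[..., 0, 0] * M[..., 1, 2]
    out[..., 2, 2] = M[..., 0, 0] * M[..., 1, 1] - M[..., 0, 1] * M[..., 1, 0]
    out /= det[..., None, None]
    return out


def _scatter_vec(indices: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    """Sum (m, 3) vectors into n nodes (bincount beats np.add.at)."""
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.bincount(indices, weights=values[:, k], minlength=n)
    return out


@dataclass(frozen=True)
class ContactSpec:
    """Chest-wall interface behaviour."""

    mode: str = "sliding"  # "sliding" | "fixed"
    friction: float = 0.5
    penalty_scale: float = 0.1  # beta in k = beta * m_node / dt^2
    gap_tol: float = 0.0

    def __post_init__(self):
        if self.mode not in ("sliding", "fixed"):
            raise ValueError("contact mode must be 'sliding' or 'fixed'")
        if not 0.0 <= self.friction <= 1.5:
            raise ValueError("friction coefficient must lie in [0, 1.5]")
        if self.penalty_scale <= 0:
            raise ValueError("penalty scale must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Run parameters for one explicit simulation."""

    gravity: tuple = (0.0, -9.8, 0.0)
    total_time: float = 0.3
    safety: float = 0.9
    record_interval: float = 0.005
    ramp: bool = False
    ramp_time: float = 0.05
    damping: float = 0.0  # mass-proportional damping coefficient (1/s)
    seed: int = 0

    def __post_init__(self):
        if self.total_time <= 0:
            raise ValueError("total time must be positive")
        if not 0.0 < self.safety <= 1.0:
            raise ValueError("time-step safety factor must lie in (0, 1]")
        if self.record_interval <= 0:
            raise ValueError("recording interval must be positive")


@dataclass
class Trajectory:
    """Time-sampled solution: displacement snapshots, nipple track, and an
    energy ledger (kinetic, strain, external work, viscous dissipation)."""

    times: np.ndarray
    displacements: np.ndarray  # (n_samples, n_nodes, 3)
    nipple_positions: np.ndarray  # (n_samples, 3)
    energy: dict  # kinetic, strain, external_work, viscous_dissipation, contact_work
    dt: float = 0.0

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=self.times)
            fh.create_dataset("displacements", data=self.displacements)
            fh.create_dataset("nipple_positions", data=self.nipple_positions)
            fh.attrs["dt"] = self.dt
            grp = fh.create_group("energy")
            for key, val in self.energy.items():
                grp.create_dataset(key, data=np.asarray(val))

    @classmethod
    def load_h5(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(
                times=fh["times"][()],
                displacements=fh["displacements"][()],
                nipple_positions=fh["nipple_positions"][()],
                energy={k: fh["energy"][k][()] for k in fh["energy"]},
                dt=float(fh.attrs.get("dt", 0.0)),
            )


# ---------------------------------------------------------------------------
# element kernel


def _element_moduli(mesh: TetMesh, materials):
    """Per-element (mu, K, rho) arrays from the region labels; tumor elements
    carry breast properties (two-tissue model)."""
    mu = np.empty(mesh.n_tets)
    K = np.empty(mesh.n_tets)
    rho = np.empty(mesh.n_tets)
    skin = mesh.region_mask("skin")
    for arr, battr in ((mu, "mu0"), (K, "K0"), (rho, "rho")):
        arr[:] = getattr(materials.breast, battr)
        arr[skin] = getattr(materials.skin, battr)
    return mu, K, rho


class ElementKernel:
    """Precomputed reference-configuration data plus the force/energy kernel.

    The strain energy is ``sum_e V0_e [mu/2 (I1_bar - 3) + K/2 (J_bar - 1)^2]``
    with ``J_bar`` the two-pass nodal-volume average of the element Jacobian;
    `forces` returns the exact (negative) gradient of this energy, with the
    deviatoric first Piola stress optionally run through the Prony recurrence.
    """

    def __init__(self, mesh: TetMesh, materials):
        self.mesh = mesh
        X = mesh.nodes
        t = mesh.tets
        Dm = np.stack([X[t[:, 1]] - X[t[:, 0]],
                       X[t[:, 2]] - X[t[:, 0]],
                       X[t[:, 3]] - X[t[:, 0]]], axis=-1)
        self.V0 = np.linalg.det(Dm) / 6.0
        if np.any(self.V0 <= 0):
            raise ValueError("reference mesh contains non-positive tet volumes")
        self.DmInv = np.linalg.inv(Dm)
        self.mu, self.K, self.rho = _element_moduli(mesh, materials)
        prony_b = materials.breast.prony
        prony_s = materials.skin.prony
        if prony_b.g != prony_s.g or prony_b.tau != prony_s.tau:
            raise ValueError("breast and skin must share the Prony spectrum")
        self.prony: PronySeries = prony_b
        # nodal weights for the volumetric averaging passes
        self.w_elem = np.repeat(self.V0 / 4.0, 4)
        self.W_node = np.zeros(mesh.n_nodes)
        np.add.at(self.W_node, t.ravel(), self.w_elem)
        self.lumped_mass = np.zeros(mesh.n_nodes)
        np.add.at(self.lumped_mass, t.ravel(), np.repeat(self.rho * self.V0 / 4.0, 4))
        self._P_prev_buf = None  # previous elastic stress (numba fast path)

    def zero_history(self):
        n = self.prony.n_terms
        return [np.zeros((self.mesh.n_tets, 3, 3)) for _ in range(n)]

    def _nodal_average(self, elem_values: np.ndarray) -> np.ndarray:
        """Volume-weighted scatter to nodes, then gather back as the element
        mean of nodal values."""
        t = self.mesh.tets
        nodal = np.bincount(t.ravel(),
                            weights=(self.V0 / 4.0)[:, None].repeat(4, 1).ravel()
                            * np.repeat(elem_values, 4),
                            minlength=self.mesh.n_nodes)
        nodal /= self.W_node
        return nodal[t].mean(axis=1)

    def kinematics(self, u: np.ndarray):
        X = self.mesh.nodes
        t = self.mesh.tets
        x = X + u
        Ds = np.stack([x[t[:, 1]] - x[t[:, 0]],
                       x[t[:, 2]] - x[t[:, 0]],
                       x[t[:, 3]] - x[t[:, 0]]], axis=-1)
        F = Ds @ self.DmInv
        J = _det3(F)
        if np.any(J <= 0):
            bad = int(np.argmin(J))
            raise InvertedElementError(
                f"element {bad} inverted (J = {J[bad]:.3g}); reduce the time "
                "step or stiffen K0")
        return F, J

    def deviatoric_piola(self, F: np.ndarray, J: np.ndarray) -> np.ndarray:
        FinvT = _invT3(F, J)
        I1 = np.einsum("eij,eij->e", F, F)
        scale = (self.mu * J ** (-2.0 / 3.0))[:, None, None]
        return scale * (F - (I1 / 3.0)[:, None, None] * FinvT), FinvT

    def strain_energy(self, F: np.ndarray, J: np.ndarray) -> float:
        """Elastic energy at the instantaneous moduli (G0 basis)."""
        dev, vol = self.strain_energy_split(F, J)
        return dev + vol

    def strain_energy_split(self, F: np.ndarray, J: np.ndarray):
        """(deviatoric, volumetric) strain energy at the instantaneous moduli."""
        I1_bar = np.einsum("eij,eij->e", F, F) * J ** (-2.0 / 3.0)
        J_bar = self._nodal_average(J)
        dev = float((self.V0 * 0.5 * self.mu * (I1_bar - 3.0)).sum())
        vol = float((self.V0 * 0.5 * self.K * (J_bar - 1.0) ** 2).sum())
        return dev, vol

    def branch_state(self, P_dev_elastic: np.ndarray, history):
        """Maxwell-branch stored energy and dashpot dissipation rate.

        Small-strain-consistent bookkeeping: each branch carries stress
        ``q_k = g_k P_el - h_k``, spring energy ``q:q / (4 g_k mu)`` and
        dashpot power ``q:q / (2 g_k mu tau_k)`` per unit reference volume.
        """
        stored = 0.0
        power = 0.0
        for g_k, tau_k, h_k in zip(self.prony.g, self.prony.tau, history):
            q = g_k * P_dev_elastic - h_k
            qq = np.einsum("eij,eij->e", q, q)
            stored += float((self.V0 * qq / (4.0 * g_k * self.mu)).sum())
            power += float((self.V0 * qq / (2.0 * g_k * self.mu * tau_k)).sum())
        return stored, power

    def effective_pressure(self, J: np.ndarray) -> np.ndarray:
        """Element pressure from the averaged-J volumetric energy; the second
        averaging pass keeps the force the exact energy gradient."""
        J_bar = self._nodal_average(J)
        return self._nodal_average(self.K * (J_bar - 1.0))

    def forces(self, u: np.ndarray, history=None, P_dev_prev=None, dt: float | None = None):
        """Internal nodal force vector (the energy gradient, positive =
        restoring) and updated viscous state.

        Returns ``(f_int, new_history, P_dev_elastic, J)``.  When numba is
        available and the Prony spectrum has at most one term, a fused
        compiled kernel is used; the history and previous-stress buffers are
        then updated in place.
        """
        use_visco = bool(self.prony.n_terms) and dt is not None
        if _kernels.HAVE_NUMBA and self.prony.n_terms <= 1:
            if history is None or (use_visco and not isinstance(history[0], np.ndarray)):
                history = self.zero_history()
            h = history[0] if self.prony.n_terms else np.zeros((0, 3, 3))
            first = P_dev_prev is None
            if self._P_prev_buf is None:
                self._P_prev_buf = np.zeros((self.mesh.n_tets, 3, 3))
                if P_dev_prev is not None:
                    self._P_prev_buf[:] = P_dev_prev
            g = self.prony.g[0] if use_visco else 0.0
            tau = self.prony.tau[0] if use_visco else 1.0
            f_int, J, P_el, ok = _kernels.tet_forces(
                self.mesh.nodes, np.ascontiguousarray(u), self.mesh.tets,
                self.DmInv, self.V0, self.mu, self.K, self.W_node,
                g, tau, dt if dt is not None else 1.0, h, self._P_prev_buf,
                use_visco, first)
            if not ok:
                self.kinematics(u)  # raises with the element diagnostic
                raise InvertedElementError("element inversion")
            return f_int, history, P_el, J
        F, J = self.kinematics(u)
        P_dev, FinvT = self.deviatoric_piola(F, J)
        P_dev_elastic = P_dev
        new_history = history
        if use_visco:
            prev = P_dev_prev if P_dev_prev is not None else np.zeros_like(P_dev)
            P_dev, new_history = visco_update(P_dev, prev, history, dt, self.prony)
        p_eff = self.effective_pressure(J)
        P = P_dev + (p_eff * J)[:, None, None] * FinvT
        f_int = self._assemble(P)
        return f_int, new_history, P_dev_elastic, J

    def _assemble(self, P: np.ndarray) -> np.ndarray:
        # grad_j E = V0 * P @ (row j of DmInv); node 0 balances the others
        G = self.V0[:, None, None] * (P @ np.swapaxes(self.DmInv, -1, -2))
        t = self.mesh.tets
        n = self.mesh.n_nodes
        f = _scatter_vec(t[:, 1], G[:, :, 0], n)
        f += _scatter_vec(t[:, 2], G[:, :, 1], n)
        f += _scatter_vec(t[:, 3], G[:, :, 2], n)
        f += _scatter_vec(t[:, 0], -G.sum(axis=2), n)
        return f


def internal_forces(mesh: TetMesh, materials, displacements: np.ndarray,
                    viscous_state=None, dt: float | None = None):
    """Nodal internal force vector for a displacement state.

    Convenience wrapper over `ElementKernel.forces`; returns ``(forces,
    updated_viscous_state)``.  Forces are the energy gradient, so a rigid
    translation or rotation yields zero to round-off.
    """
    kernel = ElementKernel(mesh, materials)
    history = viscous_state[0] if viscous_state else kernel.zero_history()
    prev = viscous_state[1] if viscous_state else None
    f_int, new_history, P_el, _ = kernel.forces(
        np.asarray(displacements, dtype=float), history, prev, dt)
    return f_int, (new_history, P_el)


# ---------------------------------------------------------------------------
# time step


def stable_timestep(mesh: TetMesh, materials, safety: float = 0.9) -> float:
    """CFL bound ``dt = safety * min_e(L_e / c_e)`` with ``L_e`` the minimum
    element edge and ``c_e`` the dilatational wave speed
    ``sqrt((K0 + 4 mu0/3) / rho)``."""
    if safety <= 0:
        raise ValueError("safety factor must be positive")
    x = mesh.nodes
    t = mesh.tets
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    edge_len = np.stack([np.linalg.norm(x[t[:, a]] - x[t[:, b]], axis=1) for a, b in pairs])
    L = edge_len.min(axis=0)
    kernel_mu, kernel_K, kernel_rho = _element_moduli(mesh, materials)
    c = np.sqrt((kernel_K + 4.0 * kernel_mu / 3.0) / kernel_rho)
    return float(safety * np.min(L / c))


# ---------------------------------------------------------------------------
# contact


@dataclass
class ContactState:
    """Per-slave-node small-sliding state: anchor facet (-1 = unassigned) and
    the anchor point on the wall used by the tangential spring."""

    facet: np.ndarray
    anchor: np.ndarray

    @classmethod
    def fresh(cls, n_nodes: int) -> "ContactState":
        return cls(facet=np.full(n_nodes, -1, dtype=np.int64),
                   anchor=np.zeros((n_nodes, 3)))


def _closest_facets(wall: TriSurface, points: np.ndarray) -> np.ndarray:
    # the wall is rigid and fixed, so its facet tree is memoized on it
    tree = getattr(wall, "_facet_tree", None)
    if tree is None:
        tree = cKDTree(wall.vertices[wall.faces].mean(axis=1))
        wall._facet_tree = tree
    _, idx = tree.query(points)
    return np.atleast_1d(idx)


def contact_forces(positions: np.ndarray, wall: TriSurface, spec: ContactSpec,
                   nodal_masses: np.ndarray, dt: float,
                   state: ContactState | None = None):
    """Penalty contact of slave nodes against a rigid wall surface.

    Normal: ``f_n = -k * gap * n`` when the signed gap (along the anchor
    facet normal) is negative, ``k = penalty_scale * m_node / dt^2``.
    Tangential: elastic spring to the anchor point capped by the Coulomb
    limit ``friction * |f_n|``; on slip the anchor is dragged to the return-
    mapped position (small-sliding: the facet assigned at first contact is
    kept).  Returns ``(forces, new_state)``.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n_pts = len(positions)
    if state is None:
        state = ContactState.fresh(n_pts)
    facet = state.facet.copy()
    anchor = state.anchor.copy()
    normals = wall.face_normals()
    forces = np.zeros((n_pts, 3))

    unassigned = facet < 0
    if np.any(unassigned):
        cand = _closest_facets(wall, positions[unassigned])
        ids = np.flatnonzero(unassigned)
        ref = wall.vertices[wall.faces[cand, 0]]
        n = normals[cand]
        gap = np.einsum("ij,ij->i", positions[ids] - ref, n)
        touching = gap < spec.gap_tol
        newly = ids[touching]
        facet[newly] = cand[touching]
        # anchor at the projection onto the wall plane at first touch
        anchor[newly] = positions[newly] - gap[touching, None] * n[touching]

    active = facet >= 0
    if np.any(active):
        ids = np.flatnonzero(active)
        fct = facet[ids]
        n = normals[fct]
        ref = wall.vertices[wall.faces[fct, 0]]
        p = positions[ids]
        gap = np.einsum("ij,ij->i", p - ref, n)
        k = spec.penalty_scale * np.asarray(nodal_masses)[ids] / dt ** 2
        pen = gap < spec.gap_tol
        f_n_mag = np.where(pen, -k * gap, 0.0)
        forces[ids] += f_n_mag[:, None] * n
        # tangential spring against the anchor, Coulomb-capped
        p_tan = p - gap[:, None] * n
        slip = p_tan - anchor[ids]
        slip -= np.einsum("ij,ij->i", slip, n)[:, None] * n
        f_t = -k[:, None] * slip
        f_t_mag = np.linalg.norm(f_t, axis=1)
        limit = spec.friction * f_n_mag
        over = f_t_mag > np.maximum(limit, 1e-300)
        scale = np.where(over & (f_t_mag > 0), limit / np.maximum(f_t_mag, 1e-300), 1.0)
        f_t = scale[:, None] * f_t
        forces[ids] += f_t
        # drag anchors of slipping nodes (return mapping); release separated
        slip_nodes = ids[over & pen]
        if slip_nodes.size:
            sel = over & pen
            drag = slip[sel] * (1.0 - scale[sel])[:, None]
            anchor[slip_nodes] += drag
        released = ids[~pen]
        facet[released] = -1
    return forces, ContactState(facet=facet, anchor=anchor)


# ---------------------------------------------------------------------------
# time integration


def run_simulation(model, config: SimulationConfig,
                   u0: np.ndarray | None = None,
                   v0: np.ndarray | None = None) -> Trajectory:
    """Central-difference explicit run on a `BodyModel`.

    Dirichlet sets enforced every step: junction ``u_x = 0``,
    superior/inferior ``u_z = 0``, and with fixed-tie contact the chest-
    interface nodes are fully fixed.  Gravity acts instantaneously at t = 0
    unless ``config.ramp``.  Deterministic for a fixed config.
    """
    mesh: TetMesh = model.mesh
    kernel = ElementKernel(mesh, model.materials)
    dt = stable_timestep(mesh, model.materials, config.safety)
    mass = kernel.lumped_mass
    gravity = np.asarray(config.gravity, dtype=float)
    f_grav_full = mass[:, None] * gravity

    # Dirichlet component masks
    fix = np.zeros((mesh.n_nodes, 3), dtype=bool)
    fix[mesh.node_sets.get("junction", []), 0] = True
    fix[mesh.node_sets.get("superior_inferior", []), 2] = True
    contact: ContactSpec = model.contact
    chest_ids = np.asarray(mesh.node_sets.get("chest_interface", []), dtype=np.int64)
    if contact.mode == "fixed" and chest_ids.size:
        fix[chest_ids, :] = True

    nipple = int(mesh.node_sets["nipple"][0]) if "nipple" in mesh.node_sets else None
    wall: TriSurface | None = getattr(model, "chest_wall", None)
    use_contact = contact.mode == "sliding" and wall is not None and chest_ids.size > 0
    cstate = ContactState.fresh(len(chest_ids)) if use_contact else None

    u = np.zeros((mesh.n_nodes, 3)) if u0 is None else np.array(u0, dtype=float)
    v = np.zeros((mesh.n_nodes, 3)) if v0 is None else np.array(v0, dtype=float)
    u[fix] = 0.0
    v[fix] = 0.0

    history = kernel.zero_history()
    P_dev_prev = None
    prev_rate = 0.0  # dashpot power of the previous step (trapezoid)

    n_rec = int(np.floor(config.total_time / config.record_interval + 1e-9))
    record_times = np.arange(n_rec + 1) * config.record_interval
    n_steps = max(1, int(np.ceil(config.total_time / dt - 1e-12)))

    times, snaps, nipples = [], [], []
    E_kin, E_strain, W_ext, D_visc, W_contact = [], [], [], [], []
    work_ext = 0.0
    work_contact = 0.0
    dissipation = 0.0
    next_rec = 0

    def record(t_rec, strain, kinetic):
        nonlocal next_rec
        times.append(t_rec)
        snaps.append(u.copy())
        x_nip = mesh.nodes[nipple] + u[nipple] if nipple is not None else np.full(3, np.nan)
        nipples.append(x_nip)
        E_strain.append(strain)
        E_kin.append(kinetic)
        W_ext.append(work_ext)
        D_visc.append(dissipation)
        W_contact.append(work_contact)
        next_rec += 1

    t = 0.0
    for step in range(n_steps):
        scale = 1.0
        if config.ramp:
            scale = min(t / max(config.ramp_time, dt), 1.0)
        f_int, history, P_el, _ = kernel.forces(u, history, P_dev_prev, dt)
        P_dev_prev = P_el
        f = scale * f_grav_full - f_int
        if use_contact:
            fc, cstate = contact_forces(mesh.nodes[chest_ids] + u[chest_ids], wall,
                                        contact, mass[chest_ids], dt, cstate)
            f[chest_ids] += fc
        else:
            fc = None
        a = f / mass[:, None]
        if config.damping > 0:
            a -= config.damping * v
        a[fix] = 0.0
        v_old = v.copy()
        v = v + a * dt
        # dashpot dissipation (trapezoid in time, non-negative by construction)
        if kernel.prony.n_terms:
            branch_stored, diss_rate = kernel.branch_state(P_el, history)
            dissipation += 0.5 * dt * (diss_rate + prev_rate)
            prev_rate = diss_rate
        else:
            branch_stored = 0.0
        # record the state at t: stored energy = long-term elastic part +
        # Maxwell spring energy, kinetic = 0.5 m v_{n-1/2} v_{n+1/2} (the
        # leapfrog-consistent pairing conserved with the potential)
        while next_rec <= n_rec and t + 1e-12 >= record_times[next_rec]:
            F, J = kernel.kinematics(u)
            dev, vol = kernel.strain_energy_split(F, J)
            stored = vol + (1.0 - sum(kernel.prony.g)) * dev + branch_stored
            record(record_times[next_rec], stored,
                   0.5 * float((mass[:, None] * v_old * v).sum()))
        du = v * dt
        du[fix] = 0.0
        if not np.all(np.isfinite(du)):
            raise FloatingPointError(
                f"NaN/Inf in displacement update at t = {t:.4g} s (step {step})")
        u = u + du
        # work terms paired with the time-centered velocity: exact for the
        # central-difference kinetic-energy increment
        dw = 0.5 * (v_old + v) * dt
        dw[fix] = 0.0
        work_ext += float((scale * f_grav_full * dw).sum())
        if fc is not None:
            work_contact += float((fc * dw[chest_ids]).sum())
        t += dt

    while next_rec <= n_rec:  # final state (and any residual record slots)
        F, J = kernel.kinematics(u)
        dev, vol = kernel.strain_energy_split(F, J)
        stored = vol + (1.0 - sum(kernel.prony.g)) * dev
        if kernel.prony.n_terms:
            stored += kernel.branch_state(P_el, history)[0]
        record(record_times[next_rec], stored,
               0.5 * float((mass[:, None] * v * v).sum()))

    return Trajectory(
        times=np.asarray(times),
        displacements=np.asarray(snaps),
        nipple_positions=np.asarray(nipples),
        energy={
            "kinetic": np.asarray(E_kin),
            "strain": np.asarray(E_strain),
            "external_work": np.asarray(W_ext),
            "viscous_dissipation": np.asarray(D_visc),
            "contact_work": np.asarray(W_contact),
        },
        dt=dt,
    )


def select_stop_state(traj: Trajectory, target_nipple):
    """Closest-approach stopping criterion: the sample whose recorded nipple
    position minimizes the distance to the target (earliest on ties).

    Returns ``(t_star, displacement_snapshot, distance_m)``.
    """
    if traj.n_samples == 0:
        raise ValueError("empty trajectory")
    target = np.asarray(target_nipple, dtype=float).reshape(3)
    d = np.linalg.norm(traj.nipple_positions - target, axis=1)
    idx = int(np.argmin(d))  # argmin returns the first minimum: earliest tie
    return float(traj.times[idx]), traj.displacements[idx], float(d[idx])
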