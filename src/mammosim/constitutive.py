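"""Visco-hyperelastic material law.

Neo-Hookean strain energy and Cauchy stress, a Prony-series stress
relaxation function, and the internal-variable recurrence that applies the
relaxation to a deviatoric stress history.  All quantities are SI (Pa, s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PronySeries",
    "MaterialParams",
    "MaterialSet",
    "DeformationState",
    "neo_hookean_energy",
    "neo_hookean_stress",
    "relaxation_modulus",
    "visco_update",
]

_EYE = np.eye(3)


@dataclass(frozen=True)
class PronySeries:
    """Shear relaxation spectrum ``G(t) = G0 (1 - sum g_k (1 - exp(-t/tau_k)))``.

    Parameters
    ----------
    g : tuple of float
        Dimensionless modulus ratios ``g_k = G_k / G0``.
    tau : tuple of float
        Relaxation times (s), one per term.
    """

    g: tuple = ()
    tau: tuple = ()

    def __post_init__(self):
        g = tuple(float(v) for v in np.atleast_1d(np.asarray(self.g, dtype=float)))
        tau = tuple(float(v) for v in np.atleast_1d(np.asarray(self.tau, dtype=float)))
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "tau", tau)
        if len(g) != len(tau):
            raise ValueError("g and tau must have the same number of terms")
        if any(v < 0 for v in g):
            raise ValueError("modulus ratios g_k must be non-negative")
        if sum(g) >= 1.0:
            raise ValueError("sum of modulus ratios must be < 1 (long-term modulus > 0)")
        if any(t <= 0 for t in tau):
            raise ValueError("relaxation times must be positive")

    @property
    def n_terms(self) -> int:
        return len(self.g)

    @property
    def g_inf(self) -> float:
        """Long-term modulus ratio ``1 - sum g_k``."""
        return 1.0 - sum(self.g)

    def moduli(self, G0: float):
        """Per-term spring stiffness ``G_k = g_k G0`` and viscosity ``eta_k = G_k tau_k``."""
        G = np.asarray(self.g) * G0
        return G, G * np.asarray(self.tau)


@dataclass(frozen=True)
class MaterialParams:
    """One tissue: instantaneous shear modulus mu0 (== G0), bulk modulus K0,
    density rho, and optional Prony relaxation."""

    mu0: float
    K0: float
    rho: float = 1000.0
    prony: PronySeries = field(default_factory=PronySeries)

    def __post_init__(self):
        if self.mu0 <= 0:
            raise ValueError("mu0 must be positive")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.K0 < 50.0 * self.mu0:
            raise ValueError(
                f"K0 = {self.K0:g} violates the quasi-incompressibility contract "
                f"K0 >= 50*mu0 = {50 * self.mu0:g}"
            )

    @property
    def G0(self) -> float:
        """Instantaneous shear modulus (identical to mu0)."""
        return self.mu0

    @property
    def wave_speed(self) -> float:
        """Dilatational wave speed ``sqrt((K0 + 4 mu0 / 3) / rho)``."""
        return float(np.sqrt((self.K0 + 4.0 * self.mu0 / 3.0) / self.rho))


def make_material(mu: float, *, k_ratio: float = 100.0, rho: float = 1000.0,
                  g: float = 0.0, tau: float = 0.01) -> MaterialParams:
    """Convenience constructor from the run-config material block."""
    prony = PronySeries(g=(g,), tau=(tau,)) if g > 0 else PronySeries()
    return MaterialParams(mu0=mu, K0=k_ratio * mu, rho=rho, prony=prony)


@dataclass(frozen=True)
class MaterialSet:
    """Breast + skin pair with the skin modulus tied to the breast by a factor f."""

    breast: MaterialParams
    skin: MaterialParams
    f: float

    @classmethod
    def from_breast(cls, breast: MaterialParams, f: float) -> "MaterialSet":
        """Derive the skin as a scaled copy of the breast (mu_S = f * mu_B).

        The skin shares the breast's density, K0/mu0 ratio and relaxation
        spectrum; only the stiffness scale differs.
        """
        if f <= 0:
            raise ValueError("skin factor f must be positive")
        skin = MaterialParams(
            mu0=f * breast.mu0,
            K0=f * breast.K0,
            rho=breast.rho,
            prony=breast.prony,
        )
        return cls(breast=breast, skin=skin, f=f)

    def __post_init__(self):
        ratio = self.skin.mu0 / self.breast.mu0
        if not np.isclose(ratio, self.f, rtol=1e-12):
            raise ValueError("skin/breast modulus ratio inconsistent with factor f")


class InvertedElementError(ValueError):
    """Deformation gradient with non-positive determinant."""


@dataclass
class DeformationState:
    """Kinematic quantities derived from a deformation gradient.

    Supports batched input: ``F`` may have shape ``(..., 3, 3)``.
    """

    F: np.ndarray
    J: np.ndarray
    B_bar: np.ndarray
    I1_bar: np.ndarray

    @classmethod
    def from_F(cls, F: np.ndarray) -> "DeformationState":
        F = np.asarray(F, dtype=float)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise InvertedElementError(
                f"deformation gradient has non-positive determinant (min J = {np.min(J):g})"
            )
        B = F @ np.swapaxes(F, -1, -2)
        B_bar = B / (J ** (2.0 / 3.0))[..., None, None] if B.ndim > 2 else B / J ** (2.0 / 3.0)
        I1_bar = np.trace(B_bar, axis1=-2, axis2=-1)
        return cls(F=F, J=J, B_bar=B_bar, I1_bar=I1_bar)


def neo_hookean_energy(state: DeformationState, mat: MaterialParams) -> np.ndarray:
    """Strain energy density ``(mu0/2)(I1_bar - 3) + (K0/2)(J - 1)^2`` in Pa."""
    return 0.5 * mat.mu0 * (state.I1_bar - 3.0) + 0.5 * mat.K0 * (state.J - 1.0) ** 2


def neo_hookean_stress(state: DeformationState, mat: MaterialParams) -> np.ndarray:
    """Cauchy stress ``sigma = (mu0 / J^{5/3}) dev(B) + K0 (J - 1) I``.

    Symmetric by construction and consistent with `neo_hookean_energy`
    (finite-difference checked in the test suite).
    """
    J = np.asarray(state.J)
    B = state.F @ np.swapaxes(state.F, -1, -2)
    trB = np.trace(B, axis1=-2, axis2=-1)
    devB = B - (trB / 3.0)[..., None, None] * _EYE if B.ndim > 2 else B - (trB / 3.0) * _EYE
    scale = (mat.mu0 / J ** (5.0 / 3.0))[..., None, None] if B.ndim > 2 else mat.mu0 / J ** (5.0 / 3.0)
    p = (mat.K0 * (J - 1.0))[..., None, None] if B.ndim > 2 else mat.K0 * (J - 1.0)
    return scale * devB + p * _EYE


def relaxation_modulus(t, mat: MaterialParams) -> np.ndarray:
    """Shear relaxation function ``G(t)``, monotone non-increasing from G0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("relaxation time argument must be non-negative")
    G0 = mat.G0
    decay = np.zeros_like(t)
    for g_k, tau_k in zip(mat.prony.g, mat.prony.tau):
        decay = decay + g_k * (1.0 - np.exp(-t / tau_k))
    return G0 * (1.0 - decay)


def visco_update(S_dev_new, S_dev_old, history, dt: float, prony: PronySeries):
    """One step of the Prony internal-variable recurrence.

    The relaxed deviatoric stress is the hereditary convolution of the
    elastic stress history with the dimensionless relaxation function,

        sigma(t) = g_inf S(t) + sum_k g_k int_0^t exp(-(t-s)/tau_k) dS(s),

    evaluated exactly for stress histories piecewise linear in time.  Each
    term carries one history tensor ``h_k`` (the stress deficit of that
    Maxwell branch) so that the returned stress is ``S^{n+1} - sum_k
    h_k^{n+1}``; with ``x = dt/tau_k`` and ``alpha = (1 - exp(-x))/x`` the
    update reads::

        h_k^{n+1} = exp(-x) h_k^n
                    + g_k (S^{n+1} - exp(-x) S^n - alpha (S^{n+1} - S^n))

    A step load held for t >> tau relaxes to ``(1 - sum g_k) S``.

    Parameters are arbitrary ndarrays (scalars, tensors, batches); the
    history is a list with one array per Prony term, zeros at t = 0.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    S_new = np.asarray(S_dev_new, dtype=float)
    S_old = np.asarray(S_dev_old, dtype=float)
    dS = S_new - S_old
    new_history = []
    relaxed = S_new.copy()
    for k, (g_k, tau_k) in enumerate(zip(prony.g, prony.tau)):
        x = dt / tau_k
        decay = np.exp(-x)
        alpha = (1.0 - decay) / x
        h_prev = history[k] if history is not None else 0.0
        h_new = decay * h_prev + g_k * (S_new - decay * S_old - alpha * dS)
        new_history.append(h_new)
        relaxed = relaxed - h_new
    return relaxed, new_history
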