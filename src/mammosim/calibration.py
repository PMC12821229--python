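"""Patient-specific material identification.

Nipple-distance objective, the piecewise viscous-modulus rule g(mu_B),
bounded hybrid simulated annealing over the breast shear modulus (Gaussian
proposals + Metropolis acceptance + golden-section refinement), and the
two-stage calibration with an exhaustive skin-factor search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from mammosim.constitutive import MaterialSet, make_material
from mammosim.solver import SimulationConfig, run_simulation, select_stop_state

__all__ = [
    "CalibrationConfig",
    "CalibrationResult",
    "g_from_mu",
    "nipple_objective",
    "anneal_mu",
    "calibrate",
]


@dataclass(frozen=True)
class CalibrationConfig:
    """Bounds, thresholds and annealing schedule.

    The 5 mm stop threshold is the adult-breast-scale default; phantom-scale
    experiments override it (2 mm on the default phantom).
    """

    mu_bounds: tuple = (160.0, 300.0)
    stop_threshold_mm: float = 5.0
    f_candidates: tuple = (4.0, 6.0, 8.0, 10.0, 12.0)
    tau: float = 0.01
    friction: float = 0.5
    k_ratio: float = 100.0
    initial_temperature: float = 20.0
    cooling: float = 0.95
    proposal_sigma: float = 20.0
    max_evaluations: int = 40
    golden_steps: int = 10
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.mu_bounds
        if not 0 < lo < hi:
            raise ValueError("mu bounds must be positive and ordered")
        if self.stop_threshold_mm <= 0:
            raise ValueError("stop threshold must be positive")
        if len(self.f_candidates) < 1:
            raise ValueError("at least one skin-factor candidate required")


@dataclass
class CalibrationResult:
    mu_B: float
    g_B: float
    f: float
    nipple_distance_mm: float
    n_evaluations: int
    t_star: float
    seed: int
    converged: bool = True
    history: list = field(default_factory=list)


def g_from_mu(mu_B: float) -> float:
    """Piecewise viscous modulus ratio: 0.8 on [160, 230), 0.5 on [230, 300),
    0.1 for mu_B >= 300 Pa."""
    if mu_B < 160.0:
        raise ValueError(f"mu_B = {mu_B:g} Pa is below the calibrated rule's range (>= 160 Pa)")
    if mu_B < 230.0:
        return 0.8
    if mu_B < 300.0:
        return 0.5
    return 0.1


def nipple_objective(mu_B: float, model, target_nipple, f: float,
                     sim_config: SimulationConfig,
                     config: CalibrationConfig | None = None) -> float:
    """Nipple misfit (mm) of one forward simulation at (mu_B, f).

    Builds the material set with ``g_B = g_from_mu(mu_B)`` and
    ``mu_S = f * mu_B``, runs the explicit solver, applies the closest-
    approach stop criterion against the target nipple, and returns the
    residual distance in millimetres.  Deterministic per (mu_B, f, config).
    """
    config = config or CalibrationConfig()
    g_B = g_from_mu(mu_B)
    try:
        materials = MaterialSet.from_breast(
            make_material(mu_B, g=g_B, tau=config.tau, k_ratio=config.k_ratio), f=f)
        traj = run_simulation(model.with_materials(materials), sim_config)
    except Exception as exc:
        raise RuntimeError(f"simulation failed at mu_B = {mu_B:g} Pa: {exc}") from exc
    _, _, dist = select_stop_state(traj, target_nipple)
    return dist * 1000.0


def anneal_mu(objective, config: CalibrationConfig):
    """Bounded hybrid simulated annealing over mu_B.

    Gaussian proposals clipped to the bounds, geometric cooling, Metropolis
    acceptance, then golden-section refinement around the incumbent (the
    "hybrid" step).  Exits early whenever the objective drops at or below
    the stop threshold.  Returns ``(mu_star, n_evaluations, history)`` where
    history is the list of (mu, value) in evaluation order.
    """
    lo, hi = config.mu_bounds
    rng = np.random.default_rng(config.seed)
    history: list = []
    cache: dict = {}

    def f(mu):
        mu = float(np.clip(mu, lo, hi))
        key = round(mu, 9)
        if key not in cache:
            try:
                cache[key] = objective(mu)
            except RuntimeError as exc:
                # element collapse at an extreme parameter combination:
                # treat as an infinitely bad trial, not a fatal error
                warnings.warn(str(exc))
                cache[key] = np.inf
            history.append((mu, cache[key]))
        return cache[key]

    current = 0.5 * (lo + hi)
    current_val = f(current)
    best, best_val = current, current_val
    T = config.initial_temperature
    while len(history) < config.max_evaluations and best_val > config.stop_threshold_mm:
        prop = float(np.clip(current + rng.normal(0.0, config.proposal_sigma), lo, hi))
        val = f(prop)
        if val < best_val:
            best, best_val = prop, val
        if val <= current_val or rng.random() < np.exp(-(val - current_val) / max(T, 1e-12)):
            current, current_val = prop, val
        T *= config.cooling

    # golden-section refinement in a bracket around the incumbent
    if best_val > config.stop_threshold_mm and config.golden_steps > 0:
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        a = max(lo, best - config.proposal_sigma)
        b = min(hi, best + config.proposal_sigma)
        c = b - gr * (b - a)
        d = a + gr * (b - a)
        fc, fd = f(c), f(d)
        for _ in range(config.golden_steps - 2):
            if best_val <= config.stop_threshold_mm:
                break
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - gr * (b - a)
                fc = f(c)
            else:
                a, c, fc = c, d, fd
                d = a + gr * (b - a)
                fd = f(d)
            for mu, val in ((c, fc), (d, fd)):
                if val < best_val:
                    best, best_val = mu, val

    if best_val > config.stop_threshold_mm and len(history) >= config.max_evaluations:
        warnings.warn(
            f"annealing exhausted {len(history)} evaluations without reaching "
            f"the {config.stop_threshold_mm:g} mm threshold (best "
            f"{best_val:.2f} mm at mu_B = {best:.1f} Pa)")
    return best, len(history), history


def calibrate(model, target_nipple, config: CalibrationConfig,
              sim_config: SimulationConfig | None = None,
              f_default: float | None = None) -> CalibrationResult:
    """Two-stage identification: anneal mu_B at a fixed skin factor, then
    exhaustively search the skin-factor candidates at the annealed mu_B
    (ties resolved toward the smaller factor)."""
    sim_config = sim_config or SimulationConfig()
    cands = tuple(sorted(config.f_candidates))
    if f_default is None:
        f_default = cands[len(cands) // 2]
    evals = 0

    def obj(mu, f=f_default):
        nonlocal evals
        evals += 1
        return nipple_objective(mu, model, target_nipple, f, sim_config, config)

    mu_star, n_anneal, history = anneal_mu(obj, config)
    base_val = dict((round(m, 9), v) for m, v in history)[round(float(np.clip(mu_star, *config.mu_bounds)), 9)]

    best_f, best_val = f_default, base_val
    failures = 0
    for f_cand in cands:
        if f_cand == f_default:
            val = base_val
        else:
            try:
                val = obj(mu_star, f=f_cand)
            except RuntimeError:
                failures += 1
                continue
            history.append((mu_star, val))
        if val < best_val - 1e-12 or (abs(val - best_val) <= 1e-12 and f_cand < best_f):
            best_f, best_val = f_cand, val
    if failures == len(cands):
        raise RuntimeError("every skin-factor candidate failed to simulate")

    # recover t* of the selected state
    g_B = g_from_mu(mu_star)
    materials = MaterialSet.from_breast(
        make_material(mu_star, g=g_B, tau=config.tau, k_ratio=config.k_ratio), f=best_f)
    traj = run_simulation(model.with_materials(materials), sim_config)
    t_star, _, dist = select_stop_state(traj, target_nipple)

    return CalibrationResult(
        mu_B=float(mu_star),
        g_B=g_B,
        f=float(best_f),
        nipple_distance_mm=dist * 1000.0,
        n_evaluations=evals,
        t_star=t_star,
        seed=config.seed,
        converged=best_val <= config.stop_threshold_mm,
        history=history,
    )
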