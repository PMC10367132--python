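"""Performance objectives for circuit designs.

Two families are provided. The cost-benefit loss balances production against
expression burden,

    J = alpha1 * J_prod + alpha2 * J_cost,

with J_prod the reciprocal of the mean production flux over the final window
(so minimizing J maximizes flux) and J_cost the time-average of total
heterologous protein expressed during the culture. The dynamic-response loss
targets trajectory shape,

    J = J_os + alpha * J_rt (+ oscillation penalty),

where J_os is the percent overshoot of the product above its steady state,
J_rt the 50%-rise time normalized by the integration horizon, and sustained
oscillations (>= 2 prominent peaks in the final half of the trajectory) add a
large regularization constant that excludes oscillatory designs from the
search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .architectures import ArchitectureSpec, ConfigurationError, DomainError
from .models import PENALTY_LOSS, PathwayModel, SimulationResult, simulate

__all__ = [
    "ObjectiveSpec",
    "cost_benefit_loss",
    "cost_benefit_components",
    "rise_time",
    "overshoot",
    "oscillation_penalty",
    "dynamic_response_loss",
    "calibrate_weights",
    "default_objective_spec",
    "make_objective",
]


@dataclass(frozen=True)
class ObjectiveSpec:
    """Loss definition; exactly the fields for its kind are meaningful."""

    kind: str = "cost_benefit"            # cost_benefit | dynamic_response
    alpha1: float = 1.0                   # weight on J_prod
    alpha2: float = 1.0                   # weight on J_cost
    alpha: float = 1.0                    # weight on J_rt (dynamic response)
    flux_window: float = 0.10             # final fraction of horizon for mean flux
    ss_window: float = 0.05               # final fraction defining steady state
    eps: float = 1e-9                     # reciprocal guard
    oscillation_constant: float = 1e6     # added when oscillation is detected
    peak_prominence_frac: float = 0.05    # prominence threshold, x trajectory mean
    min_peaks: int = 2
    response_state: str = "FA"            # trajectory used by dynamic response

    def __post_init__(self) -> None:
        if self.kind not in ("cost_benefit", "dynamic_response"):
            raise ConfigurationError(f"unknown objective kind {self.kind!r}")
        if min(self.alpha1, self.alpha2, self.alpha) <= 0:
            raise ConfigurationError("objective weights must be positive")


def _final_window(t: np.ndarray, frac: float) -> np.ndarray:
    cutoff = t[-1] - frac * (t[-1] - t[0])
    mask = t >= cutoff
    if not mask.any():
        mask[-1] = True
    return mask


def cost_benefit_components(
    result: SimulationResult, model: PathwayModel, spec: ObjectiveSpec
) -> tuple[float, float]:
    """(J_prod, J_cost) for a successful simulation."""
    flux = model.product_flux(result.y)
    mask = _final_window(result.t, spec.flux_window)
    j_prod = 1.0 / (float(flux[mask].mean()) + spec.eps)
    total_e = model.enzyme_cost(result.y)
    horizon = result.t[-1] - result.t[0]
    j_cost = float(np.trapezoid(total_e, result.t)) / horizon
    return j_prod, j_cost


def cost_benefit_loss(
    result: SimulationResult, model: PathwayModel, spec: ObjectiveSpec
) -> float:
    """J = alpha1 * J_prod + alpha2 * J_cost (penalty for failed simulations)."""
    if not result.success:
        return PENALTY_LOSS
    j_prod, j_cost = cost_benefit_components(result, model, spec)
    return spec.alpha1 * j_prod + spec.alpha2 * j_cost


def _steady_state_value(traj: np.ndarray, t: np.ndarray, frac: float) -> float:
    return float(traj[_final_window(t, frac)].mean())


def rise_time(
    traj: np.ndarray,
    tgrid: np.ndarray,
    ss: float | None = None,
    ss_window: float = 0.05,
) -> float:
    """Normalized 50% rise time in [0, 1].

    First grid time at which the trajectory reaches half its steady-state
    value (last-window mean unless ``ss`` is given), divided by the horizon;
    1 if the half level is never reached.
    """
    traj = np.asarray(traj, dtype=float)
    tgrid = np.asarray(tgrid, dtype=float)
    if traj.size == 0 or traj.size != tgrid.size:
        raise DomainError("rise_time needs a non-empty trajectory matching the grid")
    if ss is None:
        ss = _steady_state_value(traj, tgrid, ss_window)
    hits = np.flatnonzero(traj >= 0.5 * ss)
    if hits.size == 0:
        return 1.0
    horizon = tgrid[-1] - tgrid[0]
    return float((tgrid[hits[0]] - tgrid[0]) / horizon)


def overshoot(
    traj: np.ndarray,
    tgrid: np.ndarray | None = None,
    ss: float | None = None,
    ss_window: float = 0.05,
) -> float:
    """Percent excess of the trajectory maximum over its steady state,
    floored at zero."""
    traj = np.asarray(traj, dtype=float)
    if traj.size == 0:
        raise DomainError("overshoot needs a non-empty trajectory")
    if ss is None:
        if tgrid is None:
            tgrid = np.arange(traj.size, dtype=float)
        ss = _steady_state_value(traj, np.asarray(tgrid, dtype=float), ss_window)
    if ss <= 0:
        raise DomainError(f"steady-state value must be positive, got {ss}")
    return max(100.0 * (float(traj.max()) - ss) / ss, 0.0)


def oscillation_penalty(
    traj: np.ndarray, tgrid: np.ndarray, spec: ObjectiveSpec
) -> float:
    """Large constant if >= ``min_peaks`` prominent peaks appear in the final
    half of the trajectory, else 0 (applied once; idempotent by construction)."""
    traj = np.asarray(traj, dtype=float)
    half = traj[traj.size // 2 :]
    scale = float(np.abs(traj).mean())
    if scale <= 0:
        return 0.0
    peaks, _ = find_peaks(half, prominence=spec.peak_prominence_frac * scale)
    return spec.oscillation_constant if peaks.size >= spec.min_peaks else 0.0


def dynamic_response_loss(
    result: SimulationResult, spec: ObjectiveSpec
) -> float:
    """J = J_os + alpha * J_rt, plus the oscillation penalty when triggered."""
    if not result.success:
        return PENALTY_LOSS
    traj = result.state(spec.response_state)
    ss = _steady_state_value(traj, result.t, spec.ss_window)
    if ss <= 0:
        return PENALTY_LOSS  # no production at all: worst non-oscillatory case
    j_os = overshoot(traj, result.t, ss=ss)
    j_rt = rise_time(traj, result.t, ss=ss)
    return j_os + spec.alpha * j_rt + oscillation_penalty(traj, result.t, spec)


def default_objective_spec(model: PathwayModel, kind: str = "cost_benefit") -> ObjectiveSpec:
    """Objective spec with the model's calibrated cost-benefit weights."""
    a1, a2 = model.default_cost_weights
    return ObjectiveSpec(kind=kind, alpha1=a1, alpha2=a2)


def make_objective(
    model: PathwayModel,
    spec: ObjectiveSpec,
    t_span: tuple[float, float] | None = None,
) -> Callable[[ArchitectureSpec, Sequence[float]], float]:
    """Total objective over the design space: simulate then score; failed
    integrations map to the penalty loss."""

    def objective(arch: ArchitectureSpec, p_c: Sequence[float]) -> float:
        result = simulate(model, arch, p_c, t_span=t_span)
        if spec.kind == "cost_benefit":
            return cost_benefit_loss(result, model, spec)
        return dynamic_response_loss(result, spec)

    objective.model = model
    objective.spec = spec
    return objective


def calibrate_weights(
    model: PathwayModel,
    sampler: Callable[[np.random.Generator], tuple[ArchitectureSpec, np.ndarray]] | None = None,
    n_samples: int = 48,
    seed: int = 0,
    spec: ObjectiveSpec | None = None,
) -> tuple[float, float]:
    """Choose (alpha1, alpha2) so the two cost-benefit components carry similar
    weight: alpha1 = 1 and alpha2 = median(J_prod) / median(J_cost) over
    uniformly sampled designs, making the medians of alpha1*J_prod and
    alpha2*J_cost equal. Deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    spec = spec or ObjectiveSpec(kind="cost_benefit")
    archs = model.architectures()
    lo = np.array([b[0] for b in model.pc_bounds])
    hi = np.array([b[1] for b in model.pc_bounds])

    prods, costs = [], []
    for _ in range(n_samples):
        if sampler is None:
            arch = archs[rng.integers(len(archs))]
            p_c = rng.uniform(lo, hi)
        else:
            arch, p_c = sampler(rng)
        result = simulate(model, arch, p_c)
        if not result.success:
            continue
        j_prod, j_cost = cost_benefit_components(result, model, spec)
        prods.append(j_prod)
        costs.append(j_cost)
    if not prods:
        raise RuntimeError("weight calibration failed: no successful simulations")
    med_prod, med_cost = float(np.median(prods)), float(np.median(costs))
    if med_cost <= 0:
        raise RuntimeError("weight calibration failed: zero median enzyme cost")
    return 1.0, med_prod / med_cost
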