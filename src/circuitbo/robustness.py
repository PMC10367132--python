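"""Robustness machinery: Latin hypercube parameter sweeps, solution-ensemble
statistics, PCA projection of optimal designs, and objective-weight trade-off
curves.

A perturbation sweep re-optimizes the full design (architecture + parameters)
at each sampled kinetic/toxicity perturbation and compares the winning designs
against a background ensemble re-run at nominal parameters with fresh seeds,
mirroring a paired background-vs-perturbed comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc
from sklearn.decomposition import PCA

from .architectures import ConfigurationError, hill_response
from .models import PathwayModel, build_model
from .objectives import (
    ObjectiveSpec,
    default_objective_spec,
    make_objective,
    overshoot,
    rise_time,
)
from .optimizers import OptimizerConfig, SearchSpace, bayesopt_minimize

__all__ = [
    "PerturbationEnsemble",
    "lhs_sample",
    "perturbation_sweep",
    "ensemble_summary",
    "pca_project",
    "alpha_sweep_tradeoff",
]

#: relative positivity floor standing in for a "-100%" perturbation
PERTURB_FLOOR = 1e-6


@dataclass
class EnsembleRecord:
    sample_id: int
    seed: int
    perturbed: dict[str, float]
    arch_name: str
    loss: float
    p_c: np.ndarray
    failed: bool = False


@dataclass
class PerturbationEnsemble:
    """Optimal designs across LHS-perturbed parameters plus matched
    nominal-parameter background runs."""

    param_names: tuple[str, ...]
    records: list[EnsembleRecord] = field(default_factory=list)
    background: list[EnsembleRecord] = field(default_factory=list)

    def to_dataframe(self, which: str = "perturbed") -> pd.DataFrame:
        recs = self.records if which == "perturbed" else self.background
        rows = []
        for r in recs:
            rows.append({
                "sample_id": r.sample_id, "seed": r.seed,
                "architecture": r.arch_name, "loss": r.loss, "failed": r.failed,
                **{f"perturbed_{k}": v for k, v in r.perturbed.items()},
                **{f"pc_{i}": v for i, v in enumerate(r.p_c)},
            })
        return pd.DataFrame(rows)


def lhs_sample(
    bounds: Sequence[tuple[float, float]], n: int, seed: int
) -> np.ndarray:
    """Plain (maximin-free) Latin hypercube sample: n points, one per
    equal-width stratum in every dimension, scaled to the given bounds."""
    if n < 1:
        raise ConfigurationError("LHS needs n >= 1")
    bounds = list(bounds)
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    unit = sampler.random(n)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return qmc.scale(unit, lo, hi)


def perturbation_sweep(
    model_id: str,
    params: Mapping[str, tuple[float, float]] | Sequence[str],
    n: int,
    opt_config: OptimizerConfig,
    objective_spec: ObjectiveSpec | None = None,
    seed: int = 0,
    base_overrides: Mapping[str, float] | None = None,
    background: bool = True,
) -> PerturbationEnsemble:
    """Optimize the full design at each of ``n`` LHS-perturbed parameter sets.

    ``params`` is either a mapping name -> (lo, hi) or a sequence of names, in
    which case each range defaults to (PERTURB_FLOOR * nominal, 2 * nominal) —
    the +/-100% perturbation with a positivity floor replacing the degenerate
    -100% endpoint. Individual failed runs are recorded, not fatal. ``n``
    background runs at nominal parameters (fresh seeds) are always included.
    """
    nominal_model = build_model(model_id, overrides=base_overrides)
    spec = objective_spec or default_objective_spec(nominal_model)

    if isinstance(params, Mapping):
        names = tuple(params)
        ranges = [tuple(params[k]) for k in names]
    else:
        names = tuple(params)
        all_nominal = {**nominal_model.kinetics,
                       "lambda": nominal_model.dilution, "V_in": nominal_model.v_in,
                       "t_l": nominal_model.toxicity.t_l,
                       "t_a": nominal_model.toxicity.t_a,
                       "t_p": nominal_model.toxicity.t_p}
        missing = [k for k in names if k not in all_nominal]
        if missing:
            raise ConfigurationError(f"unknown parameters {missing} for {model_id}")
        ranges = [(PERTURB_FLOOR * all_nominal[k], 2.0 * all_nominal[k]) for k in names]

    points = lhs_sample(ranges, n, seed=seed)
    ensemble = PerturbationEnsemble(param_names=names)
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=2 * n)

    def run_one(sample_id, run_seed, overrides) -> EnsembleRecord:
        merged = dict(base_overrides or {})
        merged.update(overrides)
        try:
            model = build_model(model_id, overrides=merged or None)
            objective = make_objective(model, spec)
            space = SearchSpace.from_model(model)
            cfg = replace(opt_config, seed=int(run_seed))
            history = bayesopt_minimize(objective, space, cfg)
            best = history.best_trial()
            return EnsembleRecord(sample_id, int(run_seed), dict(overrides),
                                  best.arch_name, best.loss, best.p_c)
        except Exception:  # individual run failures are data, not errors
            return EnsembleRecord(sample_id, int(run_seed), dict(overrides),
                                  "failed", math.inf,
                                  np.full(nominal_model.n_continuous, np.nan),
                                  failed=True)

    for i in range(n):
        overrides = {k: float(points[i, d]) for d, k in enumerate(names)}
        ensemble.records.append(run_one(i, run_seeds[i], overrides))
    if background:
        for i in range(n):
            ensemble.background.append(run_one(i, run_seeds[n + i], {}))
    return ensemble


def ensemble_summary(
    ensemble: PerturbationEnsemble,
    model: PathwayModel | None = None,
    ligand_grid: np.ndarray | None = None,
    which: str = "perturbed",
) -> dict:
    """Architecture win fractions, loss statistics, and per-architecture
    dose-response parameter statistics (mean/SD of each optimal continuous
    parameter conditioned on the winning architecture). With a model and a
    ligand grid, mean dose-response curves of the winning designs are also
    evaluated."""
    recs = [r for r in (ensemble.records if which == "perturbed" else ensemble.background)
            if not r.failed]
    if not recs:
        raise ConfigurationError("empty ensemble")
    n = len(recs)
    freqs: dict[str, float] = {}
    for r in recs:
        freqs[r.arch_name] = freqs.get(r.arch_name, 0.0) + 1.0 / n
    losses = np.array([r.loss for r in recs])
    by_arch: dict[str, dict] = {}
    for name in freqs:
        pcs = np.array([r.p_c for r in recs if r.arch_name == name])
        by_arch[name] = {"mean": pcs.mean(axis=0).tolist(),
                         "sd": pcs.std(axis=0, ddof=1).tolist() if len(pcs) > 1
                               else [0.0] * pcs.shape[1],
                         "n": len(pcs)}
    out = {
        "n": n,
        "architecture_frequencies": dict(sorted(freqs.items())),
        "loss": {"mean": float(losses.mean()), "sd": float(losses.std(ddof=1))
                 if n > 1 else 0.0, "min": float(losses.min()),
                 "max": float(losses.max())},
        "parameters_by_architecture": by_arch,
    }
    if model is not None and ligand_grid is not None:
        out["dose_response_curves"] = _mean_dose_response(recs, model, ligand_grid)
    return out


def _mean_dose_response(recs, model: PathwayModel, grid: np.ndarray) -> dict:
    curves: dict[str, list[np.ndarray]] = {}
    for r in recs:
        try:
            arch = model.architecture_by_name(r.arch_name)
        except ConfigurationError:
            continue
        if arch.encoding_kind != "matrix":
            continue
        params = model.promoter_params(r.p_c, arch)
        for j, prom in enumerate(model.regulatory_spec.promoters):
            ctrl = arch.controller_of(j)
            if ctrl is None:
                continue
            mode = "repression" if ctrl[1] < 0 else "activation"
            curve = np.array([hill_response(s, params[prom.name], mode) for s in grid])
            curves.setdefault(f"{r.arch_name}:{prom.name}", []).append(curve)
    return {k: np.mean(v, axis=0).tolist() for k, v in curves.items()}


def pca_project(matrix: np.ndarray, scale: bool = True) -> dict:
    """Top-2 principal-component projection of an ensemble parameter matrix.

    Columns are centered (and unit-variance scaled by default; zero-variance
    columns are dropped with a warning). Returns scores, loadings and
    explained-variance fractions."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ConfigurationError("pca_project needs >=3 samples and >=2 dimensions")
    keep = np.flatnonzero(X.std(axis=0) > 0)
    if keep.size < X.shape[1]:
        import warnings

        warnings.warn(f"dropping {X.shape[1] - keep.size} zero-variance dimension(s)",
                      stacklevel=2)
    if keep.size < 2:
        raise ConfigurationError("fewer than 2 informative dimensions")
    X = X[:, keep]
    X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0)
    pca = PCA(n_components=2)
    scores = pca.fit_transform(X)
    return {
        "scores": scores,
        "loadings": pca.components_,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "kept_dimensions": keep,
    }


def alpha_sweep_tradeoff(
    model: PathwayModel,
    alphas: Sequence[float],
    opt_config: OptimizerConfig,
    objective_spec: ObjectiveSpec | None = None,
) -> pd.DataFrame:
    """Overshoot / rise-time trade-off curve: for each weight alpha, run the
    Bayesian optimizer on the dynamic-response loss and re-evaluate the
    winner's raw overshoot and rise time. Per-alpha failures are recorded as
    NaN rows."""
    from .models import simulate

    base = objective_spec or ObjectiveSpec(kind="dynamic_response")
    rows = []
    for i, a in enumerate(alphas):
        spec = replace(base, alpha=float(a))
        objective = make_objective(model, spec)
        space = SearchSpace.from_model(model)
        cfg = replace(opt_config, seed=opt_config.seed + i)
        try:
            history = bayesopt_minimize(objective, space, cfg)
            best = history.best_trial()
            arch = space.architectures[best.arch_index]
            result = simulate(model, arch, best.p_c)
            traj = result.state(spec.response_state)
            rows.append({"alpha": a, "architecture": best.arch_name,
                         "loss": best.loss,
                         "overshoot": overshoot(traj, result.t),
                         "rise_time": rise_time(traj, result.t),
                         **{f"pc_{d}": v for d, v in enumerate(best.p_c)}})
        except Exception:
            rows.append({"alpha": a, "architecture": "failed", "loss": np.nan,
                         "overshoot": np.nan, "rise_time": np.nan})
    return pd.DataFrame(rows)
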