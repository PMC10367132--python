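"""Mixed-integer Bayesian optimization of circuit designs.

The surrogate is a tree-structured Parzen estimator (TPE): observed trials are
split into a "good" set (the gamma best losses) and a "bad" set, kernel
density estimators l(x) and g(x) are fit to each (Gaussian Parzen windows on
continuous dimensions, re-weighted categorical distributions on the
architecture dimension, each mixed with the uniform prior), and the next
design is the candidate maximizing the density ratio l(x)/g(x) among draws
from l — the standard Expected-Improvement-equivalent acquisition for TPE.

Baselines (random search, per-architecture grid search, a generational
genetic algorithm, and multi-start bounded quasi-Newton local search) share
the same trial-history bookkeeping so optimizers can be compared at equal
evaluation budgets.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .architectures import ArchitectureSpec, ConfigurationError

__all__ = [
    "SearchSpace",
    "OptimizerConfig",
    "Trial",
    "TrialHistory",
    "tpe_propose",
    "bayesopt_minimize",
    "baseline_optimize",
    "landscape_grid",
    "exploration_stats",
]

Objective = Callable[[ArchitectureSpec, np.ndarray], float]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchSpace:
    """Joint (p_c, p_d) domain: box-bounded continuous dimensions with uniform
    priors and one categorical dimension over the feasible architectures."""

    bounds: tuple[tuple[float, float], ...]
    architectures: tuple[ArchitectureSpec, ...]
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.architectures:
            raise ConfigurationError("architecture set must be non-empty")
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigurationError(f"invalid bounds ({lo}, {hi})")

    @classmethod
    def from_model(cls, model) -> "SearchSpace":
        return cls(
            bounds=tuple(model.pc_bounds),
            architectures=tuple(model.architectures()),
            names=tuple(model.pc_names),
        )

    @property
    def n_continuous(self) -> int:
        return len(self.bounds)

    @property
    def lo(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def hi(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])

    def sample_prior(self, rng: np.random.Generator) -> tuple[int, np.ndarray]:
        return int(rng.integers(len(self.architectures))), rng.uniform(self.lo, self.hi)


@dataclass(frozen=True)
class OptimizerConfig:
    """TPE loop settings. ``gamma`` is the number of trials defining the good
    set once enough history exists (top-gamma observations); with fewer than
    2*gamma trials the good set is the best ceil(gamma_quantile * n)."""

    n_iterations: int = 200
    gamma: int = 15
    gamma_quantile: float = 0.25
    n_startup: int = 20
    n_candidates: int = 24
    seed: int = 0
    prior_weight: float = 1.0
    #: fit architecture-conditional Parzen densities for the continuous
    #: dimensions; the default pools observations across architectures,
    #: matching the flat joint encoding of the search space
    conditional: bool = False

    def __post_init__(self) -> None:
        if min(self.n_iterations, self.gamma, self.n_startup, self.n_candidates) <= 0:
            raise ConfigurationError("optimizer counts must be positive")


@dataclass
class Trial:
    index: int
    arch_index: int
    arch_name: str
    p_c: np.ndarray
    loss: float
    status: str = "ok"

    def __post_init__(self) -> None:
        if not np.isfinite(self.loss):
            raise ConfigurationError("trial losses must be finite (penalty-mapped)")


@dataclass
class TrialHistory:
    """Ordered trial records with best-so-far bookkeeping."""

    trials: list[Trial] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def append(self, trial: Trial) -> None:
        self.trials.append(trial)

    @property
    def losses(self) -> np.ndarray:
        return np.array([t.loss for t in self.trials])

    def best_trial(self) -> Trial:
        if not self.trials:
            raise ConfigurationError("empty history")
        losses = self.losses
        return self.trials[int(np.argmin(losses))]  # first-encountered argmin

    def best_trace(self) -> np.ndarray:
        return np.minimum.accumulate(self.losses)

    def architecture_fractions(self) -> dict[str, float]:
        counts: dict[str, int] = {}
        for t in self.trials:
            counts[t.arch_name] = counts.get(t.arch_name, 0) + 1
        n = len(self.trials)
        return {k: v / n for k, v in sorted(counts.items())}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "iteration": t.index,
                "architecture": t.arch_name,
                "arch_index": t.arch_index,
                "loss": t.loss,
                "status": t.status,
                **{f"pc_{i}": v for i, v in enumerate(t.p_c)},
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "meta": self.meta,
            "trials": [
                {
                    "index": t.index,
                    "arch_index": t.arch_index,
                    "arch_name": t.arch_name,
                    "p_c": [float(v) for v in t.p_c],
                    "loss": float(t.loss),
                    "status": t.status,
                }
                for t in self.trials
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TrialHistory":
        hist = cls(meta=dict(payload.get("meta", {})))
        for d in payload["trials"]:
            hist.append(
                Trial(
                    index=d["index"],
                    arch_index=d["arch_index"],
                    arch_name=d["arch_name"],
                    p_c=np.asarray(d["p_c"], dtype=float),
                    loss=d["loss"],
                    status=d.get("status", "ok"),
                )
            )
        return hist


# ---------------------------------------------------------------------------
# Parzen estimators
# ---------------------------------------------------------------------------

_SQRT2PI = math.sqrt(2.0 * math.pi)


class _Parzen1D:
    """Gaussian Parzen-window density on a bounded interval, mixed with one
    uniform prior component; bandwidths follow the adjacent-spacing heuristic
    (each kernel as wide as the larger gap to its neighbours, clipped)."""

    def __init__(self, obs: np.ndarray, lo: float, hi: float, prior_weight: float = 1.0):
        self.lo, self.hi = lo, hi
        span = hi - lo
        obs = np.sort(np.asarray(obs, dtype=float))
        self.mus = obs
        if obs.size:
            padded = np.concatenate([[lo], obs, [hi]])
            left = padded[1:-1] - padded[:-2]
            right = padded[2:] - padded[1:-1]
            sig = np.maximum(left, right)
            min_sig = span / min(100.0, 1.0 + obs.size * 2.0)
            self.sigmas = np.clip(sig, min_sig, span)
        else:
            self.sigmas = np.empty(0)
        n = obs.size
        self.w_prior = prior_weight / (n + prior_weight)
        self.w_each = (1.0 - self.w_prior) / n if n else 0.0
        if n:
            from scipy.stats import norm

            # truncated-normal normalization over [lo, hi], fixed per kernel
            mass = norm.cdf((hi - self.mus) / self.sigmas) - norm.cdf(
                (lo - self.mus) / self.sigmas
            )
            self._log_norm = -np.log(self.sigmas * _SQRT2PI) - np.log(
                np.clip(mass, 1e-12, None)
            )

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        out = rng.uniform(self.lo, self.hi, size=size)
        if self.mus.size:
            use_kernel = rng.uniform(size=size) >= self.w_prior
            idx = rng.integers(self.mus.size, size=size)
            draws = rng.normal(self.mus[idx], self.sigmas[idx])
            # re-draw out-of-bound kernel samples a few times, then clip
            for _ in range(10):
                bad = use_kernel & ((draws < self.lo) | (draws > self.hi))
                if not bad.any():
                    break
                draws[bad] = rng.normal(self.mus[idx[bad]], self.sigmas[idx[bad]])
            out = np.where(use_kernel, np.clip(draws, self.lo, self.hi), out)
        return out

    def logpdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        span = self.hi - self.lo
        prior_term = np.full((x.size, 1), math.log(self.w_prior / span))
        if not self.mus.size:
            return prior_term[:, 0]
        z = (x[:, None] - self.mus[None, :]) / self.sigmas[None, :]
        log_kern = -0.5 * z**2 + self._log_norm[None, :] + math.log(self.w_each)
        return logsumexp(np.concatenate([prior_term, log_kern], axis=1), axis=1)


class _Categorical:
    """Re-weighted categorical distribution: observed counts plus a uniform
    pseudo-count prior."""

    def __init__(self, obs: np.ndarray, n_choices: int, prior_weight: float = 1.0):
        counts = np.bincount(obs, minlength=n_choices).astype(float)
        counts += prior_weight
        self.p = counts / counts.sum()

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.choice(self.p.size, p=self.p))

    def logpdf(self, i: int) -> float:
        return float(np.log(self.p[i]))


def _split_good_bad(losses: np.ndarray, config: OptimizerConfig) -> tuple[np.ndarray, np.ndarray]:
    n = losses.size
    if n >= 2 * config.gamma:
        n_good = config.gamma
    else:
        n_good = max(1, math.ceil(config.gamma_quantile * n))
    order = np.argsort(losses, kind="stable")
    return order[:n_good], order[n_good:]


def tpe_propose(
    history: TrialHistory,
    space: SearchSpace,
    config: OptimizerConfig,
    rng: np.random.Generator,
) -> tuple[int, np.ndarray]:
    """Propose the next (architecture index, p_c) candidate.

    Prior sampling during startup or on degenerate histories; otherwise the
    candidate maximizing log l(x) - log g(x) among ``n_candidates`` draws from
    the good-set density l.
    """
    n = len(history)
    losses = history.losses
    if n < config.n_startup or np.ptp(losses) == 0:
        return space.sample_prior(rng)

    good_idx, bad_idx = _split_good_bad(losses, config)
    if bad_idx.size == 0:
        return space.sample_prior(rng)

    pcs = np.array([t.p_c for t in history.trials])
    arch_obs = np.array([t.arch_index for t in history.trials])
    good_cat = _Categorical(arch_obs[good_idx], len(space.architectures), config.prior_weight)
    bad_cat = _Categorical(arch_obs[bad_idx], len(space.architectures), config.prior_weight)

    def parzen_set(idx, arch=None):
        sel = idx if arch is None else idx[arch_obs[idx] == arch]
        return [
            _Parzen1D(pcs[sel, d], *space.bounds[d], config.prior_weight)
            for d in range(space.n_continuous)
        ]

    cache: dict = {}

    def densities(arch):
        """(good, bad) Parzen lists, conditioned on the architecture when the
        tree-structured mode is on and that branch has observations."""
        if arch in cache:
            return cache[arch]
        if config.conditional and (arch_obs[good_idx] == arch).sum() >= 2:
            good = parzen_set(good_idx, arch)
            bad = (
                parzen_set(bad_idx, arch)
                if (arch_obs[bad_idx] == arch).sum() >= 2
                else parzen_set(bad_idx)
            )
        else:
            good, bad = parzen_set(good_idx), parzen_set(bad_idx)
        cache[arch] = (good, bad)
        return cache[arch]

    m = config.n_candidates
    arch_draws = np.array([good_cat.sample(rng) for _ in range(m)])
    best_score, best = -np.inf, None
    for a in np.unique(arch_draws):
        sel = arch_draws == a
        n_a = int(sel.sum())
        good_parzen, bad_parzen = densities(int(a))
        xs = np.column_stack([p.sample(rng, n_a) for p in good_parzen])
        scores = np.full(n_a, good_cat.logpdf(int(a)) - bad_cat.logpdf(int(a)))
        for d in range(space.n_continuous):
            scores += good_parzen[d].logpdf(xs[:, d]) - bad_parzen[d].logpdf(xs[:, d])
        i = int(np.argmax(scores))
        if scores[i] > best_score:
            best_score, best = float(scores[i]), (int(a), xs[i])
    return best


def _evaluate(objective: Objective, space: SearchSpace, idx: int,
              arch_i: int, p_c: np.ndarray) -> Trial:
    arch = space.architectures[arch_i]
    loss = float(objective(arch, p_c))
    status = "ok"
    if not np.isfinite(loss):
        loss, status = 1.0e9, "penalized"
    return Trial(index=idx, arch_index=arch_i, arch_name=arch.name, p_c=p_c,
                 loss=loss, status=status)


def bayesopt_minimize(
    objective: Objective,
    space: SearchSpace,
    config: OptimizerConfig,
) -> TrialHistory:
    """Run the propose -> simulate -> score loop for ``n_iterations`` trials.

    Reproducible for a fixed seed; the full history (with best design) is
    returned.
    """
    rng = np.random.default_rng(config.seed)
    history = TrialHistory(meta={"method": "tpe", "seed": config.seed,
                                 "n_iterations": config.n_iterations,
                                 "gamma": config.gamma})
    log_every = 1 if config.n_iterations <= 1000 else 100
    for i in range(config.n_iterations):
        arch_i, p_c = tpe_propose(history, space, config, rng)
        trial = _evaluate(objective, space, i, arch_i, p_c)
        history.append(trial)
        if i % log_every == 0:
            log.info("iter %d: loss %.6g (%s), best %.6g",
                     i, trial.loss, trial.arch_name, history.best_trace()[-1])
    return history


# ---------------------------------------------------------------------------
# baseline optimizers
# ---------------------------------------------------------------------------

def _random_search(objective, space, n, rng) -> TrialHistory:
    history = TrialHistory(meta={"method": "random"})
    for i in range(n):
        arch_i, p_c = space.sample_prior(rng)
        history.append(_evaluate(objective, space, i, arch_i, p_c))
    return history


def _grid_search(objective, space, n) -> TrialHistory:
    history = TrialHistory(meta={"method": "grid"})
    n_arch = len(space.architectures)
    d = space.n_continuous
    per_arch = max(1, n // n_arch)
    m = max(2, round(per_arch ** (1.0 / d)))
    if m**d * n_arch != n:
        warnings.warn(
            f"grid budget {n} not factorizable; using {m} points/dim "
            f"({m**d * n_arch} evaluations)", stacklevel=2,
        )
    axes = [np.linspace(lo, hi, m) for lo, hi in space.bounds]
    mesh = np.stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=1)
    i = 0
    for a in range(n_arch):
        for row in mesh:
            history.append(_evaluate(objective, space, i, a, row.copy()))
            i += 1
    return history


def _ga_search(objective, space, rng, population=24, generations=25,
               tournament=3, cx_prob=0.5, mut_prob=0.2, mut_sigma_frac=0.1,
               arch_mut_prob=0.1) -> TrialHistory:
    """Generational GA: tournament selection, uniform crossover, Gaussian
    mutation on continuous dims, categorical mutation on the architecture,
    elitism 1."""
    history = TrialHistory(meta={"method": "ga", "population": population,
                                 "generations": generations})
    lo, hi = space.lo, space.hi
    sigma = mut_sigma_frac * (hi - lo)
    pop = [space.sample_prior(rng) for _ in range(population)]
    idx = 0
    fitness = []
    for a, x in pop:
        t = _evaluate(objective, space, idx, a, x)
        history.append(t)
        fitness.append(t.loss)
        idx += 1

    for _ in range(generations - 1):
        elite_i = int(np.argmin(fitness))
        new_pop = [pop[elite_i]]
        while len(new_pop) < population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(population, size=tournament)
                parents.append(pop[min(contenders, key=lambda i: fitness[i])])
            (a1, x1), (a2, x2) = parents
            mask = rng.uniform(size=x1.size) < cx_prob
            child_x = np.where(mask, x1, x2).copy()
            child_a = a1 if rng.uniform() < 0.5 else a2
            mut = rng.uniform(size=child_x.size) < mut_prob
            child_x[mut] += rng.normal(0.0, sigma[mut])
            child_x = np.clip(child_x, lo, hi)
            if rng.uniform() < arch_mut_prob:
                child_a = int(rng.integers(len(space.architectures)))
            new_pop.append((child_a, child_x))
        pop = new_pop
        fitness = []
        for a, x in pop:
            t = _evaluate(objective, space, idx, a, x)
            history.append(t)
            fitness.append(t.loss)
            idx += 1
    return history


def _gradient_search(objective, space, rng, n_starts=3) -> TrialHistory:
    """Per-architecture bounded quasi-Newton (L-BFGS-B) local search from
    random starts; convergence failures are counted, not raised."""
    history = TrialHistory(meta={"method": "gradient"})
    failures = 0
    idx = 0
    for a, arch in enumerate(space.architectures):
        for _ in range(n_starts):
            x0 = rng.uniform(space.lo, space.hi)
            evals: list[tuple[np.ndarray, float]] = []

            def f(x, _a=arch):
                loss = float(objective(_a, x))
                evals.append((x.copy(), loss))
                return loss

            res = minimize(f, x0, method="L-BFGS-B", bounds=list(space.bounds))
            if not res.success:
                failures += 1
            for x, loss in evals:
                history.append(Trial(index=idx, arch_index=a, arch_name=arch.name,
                                     p_c=x, loss=loss))
                idx += 1
    history.meta["convergence_failures"] = failures
    history.meta["n_local_searches"] = len(space.architectures) * n_starts
    return history


def baseline_optimize(
    method: str,
    objective: Objective,
    space: SearchSpace,
    settings: Mapping | None = None,
) -> TrialHistory:
    """Run one of the baseline optimizers: ``random`` (N prior draws), ``grid``
    (per-architecture regular grid), ``ga`` or ``gradient``."""
    settings = dict(settings or {})
    seed = settings.pop("seed", 0)
    rng = np.random.default_rng(seed)
    if method == "random":
        hist = _random_search(objective, space, settings.pop("n", 1000), rng)
    elif method == "grid":
        hist = _grid_search(objective, space, settings.pop("n", 40000))
    elif method == "ga":
        hist = _ga_search(objective, space, rng, **settings)
    elif method == "gradient":
        hist = _gradient_search(objective, space, rng, **settings)
    else:
        raise ConfigurationError(f"unknown baseline method {method!r}")
    hist.meta["seed"] = seed
    return hist


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def landscape_grid(
    objective: Objective,
    arch: ArchitectureSpec,
    dims: tuple[int, int],
    resolution: int,
    space: SearchSpace,
    fixed: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Loss on a regular resolution x resolution grid over two continuous
    dimensions, remaining dimensions held at ``fixed`` (default: bound
    midpoints). Returns (row coords, column coords, loss matrix)."""
    if len(dims) != 2:
        raise ConfigurationError("landscape_grid sweeps exactly two dimensions")
    i, j = dims
    base = np.asarray(
        fixed if fixed is not None else (space.lo + space.hi) / 2.0, dtype=float
    ).copy()
    xs = np.linspace(*space.bounds[i], resolution)
    ys = np.linspace(*space.bounds[j], resolution)
    Z = np.empty((resolution, resolution))
    for r, xv in enumerate(xs):
        for c, yv in enumerate(ys):
            p = base.copy()
            p[i], p[j] = xv, yv
            Z[r, c] = objective(arch, p)
    return xs, ys, Z


def exploration_stats(history: TrialHistory, n_bins: int) -> pd.DataFrame:
    """Architecture sample fractions per contiguous run segment (e.g. run
    quarters with ``n_bins=4``). Bin sizes differ by at most one; fractions
    sum to 1 within each bin."""
    if not history.trials:
        raise ConfigurationError("empty history")
    if n_bins > len(history):
        raise ConfigurationError("more bins than trials")
    names = [t.arch_name for t in history.trials]
    chunks = np.array_split(np.arange(len(names)), n_bins)
    all_names = sorted(set(names))
    rows = []
    for b, chunk in enumerate(chunks):
        sub = [names[i] for i in chunk]
        for nm in all_names:
            rows.append({"bin": b, "architecture": nm,
                         "fraction": sub.count(nm) / len(sub)})
    return pd.DataFrame(rows)
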