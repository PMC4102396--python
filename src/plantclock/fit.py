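"""Parameter search: log-uniform random seeding, parallel tempering with a
cooling ladder, and ensembles of independently optimized parameter sets.

Model parameters are positive and span decades, so all moves operate on
log-parameters: seeding samples log-uniformly within bounds, and the
Metropolis proposals are Gaussian in log space with a per-temperature
step size adapted toward ~25% acceptance.  Out-of-bounds proposals are
rejected.  Neighbouring chains attempt state swaps with the standard
replica-exchange acceptance rule; all temperatures are multiplied by a
cooling factor between stages.  A single point estimate from such a fit
is not trustworthy — parameters of sloppy ODE models are individually
ill-determined — hence `ensemble_fit` runs many independent seeds and
returns the best few, whose spread is part of the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

DEFAULT_BOUNDS = (1e-4, 1e2)


@dataclass
class FitConfig:
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    default_bounds: tuple[float, float] = DEFAULT_BOUNDS
    free_params: list[str] | None = None   # None = all parameters are free
    n_seeds: int = 1000                    # random points before tempering
    n_temperatures: int = 4
    t0: float = 1.0                        # coldest initial temperature
    ladder_ratio: float = 3.0              # geometric temperature spacing
    cooling_factor: float = 0.7
    n_stages: int = 4
    iterations: int = 200                  # sweeps per stage
    swap_interval: int = 10
    sigma0: float = 0.3                    # initial log-space proposal s.d.
    target_acceptance: float = 0.25
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_temperatures < 1:
            raise ValueError("need at least one temperature")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi):
                raise ValueError(f"bad bounds for {name}: ({lo}, {hi})")

    def bounds_for(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, self.default_bounds)


@dataclass
class FitResult:
    best_params: dict[str, float]
    best_cost: float
    cost_trace: list[float]                # cold-chain cost per sweep
    acceptance_rates: list[float]          # per temperature, whole run
    swaps_attempted: int = 0
    swaps_accepted: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        finite = [c for c in self.cost_trace if math.isfinite(c)]
        if finite and self.best_cost > min(finite) + 1e-12:
            raise ValueError("best_cost must be the cold-chain minimum")


def random_search(cost, bounds: dict[str, tuple[float, float]], n: int,
                  rng_seed: int = 0,
                  fixed: dict[str, float] | None = None) -> tuple[dict[str, float], float]:
    """Best of n log-uniform samples within bounds.

    `fixed` entries are merged into every sample (not searched).
    Returns (params, cost); raises if every sampled cost is infinite.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    names = list(bounds)
    lo = np.log([bounds[k][0] for k in names])
    hi = np.log([bounds[k][1] for k in names])
    best, best_cost = None, float("inf")
    for _ in range(n):
        x = rng.uniform(lo, hi)
        p = dict(zip(names, np.exp(x)))
        if fixed:
            p.update(fixed)
        c = cost(p)
        if c < best_cost:
            best, best_cost = p, c
    if best is None:
        raise RuntimeError("all sampled costs were infinite; widen the bounds")
    return best, best_cost


def parallel_tempering(cost, start: dict[str, float], config: FitConfig,
                       fixed: dict[str, float] | None = None) -> FitResult:
    """Metropolis chains at a ladder of temperatures with swaps and cooling.

    `start` supplies initial values for the free parameters; `fixed`
    entries are passed through to the cost unchanged.  With one chain and
    temperature ~0 this reduces to strict greedy descent.
    """
    rng = np.random.default_rng(config.rng_seed)
    free = config.free_params or list(start)
    fixed = dict(fixed or {})
    for k in start:
        if k not in free and k not in fixed:
            fixed[k] = start[k]
    lo = np.log([config.bounds_for(k)[0] for k in free])
    hi = np.log([config.bounds_for(k)[1] for k in free])
    x0 = np.log([start[k] for k in free])
    if np.any(x0 < lo - 1e-12) or np.any(x0 > hi + 1e-12):
        raise ValueError("start point outside bounds")

    def eval_cost(x: np.ndarray) -> float:
        p = dict(zip(free, np.exp(x)))
        p.update(fixed)
        c = cost(p)
        return float(c) if math.isfinite(c) else float("inf")

    nT = config.n_temperatures
    temps = np.array([config.t0 * config.ladder_ratio ** k for k in range(nT)])
    xs = [x0.copy() for _ in range(nT)]
    cs = [eval_cost(x0)] * nT
    sigmas = np.full(nT, config.sigma0)
    best_x, best_c = x0.copy(), cs[0]
    trace: list[float] = []
    acc = np.zeros(nT)
    tries = np.zeros(nT)
    swaps_att = swaps_acc = 0
    n_free = len(free)

    for stage in range(config.n_stages):
        for it in range(config.iterations):
            for k in range(nT):
                prop = xs[k] + rng.normal(0.0, sigmas[k], n_free)
                tries[k] += 1
                if np.any(prop < lo) or np.any(prop > hi):
                    continue
                c_new = eval_cost(prop)
                dc = c_new - cs[k]
                if dc <= 0 or (temps[k] > 0 and rng.random() < math.exp(-dc / temps[k])):
                    xs[k], cs[k] = prop, c_new
                    acc[k] += 1
                    if k == 0 and c_new < best_c:
                        best_x, best_c = prop.copy(), c_new
            trace.append(cs[0])
            # step-size adaptation toward the target acceptance
            if (it + 1) % 20 == 0:
                for k in range(nT):
                    if tries[k] > 0:
                        rate = acc[k] / tries[k]
                        sigmas[k] *= 1.15 if rate > config.target_acceptance else 0.87
                        sigmas[k] = float(np.clip(sigmas[k], 1e-3, 2.0))
            if nT > 1 and (it + 1) % config.swap_interval == 0:
                k = int(rng.integers(0, nT - 1))
                swaps_att += 1
                if _swap_accept(cs[k], cs[k + 1], temps[k], temps[k + 1], rng):
                    xs[k], xs[k + 1] = xs[k + 1], xs[k]
                    cs[k], cs[k + 1] = cs[k + 1], cs[k]
                    swaps_acc += 1
                    if k == 0 and cs[0] < best_c:
                        best_x, best_c = xs[0].copy(), cs[0]
        temps = temps * config.cooling_factor
    params = dict(zip(free, np.exp(best_x)))
    params.update(fixed)
    rates = [float(a / t) if t else 0.0 for a, t in zip(acc, tries)]
    return FitResult(best_params=params, best_cost=best_c, cost_trace=trace,
                     acceptance_rates=rates, swaps_attempted=swaps_att,
                     swaps_accepted=swaps_acc, rng_seed=config.rng_seed)


def _swap_accept(c_lo, c_hi, t_lo, t_hi, rng) -> bool:
    """Replica-exchange acceptance between neighbouring temperatures."""
    if math.isinf(c_lo) and math.isinf(c_hi):
        return False
    if t_lo <= 0 or t_hi <= 0:
        return c_hi <= c_lo
    delta = (1.0 / t_lo - 1.0 / t_hi) * (c_lo - c_hi)
    return delta >= 0 or rng.random() < math.exp(delta)


def ensemble_fit(cost, config: FitConfig, n_runs: int = 30, n_select: int = 8,
                 fixed: dict[str, float] | None = None,
                 start: dict[str, float] | None = None) -> list[FitResult]:
    """n_runs independent random-search + tempering runs; best n_select.

    Each run is seeded from the best of `n_seeds` log-uniform random
    points (or jittered around `start` when given), with run-offset RNG
    seeds, and is free of shared mutable state, so runs may be
    distributed.  Results come back sorted by ascending cost.
    """
    if n_select > n_runs:
        raise ValueError("n_select must be <= n_runs")
    results = []
    free = config.free_params or (list(start) if start else None)
    if free is None:
        raise ValueError("ensemble_fit requires free_params or a start point")
    fixed_all = dict(fixed or {})
    if start is not None:
        fixed_all.update({k: v for k, v in start.items() if k not in free})
    bounds = {k: config.bounds_for(k) for k in free}
    for run in range(n_runs):
        seed = config.rng_seed + 1000 * (run + 1)
        s, s_cost = random_search(cost, bounds, config.n_seeds,
                                  rng_seed=seed, fixed=fixed_all)
        if start is not None:
            # a jittered copy of the supplied start competes with the seeds
            rng = np.random.default_rng(seed)
            cand = {k: float(np.clip(start[k] * math.exp(rng.normal(0, 0.2)),
                                     *config.bounds_for(k))) for k in free}
            cand.update(fixed_all)
            if cost(cand) < s_cost:
                s = cand
        run_cfg = FitConfig(**{**config.__dict__, "rng_seed": seed,
                               "free_params": list(free)})
        results.append(parallel_tempering(cost, s, run_cfg, fixed=fixed_all))
    return sorted(results, key=lambda r: r.best_cost)[:n_select]


def sensitivity_scan(cost, params: dict[str, float], factor: float = 1.1,
                     names: list[str] | None = None) -> dict[str, tuple[float, float]]:
    """Relative cost change when each parameter is multiplied/divided by
    `factor` — a quick map of which rates the fit actually constrains."""
    base = cost(params)
    out = {}
    for k in names or list(params):
        up = dict(params); up[k] = params[k] * factor
        dn = dict(params); dn[k] = params[k] / factor
        cu, cd = cost(up), cost(dn)
        out[k] = ((cu - base) / base if base > 0 else float("nan"),
                  (cd - base) / base if base > 0 else float("nan"))
    return out
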