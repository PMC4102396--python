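"""Model/Results facade in the statsmodels idiom.

`ClockModel` couples a network definition with a time-course dataset and
a cost configuration; `fit()` runs the ensemble optimization and returns
`ClockResults`, which carries the ensemble of parameter sets, their
costs, per-parameter spread (the sloppiness diagnostic), and convenience
simulation/plot methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import load_network
from .cost import DEFAULT_ALPHA, CostBreakdown, CostEvaluator
from .data import Dataset, read_dataset
from .fit import FitConfig, FitResult, ensemble_fit, sensitivity_scan
from .light import parse_protocol
from .network import CompiledModel, Genotype, NetworkDefinition, ParameterSet
from .simulate import SimulationResult, simulate


class ClockModel:
    """A clock network to be fitted against a time-course dataset.

    Parameters
    ----------
    dataset : Dataset
        Time courses, weights and scale groups (see `plantclock.data`).
    network : NetworkDefinition, optional
        Defaults to the packaged canonical network.
    alpha : float
        Balance between profile and scaling cost terms.
    """

    def __init__(self, dataset: Dataset, network: NetworkDefinition | None = None,
                 alpha: float = DEFAULT_ALPHA, entrain_max_days: int = 50,
                 entrain_tol: float = 1e-5, rtol: float = 1e-6, atol: float = 1e-9):
        self.network = network or load_network()
        self.dataset = dataset
        self.alpha = alpha
        self.evaluator = CostEvaluator(self.network, dataset, alpha=alpha,
                                       entrain_max_days=entrain_max_days,
                                       entrain_tol=entrain_tol, rtol=rtol, atol=atol)

    @classmethod
    def from_dataset_dir(cls, path, **kwargs) -> "ClockModel":
        return cls(read_dataset(path), **kwargs)

    def cost(self, params: ParameterSet | dict) -> CostBreakdown:
        """Full cost breakdown of one parameter set."""
        return self.evaluator.breakdown(params)

    def fit(self, start: dict[str, float] | None = None,
            config: FitConfig | None = None, n_runs: int = 30,
            n_select: int = 8) -> "ClockResults":
        """Ensemble fit: independent random-search + parallel-tempering
        runs; the best `n_select` of `n_runs` become the ensemble."""
        config = config or FitConfig()
        fixed = None
        if config.free_params and start:
            fixed = {k: v for k, v in start.items() if k not in config.free_params}
        results = ensemble_fit(self.evaluator, config, n_runs=n_runs,
                               n_select=n_select, start=start, fixed=fixed)
        return ClockResults(self, results, config)

    def results_from_params(self, params_list: list[dict[str, float]]) -> "ClockResults":
        """Wrap externally obtained parameter sets (e.g. loaded from disk)."""
        results = [FitResult(best_params=dict(p), best_cost=self.evaluator(p),
                             cost_trace=[], acceptance_rates=[]) for p in params_list]
        results.sort(key=lambda r: r.best_cost)
        return ClockResults(self, results, FitConfig())


class ClockResults:
    """Fitted ensemble: parameter sets, costs, spread and diagnostics."""

    def __init__(self, model: ClockModel, results: list[FitResult], config: FitConfig):
        if not results:
            raise ValueError("empty ensemble")
        self.model = model
        self.ensemble = results
        self.config = config

    @property
    def best(self) -> FitResult:
        return self.ensemble[0]

    @property
    def best_params(self) -> dict[str, float]:
        return self.best.best_params

    @property
    def best_cost(self) -> float:
        return self.best.best_cost

    @property
    def costs(self) -> list[float]:
        return [r.best_cost for r in self.ensemble]

    def params_frame(self) -> pd.DataFrame:
        """Parameters x ensemble members, one column per member."""
        return pd.DataFrame({f"set{i + 1}": r.best_params
                             for i, r in enumerate(self.ensemble)})

    def spread(self) -> pd.Series:
        """log10(max/min) per parameter across the ensemble — parameters
        of a sloppy model routinely span an order of magnitude or more
        while the predicted trajectories stay close."""
        df = self.params_frame()
        return np.log10(df.max(axis=1) / df.min(axis=1))

    def simulate(self, genotype: str = "wt", protocol: str = "ld:5+ll:5",
                 member: int = 0, dt_out: float = 0.5) -> SimulationResult:
        geno = Genotype.from_string(genotype, self.model.network.gene_names)
        cm = CompiledModel(self.model.network, geno)
        bound = cm.bind(self.ensemble[member].best_params)
        return simulate(bound, protocol=parse_protocol(protocol), dt_out=dt_out)

    def sensitivity(self, factor: float = 1.1, names=None) -> pd.DataFrame:
        scan = sensitivity_scan(self.model.evaluator, self.best_params,
                                factor=factor, names=names)
        return pd.DataFrame(scan, index=["up", "down"]).T

    def summary(self) -> str:
        lines = []
        w = lines.append
        w("Clock model ensemble fit")
        w("=" * 60)
        w(f"network:            {self.model.network.name}")
        w(f"courses (active):   {len(self.model.dataset.active_courses())}")
        w(f"scale groups:       {len(self.model.dataset.groups)}")
        w(f"alpha:              {self.model.alpha}")
        w(f"ensemble size:      {len(self.ensemble)}")
        w(f"ensemble costs:     {', '.join(f'{c:.4g}' for c in self.costs)}")
        sp = self.spread()
        w(f"parameter spread:   median {sp.median():.2f} / max {sp.max():.2f}"
          " decades across ensemble")
        bd = self.model.cost(self.best_params)
        w(f"best total cost:    {bd.total:.6g}")
        w(f"  profile term:     {sum(bd.per_course_profile.values()):.6g}"
          f"  ({len(bd.per_course_profile)} courses)")
        w(f"  scaling term:     {sum(bd.per_group_scaling.values()):.6g}"
          f"  ({len(bd.per_group_scaling)} groups)")
        worst = sorted(bd.per_course_profile.items(), key=lambda kv: -kv[1])[:5]
        w("worst-fit courses:")
        for cid, c in worst:
            w(f"  {cid:30s} {c:.4g}")
        return "\n".join(lines)

    def plot_fit(self, course_id: str, member: int = 0, ax=None):
        """Overlay one course's data and the mean-normalized simulation."""
        import matplotlib.pyplot as plt

        course = self.model.dataset.courses[course_id]
        res = self.simulate(course.genotype, course.protocol, member=member)
        t, x = res.trace(course.species)
        sim_at = np.interp(course.times, t, x)
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3.5))
        ax.plot(course.times, course.values / course.values.mean(), "o",
                label=f"data {course_id}")
        ax.plot(t, x / sim_at.mean(), "-", label="model")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("level / mean")
        ax.legend(fontsize=8)
        return ax
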