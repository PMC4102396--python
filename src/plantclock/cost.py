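"""Two-part cost for fitting the clock model to time-course data.

Experimental time courses are individually normalized (arbitrary units),
so the profile cost compares *shapes*: both simulation and data are
divided by their own mean over the course's time points before taking the
mean squared difference.  Where several courses share a normalization (a
scale group), their relative levels are informative; the scaling cost
penalizes, in log space, non-uniform simulation/data mean ratios within
the group, so fold changes up or down are punished symmetrically.  The
total is

    C = sum_j w_j * C_profile_j + alpha * sum_g C_scaling_g

with per-course weights w_j and a balance parameter alpha (default 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import Dataset, TimeCourse, ScaleGroup
from .light import parse_protocol
from .network import CompiledModel, Genotype, NetworkDefinition, ParameterSet
from .simulate import IntegrationError, simulate

DEFAULT_ALPHA = 1.0


@dataclass
class CostBreakdown:
    per_course_profile: dict[str, float]
    per_group_scaling: dict[str, float]
    alpha: float
    total: float
    diagnostics: list[str] = field(default_factory=list)

    def weighted_profile_sum(self, weights: dict[str, float]) -> float:
        return sum(weights.get(cid, 1.0) * c for cid, c in self.per_course_profile.items())


def profile_cost(sim_values: np.ndarray, data_values: np.ndarray) -> float:
    """Mean squared difference of mean-normalized series (unit-invariant)."""
    sim = np.asarray(sim_values, dtype=float)
    dat = np.asarray(data_values, dtype=float)
    if sim.shape != dat.shape:
        raise ValueError("simulation must be sampled at exactly the data time points")
    dmean = dat.mean()
    smean = sim.mean()
    if dmean <= 0:
        raise ValueError("data mean must be positive")
    if smean <= 0:
        # dead simulated gene vs. non-trivial data: worst-case shape mismatch
        return float(np.mean((dat / dmean) ** 2))
    return float(np.mean((sim / smean - dat / dmean) ** 2))


def scaling_cost(ratios: dict[str, float]) -> float:
    """Variance of log mean-ratios within a scale group.

    ratios maps course id -> mean(sim)/mean(data).  Zero iff all ratios
    are equal; deviations f and 1/f from the group mean cost the same.
    """
    vals = np.array([r for r in ratios.values() if r > 0 and math.isfinite(r)])
    if len(vals) < 2:
        return 0.0
    logs = np.log(vals)
    return float(np.mean((logs - logs.mean()) ** 2))


def group_scaling_cost(group: ScaleGroup, sims: dict[str, np.ndarray],
                       data: dict[str, TimeCourse]) -> float:
    """Scaling cost of one group from simulated and measured series."""
    ratios = {}
    for cid in group.members:
        if cid not in sims or cid not in data:
            continue
        smean = float(np.mean(sims[cid]))
        dmean = float(np.mean(data[cid].values))
        if smean > 0 and dmean > 0:
            ratios[cid] = smean / dmean
    return scaling_cost(ratios)


class CostEvaluator:
    """Evaluates the total cost of a parameter set against a dataset.

    One simulation is run per unique (genotype, protocol) pair and shared
    across that pair's courses.  A failed simulation yields an infinite
    total with a diagnostic, so optimizers reject the point.
    """

    def __init__(self, network: NetworkDefinition, dataset: Dataset,
                 alpha: float = DEFAULT_ALPHA, entrain_max_days: int = 50,
                 entrain_tol: float = 1e-5, rtol: float = 1e-6,
                 atol: float = 1e-9, entrain_days_hint: float = 10.0):
        dataset.validate()
        self.network = network
        self.dataset = dataset
        self.alpha = alpha
        self.entrain_max_days = entrain_max_days
        self.entrain_tol = entrain_tol
        self.rtol = rtol
        self.atol = atol
        self._compiled: dict[str, CompiledModel] = {}
        # group courses by simulation condition
        self.conditions: dict[tuple[str, str], list[TimeCourse]] = {}
        for c in dataset.active_courses():
            self.conditions.setdefault((c.genotype, c.protocol), []).append(c)
        self._protocols = {}
        for (_, proto) in self.conditions:
            if proto not in self._protocols:
                horizon = max(max(c.times.max() for c in courses)
                              for (g, p), courses in self.conditions.items()
                              if p == proto)
                self._protocols[proto] = parse_protocol(proto, measure_days=horizon / 24.0 + 0.25)

    def _model_for(self, genotype: str) -> CompiledModel:
        if genotype not in self._compiled:
            geno = Genotype.from_string(genotype, self.network.gene_names)
            self._compiled[genotype] = CompiledModel(self.network, geno)
        return self._compiled[genotype]

    def __call__(self, params) -> float:
        return self.breakdown(params).total

    def breakdown(self, params: ParameterSet | dict | np.ndarray) -> CostBreakdown:
        per_course: dict[str, float] = {}
        sims: dict[str, np.ndarray] = {}
        diagnostics: list[str] = []
        for (genotype, proto_str), courses in self.conditions.items():
            cm = self._model_for(genotype)
            proto = self._protocols[proto_str]
            try:
                res = simulate(cm.bind(params), protocol=proto, dt_out=0.5,
                               entrain_max_days=self.entrain_max_days,
                               entrain_tol=self.entrain_tol,
                               rtol=self.rtol, atol=self.atol)
            except (IntegrationError, FloatingPointError, ValueError) as exc:
                diagnostics.append(f"simulation failed for ({genotype}, {proto_str}): {exc}")
                return CostBreakdown({}, {}, self.alpha, float("inf"), diagnostics)
            for c in courses:
                t, x = res.trace(c.species)
                sim_at = np.interp(c.times, t, x)
                try:
                    per_course[c.id] = profile_cost(sim_at, c.values)
                    sims[c.id] = sim_at
                except ValueError as exc:
                    diagnostics.append(f"course {c.id} excluded: {exc}")
        per_group = {gid: group_scaling_cost(g, sims, self.dataset.courses)
                     for gid, g in self.dataset.groups.items()}
        weights = {c.id: c.weight for c in self.dataset.active_courses()}
        total = sum(weights[cid] * v for cid, v in per_course.items()) \
            + self.alpha * sum(per_group.values())
        return CostBreakdown(per_course, per_group, self.alpha, total, diagnostics)


def total_cost(dataset: Dataset, network: NetworkDefinition,
               params: ParameterSet | dict, alpha: float = DEFAULT_ALPHA,
               **kwargs) -> CostBreakdown:
    """One-shot convenience wrapper around CostEvaluator."""
    return CostEvaluator(network, dataset, alpha=alpha, **kwargs).breakdown(params)
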