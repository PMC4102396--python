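"""Synthetic time-course datasets with the corpus's statistical structure.

Each generated course is a model trace sampled at design time points,
multiplied by a hidden per-course normalization factor (shared within a
scale group) and by pointwise lognormal noise.  Expression data are
non-negative and span decades, which is why the noise is multiplicative
lognormal rather than additive Gaussian — consistent with the log-space
scaling cost.  The hidden factors and the generating parameters are
returned alongside the dataset so recovery experiments can assert
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Dataset, ScaleGroup, TimeCourse
from .light import parse_protocol
from .network import CompiledModel, Genotype, NetworkDefinition, ParameterSet
from .simulate import IntegrationError, simulate


@dataclass(frozen=True)
class NoiseModel:
    multiplicative_sd: float = 0.15   # lognormal sigma per data point
    scale_jitter_sd: float = 0.5      # lognormal sigma of hidden per-course factor
    time_jitter_sd: float = 0.0       # h; sampling-time error (recorded times stay nominal)
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.multiplicative_sd, self.scale_jitter_sd, self.time_jitter_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class Design:
    """One planned time course."""

    id: str
    genotype: str
    protocol: str
    species: str
    times: np.ndarray
    weight: float = 1.0
    scale_group: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))


def default_designs(resolution_h: float = 3.0) -> list[Design]:
    """A reduced-scale stand-in for the published corpus: 12 courses over
    wild type, cca1;lhy and the rve triple mutant in an LD->LL transition,
    at ~3 h resolution, with one 3-member scale group."""
    t_ld = np.arange(0.0, 48.0 + 1e-9, resolution_h)        # 2 days LD
    t_ll = np.arange(24.0, 96.0 + 1e-9, resolution_h)       # LD day then 2 days LL
    designs = [
        Design("ld_L_m1", "wt", "ld:2", "LHY_m", t_ld, scale_group="g1"),
        Design("ld_C_m1", "wt", "ld:2", "CCA1_m", t_ld),
        Design("ld_P9_m1", "wt", "ld:2", "PRR9_m", t_ld),
        Design("ld_P7_m1", "wt", "ld:2", "PRR7_m", t_ld),
        Design("ld_T_m1", "wt", "ld:2", "TOC1_m", t_ld),
        Design("ld_G_m1", "wt", "ld:2", "GI_m", t_ld),
        Design("ld_LUX_m1", "wt", "ld:2", "LUX_m", t_ld),
        Design("ld_E3_m1", "wt", "ld:2", "ELF3_m", t_ld),
        Design("ld+ll_L_m2", "wt", "ld:1+ll:3", "LHY_m", t_ll),
        Design("ld+ll_T_m2", "wt", "ld:1+ll:3", "TOC1_m", t_ll),
        Design("ld_L_m1-cca1lhy", "cca1;lhy", "ld:2", "LHY_m", t_ld,
               scale_group="g1"),
        Design("ld_L_m1-rve4rve6rve8", "rve4;rve6;rve8", "ld:2", "LHY_m", t_ld,
               scale_group="g1"),
    ]
    return designs


def generate_dataset(network: NetworkDefinition, true_params: ParameterSet | dict,
                     designs: list[Design], noise: NoiseModel,
                     entrain_max_days: int = 50, entrain_tol: float = 1e-5,
                     ) -> tuple[Dataset, dict]:
    """Simulate each design and corrupt it per the noise model.

    Returns (dataset, truth) where truth records the generating
    parameters and every hidden scale factor.  Identical inputs give an
    identical dataset (seeded determinism).
    """
    rng = np.random.default_rng(noise.rng_seed)
    ds = Dataset()
    group_members: dict[str, list[str]] = {}
    group_factor: dict[str, float] = {}
    hidden: dict[str, float] = {}
    compiled: dict[str, CompiledModel] = {}
    sims: dict[tuple[str, str], object] = {}
    for d in designs:
        key = (d.genotype, d.protocol)
        if key not in sims:
            if d.genotype not in compiled:
                geno = Genotype.from_string(d.genotype, network.gene_names)
                compiled[d.genotype] = CompiledModel(network, geno)
            proto = parse_protocol(d.protocol,
                                   measure_days=float(d.times.max()) / 24.0 + 0.25)
            try:
                sims[key] = simulate(compiled[d.genotype].bind(true_params),
                                     protocol=proto, dt_out=0.25,
                                     entrain_max_days=entrain_max_days,
                                     entrain_tol=entrain_tol)
            except IntegrationError as exc:
                raise IntegrationError(f"design {d.id} rejected: {exc}") from exc
        res = sims[key]
        t, x = res.trace(d.species)
        sample_times = d.times + (rng.normal(0.0, noise.time_jitter_sd, d.times.shape)
                                  if noise.time_jitter_sd > 0 else 0.0)
        sample_times = np.clip(sample_times, t[0], t[-1])
        values = np.interp(sample_times, t, x)
        if d.scale_group is not None:
            if d.scale_group not in group_factor:
                group_factor[d.scale_group] = float(
                    np.exp(rng.normal(0.0, noise.scale_jitter_sd)))
            factor = group_factor[d.scale_group]
            group_members.setdefault(d.scale_group, []).append(d.id)
        else:
            factor = float(np.exp(rng.normal(0.0, noise.scale_jitter_sd)))
        hidden[d.id] = factor
        if noise.multiplicative_sd > 0:
            values = values * np.exp(rng.normal(0.0, noise.multiplicative_sd,
                                                values.shape))
        ds.add(TimeCourse(id=d.id, genotype=d.genotype, protocol=d.protocol,
                          species=d.species, times=d.times, values=values * factor,
                          weight=d.weight, scale_group=d.scale_group,
                          source="synthetic"))
    for gid, members in group_members.items():
        ds.groups[gid] = ScaleGroup(gid, tuple(members))
    ds.validate()
    truth = {
        "params": dict(true_params.values) if isinstance(true_params, ParameterSet)
        else dict(true_params),
        "hidden_factors": hidden,
        "noise": noise,
    }
    return ds, truth
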