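"""Declarative gene-network definition and compilation to an ODE system.

The canonical network shipped with the package describes a
repression-dominated model of the Arabidopsis circadian clock: twelve
transcribed genes (LHY, CCA1, the PRR wave PRR9/PRR7/PRR5/TOC1, RVE8, GI,
NOX, LUX, ELF3, ELF4), the ELF3-ELF4 and GI-ZTL protein complexes,
constitutive ZTL and COP1 pools, and an *algebraic* evening complex (EC):
EC is not a state variable but a saturating function of LUX/NOX on one
hand and ELF3-ELF4/free ELF3 on the other, entering its target promoters
as a repressor.  The only transcriptional activator is RVE8 (multiplicative
activation of six targets); everything else is multiplicative Hill
repression.

Transcription of gene g:

    d[mRNA]/dt = v_g * (1 + a_g*L) * prod_r K^h/(K^h + R^h)
                     * prod_a (1 + s*A^h/(K^h + A^h))  -  dm_g * [mRNA]

with L the binary light signal, R repressor levels (protein, EC activity,
or the summed LHY+CCA1 pool "LC") and A activator levels.

Compilation produces index arrays over a flat state vector so that the
right-hand side is a handful of vectorised numpy operations.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml


class ConfigurationError(Exception):
    """The network definition or parameter set is inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    """A transcribed gene and its protein chain.

    compartments: protein pools produced by translation; ("c", "n") for a
    cytoplasmic protein transported to the nucleus, ("n",) for direct
    nuclear translation.  Degradation uses a single rate dp_<name> shared
    across compartments, optionally split into day/night values.
    """

    name: str
    compartments: tuple[str, ...] = ("n",)
    acute_light: str | None = None      # parameter name of the acute light amplitude
    light_degradation: bool = False     # if True, dp_<name>_day / dp_<name>_night
    # genotype state (wild type defaults)
    tx_multiplier: float = 1.0
    translation_multiplier: float = 1.0
    ox_rate: float = 0.0                # added constitutive, light-independent transcription

    def __post_init__(self):
        if not self.compartments or any(c not in ("c", "n") for c in self.compartments):
            raise ConfigurationError(f"{self.name}: bad compartments {self.compartments}")
        if self.tx_multiplier < 0 or self.translation_multiplier < 0 or self.ox_rate < 0:
            raise ConfigurationError(f"{self.name}: genotype multipliers must be >= 0")


@dataclass(frozen=True)
class RegulatoryEdge:
    """Transcriptional regulation of `target` by `regulator`.

    regulator is a gene name (resolved to its nuclear protein), "EC" (the
    evening-complex activity) or a declared pseudo-regulator such as "LC"
    (the summed LHY+CCA1 nuclear pool).  h is a fixed integer Hill
    exponent written into the network file, not a fitted parameter.
    """

    regulator: str
    target: str
    mode: str = "repression"
    h: int = 2

    def __post_init__(self):
        if self.mode not in ("repression", "activation"):
            raise ConfigurationError(f"bad edge mode {self.mode!r}")
        if int(self.h) != self.h or self.h < 1:
            raise ConfigurationError(f"Hill exponent must be integer >= 1, got {self.h}")

    @property
    def K_param(self) -> str:
        return f"K_{self.regulator}_{self.target}"

    @property
    def s_param(self) -> str:
        return f"s_{self.regulator}_{self.target}"


@dataclass(frozen=True)
class ComplexRule:
    """Mass-action protein complex: A + B -> C (optionally reversible)."""

    name: str
    components: tuple[str, str]
    assoc: str                      # association rate parameter
    deg: str                        # complex degradation rate parameter
    dissoc: str | None = None       # dissociation rate parameter (optional)
    assoc_gate: str = "none"        # "none" | "light" | "dark"
    dissoc_gate: str = "none"


@dataclass(frozen=True)
class ConstitutiveSpecies:
    """A non-transcribed protein pool with constant production."""

    name: str
    production: str | None = None
    degradation: str | None = None
    transport_to: str | None = None
    transport_rate: str | None = None
    transport_gate: str = "none"


@dataclass(frozen=True)
class MediatedDegradation:
    """Enzyme-mediated degradation: substrate removed at rate*enzyme*substrate."""

    enzyme: str
    substrate: str
    rate: str
    gate: str = "none"


@dataclass(frozen=True)
class ECSpec:
    """Algebraic evening-complex activity.

    activity = f(lux + c_NOX*nox) * g(e34 + c_E3*elf3_free) with f, g Hill
    saturations (exponent h, half-points K_LUXNOX and K_ELF3).  Zero if
    either pair is wholly absent; monotone nondecreasing in each input.
    """

    lux: str = "LUX_n"
    nox: str = "NOX_n"
    complex: str = "E34_n"
    free_elf3: str = "ELF3_n"
    h: int = 2
    params: tuple[str, str, str, str] = ("c_NOX", "c_E3", "K_LUXNOX", "K_ELF3")


@dataclass(frozen=True)
class Modification:
    gene: str
    kind: str                      # "knockout" | "knockdown" | "overexpression"
    magnitude: float = 0.0         # reduction fraction (knockdown) or constitutive rate (ox)

    def __post_init__(self):
        if self.kind not in ("knockout", "knockdown", "overexpression"):
            raise ConfigurationError(f"bad modification kind {self.kind!r}")
        if self.kind == "knockdown" and not (0.0 < self.magnitude < 1.0):
            raise ConfigurationError("knockdown magnitude must lie in (0, 1)")
        if self.kind == "overexpression" and self.magnitude <= 0:
            raise ConfigurationError("overexpression rate must be > 0")


# genotype-string conventions: lower-case gene tokens are knockouts, except
# rve8 alone (partial redundancy with RVE4/6 -> 60% knockdown); the
# rve4;rve6;rve8 triple is a full RVE8 knockout.  "<GENE>-ox" adds
# constitutive transcription.
RVE8_KNOCKDOWN = 0.6
DEFAULT_OX_RATE = 1.0


@dataclass(frozen=True)
class Genotype:
    modifications: tuple[Modification, ...] = ()
    name: str = "wt"

    @classmethod
    def wild_type(cls) -> "Genotype":
        return cls()

    @classmethod
    def from_string(cls, spec: str, gene_names: tuple[str, ...] | None = None) -> "Genotype":
        spec = (spec or "").strip()
        if spec in ("", "wt", "WT"):
            return cls()
        tokens = [t.strip() for t in spec.split(";") if t.strip()]
        lowset = {t.lower() for t in tokens}
        mods: list[Modification] = []
        triple = {"rve4", "rve6", "rve8"}
        if triple <= lowset:
            mods.append(Modification("RVE8", "knockout"))
            lowset -= triple
            tokens = [t for t in tokens if t.lower() not in triple]
        for tok in tokens:
            low = tok.lower()
            if low.endswith("-ox"):
                gene = low[:-3].upper()
                mods.append(Modification(gene, "overexpression", DEFAULT_OX_RATE))
            elif low == "rve8":
                mods.append(Modification("RVE8", "knockdown", RVE8_KNOCKDOWN))
            elif low in ("rve4", "rve6"):
                continue  # not model genes; only meaningful in the triple
            else:
                mods.append(Modification(low.upper(), "knockout"))
        if gene_names is not None:
            for m in mods:
                if m.gene not in gene_names:
                    raise ConfigurationError(f"unknown gene in genotype: {m.gene}")
        return cls(tuple(mods), name=spec)


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------

class ParameterSet:
    """Named positive reals with provenance flags.

    provenance: free-text flags such as "fitted", "hand-constrained" or
    "fixed-from-prior-model"; used only for bookkeeping and the summary.
    """

    def __init__(self, values: dict[str, float], provenance: dict[str, str] | None = None):
        for k, v in values.items():
            if not (v > 0) or not math.isfinite(v):
                raise ConfigurationError(f"parameter {k} must be a positive finite real, got {v}")
        self.values = dict(values)
        self.provenance = dict(provenance or {})

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, key: str) -> bool:
        return key in self.values

    def replace(self, **updates: float) -> "ParameterSet":
        vals = dict(self.values)
        vals.update(updates)
        return ParameterSet(vals, self.provenance)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "value"])
            for k in sorted(self.values):
                w.writerow([k, repr(self.values[k])])

    @classmethod
    def from_csv(cls, path: str | Path, provenance: dict[str, str] | None = None) -> "ParameterSet":
        values = {}
        with open(path, newline="") as fh:
            rd = csv.reader(fh)
            header = next(rd)
            if [h.strip().lower() for h in header[:2]] != ["name", "value"]:
                raise ConfigurationError(f"{path}: expected header 'name,value'")
            for row in rd:
                if not row or not row[0].strip():
                    continue
                values[row[0].strip()] = float(row[1])
        return cls(values, provenance)


# ---------------------------------------------------------------------------
# Network definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkDefinition:
    name: str
    genes: tuple[GeneSpec, ...]
    edges: tuple[RegulatoryEdge, ...]
    complexes: tuple[ComplexRule, ...] = ()
    constitutive: tuple[ConstitutiveSpecies, ...] = ()
    mediated: tuple[MediatedDegradation, ...] = ()
    ec_spec: ECSpec | None = None
    pseudo_regulators: dict[str, tuple[str, ...]] = field(default_factory=dict)
    hand_constrained: tuple[str, ...] = ()
    ec_disabled: bool = False

    # -- structure ----------------------------------------------------------

    def gene(self, name: str) -> GeneSpec:
        for g in self.genes:
            if g.name == name:
                return g
        raise ConfigurationError(f"unknown gene {name!r}")

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    def species_names(self) -> list[str]:
        """Flat state-vector ordering: mRNAs, proteins, complexes, constitutive."""
        names = [f"{g.name}_m" for g in self.genes]
        for g in self.genes:
            for c in g.compartments:
                names.append(f"{g.name}_{c}")
        names.extend(c.name for c in self.complexes)
        names.extend(s.name for s in self.constitutive)
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate species names")
        return names

    def nuclear_protein(self, gene: str) -> str:
        g = self.gene(gene)
        comp = "n" if "n" in g.compartments else g.compartments[-1]
        return f"{gene}_{comp}"

    def parameter_names(self) -> list[str]:
        """Canonical parameter ordering (Hill exponents excluded)."""
        names: list[str] = []
        for g in self.genes:
            names += [f"v_{g.name}", f"dm_{g.name}", f"p_{g.name}"]
            if set(g.compartments) == {"c", "n"}:
                names.append(f"t_{g.name}")
            if g.light_degradation:
                names += [f"dp_{g.name}_day", f"dp_{g.name}_night"]
            else:
                names.append(f"dp_{g.name}")
            if g.acute_light:
                names.append(g.acute_light)
        for e in self.edges:
            names.append(e.K_param)
            if e.mode == "activation":
                names.append(e.s_param)
        if self.ec_spec is not None:
            names.extend(self.ec_spec.params)
        for c in self.complexes:
            names.append(c.assoc)
            if c.dissoc:
                names.append(c.dissoc)
            names.append(c.deg)
        for s in self.constitutive:
            for p in (s.production, s.degradation, s.transport_rate):
                if p:
                    names.append(p)
        for m in self.mediated:
            names.append(m.rate)
        if len(set(names)) != len(names):
            dup = [n for n in names if names.count(n) > 1]
            raise ConfigurationError(f"duplicate parameter names: {sorted(set(dup))}")
        return names

    def validate(self) -> None:
        species = set(self.species_names())
        genes = set(self.gene_names)
        for ps, members in self.pseudo_regulators.items():
            for m in members:
                if m not in species:
                    raise ConfigurationError(f"pseudo-regulator {ps} member {m} not a species")
        for e in self.edges:
            if e.target not in genes:
                raise ConfigurationError(f"edge target {e.target} not a declared gene")
            if e.regulator not in genes and e.regulator != "EC" \
                    and e.regulator not in self.pseudo_regulators:
                raise ConfigurationError(f"edge regulator {e.regulator} unresolved")
            if e.regulator == "EC" and self.ec_spec is None:
                raise ConfigurationError("EC edge without an ec_spec")
        for c in self.complexes:
            for comp in c.components:
                if comp not in species:
                    raise ConfigurationError(f"complex {c.name} component {comp} not a species")
        for m in self.mediated:
            for sp in (m.enzyme, m.substrate):
                if sp not in species:
                    raise ConfigurationError(f"mediated degradation references unknown species {sp}")

    # -- genotypes and variants ---------------------------------------------

    def apply_genotype(self, genotype: Genotype) -> "NetworkDefinition":
        """Return a copy with the genotype folded into the gene specs.

        Knockout zeroes both transcription and translation (no residual
        protein production path); knockdown of magnitude m multiplies
        transcription by (1-m); overexpression adds a constitutive,
        light-independent transcription rate.
        """
        genes = list(self.genes)
        for mod in genotype.modifications:
            idx = next((i for i, g in enumerate(genes) if g.name == mod.gene), None)
            if idx is None:
                raise ConfigurationError(f"genotype modifies unknown gene {mod.gene}")
            g = genes[idx]
            if mod.kind == "knockout":
                g = replace(g, tx_multiplier=0.0, translation_multiplier=0.0, ox_rate=0.0)
            elif mod.kind == "knockdown":
                g = replace(g, tx_multiplier=g.tx_multiplier * (1.0 - mod.magnitude))
            else:  # overexpression
                g = replace(g, ox_rate=g.ox_rate + mod.magnitude)
            genes[idx] = g
        return replace(self, genes=tuple(genes))

    def with_variants(self, nox_activates_cca1: bool = False,
                      cca1_activates_prr9: bool = False,
                      rve8_present: bool = True,
                      ec_disabled: bool = False) -> "NetworkDefinition":
        """The explicitly supported model variants, as config toggles."""
        genes = list(self.genes)
        edges = list(self.edges)
        if nox_activates_cca1:
            edges.append(RegulatoryEdge("NOX", "CCA1", "activation", h=2))
        if cca1_activates_prr9:
            edges.append(RegulatoryEdge("LC", "PRR9", "activation", h=2))
        if not rve8_present:
            genes = [g for g in genes if g.name != "RVE8"]
            edges = [e for e in edges if "RVE8" not in (e.regulator, e.target)]
        out = replace(self, genes=tuple(genes), edges=tuple(edges), ec_disabled=ec_disabled)
        out.validate()
        return out

    # -- scalar operations (reference algebra; the compiler vectorises these) --

    def transcription_rate(self, gene: str, regulator_levels: dict[str, float],
                           light: int, params: ParameterSet) -> float:
        """Instantaneous transcription rate of `gene` (conc/h).

        regulator_levels maps regulator identifiers (species names, "EC",
        pseudo-regulators, or bare gene names for their nuclear protein)
        to non-negative concentrations; missing regulators default to 0.
        """
        g = self.gene(gene)  # raises ConfigurationError for unknown gene

        def level(reg: str) -> float:
            if reg in regulator_levels:
                val = regulator_levels[reg]
            elif reg in self.pseudo_regulators:
                val = sum(regulator_levels.get(m, 0.0) for m in self.pseudo_regulators[reg])
            elif reg in self.gene_names:
                val = regulator_levels.get(self.nuclear_protein(reg), 0.0)
            else:
                val = 0.0
            if val < 0:
                raise ValueError(f"negative level for regulator {reg}: {val}")
            return val

        rate = params[f"v_{g.name}"] * g.tx_multiplier
        if g.acute_light:
            rate *= 1.0 + params[g.acute_light] * light
        for e in self.edges:
            if e.target != gene:
                continue
            x = level(e.regulator)
            K = params[e.K_param]
            if e.mode == "repression":
                rate *= K ** e.h / (K ** e.h + x ** e.h)
            else:
                rate *= 1.0 + params[e.s_param] * x ** e.h / (K ** e.h + x ** e.h)
        return rate + g.ox_rate

    def ec_activity(self, lux: float, nox: float, elf3_elf4: float,
                    elf3_free: float, params: ParameterSet) -> float:
        if self.ec_spec is None:
            raise ConfigurationError("network has no evening-complex specification")
        if min(lux, nox, elf3_elf4, elf3_free) < 0:
            raise ValueError("EC inputs must be non-negative")
        if self.ec_disabled:
            return 0.0
        return ec_activity(lux, nox, elf3_elf4, elf3_free, params, self.ec_spec)

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkDefinition":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "NetworkDefinition":
        genes = []
        for name, spec in (doc.get("genes") or {}).items():
            spec = spec or {}
            genes.append(GeneSpec(
                name=name,
                compartments=tuple(spec.get("compartments", ["n"])),
                acute_light=spec.get("acute_light"),
                light_degradation=bool(spec.get("light_degradation", False)),
            ))
        edges = [RegulatoryEdge(e["regulator"], e["target"],
                                e.get("mode", "repression"), int(e.get("h", 2)))
                 for e in (doc.get("edges") or [])]
        complexes = []
        for name, c in (doc.get("complexes") or {}).items():
            complexes.append(ComplexRule(
                name=name, components=tuple(c["components"]), assoc=c["assoc"],
                deg=c["deg"], dissoc=c.get("dissoc"),
                assoc_gate=c.get("assoc_gate", "none"),
                dissoc_gate=c.get("dissoc_gate", "none")))
        constitutive = []
        for name, s in (doc.get("constitutive") or {}).items():
            s = s or {}
            tr = s.get("transport") or {}
            constitutive.append(ConstitutiveSpecies(
                name=name, production=s.get("production"),
                degradation=s.get("degradation"),
                transport_to=tr.get("to"), transport_rate=tr.get("rate"),
                transport_gate=tr.get("gate", "none")))
        mediated = [MediatedDegradation(m["enzyme"], m["substrate"], m["rate"],
                                        m.get("gate", "none"))
                    for m in (doc.get("mediated_degradation") or [])]
        ec = None
        if "ec" in doc and doc["ec"] is not None:
            e = doc["ec"]
            ec = ECSpec(lux=e.get("lux", "LUX_n"), nox=e.get("nox", "NOX_n"),
                        complex=e.get("complex", "E34_n"),
                        free_elf3=e.get("free_elf3", "ELF3_n"),
                        h=int(e.get("h", 2)))
        pseudo = {k: tuple(v) for k, v in (doc.get("pseudo_regulators") or {}).items()}
        net = cls(name=doc.get("name", "unnamed"), genes=tuple(genes), edges=tuple(edges),
                  complexes=tuple(complexes), constitutive=tuple(constitutive),
                  mediated=tuple(mediated), ec_spec=ec, pseudo_regulators=pseudo,
                  hand_constrained=tuple(doc.get("hand_constrained") or ()))
        net.validate()
        return net

    def to_dict(self) -> dict:
        doc: dict = {"name": self.name, "genes": {}, "edges": []}
        for g in self.genes:
            spec: dict = {"compartments": list(g.compartments)}
            if g.acute_light:
                spec["acute_light"] = g.acute_light
            if g.light_degradation:
                spec["light_degradation"] = True
            doc["genes"][g.name] = spec
        for e in self.edges:
            doc["edges"].append({"regulator": e.regulator, "target": e.target,
                                 "mode": e.mode, "h": e.h})
        if self.complexes:
            doc["complexes"] = {c.name: {"components": list(c.components), "assoc": c.assoc,
                                         "deg": c.deg,
                                         **({"dissoc": c.dissoc} if c.dissoc else {}),
                                         **({"assoc_gate": c.assoc_gate} if c.assoc_gate != "none" else {}),
                                         **({"dissoc_gate": c.dissoc_gate} if c.dissoc_gate != "none" else {})}
                                for c in self.complexes}
        if self.constitutive:
            doc["constitutive"] = {}
            for s in self.constitutive:
                d: dict = {}
                if s.production:
                    d["production"] = s.production
                if s.degradation:
                    d["degradation"] = s.degradation
                if s.transport_to:
                    d["transport"] = {"to": s.transport_to, "rate": s.transport_rate,
                                      "gate": s.transport_gate}
                doc["constitutive"][s.name] = d
        if self.mediated:
            doc["mediated_degradation"] = [
                {"enzyme": m.enzyme, "substrate": m.substrate, "rate": m.rate,
                 **({"gate": m.gate} if m.gate != "none" else {})}
                for m in self.mediated]
        if self.ec_spec:
            e = self.ec_spec
            doc["ec"] = {"lux": e.lux, "nox": e.nox, "complex": e.complex,
                         "free_elf3": e.free_elf3, "h": e.h}
        if self.pseudo_regulators:
            doc["pseudo_regulators"] = {k: list(v) for k, v in self.pseudo_regulators.items()}
        if self.hand_constrained:
            doc["hand_constrained"] = list(self.hand_constrained)
        return doc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def ec_activity(lux: float, nox: float, elf3_elf4: float, elf3_free: float,
                params: ParameterSet | dict, ec: ECSpec | None = None) -> float:
    """Evening-complex activity (dimensionless, in [0, 1))."""
    ec = ec or ECSpec()
    get = params.__getitem__
    c_nox, c_e3, K_ln, K_e3 = (get(p) for p in ec.params)
    if not (0 < c_nox < 1) or not (0 < c_e3 < 1):
        raise ConfigurationError("EC secondary-component weights c_NOX, c_E3 must lie in (0,1)")
    u = lux + c_nox * nox
    w = elf3_elf4 + c_e3 * elf3_free
    h = ec.h
    f = u ** h / (K_ln ** h + u ** h) if u > 0 else 0.0
    g = w ** h / (K_e3 ** h + w ** h) if w > 0 else 0.0
    return f * g


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

_GATES = {"none": 0, "light": 1, "dark": 2}


class CompiledModel:
    """Structure-compiled ODE system for one network x genotype.

    `bind(params)` attaches numeric parameter values and returns a
    BoundModel whose `rhs_for(light)` is a plain f(t, y) callable.
    """

    def __init__(self, network: NetworkDefinition, genotype: Genotype | None = None):
        if genotype is not None and genotype.modifications:
            network = network.apply_genotype(genotype)
        network.validate()
        self.network = network
        self.genotype = genotype or Genotype.wild_type()
        self.species = network.species_names()
        self.index = {s: i for i, s in enumerate(self.species)}
        self.param_names = network.parameter_names()
        self._pidx = {p: i for i, p in enumerate(self.param_names)}
        self._build()

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def _p(self, name: str) -> int:
        try:
            return self._pidx[name]
        except KeyError:
            raise ConfigurationError(f"missing parameter {name!r}") from None

    def _build(self) -> None:
        net = self.network
        idx = self.index
        genes = net.genes
        ng = len(genes)

        self.mrna_idx = np.array([idx[f"{g.name}_m"] for g in genes], dtype=np.intp)
        self.v_idx = np.array([self._p(f"v_{g.name}") for g in genes], dtype=np.intp)
        self.dm_idx = np.array([self._p(f"dm_{g.name}") for g in genes], dtype=np.intp)
        self.p_idx = np.array([self._p(f"p_{g.name}") for g in genes], dtype=np.intp)
        self.tx_mult = np.array([g.tx_multiplier for g in genes])
        self.tl_mult = np.array([g.translation_multiplier for g in genes])
        self.ox = np.array([g.ox_rate for g in genes])
        self.acute_idx = np.array([self._p(g.acute_light) if g.acute_light else -1
                                   for g in genes], dtype=np.intp)
        self.trans_target = np.array([idx[f"{g.name}_{g.compartments[0]}"] for g in genes],
                                     dtype=np.intp)

        # pseudo-regulator member index arrays
        self.pseudo_names = list(net.pseudo_regulators)
        self.pseudo_members = [np.array([idx[m] for m in net.pseudo_regulators[p]], dtype=np.intp)
                               for p in self.pseudo_names]
        pseudo_id = {p: i for i, p in enumerate(self.pseudo_names)}
        gene_id = {g.name: i for i, g in enumerate(genes)}

        # regulation edges -> flat arrays; kind 0 = species, 1 = EC, 2 = pseudo
        rep, act = [], []
        for e in net.edges:
            if e.regulator == "EC":
                kind, src = 1, 0
            elif e.regulator in pseudo_id:
                kind, src = 2, pseudo_id[e.regulator]
            else:
                kind, src = 0, idx[net.nuclear_protein(e.regulator)]
            row = (gene_id[e.target], kind, src, self._p(e.K_param), float(e.h))
            if e.mode == "repression":
                rep.append(row)
            else:
                act.append(row + (self._p(e.s_param),))

        def cols(rows, n):
            if not rows:
                return [np.empty(0, dtype=np.intp)] * 3 + [np.empty(0, dtype=np.intp), np.empty(0)] \
                    + ([np.empty(0, dtype=np.intp)] if n == 6 else [])
            arrs = list(zip(*rows))
            out = [np.array(arrs[0], dtype=np.intp), np.array(arrs[1], dtype=np.intp),
                   np.array(arrs[2], dtype=np.intp), np.array(arrs[3], dtype=np.intp),
                   np.array(arrs[4])]
            if n == 6:
                out.append(np.array(arrs[5], dtype=np.intp))
            return out

        (self.r_tgt, self.r_kind, self.r_src, self.r_K, self.r_h) = cols(rep, 5)
        (self.a_tgt, self.a_kind, self.a_src, self.a_K, self.a_h, self.a_s) = cols(act, 6)
        if np.any(self.a_kind == 1):
            raise ConfigurationError("EC cannot act as an activator")

        # EC bookkeeping
        self.ec_used = bool(np.any(self.r_kind == 1))
        if self.ec_used:
            ec = net.ec_spec
            self.ec_idx = np.array([idx[ec.lux], idx[ec.nox], idx[ec.complex],
                                    idx[ec.free_elf3]], dtype=np.intp)
            self.ec_pidx = np.array([self._p(p) for p in ec.params], dtype=np.intp)
            self.ec_h = float(ec.h)

        # mass-action terms: d y[target] += sign * coef * gate(L) * y[f1] * y[f2]
        terms: list[tuple[int, float, int, int, int, int]] = []

        def add(target, sign, pname, gate="none", f1=-1, f2=-1):
            terms.append((target, sign, self._p(pname), _GATES[gate], f1, f2))

        for gi, g in enumerate(genes):
            first = idx[f"{g.name}_{g.compartments[0]}"]
            if set(g.compartments) == {"c", "n"}:
                c, n = idx[f"{g.name}_c"], idx[f"{g.name}_n"]
                add(c, -1.0, f"t_{g.name}", f1=c)
                add(n, +1.0, f"t_{g.name}", f1=c)
            for comp in g.compartments:
                s = idx[f"{g.name}_{comp}"]
                if g.light_degradation:
                    add(s, -1.0, f"dp_{g.name}_day", gate="light", f1=s)
                    add(s, -1.0, f"dp_{g.name}_night", gate="dark", f1=s)
                else:
                    add(s, -1.0, f"dp_{g.name}", f1=s)

        for c in net.complexes:
            a, b = (idx[x] for x in c.components)
            ci = idx[c.name]
            for tgt, sign in ((a, -1.0), (b, -1.0), (ci, +1.0)):
                add(tgt, sign, c.assoc, gate=c.assoc_gate, f1=a, f2=b)
            if c.dissoc:
                for tgt, sign in ((a, +1.0), (b, +1.0), (ci, -1.0)):
                    add(tgt, sign, c.dissoc, gate=c.dissoc_gate, f1=ci)
            add(ci, -1.0, c.deg, f1=ci)

        for s in net.constitutive:
            si = idx[s.name]
            if s.production:
                add(si, +1.0, s.production)
            if s.degradation:
                add(si, -1.0, s.degradation, f1=si)
            if s.transport_to:
                ti = idx[s.transport_to]
                add(si, -1.0, s.transport_rate, gate=s.transport_gate, f1=si)
                add(ti, +1.0, s.transport_rate, gate=s.transport_gate, f1=si)

        for m in net.mediated:
            add(idx[m.substrate], -1.0, m.rate, gate=m.gate,
                f1=idx[m.enzyme], f2=idx[m.substrate])

        cols2 = list(zip(*terms))
        self.t_tgt = np.array(cols2[0], dtype=np.intp)
        self.t_sign = np.array(cols2[1])
        self.t_coef = np.array(cols2[2], dtype=np.intp)
        self.t_gate = np.array(cols2[3], dtype=np.intp)
        self.t_f1 = np.array(cols2[4], dtype=np.intp)
        self.t_f2 = np.array(cols2[5], dtype=np.intp)

    def bind(self, params: ParameterSet | dict[str, float] | np.ndarray) -> "BoundModel":
        if isinstance(params, np.ndarray):
            pv = np.asarray(params, dtype=float)
            if pv.shape != (self.n_params,):
                raise ConfigurationError(f"parameter vector length {pv.shape} != {self.n_params}")
        else:
            values = params.values if isinstance(params, ParameterSet) else params
            missing = [p for p in self.param_names if p not in values]
            if missing:
                raise ConfigurationError(f"missing parameters: {missing}")
            pv = np.array([values[p] for p in self.param_names])
        if np.any(pv <= 0) or not np.all(np.isfinite(pv)):
            raise ConfigurationError("all parameter values must be positive and finite")
        return BoundModel(self, pv)


class BoundModel:
    """CompiledModel + numeric parameter values; provides rhs callables."""

    def __init__(self, compiled: CompiledModel, pv: np.ndarray):
        self.compiled = compiled
        self.pv = pv
        c = compiled
        self._v = pv[c.v_idx] * c.tx_mult
        self._dm = pv[c.dm_idx]
        self._ptl = pv[c.p_idx] * c.tl_mult
        self._acute = np.where(c.acute_idx >= 0, pv[np.maximum(c.acute_idx, 0)], 0.0)
        self._rKh = pv[c.r_K] ** c.r_h
        self._aKh = pv[c.a_K] ** c.a_h
        self._as = pv[c.a_s] if len(c.a_s) else np.empty(0)
        if c.ec_used:
            self._ecp = pv[c.ec_pidx]
        coefs = pv[c.t_coef] * c.t_sign
        self._coef_L = {L: coefs * np.where(c.t_gate == 0, 1.0,
                                            np.where(c.t_gate == 1, float(L), 1.0 - L))
                        for L in (0, 1)}
        self._m1 = c.t_f1 >= 0
        self._m2 = c.t_f2 >= 0
        self._rhs_cache: dict[int, object] = {}

    @property
    def species(self) -> list[str]:
        return self.compiled.species

    def ec_value(self, y: np.ndarray) -> float:
        c = self.compiled
        if not c.ec_used or c.network.ec_disabled:
            return 0.0
        lux, nox, e34, e3 = y[c.ec_idx]
        c_nox, c_e3, K_ln, K_e3 = self._ecp
        u = lux + c_nox * nox
        w = e34 + c_e3 * e3
        h = c.ec_h
        f = u ** h / (K_ln ** h + u ** h) if u > 0 else 0.0
        g = w ** h / (K_e3 ** h + w ** h) if w > 0 else 0.0
        return f * g

    def rhs_for(self, light: int):
        """Return f(t, y) for a constant binary light level."""
        if light in self._rhs_cache:
            return self._rhs_cache[light]
        c = self.compiled
        L = int(light)
        v_eff = self._v * (1.0 + self._acute * L)
        dm = self._dm
        ptl = self._ptl
        ox = c.ox
        mrna = c.mrna_idx
        trans_tgt = c.trans_target
        rKh, rh = self._rKh, c.r_h
        aKh, ah, a_s = self._aKh, c.a_h, self._as
        coefs = self._coef_L[L]
        t_tgt, f1, f2, m1, m2 = c.t_tgt, c.t_f1, c.t_f2, self._m1, self._m2
        ng = len(mrna)
        r_sp = c.r_kind == 0
        r_ec = c.r_kind == 1
        r_ps = c.r_kind == 2
        a_sp = c.a_kind == 0
        a_ps = c.a_kind == 2
        has_act = len(c.a_tgt) > 0

        def rhs(t, y):
            dydt = np.zeros_like(y)
            yc = np.maximum(y, 0.0)  # guard round-off undershoot inside Hill terms
            # regulator levels
            pseudo_vals = np.array([yc[mem].sum() for mem in c.pseudo_members]) \
                if c.pseudo_members else np.empty(0)
            rv = np.empty(len(c.r_tgt))
            rv[r_sp] = yc[c.r_src[r_sp]]
            if c.ec_used:
                rv[r_ec] = self.ec_value(yc)
            if len(pseudo_vals):
                rv[r_ps] = pseudo_vals[c.r_src[r_ps]]
            prod = np.ones(ng)
            xh = rv ** rh
            np.multiply.at(prod, c.r_tgt, rKh / (rKh + xh))
            if has_act:
                av = np.empty(len(c.a_tgt))
                av[a_sp] = yc[c.a_src[a_sp]]
                if len(pseudo_vals):
                    av[a_ps] = pseudo_vals[c.a_src[a_ps]]
                avh = av ** ah
                np.multiply.at(prod, c.a_tgt, 1.0 + a_s * avh / (aKh + avh))
            tx = v_eff * prod + ox
            dydt[mrna] = tx - dm * y[mrna]
            np.add.at(dydt, trans_tgt, ptl * yc[mrna])
            # mass-action terms
            rates = coefs.copy()
            rates[m1] *= yc[f1[m1]]
            rates[m2] *= yc[f2[m2]]
            np.add.at(dydt, t_tgt, rates)
            return dydt

        self._rhs_cache[light] = rhs
        return rhs


def build_rhs(network: NetworkDefinition, params: ParameterSet,
              genotype: Genotype | None = None, light=None):
    """Compile and bind, returning f(t, y) -> dy/dt.

    `light` may be a callable t -> {0,1} or a LightProtocol; the returned
    function evaluates it at t.  For segment-wise integration use
    CompiledModel/BoundModel directly (rhs_for avoids per-step light
    lookups).
    """
    bound = CompiledModel(network, genotype).bind(params)
    if light is None:
        light_fn = lambda t: 1
    elif hasattr(light, "light_at"):
        light_fn = light.light_at
    else:
        light_fn = light

    def rhs(t, y):
        return bound.rhs_for(int(light_fn(t)))(t, y)

    rhs.bound = bound  # expose for introspection
    return rhs
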