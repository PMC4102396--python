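"""Time-course corpus data model and I/O.

A dataset is a directory of per-course CSV files (columns time_h, value)
plus one `manifest.yaml` carrying course metadata: genotype, light
protocol, measured species, fitting weight, optional scale-group
membership and an excluded flag.  Courses that were plotted with a shared
normalization in the source belong to one scale group; their relative
levels are meaningful and the scaling cost penalizes the model for
distorting them.  All values are unitless by design — the profile cost is
invariant to per-course rescaling.

Course ids follow the corpus naming convention
    {ld|lgd|shd|ll|dd|rr|bb}[+...]_{geneToken}[_m]{index}[-ox][-mutants]
e.g. "ld_P9_m1" (PRR9 mRNA, LD 12:12, wild type) or "ll_C_m2-cca1lhy"
(CCA1 mRNA in constant light in the cca1;lhy double mutant).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .light import _REGIMES

GENE_TOKENS = {
    "C": "CCA1", "L": "LHY", "T": "TOC1", "P1": "TOC1", "G": "GI",
    "P5": "PRR5", "P7": "PRR7", "P9": "PRR9", "LUX": "LUX", "NOX": "NOX",
    "R8": "RVE8", "E3": "ELF3", "E4": "ELF4", "Z": "ZTL",
}
_TOKEN_BY_GENE = {"CCA1": "C", "LHY": "L", "TOC1": "T", "GI": "G",
                  "PRR5": "P5", "PRR7": "P7", "PRR9": "P9", "LUX": "LUX",
                  "NOX": "NOX", "RVE8": "R8", "ELF3": "E3", "ELF4": "E4",
                  "ZTL": "Z"}
MUTANT_TOKENS = ("cca1", "lhy", "prr9", "prr7", "prr5", "toc1", "gi", "ztl",
                 "lux", "nox", "elf3", "elf4", "rve8", "rve6", "rve4")


class NameError_(ValueError):
    """A course name does not follow the corpus grammar."""


@dataclass(frozen=True)
class CourseName:
    protocol: str              # protocol spec string, e.g. "ld" or "ld+ll"
    gene: str                  # model gene, e.g. "PRR9"
    is_mrna: bool
    index: int
    overexpressed: bool = False
    mutants: tuple[str, ...] = ()

    @property
    def species(self) -> str:
        return f"{self.gene}_m" if self.is_mrna else f"{self.gene}_p"

    @property
    def genotype(self) -> str:
        parts = list(self.mutants)
        if self.overexpressed:
            parts.append(f"{self.gene.lower()}-ox")
        return ";".join(parts) if parts else "wt"

    def format(self) -> str:
        tok = _TOKEN_BY_GENE[self.gene]
        core = f"{self.protocol}_{tok}{'_m' if self.is_mrna else ''}{self.index}"
        if self.overexpressed:
            core += "-ox"
        if self.mutants:
            core += "-" + "".join(self.mutants)
        return core


def parse_course_name(name: str) -> CourseName:
    """Parse a corpus-style course id into its metadata tuple."""
    parts = name.split("-")
    core, suffixes = parts[0], parts[1:]
    m = re.fullmatch(r"([a-z+]+)_([A-Za-z0-9]+?)(_m)?(\d+)", core)
    if not m:
        raise NameError_(f"malformed course name {name!r}")
    proto, gene_tok, mrna, index = m.group(1), m.group(2), m.group(3), m.group(4)
    for tok in proto.split("+"):
        if tok not in _REGIMES:
            raise NameError_(f"unknown light-condition token {tok!r} in {name!r}")
    if gene_tok not in GENE_TOKENS:
        raise NameError_(f"unknown gene token {gene_tok!r} in {name!r}")
    ox = False
    mutants: list[str] = []
    for suf in suffixes:
        if suf == "ox":
            ox = True
        else:
            mutants.extend(_tokenize_mutants(suf, name))
    return CourseName(protocol=proto, gene=GENE_TOKENS[gene_tok],
                      is_mrna=mrna is not None, index=int(index),
                      overexpressed=ox, mutants=tuple(mutants))


def _tokenize_mutants(s: str, context: str) -> list[str]:
    """Greedy longest-match split of concatenated lower-case mutant names."""
    out = []
    i = 0
    toks = sorted(MUTANT_TOKENS, key=len, reverse=True)
    while i < len(s):
        for tok in toks:
            if s.startswith(tok, i):
                out.append(tok)
                i += len(tok)
                break
        else:
            raise NameError_(f"unknown mutant token at {s[i:]!r} in {context!r}")
    return out


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeCourse:
    id: str
    genotype: str              # genotype spec string ("wt", "cca1;lhy", ...)
    protocol: str              # protocol spec string ("ld", "ld:3+ll:4", ...)
    species: str               # model variable, "<GENE>_m" or "<GENE>_p"
    times: np.ndarray          # h, strictly increasing
    values: np.ndarray         # unitless, >= 0
    weight: float = 1.0
    scale_group: str | None = None
    source: str = ""
    excluded: bool = False

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError(f"{self.id}: times/values must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.id}: times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError(f"{self.id}: values must be >= 0")
        if not self.weight > 0:
            raise ValueError(f"{self.id}: weight must be > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @classmethod
    def from_name(cls, name: str, times, values, **kw) -> "TimeCourse":
        parsed = parse_course_name(name)
        return cls(id=name, genotype=parsed.genotype, protocol=parsed.protocol,
                   species=parsed.species, times=np.asarray(times, float),
                   values=np.asarray(values, float), **kw)


@dataclass(frozen=True)
class ScaleGroup:
    id: str
    members: tuple[str, ...]

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError(f"scale group {self.id} needs >= 2 members")


@dataclass
class Dataset:
    courses: dict[str, TimeCourse] = field(default_factory=dict)
    groups: dict[str, ScaleGroup] = field(default_factory=dict)

    def add(self, course: TimeCourse) -> None:
        if course.id in self.courses:
            raise ValueError(f"duplicate course id {course.id}")
        self.courses[course.id] = course

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for gid, g in self.groups.items():
            for m in g.members:
                if m not in self.courses:
                    raise ValueError(f"scale group {gid} references missing course {m}")
                if m in seen:
                    raise ValueError(f"course {m} in two scale groups ({seen[m]}, {gid})")
                seen[m] = gid
                if self.courses[m].scale_group not in (None, gid):
                    raise ValueError(f"course {m} disagrees with group {gid}")

    def active_courses(self) -> list[TimeCourse]:
        return [c for c in self.courses.values() if not c.excluded]

    def __len__(self) -> int:
        return len(self.courses)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """One CSV per course plus manifest.yaml; lossless roundtrip."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dataset.validate()
    manifest: dict = {"courses": {}, "groups": {}}
    for cid, c in sorted(dataset.courses.items()):
        pd.DataFrame({"time_h": c.times, "value": c.values}).to_csv(
            path / f"{cid}.csv", index=False, float_format="%.10g")
        meta = {"genotype": c.genotype, "protocol": c.protocol,
                "species": c.species, "weight": float(c.weight)}
        if c.scale_group:
            meta["scale_group"] = c.scale_group
        if c.source:
            meta["source"] = c.source
        if c.excluded:
            meta["excluded"] = True
        manifest["courses"][cid] = meta
    for gid, g in sorted(dataset.groups.items()):
        manifest["groups"][gid] = list(g.members)
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_dataset(path: str | Path) -> Dataset:
    path = Path(path)
    with open(path / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh) or {}
    ds = Dataset()
    for cid, meta in (manifest.get("courses") or {}).items():
        df = pd.read_csv(path / f"{cid}.csv")
        ds.add(TimeCourse(
            id=cid, genotype=meta["genotype"], protocol=meta["protocol"],
            species=meta["species"], times=df["time_h"].to_numpy(),
            values=df["value"].to_numpy(), weight=float(meta.get("weight", 1.0)),
            scale_group=meta.get("scale_group"), source=meta.get("source", ""),
            excluded=bool(meta.get("excluded", False))))
    for gid, members in (manifest.get("groups") or {}).items():
        ds.groups[gid] = ScaleGroup(gid, tuple(members))
    ds.validate()
    return ds
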