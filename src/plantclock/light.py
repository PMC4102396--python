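"""Light protocols: the time -> {0, 1} light signal driving the clock.

Light enters the model in two ways: multiplicative acute terms on
transcription and hard gating of protein-level processes (GI-ZTL complex
dynamics, COP1 nuclear import, dark degradation of TOC1/PRR5).  The signal
is a binary step function; spectral quality is not modelled, so constant
red ("rr") and constant blue ("bb") protocols map to constant light with a
metadata tag.

Time is measured in hours from the first dawn (t = 0 is lights-on of day
one); within an LD segment with photoperiod p, light is on for
t mod 24 in [0, p).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Segment:
    """One piece of a light protocol.

    duration : hours (must be > 0)
    regime   : "LD", "LL" or "DD"
    photoperiod : hours of light per 24 h cycle (LD only)
    """

    duration: float
    regime: str
    photoperiod: float = 12.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError(f"segment duration must be > 0, got {self.duration}")
        if self.regime not in ("LD", "LL", "DD"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "LD" and not (0 < self.photoperiod < 24):
            raise ValueError(f"photoperiod must lie in (0, 24), got {self.photoperiod}")


@dataclass(frozen=True)
class LightProtocol:
    """Ordered light segments; t = 0 is the first dawn (ZT 0 of day one)."""

    segments: tuple[Segment, ...]
    tag: str = ""  # free-text, e.g. "rr"/"bb" noted but simulated as LL

    def __post_init__(self):
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def light_at(self, t: float) -> int:
        """Binary light state at time t (hours from the first dawn)."""
        if t < 0 or t > self.duration + 1e-9:
            raise ValueError(f"t={t} outside protocol [0, {self.duration}]")
        t0 = 0.0
        for seg in self.segments:
            if t < t0 + seg.duration or seg is self.segments[-1]:
                local = t - t0
                if seg.regime == "LL":
                    return 1
                if seg.regime == "DD":
                    return 0
                return 1 if (local % 24.0) < seg.photoperiod else 0
            t0 += seg.duration
        raise AssertionError("unreachable")

    def switch_times(self, t0: float, t1: float) -> list[float]:
        """All discontinuities of the light signal strictly inside (t0, t1)."""
        if t0 >= t1:
            raise ValueError("need t0 < t1")
        candidates: set[float] = set()
        start = 0.0
        for seg in self.segments:
            candidates.add(start)
            if seg.regime == "LD":
                k = 0
                while 24.0 * k < seg.duration:
                    for e in (start + 24.0 * k, start + 24.0 * k + seg.photoperiod):
                        if e < start + seg.duration:
                            candidates.add(e)
                    k += 1
            start += seg.duration
        eps = 1e-7
        out = []
        for e in sorted(candidates):
            if not (t0 < e < t1):
                continue
            lo = max(e - eps, 0.0)
            hi = min(e + eps, self.duration)
            if self.light_at(lo) != self.light_at(hi):
                out.append(round(e, 9))
        return out

    def last_dawn_before(self, t: float) -> float:
        """Most recent lights-on event at or before t (for ZT referencing)."""
        dawns = [0.0]
        start = 0.0
        for seg in self.segments:
            if seg.regime == "LD":
                k = 0
                while start + 24.0 * k < start + seg.duration:
                    d = start + 24.0 * k
                    if d <= t:
                        dawns.append(d)
                    k += 1
            elif seg.regime == "LL":
                if start <= t:
                    dawns.append(start)
            start += seg.duration
        return max(d for d in dawns if d <= t)


# -- corpus protocol strings --------------------------------------------------

_REGIMES = {
    "ld": ("LD", 12.0),
    "lgd": ("LD", 16.0),
    "shd": ("LD", 8.0),
    "ll": ("LL", None),
    "dd": ("DD", None),
    "rr": ("LL", None),  # constant red; binary light model -> LL
    "bb": ("LL", None),  # constant blue
}


def parse_protocol(spec: str, entrain_days: float = 10.0, measure_days: float = 5.0) -> LightProtocol:
    """Build a protocol from a corpus-style string.

    Accepted forms: single tokens ("ld", "lgd", "shd", "ll", "dd", "rr",
    "bb") and transitions joined by "+" ("ld+ll").  A token may carry an
    explicit duration in days, e.g. "ld:5+ll:5".  Tokens without duration
    get `entrain_days` for a leading cyclic segment and `measure_days`
    otherwise.  A constant-light/dark token alone implies LD 12:12
    entrainment first (the corpus convention: LL data follow entrainment).
    """
    tokens = [t.strip() for t in spec.lower().split("+") if t.strip()]
    if not tokens:
        raise ValueError("empty protocol string")
    segs: list[Segment] = []
    tags = []
    for i, tok in enumerate(tokens):
        if ":" in tok:
            name, days = tok.split(":", 1)
            dur = float(days) * 24.0
        else:
            name, dur = tok, None
        if name not in _REGIMES:
            raise ValueError(f"unknown protocol token {name!r}")
        regime, photo = _REGIMES[name]
        if name in ("rr", "bb"):
            tags.append(name)
        if i == 0 and regime in ("LL", "DD"):
            # constant-condition data are entrained in LD 12:12 first
            segs.append(Segment(entrain_days * 24.0, "LD", 12.0))
        if dur is None:
            dur = (entrain_days if regime == "LD" and i == 0 else measure_days) * 24.0
        if regime == "LD":
            segs.append(Segment(dur, "LD", photo))
        else:
            segs.append(Segment(dur, regime))
    return LightProtocol(tuple(segs), tag="+".join(tags))
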