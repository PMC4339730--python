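"""Kimura two-parameter distances and divergence summaries.

The K2P model distinguishes transitions (A<->G, C<->T) from transversions.
With P the proportion of transitional and Q of transversional differences
over the pairwise-included sites,

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

in substitutions per site.  Sites where either sequence carries anything
other than A, C, G or T are excluded pairwise ("pairwise deletion").  When
either logarithm argument is non-positive the pair is saturated and its
distance is undefined; saturated pairs are recorded as missing (NaN), never
imputed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .sequences import NucSequence

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_STRICT = frozenset("ACGT")


class SaturationWarning(UserWarning):
    pass


def _site_classes(a: str, b: str) -> tuple[int, int, int]:
    """(included sites, transitions, transversions) under pairwise deletion."""
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _STRICT or y not in _STRICT:
            continue
        n += 1
        if x == y:
            continue
        if {x, y} <= PURINES or {x, y} <= PYRIMIDINES:
            ts += 1
        else:
            tv += 1
    return n, ts, tv


def p_distance(a: NucSequence, b: NucSequence) -> float:
    """Raw proportion of differing sites over pairwise-included sites."""
    n, ts, tv = _aligned_classes(a, b)
    return (ts + tv) / n


def _aligned_classes(a: NucSequence, b: NucSequence) -> tuple[int, int, int]:
    if len(a) != len(b):
        raise ValueError(
            f"sequences {a.id!r} ({len(a)} nt) and {b.id!r} ({len(b)} nt) "
            "must be aligned to equal length"
        )
    n, ts, tv = _site_classes(a.bases, b.bases)
    if n == 0:
        raise ValueError(f"{a.id}/{b.id}: no comparable sites")
    return n, ts, tv


def k2p_distance(a: NucSequence, b: NucSequence) -> float:
    """K2P distance between two aligned sequences; NaN when saturated."""
    n, ts, tv = _aligned_classes(a, b)
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance table; NaN entries mark saturated pairs."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance table shape does not match ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate sequence ids")

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, i: str, j: str) -> float:
        return float(self.d[self.ids.index(i), self.ids.index(j)])

    @property
    def complete(self) -> bool:
        return not np.isnan(self.d).any()

    def missing_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i, j in zip(*np.where(np.isnan(self.d))):
            if i < j:
                out.append((self.ids[i], self.ids[j]))
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def pairwise_matrix(seqs: list[NucSequence]) -> DistanceMatrix:
    """All-pairs K2P matrix; saturated pairs become NaN with a warning."""
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = k2p_distance(seqs[i], seqs[j])
            if math.isnan(v):
                warnings.warn(
                    f"saturated pair {seqs[i].id}/{seqs[j].id}: "
                    "distance recorded as missing",
                    SaturationWarning,
                    stacklevel=2,
                )
            d[i, j] = d[j, i] = v
    return DistanceMatrix([s.id for s in seqs], d)


@dataclass
class DivergenceSummary:
    """Min/max conspecific and heterospecific K2P distances.

    ``intra`` maps species -> (min, max) over conspecific pairs, or ``None``
    for singleton species (an undefined range, not zero).  ``inter`` maps the
    sorted species pair -> (min, max) over heterospecific pairs.
    """

    intra: dict[str, tuple[float, float] | None]
    inter: dict[tuple[str, str], tuple[float, float]]


def divergence_summary(m: DistanceMatrix, species_of: dict[str, str]) -> DivergenceSummary:
    intra: dict[str, list[float]] = {}
    inter: dict[tuple[str, str], list[float]] = {}
    singletons: dict[str, int] = {}
    for sid in m.ids:
        sp = species_of[sid]
        singletons[sp] = singletons.get(sp, 0) + 1
    for i, j in itertools.combinations(range(len(m.ids)), 2):
        v = m.d[i, j]
        if math.isnan(v):
            continue
        si, sj = species_of[m.ids[i]], species_of[m.ids[j]]
        if si == sj:
            intra.setdefault(si, []).append(v)
        else:
            inter.setdefault(tuple(sorted((si, sj))), []).append(v)
    return DivergenceSummary(
        intra={
            sp: ((min(vs), max(vs)) if (vs := intra.get(sp)) else None)
            for sp in singletons
        },
        inter={pair: (min(vs), max(vs)) for pair, vs in inter.items()},
    )
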