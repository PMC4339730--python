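"""In-silico PCR: locate degenerate primer pairs and extract amplicon inserts.

Three primer pairs matter here: the Folmer pair (LCO1490/HCO2198) bracketing
the 658 bp full COI barcode, and two mini-barcode pairs designed for degraded
DNA - the Uni-Minibar pair (~130 bp insert) and the ZBJ-Art pair (~157 bp
insert), both lying inside the Folmer amplicon and overlapping each other.

Matching is degeneracy-aware (two IUPAC codes match when their base sets
intersect) and tolerates a configurable number of mismatches per primer.
Coordinates are 0-based, half-open; the reported insert excludes both primer
footprints, since primer-derived bases reflect the oligo, not the template.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequences import NucSequence, bases_match, reverse_complement

__all__ = [
    "PrimerPair", "AmpliconHit", "find_primer_sites", "extract_minibarcode",
    "LCO_HCO", "UNI", "ZBJ", "PRIMER_PAIRS",
]


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with a per-primer mismatch budget."""

    name: str
    forward: str
    reverse: str
    max_mismatch: int = 2
    marker: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.forward) < 15 or len(self.reverse) < 15:
            raise ValueError(f"{self.name}: primers must be >= 15 nt")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


# The three pairs used throughout; sequences as published.
LCO_HCO = PrimerPair(
    "LCO_HCO",
    forward="GGTCAACAAATCATAAAGATATTGG",    # LCO1490
    reverse="TAAACTTCAGGGTGACCAAAAAATCA",   # HCO2198
    marker="COI_full",
)
UNI = PrimerPair(
    "UNI",
    forward="TCCACTAATCACAARGATATTGGTAC",   # Uni-MinibarF1
    reverse="GAAAATCATAATGAAGGCATGAGC",     # Uni-MinibarR1
    marker="COI_mini_uni",
)
ZBJ = PrimerPair(
    "ZBJ",
    forward="AGATATTGGAACWTTATATTTTATTTTTGG",  # ZBJ-ArtF1c
    reverse="WACTAATCAATTWCCAAATCCTCC",        # ZBJ-ArtR2c
    marker="COI_mini_zbj",
)
PRIMER_PAIRS: dict[str, PrimerPair] = {"LCO_HCO": LCO_HCO, "UNI": UNI, "ZBJ": ZBJ}


@dataclass(frozen=True)
class AmpliconHit:
    """Insert coordinates of a successful in-silico amplification.

    ``start``/``end`` delimit the insert between the primer footprints,
    0-based half-open on the template.
    """

    template_id: str
    primer_name: str
    start: int
    end: int
    insert_bases: str


def _mismatches(template: str, pos: int, motif: str, budget: int) -> int | None:
    """Mismatch count of ``motif`` at ``pos``, or None once over budget."""
    n = 0
    for i, code in enumerate(motif):
        if not bases_match(template[pos + i], code):
            n += 1
            if n > budget:
                return None
    return n


def _scan(template: str, motif: str, budget: int, lo: int = 0) -> list[int]:
    stop = len(template) - len(motif)
    return [
        p for p in range(lo, stop + 1)
        if _mismatches(template, p, motif, budget) is not None
    ]


def find_primer_sites(template: NucSequence, pair: PrimerPair) -> AmpliconHit | None:
    """Locate a primer pair on a template; return the insert or ``None``.

    The forward primer is matched on the given strand; the reverse primer is
    matched as its reverse-complement strictly downstream of the forward
    footprint.  The leftmost valid forward site paired with its nearest valid
    reverse site wins.  Absence of a valid site pair is not an error.
    """
    if len(template) < len(pair.forward) + len(pair.reverse):
        return None
    seq = template.bases
    rc = reverse_complement(pair.reverse)
    fwd_sites = _scan(seq, pair.forward, pair.max_mismatch)
    for fpos in fwd_sites:
        insert_start = fpos + len(pair.forward)
        rev_sites = _scan(seq, rc, pair.max_mismatch, lo=insert_start)
        if rev_sites:
            rpos = rev_sites[0]  # nearest downstream
            return AmpliconHit(
                template_id=template.id,
                primer_name=pair.name,
                start=insert_start,
                end=rpos,
                insert_bases=seq[insert_start:rpos],
            )
    return None


def extract_minibarcode(full: NucSequence, pair: PrimerPair) -> NucSequence | None:
    """Excise the insert bracketed by ``pair`` as a new sequence.

    Returns ``None`` when the fragment is not recoverable (no valid site
    pair, or an empty insert).  The result keeps the template's identity and
    species label and is tagged with the pair's marker.
    """
    hit = find_primer_sites(full, pair)
    if hit is None or hit.end <= hit.start:
        return None
    return full.with_bases(hit.insert_bases, marker=pair.marker)
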