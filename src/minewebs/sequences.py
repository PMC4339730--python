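"""Sequence containers and FASTA input/output.

Sequences are plain IUPAC DNA strings tagged with an identifier, an optional
species label, a role in the study (leaf miner, parasitoid, reference library
member, or DNA recovered from an empty mine) and the marker they carry
(full-length COI barcode, one of the two COI mini-barcode fragments, or
unknown).  FASTA headers follow the convention ``id|species_label|role`` with
trailing fields optional.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ROLES = ("leaf_miner", "parasitoid", "reference", "mine_extract")
MARKERS = ("COI_full", "COI_mini_uni", "COI_mini_zbj", "unknown")

#: IUPAC nucleotide codes mapped to the set of concrete bases they stand for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class FastaError(ValueError):
    """Raised for malformed FASTA input (bad characters, duplicate ids)."""


def reverse_complement(bases: str) -> str:
    """Reverse-complement an IUPAC DNA string (degeneracy-aware)."""
    return bases.translate(_COMPLEMENT)[::-1]


def bases_match(a: str, b: str) -> bool:
    """True when two IUPAC codes can stand for at least one common base."""
    try:
        return not IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b])
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise FastaError(f"non-IUPAC nucleotide code {exc}") from exc


@dataclass(frozen=True)
class NucSequence:
    """One identified DNA sequence.

    Parameters
    ----------
    id
        Unique identifier within a collection.
    bases
        Upper-case IUPAC DNA; validated on construction.
    species_label
        Binomial (or cluster) label, empty string when unknown.
    role
        One of :data:`ROLES`.
    marker
        One of :data:`MARKERS`.
    """

    id: str
    bases: str
    species_label: str = ""
    role: str = "reference"
    marker: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.bases:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.bases) - set(IUPAC_SETS)
        if bad:
            raise FastaError(
                f"{self.id}: non-IUPAC character(s) {sorted(bad)!r} rejected"
            )
        if self.role not in ROLES:
            raise ValueError(f"{self.id}: unknown role {self.role!r}")
        if self.marker not in MARKERS:
            raise ValueError(f"{self.id}: unknown marker {self.marker!r}")

    def __len__(self) -> int:
        return len(self.bases)

    def with_bases(self, bases: str, marker: str | None = None) -> "NucSequence":
        return replace(self, bases=bases, marker=marker or self.marker)


def _parse_header(header: str) -> tuple[str, str, str]:
    parts = header.split("|")
    seq_id = parts[0].strip()
    species = parts[1].strip() if len(parts) > 1 else ""
    role = parts[2].strip() if len(parts) > 2 else "reference"
    return seq_id, species, role


def read_fasta(path, marker: str = "unknown") -> list[NucSequence]:
    """Read a FASTA file into a list of :class:`NucSequence`.

    Headers follow ``id|species_label|role``; missing trailing fields are
    tolerated (role defaults to ``reference``).  Bases are upper-cased and
    validated; duplicate ids and non-IUPAC characters raise
    :class:`FastaError`.  Record order is preserved.
    """
    out: list[NucSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, species, role = _parse_header(rec.description)
        if seq_id in seen:
            raise FastaError(f"duplicate sequence id {seq_id!r}")
        seen.add(seq_id)
        out.append(
            NucSequence(
                id=seq_id,
                bases=str(rec.seq).upper(),
                species_label=species,
                role=role if role in ROLES else "reference",
                marker=marker,
            )
        )
    return out


def write_fasta(seqs, path) -> None:
    """Write sequences with ``id|species|role`` headers, wrapped at 80 cols."""
    records = [
        SeqRecord(
            Seq(s.bases),
            id=f"{s.id}|{s.species_label}|{s.role}",
            description="",
        )
        for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


def fasta_string(seqs) -> str:
    buf = io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=80)
    writer.write_file(
        SeqRecord(Seq(s.bases), id=f"{s.id}|{s.species_label}|{s.role}",
                  description="")
        for s in seqs
    )
    return buf.getvalue()
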