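"""Translation-based quality control of COI fragments.

A genuine mitochondrial COI fragment translates without internal stop codons
in its correct reading frame; premature stops or a sudden run of stops
downstream of a point usually betray a frame-shifted pseudogene (NUMT) or a
sequencing artefact.  Sequences are translated in all three forward frames
under the invertebrate mitochondrial code (NCBI table 5, the standard for
insect COI) and the frame with the fewest stops is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .sequences import NucSequence

INVERTEBRATE_MITO = 5


@dataclass(frozen=True)
class QCResult:
    seq_id: str
    frame: int                  # 0, 1 or 2
    n_stop_codons: int
    frameshift_suspected: bool

    @property
    def passed(self) -> bool:
        return self.n_stop_codons == 0


def _count_stops(bases: str, frame: int, table: int) -> int:
    sub = bases[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return 0
    # Ambiguous codons (e.g. containing N) translate to X, never to a stop.
    aa = str(Seq(sub).translate(table=table))
    return aa.count("*")


def translation_qc(seq: NucSequence, code: int = INVERTEBRATE_MITO) -> QCResult:
    """Translate ``seq`` in the three forward frames and report the best one.

    The chosen frame minimises internal stop codons (ties go to the lowest
    frame).  A sequence passes QC iff that minimum is zero; any residual stop
    is treated as evidence of a frameshift or pseudogene.
    """
    if len(seq) < 30:
        raise ValueError(f"{seq.id}: sequence too short for translation QC")
    stops = [_count_stops(seq.bases, f, code) for f in (0, 1, 2)]
    best = min(range(3), key=lambda f: (stops[f], f))
    return QCResult(
        seq_id=seq.id,
        frame=best,
        n_stop_codons=stops[best],
        frameshift_suspected=stops[best] > 0,
    )
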