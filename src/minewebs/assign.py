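"""Reference-library search and consensus taxon assignment.

Queries are identified against local reference libraries by best percent
identity - a stand-in for remote megaBLAST (broad, GenBank-like library) and
for the BOLD identification engine (curated library).  The individual method
hits are then combined by a consensus cascade:

1. best-hit identity >= 96% and no disagreeing method -> accept the species;
2. best-hit identity < 96% but curated-library similarity >= 99.45% and the
   query's cluster is consistent with that species -> accept it;
3. no reference support, but the query sits in a multi-member cluster ->
   assign the cluster label (e.g. ``Braconidae sp. 2``), rank ``cluster``;
4. otherwise ``unidentified``.

Two high-confidence methods naming different species are a conflict and
raise, never silently override.  The 96 / 99.45 thresholds default to the
decision boundaries observed in practice and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .clustering import ClusterPartition
from .sequences import NucSequence

BLAST_ACCEPT = 96.0
LIBRARY_ACCEPT = 99.45
IDENTITY_FLOOR = 85.0

METHODS = ("blast_like", "library_similarity", "cluster_membership")


class IdentificationConflict(ValueError):
    """Contradictory high-confidence identifications; needs manual review."""


class ClusterNamingConflict(ValueError):
    """A single distance cluster contains two different reference species."""


@dataclass(frozen=True)
class ReferenceLibrary:
    """Reference barcodes with mandatory species labels, one marker."""

    sequences: tuple[NucSequence, ...]
    marker: str = "unknown"

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty reference library")
        for s in self.sequences:
            if not s.species_label:
                raise ValueError(f"reference {s.id} lacks a species label")

    @classmethod
    def from_sequences(cls, seqs, marker: str = "unknown") -> "ReferenceLibrary":
        return cls(tuple(seqs), marker=marker)


@dataclass(frozen=True)
class MethodHit:
    query_id: str
    method: str
    best_species: str | None = None
    identity_pct: float | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if (self.best_species is None) != (self.identity_pct is None):
            raise ValueError("identity_pct present iff best_species present")


@dataclass(frozen=True)
class ConsensusAssignment:
    query_id: str
    species: str | None
    rank: str  # species | genus | cluster | unidentified
    basis: tuple[str, ...] = field(default_factory=tuple)


def _identity(query: str, ref: str) -> float | None:
    """Percent identity over compared ACGT sites at the best ungapped offset.

    When lengths differ the shorter sequence is slid along the longer one and
    the best-scoring full-overlap offset is taken (the mini-barcodes are
    sub-fragments of the full barcode, so an ungapped scan suffices).
    """
    short, long_ = (query, ref) if len(query) <= len(ref) else (ref, query)
    best = None
    strict = set("ACGT")
    for off in range(len(long_) - len(short) + 1):
        match = comp = 0
        for a, b in zip(short, long_[off:off + len(short)]):
            if a not in strict or b not in strict:
                continue
            comp += 1
            if a == b:
                match += 1
        if comp == 0:
            continue
        pct = 100.0 * match / comp
        if best is None or pct > best:
            best = pct
    return best


def best_hit(
    query: NucSequence,
    lib: ReferenceLibrary,
    method: str = "blast_like",
    floor: float = IDENTITY_FLOOR,
) -> MethodHit:
    """Best-identity reference species for ``query``.

    Ties on identity are broken by the species with most supporting
    references, then lexicographically.  Below ``floor`` percent identity the
    species is withheld (prevents nonsense family-level matches).
    """
    per_species: dict[str, list[float]] = {}
    for ref in lib.sequences:
        pct = _identity(query.bases, ref.bases)
        if pct is not None:
            per_species.setdefault(ref.species_label, []).append(pct)
    if not per_species:
        return MethodHit(query.id, method)
    ranked = sorted(
        (
            (max(pcts), sum(1 for p in pcts if p >= max(pcts) - 1e-9), sp)
            for sp, pcts in per_species.items()
        ),
        key=lambda t: (-t[0], -t[1], t[2]),
    )
    pct, _, species = ranked[0]
    if pct < floor:
        return MethodHit(query.id, method)
    return MethodHit(query.id, method, best_species=species, identity_pct=pct)


def consensus_assign(
    hits: list[MethodHit],
    cluster_label: str | None = None,
    cluster_size: int = 1,
    blast_accept: float = BLAST_ACCEPT,
    library_accept: float = LIBRARY_ACCEPT,
) -> ConsensusAssignment:
    """Combine per-method hits into one assignment (pure, order-invariant).

    ``cluster_label``/``cluster_size`` describe the query's distance cluster
    (see :func:`name_clusters`); they feed rule 3 and the consistency check
    of rule 2.
    """
    by_method = {h.method: h for h in hits}
    if len(by_method) != len(hits):
        raise ValueError("at most one hit per method")
    blast = by_method.get("blast_like")
    lib = by_method.get("library_similarity")
    clus = by_method.get("cluster_membership")
    if blast is None:
        raise ValueError("the blast_like hit is required")
    qid = blast.query_id

    blast_conf = blast.best_species and blast.identity_pct >= blast_accept
    lib_conf = lib and lib.best_species and lib.identity_pct >= library_accept
    if blast_conf and lib_conf and blast.best_species != lib.best_species:
        raise IdentificationConflict(
            f"{qid}: blast-like {blast.best_species!r} "
            f"({blast.identity_pct:.2f}%) vs library {lib.best_species!r} "
            f"({lib.identity_pct:.2f}%)"
        )

    if blast_conf:
        basis = ["blast_like"]
        for other in (lib, clus):
            if other and other.best_species == blast.best_species:
                basis.append(other.method)
        return ConsensusAssignment(qid, blast.best_species, "species",
                                   tuple(sorted(basis)))

    if lib_conf:
        cluster_ok = clus is None or clus.best_species is None \
            or clus.best_species == lib.best_species
        if cluster_ok:
            basis = ["library_similarity"]
            if clus and clus.best_species == lib.best_species:
                basis.append("cluster_membership")
            return ConsensusAssignment(qid, lib.best_species, "species",
                                       tuple(sorted(basis)))

    if cluster_label is not None and cluster_size >= 2:
        return ConsensusAssignment(qid, cluster_label, "cluster",
                                   ("cluster_membership",))
    return ConsensusAssignment(qid, None, "unidentified", ())


def name_clusters(
    partition: ClusterPartition,
    family_of: dict[str, str],
    reference_species_of: dict[str, str] | None = None,
) -> dict[int, str]:
    """Deterministic labels for distance clusters.

    Clusters containing a reference-identified member inherit that species
    name; the rest are numbered ``<family> sp. k`` in order of their smallest
    member id.  A cluster spanning two different reference species raises
    :class:`ClusterNamingConflict`.
    """
    reference_species_of = reference_species_of or {}
    labels: dict[int, str] = {}
    counter: dict[str, int] = {}
    ordered = sorted(partition.clusters().items(), key=lambda kv: kv[1][0])
    for cid, members in ordered:
        ref_names = sorted({reference_species_of[m] for m in members
                            if m in reference_species_of})
        if len(ref_names) > 1:
            raise ClusterNamingConflict(
                f"cluster {cid} spans reference species {ref_names}"
            )
        if ref_names:
            labels[cid] = ref_names[0]
            continue
        fams = sorted({family_of.get(m, "") for m in members} - {""})
        family = fams[0] if len(fams) == 1 else ""
        key = family or "sp."
        counter[key] = counter.get(key, 0) + 1
        labels[cid] = (f"{family} sp. {counter[key]}" if family
                       else f"sp. {counter[key]}")
    return labels
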