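"""Assembly of tri-partite plant / leaf miner / parasitoid food webs.

A web is built from leaf records plus molecular evidence (specimen barcode
assignments and mine assays) in one of two modes:

* ``molecular`` - the miner is taken from the specimen barcode when one was
  sequenced, else from the mine assay (primer precedence ZBJ > UNI > LCO_HCO
  when several succeed; disagreement is a conflict and the leaf is excluded
  with a log entry).  Barcode-delimited taxa, including ``sp.`` clusters,
  stay distinct.
* ``morphological`` - the adult specimen's morphological identification when
  available, else the identification from the shape of the mine; assay data
  are never used.  Taxa that morphology cannot separate are collapsed:
  by default the three Chromatomyia leaf miners into one aggregate node and
  the four cryptic Braconidae clusters into another.

Edge weights are counts of supporting leaf records.  A leaf from which a
parasitoid emerged yields a tripartite triple (plant -> miner -> parasitoid)
when its miner is identified, otherwise a "dashed" plant -> parasitoid edge
recording that the intermediate host is unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .records import LeafRecord, MineAssay, SpecimenAssignment

logger = logging.getLogger(__name__)

#: Mine-assay primer precedence when several amplifications succeed.
PRIMER_PRECEDENCE = ("ZBJ", "UNI", "LCO_HCO")

#: Default morphological collapse of molecularly distinct taxa.
MORPH_MINER_COLLAPSE = {
    "Chromatomyia horticola": "Chromatomyia agg.",
    "Chromatomyia nigra": "Chromatomyia agg.",
    "Chromatomyia syngenesiae": "Chromatomyia agg.",
}
MORPH_PARASITOID_COLLAPSE = {
    "Braconidae sp. 1": "Braconidae agg.",
    "Braconidae sp. 2": "Braconidae agg.",
    "Braconidae sp. 3": "Braconidae agg.",
    "Dacnusa sp.": "Braconidae agg.",
}


@dataclass(frozen=True)
class ResolvedLeaf:
    miner: str | None
    parasitoid: str | None
    conflict: bool = False
    miner_source: str | None = None   # specimen | assay | morphology | mine_shape


@dataclass
class TriPartiteWeb:
    """Weighted tri-partite web; node lists derive from realized edges."""

    mode: str
    pm_edges: dict[tuple[str, str], int] = field(default_factory=dict)
    mp_edges: dict[tuple[str, str], int] = field(default_factory=dict)
    dashed_edges: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def plants(self) -> list[str]:
        return sorted({p for p, _ in self.pm_edges}
                      | {p for p, _ in self.dashed_edges})

    @property
    def miners(self) -> list[str]:
        return sorted({m for _, m in self.pm_edges}
                      | {m for m, _ in self.mp_edges})

    @property
    def parasitoids(self) -> list[str]:
        return sorted({h for _, h in self.mp_edges}
                      | {h for _, h in self.dashed_edges})

    @property
    def n_species(self) -> int:
        return len(self.plants) + len(self.miners) + len(self.parasitoids)

    def n_links(self, include_dashed: bool = True) -> int:
        n = len(self.pm_edges) + len(self.mp_edges)
        return n + (len(self.dashed_edges) if include_dashed else 0)

    def total_weight(self) -> int:
        return (sum(self.pm_edges.values()) + sum(self.mp_edges.values())
                + sum(self.dashed_edges.values()))

    def edge_list(self):
        """Three-block edge list (block, source, target, weight) tuples."""
        out = []
        for block, edges in (("plant-miner", self.pm_edges),
                             ("miner-parasitoid", self.mp_edges),
                             ("plant-parasitoid-dashed", self.dashed_edges)):
            for (a, b), w in sorted(edges.items()):
                out.append((block, a, b, w))
        return out


def _assay_species(assays: list[MineAssay]) -> tuple[str | None, bool]:
    """Species from mine assays under primer precedence; (species, conflict).

    When successful primers name different species the precedence winner is
    still reported but the leaf is flagged as conflicting (and web assembly
    excludes it).
    """
    named = {a.primer: a.assigned_species for a in assays
             if a.success and a.assigned_species}
    if not named:
        return None, False
    conflict = len(set(named.values())) > 1
    for primer in PRIMER_PRECEDENCE:
        if primer in named:
            return named[primer], conflict
    return None, conflict  # pragma: no cover


def resolve_leaf_species(
    record: LeafRecord,
    assays: list[MineAssay],
    assignments: list[SpecimenAssignment],
    mode: str,
) -> ResolvedLeaf:
    """Resolve one leaf to (miner species, parasitoid species) under ``mode``.

    Molecular mode: the sequenced specimen wins over the mine assay for the
    miner; the parasitoid comes from its specimen barcode.  Morphological
    mode: adult morphology, else mine-shape identification, never assays.
    Conflicting assay identifications across primers flag the leaf.
    """
    if mode not in ("molecular", "morphological"):
        raise ValueError(f"unknown mode {mode!r}")
    spec = {a.role: a.species for a in assignments}
    if mode == "molecular":
        parasitoid = spec.get("parasitoid")
        miner, source = spec.get("miner"), "specimen"
        conflict = False
        if miner is None:
            miner, conflict = _assay_species(assays)
            source = "assay" if miner else None
        return ResolvedLeaf(miner, parasitoid, conflict, source)
    # morphological: morph_id belongs to whatever emerged
    parasitoid = record.morph_id if record.outcome == "parasitoid_emerged" else None
    if record.outcome in ("miner_adult_emerged", "miner_immature_dissected") \
            and record.morph_id:
        return ResolvedLeaf(record.morph_id, parasitoid, False, "morphology")
    if record.mine_shape_id:
        return ResolvedLeaf(record.mine_shape_id, parasitoid, False, "mine_shape")
    return ResolvedLeaf(None, parasitoid, False, None)


def _collapse(name: str | None, mapping: dict[str, str]) -> str | None:
    return mapping.get(name, name) if name is not None else None


def build_web(
    records: list[LeafRecord],
    assays: list[MineAssay],
    assignments: list[SpecimenAssignment],
    mode: str,
    miner_collapse: dict[str, str] | None = None,
    parasitoid_collapse: dict[str, str] | None = None,
) -> TriPartiteWeb:
    """Assemble the tri-partite web from the survey evidence.

    In morphological mode the collapse maps (defaulting to the Chromatomyia
    and Braconidae aggregates) are applied to every label; in molecular mode
    no collapsing happens.  Leaves with conflicting assay identifications are
    excluded and logged.
    """
    if mode == "morphological":
        m_map = MORPH_MINER_COLLAPSE if miner_collapse is None else miner_collapse
        p_map = (MORPH_PARASITOID_COLLAPSE if parasitoid_collapse is None
                 else parasitoid_collapse)
    else:
        m_map, p_map = {}, {}
    assays_by_leaf: dict[str, list[MineAssay]] = {}
    for a in assays:
        assays_by_leaf.setdefault(a.leaf_id, []).append(a)
    assign_by_leaf: dict[str, list[SpecimenAssignment]] = {}
    for s in assignments:
        assign_by_leaf.setdefault(s.leaf_id, []).append(s)

    web = TriPartiteWeb(mode=mode)
    for rec in records:
        res = resolve_leaf_species(
            rec,
            assays_by_leaf.get(rec.leaf_id, []),
            assign_by_leaf.get(rec.leaf_id, []),
            mode,
        )
        if res.conflict:
            logger.warning(
                "leaf %s: conflicting assay identifications across primers; "
                "excluded from the %s web", rec.leaf_id, mode)
            continue
        miner = _collapse(res.miner, m_map)
        parasitoid = _collapse(res.parasitoid, p_map)
        if miner is not None:
            key = (rec.plant, miner)
            web.pm_edges[key] = web.pm_edges.get(key, 0) + 1
        if parasitoid is not None:
            if miner is not None:
                key = (miner, parasitoid)
                web.mp_edges[key] = web.mp_edges.get(key, 0) + 1
            else:
                key = (rec.plant, parasitoid)
                web.dashed_edges[key] = web.dashed_edges.get(key, 0) + 1
    return web


def collapse_web(
    web: TriPartiteWeb,
    miner_map: dict[str, str],
    parasitoid_map: dict[str, str],
) -> TriPartiteWeb:
    """Quotient a web under node-collapse maps; total edge weight is conserved."""
    out = TriPartiteWeb(mode=web.mode)
    for (p, m), w in web.pm_edges.items():
        key = (p, miner_map.get(m, m))
        out.pm_edges[key] = out.pm_edges.get(key, 0) + w
    for (m, h), w in web.mp_edges.items():
        key = (miner_map.get(m, m), parasitoid_map.get(h, h))
        out.mp_edges[key] = out.mp_edges.get(key, 0) + w
    for (p, h), w in web.dashed_edges.items():
        key = (p, parasitoid_map.get(h, h))
        out.dashed_edges[key] = out.dashed_edges.get(key, 0) + w
    return out


def count_tripartite(
    records: list[LeafRecord],
    assays: list[MineAssay],
    assignments: list[SpecimenAssignment],
) -> int:
    """Number of parasitoid leaves whose miner host was molecularly resolved."""
    assays_by_leaf: dict[str, list[MineAssay]] = {}
    for a in assays:
        assays_by_leaf.setdefault(a.leaf_id, []).append(a)
    assign_by_leaf: dict[str, list[SpecimenAssignment]] = {}
    for s in assignments:
        assign_by_leaf.setdefault(s.leaf_id, []).append(s)
    n = 0
    for rec in records:
        if rec.outcome != "parasitoid_emerged":
            continue
        res = resolve_leaf_species(
            rec, assays_by_leaf.get(rec.leaf_id, []),
            assign_by_leaf.get(rec.leaf_id, []), "molecular")
        if res.miner is not None and res.parasitoid is not None:
            n += 1
    return n
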