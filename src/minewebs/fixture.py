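"""Deterministic in-study fixture: 407 collected leaves with assays.

The field study's printed summaries pin down marginal counts, not the
specimen-level table, so this module encodes ONE deterministic specimen-level
arrangement consistent with all of them:

* per-plant occupied/empty leaf counts (totals 147 / 260);
* per-primer amplification successes on occupied and empty leaves
  (full barcode 2/0, Uni mini-barcode 39/3, ZBJ mini-barcode 46/15) with
  union totals 48 and 15;
* specimen composition 68 adult Diptera + 21 immature Diptera + 10 immature
  Lepidoptera + 48 parasitoid adults = 147;
* the 15 identified empty-leaf mines (1 Phytomyza cirsii and
  1 Chromatomyia syngenesiae on Cirsium arvense; 2 C. horticola and
  1 Chromatomyia sp on Pisum sativum; 3 Stigmella samiatella and
  2 Ectoedemia albifasciella on Quercus robur; 1 Stigmella
  splendidissimella on Rubus fruticosus; 4 C. horticola on Triticum
  aestivum);
* 15 of the 48 emerged parasitoids resolved to their leaf-miner host via
  the mine assay;
* the guild sizes and link counts the two published webs' qualitative
  descriptors imply (molecular: 16 plants, 16 miners, 8 parasitoids,
  29 links; morphological: 16 plants, 14 miners, 5 parasitoids, 23 links).

Rows not constrained by a printed marginal (which individual leaf carries
which species, which adults were morphologically identifiable) are filled
deterministically and are documented as invented; only the marginals above
are asserted as reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import LeafRecord, MineAssay, SpecimenAssignment

#: Table of per-plant (occupied, empty) leaf counts.
PLANT_COUNTS: dict[str, tuple[int, int]] = {
    "Aesculus hippocastanum": (2, 4),
    "Chenopodium album": (2, 3),
    "Cirsium arvense": (7, 21),
    "Compositae sp": (1, 11),
    "Epilobium sp": (1, 3),
    "Heracleum sphondylium": (5, 6),
    "Pisum sativum": (91, 31),
    "Quercus robur": (1, 21),
    "Quercus sp": (1, 5),
    "Rosa canina": (2, 7),
    "Rubus fruticosus": (2, 23),
    "Rumex obtusifolius": (3, 7),
    "Rumex sp": (2, 13),
    "Stellaria graminea": (1, 5),
    "Trifolium sp": (1, 9),
    "Triticum aestivum": (25, 91),
}

COLLECTION_DATE = "2012-07-15"


@dataclass
class _Leaf:
    plant: str
    outcome: str
    order: str = "none"
    miner: str | None = None          # molecular (barcode/assay) miner species
    parasitoid: str | None = None     # molecular parasitoid species
    morph_id: str | None = None
    mine_shape_id: str | None = None
    resolved: bool = False            # parasitoid leaf with successful mine assay
    assay_success: bool = False       # miner leaf whose mine also amplified
    empty_assay_species: str | None = None   # identified empty-leaf mine


def _occupied_leaves() -> list[_Leaf]:
    L: list[_Leaf] = []

    def lep(plant: str, species: str, n: int = 1) -> None:
        for _ in range(n):
            L.append(_Leaf(plant, "miner_immature_dissected", "lepidoptera",
                           miner=species, mine_shape_id=species))

    def dip_adult(plant: str, species: str, n: int = 1, n_morph: int = 0,
                  shape: str | None = None, n_assay: int = 0) -> None:
        for k in range(n):
            L.append(_Leaf(plant, "miner_adult_emerged", "diptera",
                           miner=species,
                           morph_id=species if k < n_morph else None,
                           mine_shape_id=shape,
                           assay_success=k < n_assay))

    def dip_immature(plant: str, species: str, n: int = 1,
                     shape: str | None = None) -> None:
        for _ in range(n):
            L.append(_Leaf(plant, "miner_immature_dissected", "diptera",
                           miner=species, mine_shape_id=shape))

    def parasitoid(plant: str, species: str, host: str, n: int = 1,
                   resolved: bool = False) -> None:
        for _ in range(n):
            L.append(_Leaf(plant, "parasitoid_emerged", "hymenoptera",
                           miner=host if resolved else None,
                           parasitoid=species, morph_id=species,
                           resolved=resolved))

    lep("Aesculus hippocastanum", "Cameraria ohridella", 2)
    lep("Chenopodium album", "Chrysoesthia drurella", 2)
    # Cirsium: 3 unidentifiable syngenesiae adults (3 of them with a
    # successfully amplified mine), plus 4 parasitoid leaves
    dip_adult("Cirsium arvense", "Chromatomyia syngenesiae", 3, n_assay=3)
    parasitoid("Cirsium arvense", "Dacnusa sp.",
               "Chromatomyia syngenesiae", resolved=True)
    parasitoid("Cirsium arvense", "Diglyphus isaea",
               "Chromatomyia syngenesiae", resolved=True)
    parasitoid("Cirsium arvense", "Halicoptera sp.",
               "Chromatomyia syngenesiae", n=2)
    dip_adult("Compositae sp", "Chromatomyia syngenesiae", 1, n_morph=1)
    dip_immature("Epilobium sp", "Pegomyia bicolor", 1, shape="Pegomyia bicolor")
    dip_adult("Heracleum sphondylium", "Phytomyza spondylii", 5, n_morph=2,
              n_assay=5)
    dip_adult("Pisum sativum", "Chromatomyia horticola", 48, n_assay=25)
    dip_adult("Pisum sativum", "Scaptomyza flava", 1, n_morph=1)
    dip_immature("Pisum sativum", "Chromatomyia horticola", 20)
    parasitoid("Pisum sativum", "Diglyphus isaea",
               "Chromatomyia horticola", n=8, resolved=True)
    parasitoid("Pisum sativum", "Chrysocharis pallipes",
               "Chromatomyia horticola", n=3, resolved=True)
    parasitoid("Pisum sativum", "Braconidae sp. 3",
               "Chromatomyia horticola", n=6)
    parasitoid("Pisum sativum", "Chrysocharis pubicornis",
               "Chromatomyia horticola", n=5)
    lep("Quercus robur", "Ectoedemia albifasciella", 1)
    lep("Quercus sp", "Stigmella samiatella", 1)
    lep("Rosa canina", "Coleophora gryphipennella", 2)
    lep("Rubus fruticosus", "Stigmella splendidissimella", 2)
    dip_adult("Rumex obtusifolius", "Pegomyia solennis", 1)
    parasitoid("Rumex obtusifolius", "Braconidae sp. 1",
               "Pegomyia solennis", n=2, resolved=True)
    dip_adult("Rumex sp", "Pegomyia solennis", 2, n_morph=1)
    dip_adult("Stellaria graminea", "Chromatomyia nigra", 1,
              shape="Chromatomyia sp")
    dip_adult("Trifolium sp", "Agromyza frontella", 1, n_morph=1)
    dip_adult("Triticum aestivum", "Chromatomyia horticola", 5)
    parasitoid("Triticum aestivum", "Braconidae sp. 2",
               "Chromatomyia horticola", n=20)
    return L


#: Identified empty-leaf mines: (plant, species, mine shape usable?).
EMPTY_IDENTIFICATIONS: list[tuple[str, str, bool]] = [
    ("Cirsium arvense", "Phytomyza cirsii", True),
    ("Cirsium arvense", "Chromatomyia syngenesiae", False),
    ("Pisum sativum", "Chromatomyia horticola", False),
    ("Pisum sativum", "Chromatomyia horticola", False),
    ("Pisum sativum", "Chromatomyia sp", False),
    ("Quercus robur", "Stigmella samiatella", False),
    ("Quercus robur", "Stigmella samiatella", False),
    ("Quercus robur", "Stigmella samiatella", False),
    ("Quercus robur", "Ectoedemia albifasciella", True),
    ("Quercus robur", "Ectoedemia albifasciella", True),
    ("Rubus fruticosus", "Stigmella splendidissimella", True),
    ("Triticum aestivum", "Chromatomyia horticola", False),
    ("Triticum aestivum", "Chromatomyia horticola", False),
    ("Triticum aestivum", "Chromatomyia horticola", False),
    ("Triticum aestivum", "Chromatomyia horticola", False),
]

#: Empty leaves whose mine also amplified with the Uni pair (besides ZBJ).
_EMPTY_UNI_INDICES = (2, 3, 11)


def paper_fixture() -> tuple[list[LeafRecord], list[MineAssay], list[SpecimenAssignment]]:
    """Build the deterministic study tables (records, assays, assignments)."""
    leaves = _occupied_leaves()

    records: list[LeafRecord] = []
    assays: list[MineAssay] = []
    assignments: list[SpecimenAssignment] = []

    def emit_assays(leaf_id: str, species: str | None,
                    zbj: bool, uni: bool, lco: bool) -> None:
        for primer, ok in (("LCO_HCO", lco), ("UNI", uni), ("ZBJ", zbj)):
            assays.append(MineAssay(
                leaf_id=leaf_id, primer=primer, success=ok,
                assigned_species=species if ok else None))

    # ---- occupied leaves -------------------------------------------------
    # Amplification pattern over the 48 successful occupied mines, ranked in
    # generation order: ZBJ succeeds on all but the last two (which are
    # Uni-only), Uni on the first 37 and the last two, and the full barcode
    # additionally on two miner leaves (ranks 15-16).  This realises the
    # printed per-primer counts 46/39/2 with union 48.
    success_rank = 0
    n_union = 48
    counter = 0
    for leaf in leaves:
        counter += 1
        leaf_id = f"L{counter:03d}"
        records.append(LeafRecord(
            leaf_id=leaf_id, plant=leaf.plant, date=COLLECTION_DATE,
            occupied_at_collection=True, outcome=leaf.outcome,
            insect_order=leaf.order, morph_id=leaf.morph_id,
            mine_shape_id=leaf.mine_shape_id))
        if leaf.outcome == "parasitoid_emerged":
            assignments.append(SpecimenAssignment(leaf_id, "parasitoid",
                                                  leaf.parasitoid))
        else:
            assignments.append(SpecimenAssignment(leaf_id, "miner", leaf.miner))
        success = leaf.resolved or leaf.assay_success
        if success:
            rank = success_rank
            success_rank += 1
            zbj = rank < n_union - 2
            uni = rank < 37 or rank >= n_union - 2
            lco = rank in (15, 16)
            emit_assays(leaf_id, leaf.miner, zbj, uni, lco)
        else:
            emit_assays(leaf_id, None, False, False, False)
    assert success_rank == n_union

    # ---- empty leaves ----------------------------------------------------
    identified = {plant: [] for plant in PLANT_COUNTS}
    for idx, (plant, species, shaped) in enumerate(EMPTY_IDENTIFICATIONS):
        identified[plant].append((idx, species, shaped))
    for plant, (_, n_empty) in PLANT_COUNTS.items():
        hits = identified[plant]
        for k in range(n_empty):
            counter += 1
            leaf_id = f"L{counter:03d}"
            if k < len(hits):
                idx, species, shaped = hits[k]
                records.append(LeafRecord(
                    leaf_id=leaf_id, plant=plant, date=COLLECTION_DATE,
                    occupied_at_collection=False, outcome="empty",
                    insect_order="none",
                    mine_shape_id=species if shaped else None))
                emit_assays(leaf_id, species,
                            zbj=True, uni=idx in _EMPTY_UNI_INDICES, lco=False)
            else:
                records.append(LeafRecord(
                    leaf_id=leaf_id, plant=plant, date=COLLECTION_DATE,
                    occupied_at_collection=False, outcome="empty",
                    insect_order="none"))
                emit_assays(leaf_id, None, False, False, False)
    assert counter == 407
    return records, assays, assignments


def write_fixture(directory) -> None:
    """Write records.tsv, assays.tsv and assignments.tsv to ``directory``."""
    import pathlib

    from .records import write_table

    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    records, assays, assignments = paper_fixture()
    write_table(records, d / "records.tsv")
    write_table(assays, d / "assays.tsv")
    write_table(assignments, d / "assignments.tsv")
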