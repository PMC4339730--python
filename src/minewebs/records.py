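"""Survey records: collected leaves, mine amplification assays, specimens.

One :class:`LeafRecord` describes one collected infested leaf - its host
plant, whether an insect was still inside at collection, what eventually
emerged (or was dissected), and any morphological identifications (of the
emerged adult, and of the mine's shape).  One :class:`MineAssay` describes
one PCR attempt on the residual DNA of that leaf's mine with one primer
pair.  :class:`SpecimenAssignment` carries the molecular identification of a
physical specimen (emerged/dissected insect) from that leaf.

Tables are read and written as TSV through pandas with strict validation;
violations are reported with their row number.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

OUTCOMES = ("miner_adult_emerged", "miner_immature_dissected",
            "parasitoid_emerged", "empty")
ORDERS = ("diptera", "lepidoptera", "hymenoptera", "none")
PRIMERS = ("LCO_HCO", "UNI", "ZBJ")
SPECIMEN_ROLES = ("miner", "parasitoid")


class RecordValidationError(ValueError):
    pass


@dataclass(frozen=True)
class LeafRecord:
    leaf_id: str
    plant: str
    date: str                      # ISO date
    occupied_at_collection: bool
    outcome: str
    insect_order: str = "none"
    morph_id: str | None = None    # adult-specimen morphology
    mine_shape_id: str | None = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise RecordValidationError(
                f"{self.leaf_id}: unknown outcome {self.outcome!r}")
        if self.insect_order not in ORDERS:
            raise RecordValidationError(
                f"{self.leaf_id}: unknown insect_order {self.insect_order!r}")
        if not self.occupied_at_collection and self.outcome != "empty":
            raise RecordValidationError(
                f"{self.leaf_id}: unoccupied leaf must have outcome 'empty'")
        if self.outcome == "parasitoid_emerged" and self.insect_order != "hymenoptera":
            raise RecordValidationError(
                f"{self.leaf_id}: an emerged parasitoid must be hymenoptera")


@dataclass(frozen=True)
class MineAssay:
    leaf_id: str
    primer: str
    success: bool
    assigned_species: str | None = None

    def __post_init__(self) -> None:
        if self.primer not in PRIMERS:
            raise RecordValidationError(
                f"{self.leaf_id}: unknown primer {self.primer!r}")
        if self.assigned_species is not None and not self.success:
            raise RecordValidationError(
                f"{self.leaf_id}/{self.primer}: species assigned to a "
                "failed amplification")


@dataclass(frozen=True)
class SpecimenAssignment:
    leaf_id: str
    role: str                      # miner | parasitoid
    species: str

    def __post_init__(self) -> None:
        if self.role not in SPECIMEN_ROLES:
            raise RecordValidationError(
                f"{self.leaf_id}: unknown specimen role {self.role!r}")


def _load(path, cls, bool_cols=(), optional=()):
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = [f.name for f in fields(cls)]
    missing = set(expected) - set(df.columns)
    if missing:
        raise RecordValidationError(
            f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        kwargs = {}
        for name in expected:
            val = getattr(row, name)
            if name in bool_cols:
                if val not in ("True", "False", "true", "false", "1", "0"):
                    raise RecordValidationError(
                        f"{path} row {row_no}, field {name}: "
                        f"expected a boolean, got {val!r}")
                val = val in ("True", "true", "1")
            elif name in optional and val == "":
                val = None
            kwargs[name] = val
        try:
            out.append(cls(**kwargs))
        except RecordValidationError as exc:
            raise RecordValidationError(f"{path} row {row_no}: {exc}") from exc
    return out


def load_records(path) -> list[LeafRecord]:
    """Load and validate a leaf-record TSV; errors carry row numbers."""
    return _load(path, LeafRecord,
                 bool_cols={"occupied_at_collection"},
                 optional={"morph_id", "mine_shape_id"})


def load_assays(path) -> list[MineAssay]:
    return _load(path, MineAssay, bool_cols={"success"},
                 optional={"assigned_species"})


def load_assignments(path) -> list[SpecimenAssignment]:
    return _load(path, SpecimenAssignment)


def _frame(items) -> pd.DataFrame:
    rows = []
    for it in items:
        row = {}
        for f in fields(it):
            v = getattr(it, f.name)
            row[f.name] = "" if v is None else v
        rows.append(row)
    return pd.DataFrame(rows)


def write_table(items, path) -> None:
    """Write records/assays/assignments back to TSV (round-trip safe)."""
    _frame(items).to_csv(path, sep="\t", index=False)


def summarize_sampling(records: list[LeafRecord]) -> pd.DataFrame:
    """Per-plant counts of occupied vs empty leaves, plus a Total row.

    The two columns partition the records exactly; the Total row equals the
    column sums.
    """
    df = pd.DataFrame(
        {"plant": [r.plant for r in records],
         "occupied": [r.occupied_at_collection for r in records]}
    )
    tab = (
        df.groupby("plant")["occupied"]
        .agg(occupied="sum", total="count")
        .assign(empty=lambda t: t.total - t.occupied)
        [["occupied", "empty"]]
        .astype(int)
        .sort_index()
    )
    tab.loc["Total"] = tab.sum()
    return tab


def summarize_amplification(
    assays: list[MineAssay], records: list[LeafRecord]
) -> pd.DataFrame:
    """Per-primer success counts split by occupied/empty, plus the union.

    The ``Total`` row counts leaves with at least one successful assay of any
    primer, so it is at least the per-primer maximum and at most the
    per-primer sum.  An assay whose leaf is unknown is an error.
    """
    occupied = {r.leaf_id: r.occupied_at_collection for r in records}
    counts = {p: {"occupied": set(), "empty": set()} for p in PRIMERS}
    union = {"occupied": set(), "empty": set()}
    for a in assays:
        if a.leaf_id not in occupied:
            raise RecordValidationError(
                f"assay references unknown leaf {a.leaf_id!r}")
        if a.success:
            key = "occupied" if occupied[a.leaf_id] else "empty"
            counts[a.primer][key].add(a.leaf_id)
            union[key].add(a.leaf_id)
    rows = {p: {k: len(v) for k, v in counts[p].items()} for p in PRIMERS}
    rows["Total"] = {k: len(v) for k, v in union.items()}
    return pd.DataFrame(rows).T[["occupied", "empty"]]
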