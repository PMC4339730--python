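"""Synthetic barcode libraries and survey tables with known ground truth.

Two generators back the test harness and the examples:

* :func:`simulate_library` builds per-species barcode "clouds" around a
  common ancestral COI template.  Species ancestors diverge by draws from an
  interspecific K2P range, conspecifics scatter around their ancestor at a
  target intraspecific divergence, and the three primer-pair binding sites
  (Folmer full barcode; Uni and ZBJ mini-barcodes nested inside it, mutually
  overlapping) are planted intact at fixed template coordinates.

* :func:`simulate_survey` emulates the field study: leaves on host plants,
  an insect that either is still inside at collection (occupied) or has long
  emerged (empty), and per-primer amplification of the residual mine DNA
  whose success decays exponentially with the age of that DNA.  Occupied
  leaves are young (the insect emerged in the lab within the 14-day waiting
  window); empty leaves carry an unknown, longer time since emergence,
  modelled as 14 days plus an exponential tail.  With the default
  amplifiability (p0 = 0.53, lambda = 0.075 per day) the expected success
  rates are about 33% for occupied and 6% for empty leaves - the gradient
  the mini-barcoding approach is designed around.

Substitutions follow a K2P process with transition:transversion ratio 3
(typical for insect COI).  Everything is reproducible from the seed, and the
truth tables are returned separately so they can never leak into pipeline
inputs except through the test harness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .primers import LCO_HCO, UNI, ZBJ
from .records import LeafRecord, MineAssay, SpecimenAssignment
from .sequences import IUPAC_SETS, NucSequence, reverse_complement

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

#: Template coordinates (0-based) at which each primer footprint is planted.
#: The full-barcode insert spans [25, 683) (658 bp); the Uni insert
#: [66, 196) is 130 bp and the ZBJ insert [110, 268) is 158 bp, overlapping
#: the Uni fragment over [110, 196).  Footprint registers are chosen so that
#: no planted footprint carries an in-frame stop codon inside the barcode.
PRIMER_LAYOUT: dict[str, tuple[int, int]] = {
    # pair name -> (forward footprint start, reverse footprint start)
    "LCO_HCO": (0, 683),
    "UNI": (40, 196),
    "ZBJ": (80, 268),
}
TEMPLATE_LENGTH = 709


@dataclass
class SynthConfig:
    """Parameters of the synthetic study; defaults mirror the field design."""

    seed: int
    n_species: int = 10
    n_seqs_per_species: int = 5
    n_queries_per_species: int = 2
    seq_length: int = TEMPLATE_LENGTH
    intra_divergence: float = 0.01        # target conspecific K2P
    inter_divergence: tuple[float, float] = (0.05, 0.10)
    ts_tv_ratio: float = 3.0
    # survey parameters
    n_leaves: int = 407
    occupancy: float = 147 / 407          # share of leaves still occupied
    parasitism: float = 48 / 147          # parasitoid share of occupied leaves
    n_plants: int = 8
    p0: dict[str, float] = field(default_factory=lambda: {
        "union": 0.53, "ZBJ": 0.95, "UNI": 0.90, "LCO_HCO": 0.05})
    lam: float = 0.075                    # amplifiability decay, per day
    uni_age_decay: float = 0.035          # extra length penalty, UNI vs ZBJ
    lco_age_decay: float = 0.2            # full barcode decays much faster
    occupied_age_max: float = 14.0        # days; lab emergence window
    empty_age_offset: float = 14.0        # days; emptied before collection
    empty_age_mean: float = 30.0          # exponential tail beyond the offset

    def __post_init__(self) -> None:
        if self.intra_divergence > self.inter_divergence[0]:
            raise ValueError(
                "interspecific divergence must exceed intraspecific target")
        for v in (self.occupancy, self.parasitism, *self.p0.values()):
            if not 0.0 <= v <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth emitted alongside synthetic data (test harness only)."""

    species_of: dict[str, str] = field(default_factory=dict)   # seq id -> species
    miner_of: dict[str, str] = field(default_factory=dict)     # leaf id -> miner
    parasitoid_of: dict[str, str | None] = field(default_factory=dict)
    age_of: dict[str, float] = field(default_factory=dict)     # leaf -> days


def _instantiate(motif: str) -> str:
    """Resolve degenerate codes in a primer motif to concrete bases.

    Deterministic ('A' when allowed, else first alphabetically); the chosen
    bases keep the planted footprints free of reading-frame stop codons.
    """
    return "".join(
        b if b in "ACGT" else ("A" if "A" in IUPAC_SETS[b]
                               else sorted(IUPAC_SETS[b])[0])
        for b in motif
    )


#: Reading frame of the barcode region: codon boundaries at template
#: positions 25, 28, ... 679 (the full-barcode insert is in frame with
#: itself; both mini-barcode inserts inherit the same frame).
_CODON_START, _CODON_STOP = 25, 680
_STOPS = {"TAA", "TAG"}  # invertebrate mitochondrial code; TGA is Trp


def _repair_stops(bases: list[str], protected: set[int]) -> None:
    """Remove in-frame stop codons from the barcode region, in place.

    Tries the third, then second, then first codon position, skipping
    protected primer-footprint sites; replacement bases are chosen so the
    codon becomes Tyr/Ser/Gln respectively, never a stop.
    """
    for c in range(_CODON_START, _CODON_STOP, 3):
        if "".join(bases[c:c + 3]) not in _STOPS:
            continue
        for offset, repl in ((2, "T"), (1, "C"), (0, "C")):
            if c + offset not in protected:
                bases[c + offset] = repl
                break


def _template_scaffold(length: int, rng: np.random.Generator) -> tuple[list[str], set[int]]:
    """Random template with all six primer footprints planted; returns
    (bases, set of protected positions)."""
    bases = list(rng.choice(list("ACGT"), size=length))
    protected: set[int] = set()
    for pair, (fpos, rpos) in PRIMER_LAYOUT.items():
        p = {"LCO_HCO": LCO_HCO, "UNI": UNI, "ZBJ": ZBJ}[pair]
        fwd = _instantiate(p.forward)
        rev = _instantiate(reverse_complement(p.reverse))
        for i, b in enumerate(fwd):
            bases[fpos + i] = b
            protected.add(fpos + i)
        for i, b in enumerate(rev):
            bases[rpos + i] = b
            protected.add(rpos + i)
    _repair_stops(bases, protected)
    return bases, protected


def _mutate(
    bases: list[str], rate: float, protected: set[int],
    rng: np.random.Generator, ts_tv: float,
) -> list[str]:
    """Per-site K2P substitution at probability ``rate`` outside primer sites.

    The rate is rescaled by the mutable fraction of the template so that the
    realized sequence-wide divergence (computed over all sites, including
    the invariant primer footprints) matches the requested target.
    """
    out = list(bases)
    p_ts = ts_tv / (ts_tv + 1.0)
    mutable = len(out) - len(protected)
    eff = min(1.0, rate * len(out) / mutable) if mutable else 0.0
    for i in range(len(out)):
        if i in protected or rng.random() >= eff:
            continue
        if rng.random() < p_ts:
            out[i] = TRANSITION[out[i]]
        else:
            tv = TRANSVERSIONS[out[i]]
            out[i] = tv[rng.integers(2)]
    _repair_stops(out, protected)
    return out


def simulate_library(
    cfg: SynthConfig,
) -> tuple[list[NucSequence], list[NucSequence], TruthTable]:
    """Reference library + unlabeled queries + truth table.

    Each species gets an ancestor derived from a shared root by half its
    interspecific divergence draw, so heterospecific pairs land inside the
    configured range; conspecifics then scatter by half the intraspecific
    target each.  Primer binding sites are never mutated.
    """
    rng = np.random.default_rng(cfg.seed)
    root, protected = _template_scaffold(cfg.seq_length, rng)
    truth = TruthTable()
    refs: list[NucSequence] = []
    queries: list[NucSequence] = []
    lo, hi = cfg.inter_divergence
    for s in range(cfg.n_species):
        species = f"Species {s + 1:02d}"
        draw = rng.uniform(lo, hi)
        ancestor = _mutate(root, draw / 2.0, protected, rng, cfg.ts_tv_ratio)
        for k in range(cfg.n_seqs_per_species):
            seq = _mutate(ancestor, cfg.intra_divergence / 2.0, protected,
                          rng, cfg.ts_tv_ratio)
            sid = f"REF_{s + 1:02d}_{k + 1:02d}"
            refs.append(NucSequence(sid, "".join(seq), species_label=species,
                                    role="reference", marker="COI_full"))
            truth.species_of[sid] = species
        for k in range(cfg.n_queries_per_species):
            seq = _mutate(ancestor, cfg.intra_divergence / 2.0, protected,
                          rng, cfg.ts_tv_ratio)
            qid = f"QRY_{s + 1:02d}_{k + 1:02d}"
            queries.append(NucSequence(qid, "".join(seq), role="mine_extract",
                                       marker="COI_full"))
            truth.species_of[qid] = species
    return refs, queries, truth


def _primer_success_probs(cfg: SynthConfig, age: float) -> dict[str, float]:
    """Per-primer success probabilities at DNA age ``age`` (days).

    A leaf-level amplifiability gate p0_union * exp(-lambda * age) is shared
    by all primers (one mine, one DNA pool); conditional on an amplifiable
    mine, each primer succeeds with its own probability, penalised by
    amplicon length (UNI slightly, the 658 bp full barcode heavily).
    """
    gate = cfg.p0["union"] * math.exp(-cfg.lam * age)
    return {
        "gate": gate,
        "ZBJ": cfg.p0["ZBJ"],
        "UNI": cfg.p0["UNI"] * math.exp(-cfg.uni_age_decay * age),
        "LCO_HCO": cfg.p0["LCO_HCO"] * math.exp(-cfg.lco_age_decay * age),
    }


def simulate_survey(
    cfg: SynthConfig,
) -> tuple[list[LeafRecord], list[MineAssay], list[SpecimenAssignment], TruthTable]:
    """Synthetic survey: leaf records, mine assays, specimen assignments, truth.

    Occupied leaves draw their DNA age uniformly on [0, occupied_age_max];
    empty leaves add an exponential tail beyond ``empty_age_offset``, so
    their mine DNA is systematically older and amplification success lower -
    the occupied >> empty gradient.  Setting ``lam`` to 0 removes the
    gradient entirely.
    """
    rng = np.random.default_rng(cfg.seed)
    plants = [f"Plant {p + 1:02d}" for p in range(cfg.n_plants)]
    miners = [f"Species {s + 1:02d}" for s in range(cfg.n_species)]
    parasitoids = [f"Parasitoid {s + 1:02d}" for s in range(max(2, cfg.n_species // 2))]
    # each miner species feeds on 1-2 host plants; each parasitoid attacks one miner
    host_of = {m: sorted(rng.choice(plants, size=rng.integers(1, 3), replace=False))
               for m in miners}
    victim_of = {h: miners[i % len(miners)] for i, h in enumerate(parasitoids)}

    records: list[LeafRecord] = []
    assays: list[MineAssay] = []
    assignments: list[SpecimenAssignment] = []
    truth = TruthTable()
    for n in range(cfg.n_leaves):
        leaf = f"SL{n + 1:04d}"
        occupied = bool(rng.random() < cfg.occupancy)
        parasitized = occupied and bool(rng.random() < cfg.parasitism)
        if parasitized:
            parasitoid = parasitoids[rng.integers(len(parasitoids))]
            miner = victim_of[parasitoid]
        else:
            parasitoid = None
            miner = miners[rng.integers(len(miners))]
        plant = host_of[miner][rng.integers(len(host_of[miner]))]
        if occupied:
            age = float(rng.uniform(0.0, cfg.occupied_age_max))
            outcome = ("parasitoid_emerged" if parasitized
                       else ("miner_adult_emerged" if rng.random() < 0.7
                             else "miner_immature_dissected"))
            order = "hymenoptera" if parasitized else "diptera"
        else:
            age = cfg.empty_age_offset + float(rng.exponential(cfg.empty_age_mean))
            outcome, order = "empty", "none"
        records.append(LeafRecord(
            leaf_id=leaf, plant=plant, date="2012-07-15",
            occupied_at_collection=occupied, outcome=outcome,
            insect_order=order))
        truth.miner_of[leaf] = miner
        truth.parasitoid_of[leaf] = parasitoid
        truth.age_of[leaf] = age
        if occupied and not parasitized:
            assignments.append(SpecimenAssignment(leaf, "miner", miner))
        if parasitized:
            assignments.append(SpecimenAssignment(leaf, "parasitoid", parasitoid))
        probs = _primer_success_probs(cfg, age)
        amplifiable = bool(rng.random() < probs["gate"])
        for primer in ("LCO_HCO", "UNI", "ZBJ"):
            ok = amplifiable and bool(rng.random() < probs[primer])
            assays.append(MineAssay(
                leaf_id=leaf, primer=primer, success=ok,
                assigned_species=miner if ok else None))
    return records, assays, assignments, truth
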