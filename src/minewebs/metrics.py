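"""Food-web descriptors: link density, connectance, vulnerability,
generality (qualitative and quantitative), NODF nestedness and Barber
bipartite modularity.

Qualitative descriptors are simple ratios over realized links L and species
counts: link density L/S, vulnerability L/(plants + miners), generality
L/(miners + parasitoids), and connectance defined as link density divided by
S.  "Dashed" plant -> parasitoid links (host unknown) count as links and
their endpoints as nodes by default, with a switch to exclude them.

Quantitative descriptors follow the effective-number (Shannon-entropy)
scheme of Bersier, Banasek-Richter & Cattin (2002): for taxon k with
in-flows b(i,k) and out-flows b(k,j), the effective number of prey is
2^H of the normalized in-flow distribution and the effective number of
consumers the analogue on out-flows; quantitative generality/vulnerability
are the flow-weighted means of those effective numbers, quantitative link
density their average, and quantitative connectance that density over S.

NODF and modularity are computed on the plant x leaf-miner bipartite block
only (every parasitoid here attaches to a single miner, so the upper block
carries no nested/modular signal of its own).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .web import TriPartiteWeb


@dataclass
class BipartiteMatrix:
    """Non-negative interaction weights between two guilds."""

    row_ids: list[str]
    col_ids: list[str]
    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("weight matrix shape does not match id lists")
        if (self.w < 0).any():
            raise ValueError("negative interaction weights")

    @classmethod
    def from_edges(cls, edges: dict[tuple[str, str], int]) -> "BipartiteMatrix":
        rows = sorted({a for a, _ in edges})
        cols = sorted({b for _, b in edges})
        w = np.zeros((len(rows), len(cols)))
        for (a, b), weight in edges.items():
            w[rows.index(a), cols.index(b)] = weight
        return cls(rows, cols, w)


@dataclass
class MetricsReport:
    """The descriptor set for one web (Table-3-style layout)."""

    n_species: int
    n_links: int
    ld_qual: float
    ld_quant: float
    conn_qual: float
    conn_quant: float
    vul_qual: float
    vul_quant: float
    gen_qual: float
    gen_quant: float
    nodf: float
    modularity: float

    ROW_NAMES = (
        ("n_species", "Number of species"),
        ("n_links", "Number of links"),
        ("ld_qual", "Qualitative link density"),
        ("ld_quant", "Quantitative link density"),
        ("conn_qual", "Qualitative connectance"),
        ("conn_quant", "Quantitative connectance"),
        ("vul_qual", "Qualitative vulnerability"),
        ("vul_quant", "Quantitative vulnerability"),
        ("gen_qual", "Qualitative generality"),
        ("gen_quant", "Quantitative generality"),
        ("nodf", "Plant Leaf-miner NODF"),
        ("modularity", "Plant Leaf-miner Modularity"),
    )

    def rows(self) -> list[tuple[str, str]]:
        """(label, value rounded to 3 decimals, half-up) display rows."""
        out = []
        for attr, label in self.ROW_NAMES:
            v = getattr(self, attr)
            if attr in ("n_species", "n_links"):
                out.append((label, str(int(v))))
            else:
                out.append((label, str(Decimal(repr(v)).quantize(
                    Decimal("0.001"), rounding=ROUND_HALF_UP))))
        return out


def round3(x: float) -> float:
    """Round half-up to 3 decimals, as printed in report tables."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"),
                                           rounding=ROUND_HALF_UP))


def qualitative_from_counts(
    n_links: int, n_plants: int, n_miners: int, n_parasitoids: int
) -> dict[str, float]:
    """Qualitative descriptors as arithmetic functions of (S, L) and guild sizes."""
    s = n_plants + n_miners + n_parasitoids
    if s == 0:
        raise ValueError("empty web: no species")
    ld = n_links / s
    return {
        "n_species": s,
        "n_links": n_links,
        "ld_qual": ld,
        "conn_qual": ld / s,
        "vul_qual": n_links / (n_plants + n_miners),
        "gen_qual": n_links / (n_miners + n_parasitoids),
    }


def qualitative_metrics(web: TriPartiteWeb, include_dashed: bool = True) -> dict[str, float]:
    """Qualitative descriptor set of a tri-partite web.

    L counts distinct realized links (plant-miner, miner-parasitoid and,
    unless excluded, dashed plant-parasitoid links); S counts nodes touched
    by those links.
    """
    if include_dashed:
        plants, paras = web.plants, web.parasitoids
    else:
        plants = sorted({p for p, _ in web.pm_edges})
        paras = sorted({h for _, h in web.mp_edges})
    n_links = web.n_links(include_dashed=include_dashed)
    return qualitative_from_counts(n_links, len(plants), len(web.miners),
                                   len(paras))


def _flows(web: TriPartiteWeb, include_dashed: bool) -> list[tuple[str, str, float]]:
    # node names are disambiguated by guild prefix so that an identical label
    # in two guilds (not expected, but possible) cannot alias
    fl = [(f"P:{p}", f"M:{m}", float(w)) for (p, m), w in web.pm_edges.items()]
    fl += [(f"M:{m}", f"H:{h}", float(w)) for (m, h), w in web.mp_edges.items()]
    if include_dashed:
        fl += [(f"P:{p}", f"H:{h}", float(w))
               for (p, h), w in web.dashed_edges.items()]
    return fl


def effective_numbers(flows: list[tuple[str, str, float]]) -> tuple[dict, dict]:
    """Per-taxon effective prey (n_N) and consumer (n_P) counts, 2**H, base 2."""
    inflow: dict[str, dict[str, float]] = {}
    outflow: dict[str, dict[str, float]] = {}
    for res, cons, w in flows:
        if w <= 0:
            continue
        inflow.setdefault(cons, {})[res] = inflow.get(cons, {}).get(res, 0) + w
        outflow.setdefault(res, {})[cons] = outflow.get(res, {}).get(cons, 0) + w

    def eff(d: dict[str, float]) -> float:
        tot = sum(d.values())
        h = -sum((w / tot) * math.log2(w / tot) for w in d.values() if w > 0)
        return 2.0 ** h

    return ({k: eff(v) for k, v in inflow.items()},
            {k: eff(v) for k, v in outflow.items()})


def quantitative_metrics(
    web: TriPartiteWeb, include_dashed: bool = True
) -> dict[str, float]:
    """Effective-number (entropy-based) descriptors of a weighted web.

    Generality is the flow-weighted mean effective number of prey over
    consumers, vulnerability the flow-weighted mean effective number of
    consumers over resources, link density half their sum, and connectance
    that density over S.  Taxa with zero total flow do not enter the
    averages.
    """
    flows = _flows(web, include_dashed)
    if not flows:
        raise ValueError("web carries no positive flows")
    total = sum(w for _, _, w in flows)
    n_n, n_p = effective_numbers(flows)
    in_tot: dict[str, float] = {}
    out_tot: dict[str, float] = {}
    for res, cons, w in flows:
        in_tot[cons] = in_tot.get(cons, 0.0) + w
        out_tot[res] = out_tot.get(res, 0.0) + w
    gen = sum(in_tot[k] * n_n[k] for k in n_n) / total
    vul = sum(out_tot[k] * n_p[k] for k in n_p) / total
    ld = 0.5 * (gen + vul)
    s = qualitative_metrics(web, include_dashed)["n_species"]
    return {
        "gen_quant": gen,
        "vul_quant": vul,
        "ld_quant": ld,
        "conn_quant": ld / s,
    }


def nodf(m: BipartiteMatrix, scale: str = "unit") -> float:
    """Nestedness by overlap and decreasing fill of the binary matrix.

    For every ordered pair of rows (and of columns) whose first member has
    strictly greater marginal fill, the paired overlap is the fraction of the
    sparser profile's presences shared by the fuller one; pairs with equal
    fill contribute zero.  NODF is the mean over all row pairs and column
    pairs, on a 0-1 scale by default (``scale="percent"`` gives the
    conventional 0-100).
    """
    b = (m.w > 0).astype(int)
    nr, nc = b.shape
    if nr < 2 and nc < 2:
        raise ValueError("NODF undefined for a matrix with <2 rows and <2 columns")

    def pair_terms(mat: np.ndarray) -> list[float]:
        fills = mat.sum(axis=1)
        terms = []
        for i, j in itertools.combinations(range(mat.shape[0]), 2):
            hi, lo = (i, j) if fills[i] > fills[j] else (j, i)
            if fills[hi] == fills[lo] or fills[lo] == 0:
                terms.append(0.0)
            else:
                shared = int(np.minimum(mat[hi], mat[lo]).sum())
                terms.append(shared / fills[lo])
        return terms

    terms = pair_terms(b) + pair_terms(b.T)
    val = float(np.mean(terms)) if terms else 0.0
    return val * 100.0 if scale == "percent" else val


def barber_modularity_q(
    m: BipartiteMatrix, row_modules: np.ndarray, col_modules: np.ndarray
) -> float:
    """Barber's bipartite modularity Q for a given module assignment."""
    w = m.w
    f = w.sum()
    if f <= 0:
        raise ValueError("all-zero matrix")
    k = w.sum(axis=1)
    d = w.sum(axis=0)
    same = row_modules[:, None] == col_modules[None, :]
    return float(((w - np.outer(k, d) / f) * same).sum() / f)


def bipartite_modularity(
    m: BipartiteMatrix, seed: int = 0, n_restarts: int = 20, n_sweeps: int = 50
) -> tuple[float, dict[str, int]]:
    """Maximise Barber's Q by seeded greedy label moving with restarts.

    Returns the best Q found and the module id per node (row and column ids
    share one label space).  The search is deterministic for a given seed.
    """
    w = m.w
    if w.sum() <= 0:
        raise ValueError("all-zero matrix")
    nr, nc = w.shape
    n_modules = max(nr, nc)
    rng = np.random.default_rng(seed)
    best_q, best = -np.inf, None
    for restart in range(n_restarts):
        if restart == 0:
            rows = np.arange(nr) % n_modules
            cols = np.argmax(w, axis=0) % n_modules
        else:
            rows = rng.integers(0, n_modules, size=nr)
            cols = rng.integers(0, n_modules, size=nc)
        for _ in range(n_sweeps):
            moved = False
            for i in range(nr):
                qs = [barber_modularity_q(m, np.where(
                    np.arange(nr) == i, g, rows), cols) for g in range(n_modules)]
                g = int(np.argmax(qs))
                if g != rows[i] and qs[g] > qs[rows[i]] + 1e-12:
                    rows[i] = g
                    moved = True
            for j in range(nc):
                qs = [barber_modularity_q(m, rows, np.where(
                    np.arange(nc) == j, g, cols)) for g in range(n_modules)]
                g = int(np.argmax(qs))
                if g != cols[j] and qs[g] > qs[cols[j]] + 1e-12:
                    cols[j] = g
                    moved = True
            if not moved:
                break
        q = barber_modularity_q(m, rows, cols)
        if q > best_q:
            best_q, best = q, (rows.copy(), cols.copy())
    rows, cols = best
    labels = {rid: int(g) for rid, g in zip(m.row_ids, rows)}
    labels.update({cid: int(g) for cid, g in zip(m.col_ids, cols)})
    return best_q, labels


def metrics_report(
    web: TriPartiteWeb, seed: int = 0, include_dashed: bool = True,
    nodf_scale: str = "unit",
) -> MetricsReport:
    """Full descriptor set for one web (NODF/modularity on the plant-miner block)."""
    qual = qualitative_metrics(web, include_dashed)
    quant = quantitative_metrics(web, include_dashed)
    pm = BipartiteMatrix.from_edges(web.pm_edges)
    q, _ = bipartite_modularity(pm, seed=seed)
    return MetricsReport(
        n_species=int(qual["n_species"]),
        n_links=int(qual["n_links"]),
        ld_qual=qual["ld_qual"],
        ld_quant=quant["ld_quant"],
        conn_qual=qual["conn_qual"],
        conn_quant=quant["conn_quant"],
        vul_qual=qual["vul_qual"],
        vul_quant=quant["vul_quant"],
        gen_qual=qual["gen_qual"],
        gen_quant=quant["gen_quant"],
        nodf=nodf(pm, scale=nodf_scale),
        modularity=q,
    )
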