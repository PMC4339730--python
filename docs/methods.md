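# Methods

This note documents the models, parameter choices and numerical conventions
behind `minewebs`, and what the synthetic data can and cannot demonstrate.

## Sequence model and in-silico PCR

Sequences are IUPAC DNA strings; two codes match when their base sets
intersect, so degenerate primer positions (R, W, …) accept every base they
encode at zero mismatch cost.  Primer-pair location uses an exhaustive scan:
the leftmost forward site within the mismatch budget wins, paired with the
nearest valid reverse-complement site strictly downstream.  The default
budget is **2 mismatches per primer** — a compromise between the
permissiveness of degenerate-primer PCR on diverse insect templates and the
false-priming risk of looser thresholds.  The reported amplicon is the
insert *between* the primer footprints: primer-derived bases reflect the
oligonucleotide, not the template, and would otherwise flatten apparent
divergence at the fragment ends.  Coordinates are 0-based, half-open
everywhere; only human-readable logs may print 1-based positions.

Translation QC translates all three forward frames under the invertebrate
mitochondrial code (NCBI table 5, the standard for insect COI) and reports
the frame with fewest stop codons; any residual stop marks the sequence as
a suspected frameshift/pseudogene (NUMT).  Codons containing ambiguity
codes translate to X and never count as stops — degraded-template
sequencing should not fail QC for an N.

## Distances, trees, clusters

K2P distances use **pairwise deletion**: a site is excluded for a pair when
either sequence carries anything outside A/C/G/T.  (Whether complete or
pairwise deletion is used upstream of published distance tables is often
unstated; pairwise deletion wastes no sites and is this package's
convention.)  When `1-2P-Q ≤ 0` or `1-2Q ≤ 0` the logarithms are undefined:
such saturated pairs are recorded as *missing* (NaN) and are never imputed
— downstream, clustering treats them as "further than any threshold" and
neighbor-joining refuses incomplete matrices outright.

Maximum-likelihood tree inference is deliberately replaced by
**neighbor-joining plus single-linkage threshold clustering**: every use of
trees here (cluster membership, divergence visualisation) depends only on
topology and path lengths, which NJ recovers exactly on additive matrices,
and the result is deterministic and dependency-free.  Negative NJ branch
estimates are clamped to zero with the deficit moved to the sibling branch,
preserving path lengths through the joined pair.  Ties in the Q-criterion
go to the lexicographically first pair, making the tree reproducible.

The default cluster threshold **t = 0.03 substitutions/site** sits in the
COI "barcode gap": conspecific divergence in this system is ≤ ~0.03 and
congeneric divergence ≥ ~0.05.  It is a configuration value, not a claim
about universal species limits; cluster labels are numbered by smallest
member id so the naming is input-order invariant, and clusters containing
a reference-identified member inherit that species name.

## Consensus identification

Remote search engines are emulated by one local best-identity search run
against two configurable libraries (a broad one and a curated one), which
makes identification reproducible and testable offline.  The cascade:

1. broad-library identity ≥ **96%** with no disagreeing method → accept;
2. else curated-library similarity ≥ **99.45%**, cluster-consistent →
   accept;
3. else a multi-member cluster → cluster-rank label;
4. else unidentified.

The two thresholds default to the empirical decision boundaries of the
motivating study and are parameters, not constants.  Identities below an
**85% floor** are withheld entirely (a best hit at 70% identity is a
family-level statement at best).  Two methods confidently naming different
species raise an exception — conflicts demand manual review and are never
silently resolved.  A genus-rank assignment (`Chromatomyia sp`) is treated
as an ordinary label supplied by the data rather than produced by an
automated fallback rule.

## Web assembly

A leaf contributes to the web according to the evidence mode.  Molecular
mode: the sequenced specimen's barcode identifies the miner when one was
obtained; otherwise the mine assay does, with primer precedence
**ZBJ > UNI > full barcode** when several succeed (ZBJ had the best
amplification success on degraded templates; an inter-primer disagreement
flags the leaf and excludes it, with a log entry).  Morphological mode uses
adult morphology, then the mine-shape identification, and never assay data;
taxa morphology cannot separate are collapsed (by default the three
*Chromatomyia* leaf miners into one aggregate and the four cryptic
Braconidae clusters into another).  Collapsing is exposed separately as a
quotient operation (`collapse_web`) that conserves total edge weight.

Edge weights are **leaf counts**, not specimen counts — one mine can hold
several larvae, and the leaf is the sampling unit.  A parasitoid whose host
mine could not be identified contributes a "dashed" plant → parasitoid
edge; dashed links count as links and their endpoints as nodes by default
(they are real observed interactions), with a switch to exclude them.
Genus-rank taxa are kept as distinct nodes rather than merged into a
congener, which is conservative for link counts.

## Descriptors

Qualitative: with L realized links and S species, link density L/S,
vulnerability L/(plants + miners), generality L/(miners + parasitoids), and
connectance defined as link density over S (the convention of the
descriptor set this package mirrors).  Quantitative descriptors follow the
effective-number scheme of Bersier, Banasek-Richter & Cattin (2002):
per-taxon effective prey/consumer counts are `2^H` of the normalized
in-/out-flow distributions (entropy base 2), and the web-level descriptors
are **flow-weighted** means of those effective numbers; quantitative link
density is their average and quantitative connectance that density over S.
Under uniform weights each effective number equals the realized partner
count, so the quantitative descriptors collapse to weighted averages of
qualitative degrees — a property the tests assert.

NODF uses the paired-overlap/decreasing-fill formula on the binary
plant × miner matrix; pairs with equal marginal fill contribute zero.  It
is reported on a **0–1 scale** by default (a `percent` flag gives the
conventional 0–100) to match the scale on which comparable published
tables print it.  Modularity is Barber's bipartite Q maximised by seeded
greedy label-moving with 20 restarts — the published analysis named only
the R package used, not the algorithm, so this optimiser is a declared
substitution; correctness is asserted through closed-form cases (two equal
disconnected blocks give Q = ½ exactly) and dominance over random
partitions, not through reproducing any particular published Q value.
Display rounding is 3 decimals, half-up.

## Synthetic data

`simulate_library` grows per-species barcode clouds around one ancestral
template: species ancestors diverge from a shared root by half a draw from
the interspecific range (heterospecific pairs then land inside the range),
conspecifics scatter by half the intraspecific target.  Substitutions
follow a K2P process with transition:transversion ratio 3 (typical for
insect COI).  Primer binding sites are planted at fixed coordinates — the
full-barcode insert spans 658 bp, the Uni insert 130 bp, the ZBJ insert
158 bp overlapping it — and are excluded from mutation; the per-site rate
is rescaled by the mutable fraction so realized sequence-wide divergence
hits the target.  A reading frame across the barcode region is kept free
of stop codons (repairs avoid primer footprints), so simulated fragments
behave like genuine coding COI under translation QC.

`simulate_survey` emulates the field design: 407 leaves, occupancy
147/407, parasitism 48/147 among occupied leaves.  The mechanism of
interest is DNA age: occupied leaves draw an age uniform on 0–14 days (the
rearing window within which emergence was observed), empty leaves
14 days + Exponential(mean 30) — emergence preceded collection by an
unknown, longer time.  Amplifiability is a shared per-leaf gate
`p0 · exp(-λ · age)` with p0 = 0.53 and λ = 0.075/day, chosen so the
expected union success is ≈ 33% for occupied and ≈ 6% for empty leaves —
the observed field gradient the generator must emulate.  (A model in which
empty leaves have no age offset cannot produce a 6/33 ratio for any λ:
with U(0, 14) and Exp(30) ages the ratio is bounded below by about 0.43;
the offset is the mechanistically honest fix.)  Conditional on an
amplifiable mine, each primer succeeds with its own probability, penalised
by amplicon length (the 658 bp full barcode most strongly), reproducing
the ZBJ > Uni ≫ full-barcode ordering.

What passing simulation tests shows — and does not.  The generator
produces clean co-aligned fragments, perfect reference labels and
error-free assay identifications; it does not simulate alignment error,
chimeras, NUMTs, contamination, heteroplasmy or misidentified vouchers.
Tests on it therefore validate the *pipeline logic* (extraction, distance
arithmetic, clustering, consensus rules, web assembly, descriptor
algebra), not robustness to real-world sequence artefacts.

## The study fixture

The published survey's specimen-level table is not printed, only marginal
summaries.  `fixture.paper_fixture()` therefore encodes one deterministic
specimen-level arrangement consistent with every printed marginal: the
per-plant occupied/empty counts (147/260), the per-primer amplification
table (2/39/46 occupied, 0/3/15 empty, unions 48/15), the specimen
composition (68 + 21 + 10 + 48), the fifteen identified empty-leaf mines,
the 15-of-48 parasitoid host resolutions, and the guild sizes and link
counts implied by the published qualitative descriptors (molecular
16/16/8 nodes and 29 links, morphological 16/14/5 and 23 links).  Which
individual leaf carries which species — and which adults were
morphologically identifiable — is invented, deterministic and documented
in the source; only the marginals are asserted as reproduced.  In
particular the quantitative descriptors, NODF and modularity of the
fixture webs depend on the invented weight distribution and are *not*
expected to match published values; they are validated by the
property-based checks instead.

## Numerical conventions and edge cases

* Saturated distances: missing, never imputed; clustering treats them as
  super-threshold, NJ rejects them.
* Singleton species: intraspecific range *undefined* (`None`), never 0.
* Zero-flow taxa are excluded from quantitative averages; an all-zero
  matrix is an error for NODF/modularity.
* All stochastic components (generator, modularity restarts) take explicit
  seeds; identical seeds give byte-identical outputs.
* Problem sizes used by the test-suite simulations (10 species × 5
  sequences, surveys of 300–2000 leaves, 25 replicate surveys in the
  acceptance script) were chosen as the smallest scales at which the
  binomial error bands around the emulated rates are informative.

## Known limitations

* No multiple sequence alignment: inputs are assumed co-aligned or
  locatable sub-fragments (ungapped sliding identity).
* The greedy modularity optimiser is exact only on the small matrices
  typical of these webs; no global optimality guarantee.
* Bootstrap support, ML model selection and null-model significance tests
  for nestedness/modularity are out of scope.
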