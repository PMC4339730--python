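# minewebs

Molecular resolution of plant – leaf miner – parasitoid interactions:
COI (mini-)barcoding of leaf-mine residues and tri-partite food-web
analysis.

## The problem

Leaf-mining insects (mostly agromyzid flies and small moths) and their
hymenopteran parasitoids are hard to place in ecological networks: adults
are difficult to rear and identify, many taxa are cryptic, and a large
fraction of field-collected mines are already empty.  The feeding tunnel,
however, retains shed cells and frass of the miner, so a short **COI
mini-barcode** (~130 bp, amplifiable from degraded DNA) can identify the
insect even after it has left — turning unusable leaves into interaction
records and letting a parasitoid that emerged from a mine be linked to its
actual host.

`minewebs` implements that workflow end to end for ecologists working with
survey tables and barcode libraries:

* **in-silico PCR** for the Folmer full barcode (LCO1490/HCO2198) and the
  Uni-Minibar and ZBJ-Art mini-barcode pairs (degeneracy-aware matching,
  configurable mismatch budget), with translation QC under the invertebrate
  mitochondrial code to flag frameshifts and pseudogenes;
* **K2P distances** with pairwise deletion
  (`d = -½·ln(1-2P-Q) - ¼·ln(1-2Q)` for transition/transversion
  proportions P, Q), divergence summaries, neighbor-joining trees and
  single-linkage **threshold clustering** (default t = 0.03
  substitutions/site) for delimiting cryptic lineages;
* **consensus identification** against local reference libraries: accept a
  best hit at ≥ 96% identity; below that, accept a curated-library match at
  ≥ 99.45% when the query's distance cluster agrees; fall back to cluster
  labels (`Braconidae sp. 2`) for taxa absent from the libraries;
* **tri-partite web assembly** from leaf records, mine assays and specimen
  barcodes, in a *molecular* mode (barcode taxa kept distinct) and a
  *morphological* mode (adult morphology / mine shapes, with
  morphologically inseparable taxa collapsed), including "dashed"
  plant → parasitoid links when the intermediate host is unknown;
* **web descriptors**: qualitative link density L/S, connectance,
  vulnerability and generality; their quantitative (effective-number,
  Shannon-entropy `2^H`) counterparts; NODF nestedness and Barber
  bipartite modularity of the plant × miner block;
* a **synthetic-data generator** (barcode clouds with controlled intra- and
  interspecific divergence; surveys whose amplification success decays
  exponentially with time since emergence) and a deterministic **study
  fixture** encoding the published survey's marginal counts.

## Worked example

```bash
python examples/04_study_webs_and_metrics.py
```

prints (abridged):

```
collected leaves: 147 occupied, 260 already empty
mine amplification successes (union): 48 occupied (32.65%), 15 empty (5.77%)

descriptor                          molecular  morphological
Number of species                          40             35
Number of links                            29             23
Qualitative link density                0.725          0.657
Qualitative connectance                 0.018          0.019
Qualitative vulnerability               0.906          0.767
Qualitative generality                  1.208          1.211
```

One third of occupied-leaf mines but only ~6% of already-empty mines
amplify — the DNA-degradation gradient that motivates the mini-barcode.
The molecular web resolves more taxa (cryptic parasitoid clusters, empty-
leaf identifications) and more links than the morphology-only web, raising
link density and vulnerability; generality and connectance barely move.
The remaining examples cover mini-barcode extraction and QC, distances /
clustering / trees, consensus identification, and a fully simulated survey
with known ground truth.

A thin CLI mirrors the stages:

```bash
minewebs fixture --out study/
minewebs metrics --records study/records.tsv --assays study/assays.tsv \
                 --assign study/assignments.tsv --mode molecular
minewebs run                    # both webs side by side
```

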