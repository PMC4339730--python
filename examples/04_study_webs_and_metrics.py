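"""Build both food webs from the study fixture and print their descriptors.

The deterministic fixture encodes the field study's 407 collected leaves,
their mine assays and specimen identifications.  The molecular web keeps
barcode-delimited taxa (including the four cryptic parasitoid clusters)
distinct; the morphological web uses adult morphology / mine shapes and
collapses taxa morphology cannot separate.
"""

from minewebs import build_web, metrics_report, paper_fixture
from minewebs.records import summarize_amplification, summarize_sampling

records, assays, assignments = paper_fixture()

tab = summarize_sampling(records)
amp = summarize_amplification(assays, records)
print(f"collected leaves: {tab.loc['Total', 'occupied']} occupied, "
      f"{tab.loc['Total', 'empty']} already empty")
print(f"mine amplification successes (union): "
      f"{amp.loc['Total', 'occupied']} occupied "
      f"({100 * amp.loc['Total', 'occupied'] / 147:.2f}%), "
      f"{amp.loc['Total', 'empty']} empty "
      f"({100 * amp.loc['Total', 'empty'] / 260:.2f}%)\n")

reports = {}
for mode in ("molecular", "morphological"):
    web = build_web(records, assays, assignments, mode)
    reports[mode] = metrics_report(web, seed=0)

print(f"{'descriptor':34s} {'molecular':>10s} {'morphological':>14s}")
mol = dict(reports["molecular"].rows())
mor = dict(reports["morphological"].rows())
for label in mol:
    print(f"{label:34s} {mol[label]:>10s} {mor[label]:>14s}")

# The molecular web resolves more species and links (cryptic parasitoid
# clusters, mine-DNA identifications of empty leaves), which raises link
# density and vulnerability relative to the morphology-only web.
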