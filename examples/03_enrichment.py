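"""Test whether a focal gene set is enriched on microchromosomes.

First reproduces the exact Fisher test on a published-style 2x2 table
(47 venom-related genes, 27 of them on MICs, against 2,602 other anchored
genes), then runs the full anchoring pipeline — synteny markers -> scaffolds
-> genes — on synthetic data with a known enrichment odds ratio.
"""

from venomkit import (
    ContingencyTable,
    anchor_genes,
    enrichment_report,
    fisher_exact_two_sided,
)
from venomkit.simulate import AnchoringConfig, generate_anchoring_data

# --- published-style table ---------------------------------------------------
table = ContingencyTable(27, 20, 837, 1765)
p = fisher_exact_two_sided(table)
print(f"focal MIC fraction : {table.a}/{table.a + table.b} "
      f"({100 * table.a / (table.a + table.b):.0f}%)")
print(f"other MIC fraction : {table.c}/{table.c + table.d} "
      f"({100 * table.c / (table.c + table.d):.0f}%)")
print(f"two-sided Fisher p : {p:.4f}")

# --- synthetic anchoring with true odds ratio 5 ------------------------------
data = generate_anchoring_data(
    AnchoringConfig(seed=3, n_focal=47, n_other=2602, odds_ratio=5.0,
                    marker_density=0.8)
)
assignments = anchor_genes(
    data.gene_scaffold_map, data.scaffold_marker_hits, data.marker_table
)
anchored_focal = [g for g in data.focal_ids if g in assignments]
result = enrichment_report(assignments, anchored_focal)
print(f"\nsynthetic run      : {len(assignments)} genes anchored "
      f"({len(anchored_focal)} focal)")
print(f"focal vs other MIC : {result.focal_mic_percent}% vs "
      f"{result.other_mic_percent}%")
print(f"odds ratio         : {result.odds_ratio:.2f}")
print(f"two-sided Fisher p : {result.p_two_sided:.2e}")
# With a true odds ratio of 5 the focal set sits mostly on microchromosomes
# and the exact test rejects decisively; at odds ratio 1 it rejects at the
# nominal 5% rate (see the calibration in the test suite).
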