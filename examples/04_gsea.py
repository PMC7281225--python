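"""Gene-set enrichment between CYT-high and CYT-low samples.

Genes are ranked by signal-to-noise; each set's enrichment score is the
signed extremum of the weighted hit/miss running sum; significance comes
from a permutation null. The planted immune program (all heat-loaded genes)
should reach a large positive ES; decoy sets should not.
"""

from immunocyt import (
    APOBEC3_PANEL,
    CHECKPOINT_PANEL,
    GeneSet,
    build_score_frame,
    default_config,
    generate_cohort,
    gsea_collection,
)
from immunocyt.gsea import gsea_table

cohort = generate_cohort(default_config(n_samples=371, seed=0))
frame = build_score_frame(cohort.expression)

planted = GeneSet(
    "IMMUNE_PROGRAM", "all heat-loaded genes",
    frozenset(("GZMA", "PRF1", "HLA-A", "HLA-B")
              + APOBEC3_PANEL.members + CHECKPOINT_PANEL.members),
)
decoys = [
    GeneSet(f"DECOY_SET_{k}", "unloaded genes",
            frozenset(f"DECOY{i:04d}" for i in range(30 * k - 29, 30 * k + 1)))
    for k in (1, 2)
]

results = gsea_collection(
    cohort.expression, frame.groups("cyt"), [planted, *decoys],
    n_perm=1000, perm_mode="gene_set", seed=0,
)
table = gsea_table(results).drop(columns="leading_edge")
print(table.round(3).to_string(index=False))
print(
    "\nES near +1 with tiny nominal p marks the planted program as enriched "
    "at the top of the CYT-high ranking; decoy sets stay near the null. "
    "NES rescales ES by the mean |null ES| so sets of different sizes are "
    "comparable; fdr_q pools all sets' normalized nulls."
)
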