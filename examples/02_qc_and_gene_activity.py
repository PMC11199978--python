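"""Per-cell ATAC quality metrics, cell filtering and gene-activity counting.

Nucleosome signal is the ratio of mononucleosomal (147-294 bp) to
sub-nucleosomal (< 147 bp) fragments; TSS enrichment compares per-base
fragment coverage around transcription start sites with distal flanks. All
filter inequalities are strict. Gene activity counts fragments overlapping
the gene body extended 2 kb upstream, giving an ATAC-side proxy for
expression.
"""
import numpy as np

from rootlink import (
    SimConfig,
    compute_nucleosome_signal,
    compute_tss_enrichment,
    filter_cells,
    gene_activity_matrix,
    generate_multiome,
)

sim = generate_multiome(SimConfig(n_cells_per_condition=300, seed=7))
barcodes = sim.multiome.barcodes

# recompute the QC metrics from the raw fragments
ns = compute_nucleosome_signal(sim.fragments, barcodes)
tss = compute_tss_enrichment(sim.fragments, sim.genes, barcodes)
print(f"nucleosome signal: median {np.median(ns[np.isfinite(ns)]):.3f}")
print(f"TSS enrichment:    median {np.median(tss[np.isfinite(tss)]):.3f}")

kept = filter_cells(sim.cell_table)
print(f"cells passing QC: {len(kept)} / {len(sim.cell_table)}")

activity = gene_activity_matrix(sim.fragments, sim.genes, barcodes)
print(f"gene activity matrix: {activity.shape[0]} genes x {activity.shape[1]} cells, "
      f"mean per-cell total {activity.sum(axis=0).mean():.0f}")
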