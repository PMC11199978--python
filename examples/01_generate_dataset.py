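"""Generate a paired snRNA + snATAC dataset and look around.

The generator simulates root-tip nuclei from two growth conditions (control
and osmotic stress) with ~15 RNA-defined cell types, a planted set of
cCRE-gene links (some active in both conditions, some only under stress) and
a planted subset of "primed" initial cells whose chromatin borrows a
differentiated lineage's accessibility program. The ground truth travels with
the dataset, so every downstream inference can be scored.
"""
from pathlib import Path

from rootlink import SimConfig, generate_multiome, write_dataset

cfg = SimConfig(n_cells_per_condition=500, seed=42)
sim = generate_multiome(cfg)

mm = sim.multiome
print(f"RNA matrix:  {mm.rna.shape[0]} genes x {mm.rna.shape[1]} cells")
print(f"ATAC matrix: {mm.atac.shape[0]} peaks x {mm.atac.shape[1]} cells")
print(f"fragment records: {len(sim.fragments.start):,}")

print("\ncells per condition and type (first rows):")
print(sim.cell_table.groupby(["condition", "rna_label"]).size().head(8))

print("\nplanted links by scope:")
print(sim.truth.links["scope"].value_counts())
print(f"planted primed initials: {len(sim.truth.primed)}")

out = Path("example_dataset")
write_dataset(sim, out)
print(f"\nwrote 10x-style triplets, BED/GTF annotation and fragments to {out}/")
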