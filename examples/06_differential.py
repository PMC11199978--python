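"""Differential expression and differential accessibility between conditions.

Expression uses a per-gene two-sided Wilcoxon rank-sum test on
library-normalized values with Benjamini-Hochberg adjustment. Accessibility
uses a per-peak logistic-regression likelihood-ratio test on binarized
detection with the per-cell total count as a latent covariate, which absorbs
depth differences that would otherwise masquerade as biology.
"""
import numpy as np

from rootlink import SimConfig, generate_multiome, lr_dacr, wilcoxon_de

sim = generate_multiome(SimConfig(n_cells_per_condition=300, seed=3))
cond = sim.cell_table["condition"].to_numpy()
stress = np.nonzero(cond == "stress")[0]
control = np.nonzero(cond == "control")[0]

de = wilcoxon_de(sim.multiome.rna, stress, control,
                 gene_names=[g.gene_id for g in sim.genes])
print(f"genes passing (|log2FC| >= 0.25, adj. p < 0.05): {int(de['pass'].sum())} / {len(de)}")
print(de[de["pass"]].nlargest(5, "log2fc")[["gene", "log2fc", "adjusted_p"]].to_string(index=False))

# differential accessibility on a subset of peaks to keep the example quick
peak_names = [p.name for p in sim.multiome.peaks]
dacr = lr_dacr(sim.multiome.atac[:100], stress, control, peak_names=peak_names[:100])
print(f"\npeaks tested: {len(dacr)}, passing: {int(dacr['pass'].sum())}")
print(dacr.nsmallest(3, "p_value")[["peak", "log2fc", "adjusted_p"]].to_string(index=False))
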